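"""Long-term synaptic plasticity of the two-compartment neuron.

The excitatory rule combines, per compartment, a BCM term (Hebbian with a
sliding threshold proportional to the squared running-mean activity) with a
coincidence term proportional to the product of somatic and dendritic
activity.  The relative weight of the coincidence term is ``alpha``: for
``alpha = 0`` each compartment performs independent PCA-like BCM learning;
for large ``alpha`` the pair of compartments extracts mutually correlated
input components, an operation analogous to canonical correlation analysis
(CCA).  Dendrite-targeting inhibitory synapses follow the same functional
form with a fixed threshold.

Weight changes are not applied instantaneously: a second-order dynamics
low-pass filters the instantaneous update with time constant ``tau_w``, and
the weights themselves additionally decay slowly and fluctuate with small
Gaussian noise.  Weights are clipped at zero and recurrent self-connections
are held at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlasticityParams",
    "PlasticityState",
    "WeightSet",
    "make_plasticity_state",
    "two_compartment_update_terms",
    "inhibitory_update_term",
    "alt_activities",
    "alt_calcium_bcm_terms",
    "update_moving_thresholds",
    "step_weight_dynamics",
    "objective_value",
    "objective_value_fixed_thresholds",
]


@dataclass
class PlasticityParams:
    """Learning-rule parameters.

    alpha
        Relative weight of the coincidence (CCA-like) term, in [0, 1].
    eta, eta_inh
        Learning rates of excitatory and dendritic-inhibitory synapses.
    c0
        Scale of the sliding threshold, theta = c0 * E^2.
    theta_inh
        Fixed threshold of the inhibitory rule.
    tau_w
        Time constant (ms) of the delayed second-order weight change.
    eta_decay
        Passive weight decay rate (1/ms).
    sigma_w
        Standard deviation of the spontaneous weight fluctuation per
        sqrt(ms).
    tau_mean
        Time constant (ms) of the running-mean activity used by the
        sliding threshold.
    """

    alpha: float = 0.5
    eta: float = 1.0
    eta_inh: float = 1.0
    c0: float = 70.0
    theta_inh: float = 0.5
    tau_w: float = 1000.0
    eta_decay: float = 1e-7
    sigma_w: float = 0.001
    tau_mean: float = 60000.0

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha)
        if np.any(a < 0) or np.any(a > 1):
            raise ValueError("alpha must lie in [0, 1]")
        if self.tau_w <= 0 or self.tau_mean <= 0:
            raise ValueError("time constants must be positive")
        if self.eta_decay < 0:
            raise ValueError("eta_decay must be non-negative")


@dataclass
class PlasticityState:
    """Second-order weight-change variables, running means, and thresholds."""

    dw_som: np.ndarray
    dw_dnd: np.ndarray
    dv_dnd: np.ndarray | None
    E_som: np.ndarray
    E_dnd: np.ndarray
    theta_som: np.ndarray
    theta_dnd: np.ndarray


@dataclass
class WeightSet:
    """Synaptic weights of one cell or one network.

    ``w_som``: somatic (recurrent or external) excitatory weights;
    ``w_dnd``: dendritic excitatory weights; ``v_dnd``: plastic dendritic
    inhibitory weights; ``v_som``: fixed somatic inhibitory weight(s).
    When ``recurrent`` is set, ``w_som`` is square and its diagonal is
    pinned at zero.
    """

    w_som: np.ndarray
    w_dnd: np.ndarray
    v_dnd: np.ndarray | None = None
    v_som: float | np.ndarray = 0.0
    recurrent: bool = False

    def __post_init__(self) -> None:
        if self.recurrent:
            if self.w_som.shape[0] != self.w_som.shape[1]:
                raise ValueError("recurrent weight matrix must be square")
            np.fill_diagonal(self.w_som, 0.0)


def make_plasticity_state(shape_som, shape_dnd, shape_v=None,
                          neuron_shape=()) -> PlasticityState:
    """Zero-initialised state: dw = 0, running means 0, thresholds 0.

    Zero initial thresholds are maximally permissive for early LTP.
    """
    z = np.zeros
    return PlasticityState(
        dw_som=z(shape_som), dw_dnd=z(shape_dnd),
        dv_dnd=None if shape_v is None else z(shape_v),
        E_som=z(neuron_shape), E_dnd=z(neuron_shape),
        theta_som=z(neuron_shape), theta_dnd=z(neuron_shape),
    )


def _times_trace(g, I):
    """Multiply a per-neuron prefactor with per-source traces.

    Two 1-D arrays form an outer product (neurons x sources); otherwise the
    trace broadcasts against ``g[..., None]`` (e.g. batched single cells).
    """
    g = np.asarray(g, dtype=float)
    I = np.asarray(I, dtype=float)
    if g.ndim == 0 or I.ndim == 0:
        return g * I
    if g.ndim == 1 and I.ndim == 1:
        return np.outer(g, I)
    if I.ndim == g.ndim + 1:
        # shared leading axes (e.g. time or trial), per-source trailing axis
        return g[..., None] * I
    # per-unit prefactor times shared traces (e.g. (trials, cells) x
    # (trials, sources) -> (trials, cells, sources))
    return g[..., None] * I[..., None, :]


def two_compartment_update_terms(x, y, theta_som, theta_dnd, I_som, I_dnd,
                                 p: PlasticityParams):
    """Instantaneous update targets of the combined BCM + coincidence rule.

    somatic:   eta * [(1-alpha) x (x - theta_som) + alpha x y] (1-x) I_som
    dendritic: eta * [(1-alpha) y (y - theta_dnd) + alpha x y] (1-y) I_dnd
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a = p.alpha
    xy = x * y
    g_som = p.eta * ((1.0 - a) * x * (x - theta_som) + a * xy) * (1.0 - x)
    g_dnd = p.eta * ((1.0 - a) * y * (y - theta_dnd) + a * xy) * (1.0 - y)
    return _times_trace(g_som, I_som), _times_trace(g_dnd, I_dnd)


def inhibitory_update_term(x, y, I_inh, p: PlasticityParams):
    """Update target of dendritic inhibitory synapses.

    eta_inh * [(1-alpha) y (y - theta_inh) + alpha x y] (1-y) I_inh
    with a fixed threshold ``theta_inh``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    g = p.eta_inh * ((1.0 - p.alpha) * y * (y - p.theta_inh)
                     + p.alpha * x * y) * (1.0 - y)
    return _times_trace(g, I_inh)


def alt_activities(x, y, alpha_som, alpha_dnd):
    """Effective calcium-like activities of the alternative BCM rule.

    z_som = (1-alpha_som) x + alpha_som x y and the dendritic analogue; the
    coincidence product enters the activity rather than adding a separate
    always-LTP term.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xy = x * y
    return (1.0 - alpha_som) * x + alpha_som * xy, (1.0 - alpha_dnd) * y + alpha_dnd * xy


def alt_calcium_bcm_terms(x, y, theta_som, theta_dnd, I_som, I_dnd,
                          alpha_som, alpha_dnd, eta: float = 1.0):
    """Alternative rule: plain BCM applied to the calcium-like activities.

    eta * z (z - theta) (1 - activation) * I per compartment, where the
    sliding thresholds are computed from running means of z_som / z_dnd.
    """
    z_som, z_dnd = alt_activities(x, y, alpha_som, alpha_dnd)
    g_som = eta * z_som * (z_som - theta_som) * (1.0 - np.asarray(x, dtype=float))
    g_dnd = eta * z_dnd * (z_dnd - theta_dnd) * (1.0 - np.asarray(y, dtype=float))
    return _times_trace(g_som, I_som), _times_trace(g_dnd, I_dnd)


def update_moving_thresholds(state: PlasticityState, x, y, dt: float,
                             p: PlasticityParams) -> PlasticityState:
    """Low-pass filter the activities and recompute theta = c0 * E^2.

    The filter is solved exactly over the step, so a step input reaches
    (1 - 1/e) of its asymptote after exactly tau_mean ms.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = np.exp(-dt / p.tau_mean)
    state.E_som = state.E_som * a + (1.0 - a) * np.asarray(x, dtype=float)
    state.E_dnd = state.E_dnd * a + (1.0 - a) * np.asarray(y, dtype=float)
    state.theta_som = p.c0 * state.E_som ** 2
    state.theta_dnd = p.c0 * state.E_dnd ** 2
    return state


def _integrate_family(w, dw, target, dt, p: PlasticityParams,
                      rng: np.random.Generator | None, noise: bool,
                      noise_scale: float = 1.0):
    """Relax dw toward the target with tau_w, then integrate the weight with
    exact multiplicative decay and optional Gaussian fluctuation.

    ``noise_scale`` rescales the fluctuation when it is applied at a
    coarser interval than dt (sqrt(k) for every k-th step), preserving the
    variance accumulated per unit time.  Arrays are updated in place.
    """
    a = np.exp(-dt / p.tau_w)
    dw *= a
    dw += (1.0 - a) * target
    if p.eta_decay:
        w *= np.exp(-p.eta_decay * dt)
    w += dt * dw
    if noise and p.sigma_w > 0.0 and rng is not None:
        w += (p.sigma_w * np.sqrt(dt) * noise_scale) * rng.standard_normal(w.shape)
    return np.maximum(w, 0.0, out=w), dw


def step_weight_dynamics(weights: WeightSet, state: PlasticityState, target_terms,
                         dt: float, p: PlasticityParams,
                         rng: np.random.Generator | None = None,
                         noise_scale: float = 1.0):
    """One step of the second-order stochastic weight dynamics.

    ``target_terms`` is ``(t_som, t_dnd)`` or ``(t_som, t_dnd, t_v)``; each
    dw variable relaxes toward its target with tau_w while the weight
    integrates dw, decays with rate eta_decay and (excitatory families
    only) fluctuates with amplitude sigma_w.  Negative weights are clipped
    to zero and the recurrent diagonal is re-zeroed every step.
    """
    t_som, t_dnd = target_terms[0], target_terms[1]
    t_v = target_terms[2] if len(target_terms) > 2 else None
    weights.w_som, state.dw_som = _integrate_family(
        weights.w_som, state.dw_som, t_som, dt, p, rng, noise=True,
        noise_scale=noise_scale)
    weights.w_dnd, state.dw_dnd = _integrate_family(
        weights.w_dnd, state.dw_dnd, t_dnd, dt, p, rng, noise=True,
        noise_scale=noise_scale)
    if t_v is not None and weights.v_dnd is not None:
        # the inhibitory family carries no spontaneous fluctuation term
        weights.v_dnd, state.dv_dnd = _integrate_family(
            weights.v_dnd, state.dv_dnd, t_v, dt, p, rng, noise=False)
    if weights.recurrent:
        np.fill_diagonal(weights.w_som, 0.0)
    return weights, state


def objective_value(x_trace, y_trace, alpha: float, c0: float) -> float:
    """Objective maximised by the combined rule (with sliding thresholds):

    L = (1-alpha) (E[x^2]/2 + E[y^2]/2 - c0 E[x]^3 - c0 E[y]^3) + alpha E[xy]
    """
    x = np.asarray(x_trace, dtype=float)
    y = np.asarray(y_trace, dtype=float)
    if x.size == 0 or y.size == 0 or x.shape != y.shape:
        raise ValueError("traces must be non-empty and of equal length")
    return float(
        (1.0 - alpha) * (0.5 * np.mean(x ** 2) + 0.5 * np.mean(y ** 2)
                         - c0 * np.mean(x) ** 3 - c0 * np.mean(y) ** 3)
        + alpha * np.mean(x * y)
    )


def objective_value_fixed_thresholds(x_trace, y_trace, alpha: float,
                                     theta_som: float, theta_dnd: float) -> float:
    """Objective with the sliding thresholds frozen at fixed values.

    L = (1-alpha) (E[x^2]/2 + E[y^2]/2 - theta_som E[x] - theta_dnd E[y])
        + alpha E[xy]

    Treating theta as constant during differentiation, the gradient of this
    functional with respect to the weights reproduces the time-averaged
    update terms exactly; it is the form used for gradient verification.
    """
    x = np.asarray(x_trace, dtype=float)
    y = np.asarray(y_trace, dtype=float)
    if x.size == 0 or y.size == 0 or x.shape != y.shape:
        raise ValueError("traces must be non-empty and of equal length")
    return float(
        (1.0 - alpha) * (0.5 * np.mean(x ** 2) + 0.5 * np.mean(y ** 2)
                         - theta_som * np.mean(x) - theta_dnd * np.mean(y))
        + alpha * np.mean(x * y)
    )
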