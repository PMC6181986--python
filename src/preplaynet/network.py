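"""Assembly and stepping of the recurrent CA3-like network.

``RecurrentNetwork`` implements the two-compartment recurrent model:
somatic compartments receive recurrent excitation, feedback inhibition,
theta/trigger/noise input; dendritic compartments receive EC input and
plastic dendritic inhibition.  A single-compartment control routes both
excitatory pathways into the soma.  ``CellEnsemble`` implements the small
feed-forward configurations (one or two cells, optional shared
interneuron) used to characterise the learning rule itself.

Weight constructors build the initial connectivity: a Gaussian distance
profile along the chain of neuron indices (so that strong preexisting
sequences can propagate), arm-segregated chains for the Y-maze and a
trunk-plus-two-branches topology for the branching track.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .core_dynamics import (
    NeuronParams,
    filtered_step,
    make_inhibitory_pool,
    stp_derivatives,
)
from .plasticity import (
    PlasticityParams,
    WeightSet,
    inhibitory_update_term,
    make_plasticity_state,
    step_weight_dynamics,
    two_compartment_update_terms,
    update_moving_thresholds,
    _times_trace,
)

__all__ = [
    "NetworkConfig",
    "build_chain_weights",
    "build_ec_weights",
    "build_ymaze_weights",
    "build_branching_weights",
    "RecurrentNetwork",
    "CellEnsemble",
]

TAU_L = 10.0
#: baseline release probability, and its value at recurrent synapses during run
U_REST = 0.5
U_RUN = 0.03


def _gauss_profile(i, j, amplitude, width):
    return amplitude * np.exp(-0.5 * ((i - j) / width) ** 2)


def build_chain_weights(n: int, w_max: float = 18.0, w_width: float = 5.0,
                        rng: np.random.Generator | None = None,
                        noise: bool = True) -> np.ndarray:
    """Recurrent weights with a Gaussian profile in |i - j|.

    Standard-normal fluctuations are added per entry, negatives are zeroed
    and self-connections are fixed at zero.
    """
    if n < 2:
        raise ValueError("need at least two neurons")
    idx = np.arange(n)
    w = _gauss_profile(idx[:, None], idx[None, :], w_max, w_width)
    if noise:
        if rng is None:
            raise ValueError("rng required when noise is enabled")
        w = w + rng.standard_normal((n, n))
    np.maximum(w, 0.0, out=w)
    np.fill_diagonal(w, 0.0)
    return w


def build_ec_weights(n_ca3: int, n_ec: int, w_dnd_max: float = 5.0,
                     w_width: float = 5.0, familiarity: str = "familiar",
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Initial EC-to-CA3 weights.

    ``familiar``: Gaussian profile peaking at i = j, aligning each cell
    with the similarly indexed (hence similarly tuned) EC neuron.
    ``unfamiliar``: each postsynaptic row of the familiar matrix is
    randomly permuted over the presynaptic index, destroying the spatial
    alignment while preserving each row's weight multiset.
    """
    i = np.arange(n_ca3)[:, None]
    j = np.arange(n_ec)[None, :]
    w = _gauss_profile(i, j, w_dnd_max, w_width)
    if familiarity == "familiar":
        return w
    if familiarity != "unfamiliar":
        raise ValueError("familiarity must be 'familiar' or 'unfamiliar'")
    if rng is None:
        raise ValueError("rng required for the unfamiliar shuffle")
    return np.array([row[rng.permutation(n_ec)] for row in w])


def build_ymaze_weights(n_per_group: int = 150, w_max: float = 20.0,
                        w_width: float = 5.0,
                        rng: np.random.Generator | None = None,
                        noise: bool = True) -> np.ndarray:
    """Three disjoint chain groups with zero cross-group weights."""
    n = 3 * n_per_group
    w = np.zeros((n, n))
    for g in range(3):
        sl = slice(g * n_per_group, (g + 1) * n_per_group)
        w[sl, sl] = build_chain_weights(n_per_group, w_max, w_width, rng, noise)
    return w


def build_branching_weights(n_root: int = 100, n_branch: int = 150,
                            w_max: float = 18.0, w_prime_max: float = 14.0,
                            w_width: float = 5.0,
                            rng: np.random.Generator | None = None,
                            noise: bool = True) -> np.ndarray:
    """Trunk plus two branches; branches do not connect to each other.

    Within each group the chain profile applies.  Root-to-branch couplings
    are symmetric Gaussian profiles of the path distance across the
    junction: for branch A the index gap i - j, for branch B the distance
    (root_end - i) + (j - branchB_start + 1), so both branch entries sit
    one step beyond the last root neuron.
    """
    n = n_root + 2 * n_branch
    w = np.zeros((n, n))
    groups = [slice(0, n_root),
              slice(n_root, n_root + n_branch),
              slice(n_root + n_branch, n)]
    for sl in groups:
        m = sl.stop - sl.start
        w[sl, sl] = build_chain_weights(m, w_max, w_width, rng, noise)
    i_root = np.arange(n_root)[:, None]           # 0-based root indices
    j_a = np.arange(n_root, n_root + n_branch)[None, :]
    dist_a = i_root - j_a
    w_ra = w_prime_max * np.exp(-0.5 * (dist_a / w_width) ** 2)
    j_b = np.arange(n_branch)[None, :]
    dist_b = (n_root - 1 - i_root) + (j_b + 1)    # path length through the junction
    w_rb = w_prime_max * np.exp(-0.5 * (dist_b / w_width) ** 2)
    w[groups[0], groups[1]] = w_ra
    w[groups[1], groups[0]] = w_ra.T
    w[groups[0], groups[2]] = w_rb
    w[groups[2], groups[0]] = w_rb.T
    return w


@dataclass
class NetworkConfig:
    """Configuration of the recurrent network.

    ``w_scale`` multiplies the recurrent amplitude (used for the weakened /
    strengthened preexisting-sequence controls).  ``ec_init`` selects the
    initial EC-weight constructor: the Gaussian profile with a familiarity
    flag, or uniform random weights on [0, ec_uniform_high].
    """

    n_ca3: int = 300
    n_ec: int = 500
    n_inh: int = 100
    topology: str = "chain"            # chain | ymaze | branching
    familiarity: str = "unfamiliar"
    w_max: float = 18.0
    w_width: float = 5.0
    w_dnd_max: float = 5.0
    w_prime_max: float = 14.0
    w_scale: float = 1.0
    ymaze_w_max: float = 20.0
    n_root: int = 100
    n_branch: int = 150
    ec_init: str = "profile"           # profile | uniform
    ec_uniform_high: float = 2.0
    # fixed somatic inhibitory weight (per readout); the summed feedback
    # is v_som * (population-summed output trace) / n_inh
    v_som_value: float = 20.0
    single_compartment: bool = False
    stp_on_inhibitory_path: bool = False
    neuron: NeuronParams = field(default_factory=lambda: NeuronParams(
        phi=0.08, beta=2.5, gamma=1.0))
    plasticity: PlasticityParams = field(default_factory=lambda: PlasticityParams(
        alpha=0.9, eta=1.0, eta_inh=1.0))

    def __post_init__(self) -> None:
        if min(self.n_ca3, self.n_ec, self.n_inh) <= 0:
            raise ValueError("population sizes must be positive")
        if self.w_width <= 0:
            raise ValueError("w_width must be positive")
        if self.topology == "ymaze" and self.n_ca3 % 3:
            raise ValueError("Y-maze topology needs n_ca3 divisible by 3")
        if self.topology == "branching" and self.n_root + 2 * self.n_branch != self.n_ca3:
            raise ValueError("branching topology needs n_ca3 = n_root + 2*n_branch")


def _build_recurrent(cfg: NetworkConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.topology == "chain":
        return build_chain_weights(cfg.n_ca3, cfg.w_max * cfg.w_scale, cfg.w_width, rng)
    if cfg.topology == "ymaze":
        return build_ymaze_weights(cfg.n_ca3 // 3, cfg.ymaze_w_max * cfg.w_scale,
                                   cfg.w_width, rng)
    if cfg.topology == "branching":
        return build_branching_weights(cfg.n_root, cfg.n_branch,
                                       cfg.w_max * cfg.w_scale,
                                       cfg.w_prime_max * cfg.w_scale,
                                       cfg.w_width, rng)
    raise ValueError(f"unknown topology {cfg.topology!r}")


def _build_ec(cfg: NetworkConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.ec_init == "uniform":
        return rng.uniform(0.0, cfg.ec_uniform_high, (cfg.n_ca3, cfg.n_ec))
    return build_ec_weights(cfg.n_ca3, cfg.n_ec, cfg.w_dnd_max, cfg.w_width,
                            cfg.familiarity, rng)


class RecurrentNetwork:
    """Stateful recurrent network stepped at a fixed dt (default 1 ms).

    Update order within a step (everything reads time t - dt information):
    feedback inhibition from the previous-step output rates, short-term
    plasticity and synaptic traces, compartment activations using the
    delayed partner activities, output rates, then long-term plasticity.
    """

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.p = cfg.neuron
        self.pp = cfg.plasticity
        n, n_ec, n_inh = cfg.n_ca3, cfg.n_ec, cfg.n_inh
        self.n, self.n_ec, self.n_inh = n, n_ec, n_inh
        self.weights = WeightSet(
            w_som=_build_recurrent(cfg, rng),
            w_dnd=_build_ec(cfg, rng),
            v_dnd=np.zeros((n, n_inh)),
            v_som=cfg.v_som_value,
            recurrent=True,
        )
        # per-source normalisation: the summed readout output equals the
        # population-summed trace / n_inh, so a localised bump exerts the
        # same absolute inhibition at any network size, and the plastic
        # dendritic inhibition builds up slowly (over hundreds of seconds
        # of strong coincident activity) rather than within one session
        self.pool = make_inhibitory_pool(n, n_inh, rng, TAU_L,
                                         normalization="per_source")
        self.pstate = make_plasticity_state((n, n), (n, n_ec), (n, n_inh), (n,))
        f0 = expit(-self.p.theta_f)
        self.x = np.full(n, f0)
        self.y = np.full(n, 0.0 if cfg.single_compartment else f0)
        self.z = (1.0 + self.p.gamma * self.y) * self.p.phi * self.x \
            if not cfg.single_compartment else self.p.phi * self.x
        self.I_som = np.zeros(n)
        self.I_dnd = np.zeros(n_ec)
        self.D_som = np.ones(n)
        self.F_som = np.full(n, U_REST)
        self.D_dnd = np.ones(n_ec)
        self.F_dnd = np.full(n_ec, U_REST)
        self.D_py = np.ones(n)
        self.F_py = np.full(n, U_REST)
        self._was_running = False
        self._steps = 0
        #: interval (in steps) at which the weight fluctuation is applied,
        #: with variance-preserving sqrt scaling
        self.noise_every = 10

    # -- helpers -----------------------------------------------------------
    def copy(self) -> "RecurrentNetwork":
        """Deep copy of the full dynamical state (for branching protocols)."""
        return copy.deepcopy(self)

    def _stp_step(self, D, F, u, U, dt):
        dD, dF = stp_derivatives(D, F, u, U, 500.0, 200.0)
        D += dt * dD
        F += dt * dF

    def step(self, u_ec: np.ndarray, ext: np.ndarray, dt: float = 1.0, *,
             running: bool = False, plasticity_on: bool = True,
             inh_plasticity_on: bool = True,
             rng: np.random.Generator | None = None) -> np.ndarray:
        """Advance one step; returns the output rates z (kHz)."""
        p, pp, w = self.p, self.pp, self.weights
        z_prev = self.z

        # release probability of recurrent synapses is neuromodulated during run
        U_som = U_RUN if running else U_REST
        if running and not self._was_running:
            self.F_som[:] = U_RUN
        self._was_running = running

        # feedback inhibition from previous-step pyramidal output
        if self.cfg.stp_on_inhibitory_path:
            py_factor = self.D_py * self.F_py
            self.pool.I_pyr_trace.I = filtered_step(
                self.pool.I_pyr_trace.I, z_prev * py_factor, TAU_L, dt)
            self._stp_step(self.D_py, self.F_py, z_prev, U_som, dt)
        else:
            self.pool.I_pyr_trace.I = filtered_step(
                self.pool.I_pyr_trace.I, z_prev, TAU_L, dt)
        I_py = self.pool.I_pyr_trace.I
        I_sominh = self.pool.theta_som @ I_py
        I_dndinh = self.pool.theta_dnd @ I_py
        # uniform fixed somatic weights: total inhibition v_som times the
        # summed readout output (= population-summed trace / n_inh)
        inh_som = w.v_som * I_sominh.sum()
        inh_dnd = w.v_dnd @ I_dndinh

        # synaptic traces use the pre-update short-term plasticity factors
        self.I_som = filtered_step(self.I_som, z_prev * (self.D_som * self.F_som),
                                   TAU_L, dt)
        self.I_dnd = filtered_step(self.I_dnd, u_ec * (self.D_dnd * self.F_dnd),
                                   TAU_L, dt)
        self._stp_step(self.D_som, self.F_som, z_prev, U_som, dt)
        self._stp_step(self.D_dnd, self.F_dnd, u_ec, U_REST, dt)

        if self.cfg.single_compartment:
            drive = w.w_som @ self.I_som + w.w_dnd @ self.I_dnd - inh_som + ext
            x = expit(drive - p.theta_f)
            y = self.y  # passive, unused
            z = p.phi * x
        else:
            x = expit(w.w_som @ self.I_som - inh_som
                      + p.beta * self.y + ext - p.theta_f)
            y = expit(w.w_dnd @ self.I_dnd - inh_dnd
                      + p.beta * self.x - p.theta_f)
            z = (1.0 + p.gamma * y) * p.phi * x

        if plasticity_on:
            update_moving_thresholds(self.pstate, x, y, dt, pp)
            if self.cfg.single_compartment:
                g = pp.eta * x * (x - self.pstate.theta_som) * (1.0 - x)
                targets = (_times_trace(g, self.I_som), _times_trace(g, self.I_dnd))
            else:
                t_som, t_dnd = two_compartment_update_terms(
                    x, y, self.pstate.theta_som, self.pstate.theta_dnd,
                    self.I_som, self.I_dnd, pp)
                targets = (t_som, t_dnd)
                if inh_plasticity_on and pp.eta_inh != 0.0:
                    targets = targets + (inhibitory_update_term(x, y, I_dndinh, pp),)
            noisy = self._steps % self.noise_every == 0
            step_weight_dynamics(w, self.pstate, targets, dt, pp,
                                 rng if noisy else None,
                                 noise_scale=np.sqrt(self.noise_every))

        self.x, self.y, self.z = x, y, z
        self._steps += 1
        if self._steps % 1000 == 0 and not np.all(np.isfinite(z)):
            bad = int(np.flatnonzero(~np.isfinite(z))[0])
            raise FloatingPointError(
                f"non-finite rate at step {self._steps}, neuron {bad}")
        return z


class CellEnsemble:
    """One or a few two-compartment cells driven by external input neurons.

    Shapes carry a leading batch axis over independent trials and a cell
    axis: activations are (B, C), weights (B, C, m).  All cells within a
    trial share the same input neurons; an optional single shared
    interneuron provides somatic and (plastic) dendritic feedback
    inhibition, mediating competition between the cells.

    ``alpha`` and ``beta`` may be per-trial arrays, which vectorises
    parameter sweeps.
    """

    def __init__(self, n_trials: int, n_cells: int, n_som: int, n_dnd: int,
                 rng: np.random.Generator, *,
                 alpha=0.5, beta=0.0, gamma=1.0, eta=0.2, eta_inh=0.0,
                 phi=0.08, theta_f=5.0, sigma_w=0.005,
                 c0=70.0, theta_inh=0.5, tau_w=1000.0, eta_decay=1e-7,
                 tau_mean=60000.0, v_som=0.0, inhibition=False,
                 w_init_high=5.0, alt_rule=False, alpha_som=None, alpha_dnd=None):
        B, C = n_trials, n_cells
        self.B, self.C = B, C
        self.p = NeuronParams(phi=phi, theta_f=theta_f, gamma=gamma,
                              beta=float(np.max(beta)))
        self.pp = PlasticityParams(alpha=float(np.max(alpha)), eta=eta, eta_inh=eta_inh,
                                   c0=c0, theta_inh=theta_inh, tau_w=tau_w,
                                   eta_decay=eta_decay, sigma_w=sigma_w,
                                   tau_mean=tau_mean)
        self.alpha = np.broadcast_to(np.asarray(alpha, float), (B,))[:, None]
        self.beta = np.broadcast_to(np.asarray(beta, float), (B,))[:, None]
        self.gamma = gamma
        self.phi = phi
        self.theta_f = theta_f
        self.eta, self.eta_inh = eta, eta_inh
        self.alt_rule = alt_rule
        if alt_rule:
            self.alpha_som = np.broadcast_to(np.asarray(alpha_som, float), (B,))[:, None]
            self.alpha_dnd = np.broadcast_to(np.asarray(alpha_dnd, float), (B,))[:, None]
        self.w_som = rng.uniform(0.0, w_init_high, (B, C, n_som))
        self.w_dnd = rng.uniform(0.0, w_init_high, (B, C, n_dnd))
        self.inhibition = inhibition
        self.v_som = v_som
        self.v_dnd = np.zeros((B, C))
        f0 = expit(-theta_f)
        self.x = np.full((B, C), f0)
        self.y = np.full((B, C), f0)
        self.z = (1.0 + gamma * self.y) * phi * self.x
        self.I_som = np.zeros((B, n_som))
        self.I_dnd = np.zeros((B, n_dnd))
        self.I_py = np.zeros((B, C))
        self.dw_som = np.zeros_like(self.w_som)
        self.dw_dnd = np.zeros_like(self.w_dnd)
        self.dv = np.zeros((B, C))
        self.noise_every = 10
        self._steps = 0
        self.E_som = np.zeros((B, C))
        self.E_dnd = np.zeros((B, C))
        self.c0 = c0
        self.theta_inh = theta_inh

    def step(self, u_som: np.ndarray, u_dnd: np.ndarray, dt: float,
             rng: np.random.Generator) -> None:
        pp = self.pp
        # shared interneuron: unit projection of every cell's output trace
        self.I_py = filtered_step(self.I_py, self.z, TAU_L, dt)
        I_inh = self.I_py.sum(axis=1) if self.inhibition else np.zeros(self.B)

        self.I_som = filtered_step(self.I_som, u_som, TAU_L, dt)
        self.I_dnd = filtered_step(self.I_dnd, u_dnd, TAU_L, dt)

        drive_som = np.matmul(self.w_som, self.I_som[:, :, None])[..., 0] \
            - self.v_som * I_inh[:, None] + self.beta * self.y
        drive_dnd = np.matmul(self.w_dnd, self.I_dnd[:, :, None])[..., 0] \
            - self.v_dnd * I_inh[:, None] + self.beta * self.x
        x = expit(drive_som - self.theta_f)
        y = expit(drive_dnd - self.theta_f)
        z = (1.0 + self.gamma * y) * self.phi * x

        am = np.exp(-dt / pp.tau_mean)
        if self.alt_rule:
            z_som = (1.0 - self.alpha_som) * x + self.alpha_som * x * y
            z_dnd = (1.0 - self.alpha_dnd) * y + self.alpha_dnd * x * y
            self.E_som = self.E_som * am + (1.0 - am) * z_som
            self.E_dnd = self.E_dnd * am + (1.0 - am) * z_dnd
            th_s = self.c0 * self.E_som ** 2
            th_d = self.c0 * self.E_dnd ** 2
            g_som = self.eta * z_som * (z_som - th_s) * (1.0 - x)
            g_dnd = self.eta * z_dnd * (z_dnd - th_d) * (1.0 - y)
        else:
            self.E_som = self.E_som * am + (1.0 - am) * x
            self.E_dnd = self.E_dnd * am + (1.0 - am) * y
            th_s = self.c0 * self.E_som ** 2
            th_d = self.c0 * self.E_dnd ** 2
            a = self.alpha
            xy = x * y
            g_som = self.eta * ((1.0 - a) * x * (x - th_s) + a * xy) * (1.0 - x)
            g_dnd = self.eta * ((1.0 - a) * y * (y - th_d) + a * xy) * (1.0 - y)

        aw = np.exp(-dt / pp.tau_w)
        self.dw_som = self.dw_som * aw + (1.0 - aw) * g_som[..., None] * self.I_som[:, None, :]
        self.dw_dnd = self.dw_dnd * aw + (1.0 - aw) * g_dnd[..., None] * self.I_dnd[:, None, :]
        decay = np.exp(-pp.eta_decay * dt)
        self.w_som = self.w_som * decay + dt * self.dw_som
        self.w_dnd = self.w_dnd * decay + dt * self.dw_dnd
        if self._steps % self.noise_every == 0:
            ns = pp.sigma_w * np.sqrt(dt * self.noise_every)
            self.w_som += ns * rng.standard_normal(self.w_som.shape)
            self.w_dnd += ns * rng.standard_normal(self.w_dnd.shape)
        self._steps += 1
        np.maximum(self.w_som, 0.0, out=self.w_som)
        np.maximum(self.w_dnd, 0.0, out=self.w_dnd)

        if self.inhibition and self.eta_inh != 0.0:
            a = self.alpha
            g_v = self.eta_inh * ((1.0 - a) * y * (y - self.theta_inh)
                                  + a * x * y) * (1.0 - y) * I_inh[:, None]
            self.dv = self.dv * aw + (1.0 - aw) * g_v
            self.v_dnd = np.maximum(self.v_dnd * decay + dt * self.dv, 0.0)

        self.x, self.y, self.z = x, y, z
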