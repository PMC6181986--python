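"""Rate-model primitives of the two-compartment pyramidal neuron.

The neuron is split into a somatic compartment (soma plus basal/proximal
dendrites, receiving recurrent input) and a distal dendritic compartment
(apical tuft, receiving afferent input).  Each compartment has a sigmoidal
activation; coincident activation of both compartments amplifies the
output firing rate, mimicking dendritic calcium spikes.  Synaptic drive is
low-pass filtered with a short time constant, and each presynaptic source
carries short-term depression/facilitation variables.  A fixed random
projection of pyramidal output onto interneuron pools provides somatic and
dendritic feedback inhibition.

Units: time in milliseconds, rates in kHz (0.08 kHz = 80 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "NeuronParams",
    "CompartmentState",
    "SynapticTrace",
    "STPState",
    "InhibitoryPool",
    "sigmoid_response",
    "filtered_step",
    "step_synaptic_trace",
    "make_stp_state",
    "stp_derivatives",
    "step_stp",
    "compartment_activations",
    "output_rate",
    "make_inhibitory_pool",
    "inhibitory_feedback",
]

#: default sigmoid threshold of the response nonlinearity
THETA_F = 5.0


@dataclass
class NeuronParams:
    """Parameters of the two-compartment rate neuron.

    phi
        Maximum somatic firing rate in kHz.
    phi_input
        Maximum firing rate of input neurons in kHz.
    theta_f
        Threshold of the sigmoidal response function (dimensionless drive).
    beta
        Gain of the cross-compartment threshold modulation (the delayed
        activity of one compartment lowers the effective threshold of the
        other).
    gamma
        Amplification factor of dendritic calcium spikes on the output rate.
    delta_t
        Cross-compartment delay in ms; with the default 1-ms step this is
        exactly one integration step.
    """

    phi: float = 0.08
    phi_input: float = 0.08
    theta_f: float = THETA_F
    beta: float = 0.0
    gamma: float = 1.0
    delta_t: float = 1.0

    def __post_init__(self) -> None:
        if self.phi <= 0 or self.phi_input <= 0:
            raise ValueError("maximum rates must be positive")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        if self.gamma < 0 or self.beta < 0:
            raise ValueError("beta and gamma must be non-negative")


@dataclass
class CompartmentState:
    """Somatic (x) and dendritic (y) activations with one-step-delayed copies."""

    x: np.ndarray
    y: np.ndarray
    x_prev: np.ndarray
    y_prev: np.ndarray


def sigmoid_response(I, theta_f: float = THETA_F):
    """Sigmoidal response f(I) = 1 / (1 + exp(-(I - theta_f))).

    Strictly increasing, saturating at 0 and 1.  Raises on non-finite input.
    """
    I = np.asarray(I, dtype=float)
    if not np.all(np.isfinite(I)):
        raise ValueError("non-finite drive passed to sigmoid_response")
    return expit(I - theta_f)


def filtered_step(value, drive, tau: float, dt: float):
    """Advance ``dI/dt = -I/tau + u`` by one step of size ``dt``.

    Exact for piecewise-constant drive: the fixed point for constant u is
    tau * u and free decay follows exp(-t/tau).
    """
    a = np.exp(-dt / tau)
    return value * a + drive * (tau * (1.0 - a))


@dataclass
class SynapticTrace:
    """Per-source filtered postsynaptic current with decay constant tau_L (ms)."""

    I: np.ndarray
    tau_L: float = 10.0


def step_synaptic_trace(trace: SynapticTrace, u, stp_factor=1.0, dt: float = 1.0) -> SynapticTrace:
    """Advance a synaptic trace, integrating presynaptic rate ``u`` (kHz).

    ``stp_factor`` is the product D*F of the short-term plasticity variables
    (or 1 when short-term plasticity is absent).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("presynaptic rates must be non-negative")
    return SynapticTrace(filtered_step(trace.I, u * stp_factor, trace.tau_L, dt), trace.tau_L)


@dataclass
class STPState:
    """Short-term depression (D) and facilitation (F) per presynaptic source.

    D relaxes to 1 with tau_STD and is consumed by release u*D*F;
    F relaxes to the baseline release probability U_STF with tau_STF and
    facilitates toward 1 with presynaptic activity.
    """

    D: np.ndarray
    F: np.ndarray
    tau_STD: float = 500.0
    tau_STF: float = 200.0
    U_STF: float = 0.5


def make_stp_state(n: int, U_STF: float = 0.5, tau_STD: float = 500.0,
                   tau_STF: float = 200.0) -> STPState:
    """Rest-state initialisation: D = 1, F = U_STF."""
    return STPState(np.ones(n), np.full(n, U_STF), tau_STD, tau_STF, U_STF)


def stp_derivatives(D, F, u, U_STF: float, tau_STD: float, tau_STF: float):
    """Time derivatives of the depression/facilitation variables."""
    dD = (1.0 - D) / tau_STD - u * D * F
    dF = (U_STF - F) / tau_STF + U_STF * (1.0 - F) * u
    return dD, dF


def step_stp(state: STPState, u, dt: float = 1.0, U_STF: float | None = None) -> STPState:
    """One forward-Euler step of the short-term plasticity dynamics.

    The Euler fixed point coincides with the fixed point of the continuous
    flow, so stationary values are exact.  ``U_STF`` may be overridden per
    call (the baseline release probability is neuromodulated during
    locomotion).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = np.asarray(u, dtype=float)
    U = state.U_STF if U_STF is None else U_STF
    dD, dF = stp_derivatives(state.D, state.F, u, U, state.tau_STD, state.tau_STF)
    return STPState(state.D + dt * dD, state.F + dt * dF,
                    state.tau_STD, state.tau_STF, U)


def compartment_activations(exc_som, exc_dnd, inh_som, inh_dnd, ext,
                            state: CompartmentState, p: NeuronParams):
    """Somatic and dendritic activations for one step.

    x = f(exc_som - inh_som + beta * y_prev + ext)
    y = f(exc_dnd - inh_dnd + beta * x_prev)

    where x_prev / y_prev are the partner-compartment activations one
    delay step earlier.
    """
    arg_x = np.asarray(exc_som) - inh_som + p.beta * state.y_prev + ext
    arg_y = np.asarray(exc_dnd) - inh_dnd + p.beta * state.x_prev
    if np.shape(arg_x) != np.shape(state.x) or np.shape(arg_y) != np.shape(state.y):
        raise ValueError("drive shape does not match compartment state")
    x = expit(arg_x - p.theta_f)
    y = expit(arg_y - p.theta_f)
    return x, y


def output_rate(x, y, p: NeuronParams):
    """Net output rate z = (1 + gamma*y) * phi * x in kHz.

    Bounded by (1 + gamma) * phi; with gamma = 0 the dendrite does not
    modulate the output gain.
    """
    return (1.0 + p.gamma * np.asarray(y)) * p.phi * np.asarray(x)


@dataclass
class InhibitoryPool:
    """Fixed random projection of pyramidal output onto inhibitory readouts.

    ``theta_som`` and ``theta_dnd`` are (n_inh, n_pyr) matrices mixing the
    filtered pyramidal output trace into per-readout somatic/dendritic
    inhibitory signals; they are fixed for the whole simulation.  Two
    normalisations are supported:

    ``per_source``
        every column (one presynaptic pyramidal cell, summed over
        readouts) sums to 1/n_inh, so the summed readout output equals
        the population-summed trace divided by n_inh;
    ``per_readout``
        every row sums to 1, making each readout an O(1) random convex
        average of the pyramidal traces, independent of population size.

    The per-readout form keeps inhibitory signals on the same scale as
    single-cell traces, which is what gives the plastic dendritic
    inhibitory weights (learned from zero against these signals) traction
    in large networks.
    """

    theta_som: np.ndarray
    theta_dnd: np.ndarray
    I_pyr_trace: SynapticTrace
    #: one normalization for both projections, or a (somatic, dendritic) pair
    normalization: str | tuple = "per_source"
    n_inh: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_inh = self.theta_som.shape[0]
        norms = self.normalization
        if isinstance(norms, str):
            norms = (norms, norms)
        for (name, mat), norm in zip(
                (("theta_som", self.theta_som), ("theta_dnd", self.theta_dnd)), norms):
            if norm == "per_source":
                sums, target = mat.sum(axis=0), 1.0 / self.n_inh
            elif norm == "per_readout":
                sums, target = mat.sum(axis=1), 1.0
            else:
                raise ValueError(f"unknown normalization {norm!r}")
            if not np.allclose(sums, target, atol=1e-10):
                raise ValueError(f"{name} is not {norm}-normalized")


def _normalized_projection(n_inh: int, n_pyr: int, rng: np.random.Generator,
                           normalization: str) -> np.ndarray:
    m = rng.uniform(0.0, 1.0, size=(n_inh, n_pyr))
    if normalization == "per_source":
        return m / (m.sum(axis=0, keepdims=True) * n_inh)
    return m / m.sum(axis=1, keepdims=True)


def make_inhibitory_pool(n_pyr: int, n_inh: int, rng: np.random.Generator,
                         tau_L: float = 10.0,
                         normalization: str | tuple = "per_source") -> InhibitoryPool:
    """Sample uniform projection weights and normalise them (see
    :class:`InhibitoryPool` for the two conventions; a pair applies
    separate conventions to the somatic and dendritic projections)."""
    norms = (normalization, normalization) if isinstance(normalization, str) \
        else tuple(normalization)
    for n in norms:
        if n not in ("per_source", "per_readout"):
            raise ValueError(f"unknown normalization {n!r}")
    return InhibitoryPool(
        _normalized_projection(n_inh, n_pyr, rng, norms[0]),
        _normalized_projection(n_inh, n_pyr, rng, norms[1]),
        SynapticTrace(np.zeros(n_pyr), tau_L),
        normalization,
    )


def inhibitory_feedback(pool: InhibitoryPool, z, dt: float = 1.0):
    """Update the pyramidal output trace with rates ``z`` and return the
    per-readout somatic and dendritic inhibitory signals."""
    pool.I_pyr_trace = step_synaptic_trace(pool.I_pyr_trace, z, 1.0, dt)
    return pool.theta_som @ pool.I_pyr_trace.I, pool.theta_dnd @ pool.I_pyr_trace.I
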