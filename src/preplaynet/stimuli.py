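"""Input and behaviour generators.

Everything the simulator consumes is generated internally: Ornstein-
Uhlenbeck (OU) source signals, the single-cell input protocols (correlated
/ uncorrelated source groups, the two-cell separation protocol and the
correlation-switch stability protocol), behavioural position schedules for
the linear track, Y-maze and branching track, entorhinal (EC) drives
(place-tuned, grid-tuned, distractor, population bursts), theta oscillation
and dentate-like trigger pulses.

Noise convention: the OU equation ds/dt = -s/tau + sigma*eps(t) is
discretised exactly in distribution at the 1-ms reference resolution, with
the stationary variance sigma^2 * tau / 2 implied by unit-variance Gaussian
increments per millisecond.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .core_dynamics import THETA_F

__all__ = [
    "OUParams",
    "ou_step",
    "OUProcess",
    "DrivenFilter",
    "SingleCellInputs",
    "position_1d",
    "moving_1d",
    "ymaze_position",
    "theta_drive",
    "TriggerProcess",
    "BurstGate",
    "ECInput",
    "ExtInput",
    "BehaviorSchedule",
]

TAU_L = 10.0  # synaptic filter constant shared by input-current dynamics, ms


@dataclass
class OUParams:
    tau: float
    sigma: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def _ou_noise_scale(tau: float, sigma: float, dt: float) -> float:
    a = np.exp(-dt / tau)
    return sigma * np.sqrt(tau / 2.0 * (1.0 - a * a))


def ou_step(s, p: OUParams, dt: float, rng: np.random.Generator):
    """Exact-in-distribution OU update; stationary variance sigma^2 tau / 2."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = np.asarray(s, dtype=float)
    out = s * np.exp(-dt / p.tau)
    if p.sigma > 0.0:
        out = out + _ou_noise_scale(p.tau, p.sigma, dt) * rng.standard_normal(s.shape)
    return out


class OUProcess:
    """Stateful vector OU process started at zero."""

    def __init__(self, shape, tau: float, sigma: float):
        self.s = np.zeros(shape)
        self.p = OUParams(tau, sigma)

    def step(self, dt: float, rng: np.random.Generator) -> np.ndarray:
        self.s = ou_step(self.s, self.p, dt, rng)
        return self.s


class DrivenFilter:
    """First-order filter dI/dt = -I/tau + drive + sigma*eps(t).

    Used for the input currents of simulated input neurons, which low-pass
    filter their source signals and intrinsic noise.
    """

    def __init__(self, shape, tau: float = TAU_L, sigma: float = 0.0):
        self.I = np.zeros(shape)
        self.tau = tau
        self.sigma = sigma

    def step(self, drive, dt: float, rng: np.random.Generator) -> np.ndarray:
        a = np.exp(-dt / self.tau)
        self.I = self.I * a + np.asarray(drive) * (self.tau * (1.0 - a))
        if self.sigma > 0.0:
            self.I = self.I + _ou_noise_scale(self.tau, self.sigma, dt) \
                * rng.standard_normal(self.I.shape)
        return self.I


# ---------------------------------------------------------------------------
# single-cell input protocols
# ---------------------------------------------------------------------------

class SingleCellInputs:
    """Input rates for the single-cell and few-cell plasticity protocols.

    Conditions
    ----------
    ``correlated`` / ``uncorrelated``
        Somatic inputs come from a minority group A (10 neurons, source s1)
        and a majority group B (40 neurons, source s3); dendritic inputs
        from A' (10 neurons) and B' (40 neurons, source s4).  In the
        correlated condition A' shares A's source; in the uncorrelated
        condition A' uses an independent source.  ``literal_mapping``
        applies the opposite (internally inconsistent) printed assignment
        and exists only for comparison.
    ``separation``
        Two sources; 10 somatic inputs driven by s1 + s2, 20 dendritic
        inputs split into group A (s1) and group B (s2).
    ``stability``
        21 sources; 10 somatic inputs driven by s1 and 20 dendritic inputs
        whose sources switch at ``phase_times`` (ms): initially all
        independent, then group A shares the somatic source, then group B
        does.

    All rates are phi_input * f(I) with the shared sigmoidal f, hence lie
    in [0, phi_input].  A leading batch axis runs over independent trials.
    """

    #: group slices for the correlated/uncorrelated conditions
    GROUP_A = slice(0, 10)
    GROUP_B = slice(10, 50)

    def __init__(self, condition: str, n_trials: int = 1, *,
                 tau_s: float = 10.0, sigma_s: float = 0.1,
                 sigma_n: float = 0.1, phi_input: float = 0.08,
                 theta_f: float = THETA_F,
                 phase_times: tuple[float, float] = (300e3, 600e3),
                 literal_mapping: bool = False):
        known = {"correlated", "uncorrelated", "separation", "stability"}
        if condition not in known:
            raise ValueError(f"unknown condition {condition!r}; expected one of {sorted(known)}")
        self.condition = condition
        self.phi_input = phi_input
        self.theta_f = theta_f
        self.phase_times = phase_times
        self.literal_mapping = literal_mapping
        B = n_trials
        if condition in ("correlated", "uncorrelated"):
            self.sources = OUProcess((B, 4), tau_s, sigma_s)
            self.f_som = DrivenFilter((B, 50), TAU_L, sigma_n)
            self.f_dnd = DrivenFilter((B, 50), TAU_L, sigma_n)
        elif condition == "separation":
            self.sources = OUProcess((B, 2), tau_s, sigma_s)
            self.f_som = DrivenFilter((B, 10), TAU_L, sigma_n)
            self.f_dnd = DrivenFilter((B, 20), TAU_L, sigma_n)
        else:  # stability
            self.sources = OUProcess((B, 21), tau_s, sigma_s)
            self.f_som = DrivenFilter((B, 10), TAU_L, sigma_n)
            self.f_dnd = DrivenFilter((B, 20), TAU_L, sigma_n)

    def _dendritic_drive(self, s: np.ndarray, t: float) -> np.ndarray:
        B = s.shape[0]
        if self.condition in ("correlated", "uncorrelated"):
            shared = self.condition == "correlated"
            if self.literal_mapping:
                shared = not shared
            d = np.empty((B, 50))
            d[:, self.GROUP_A] = s[:, [0] if shared else [1]]
            d[:, self.GROUP_B] = s[:, [3]]
            return d
        if self.condition == "separation":
            d = np.empty((B, 20))
            d[:, :10] = s[:, [0]]
            d[:, 10:] = s[:, [1]]
            return d
        # stability: independent sources s2..s21, with one group tied to s1
        d = s[:, 1:21].copy()
        t1, t2 = self.phase_times
        if t1 <= t < t2:
            d[:, :10] = s[:, [0]]
        elif t >= t2:
            d[:, 10:] = s[:, [0]]
        return d

    def step(self, t: float, dt: float, rng: np.random.Generator):
        """Advance sources and input filters; return (u_som, u_dnd) in kHz."""
        s = self.sources.step(dt, rng)
        if self.condition in ("correlated", "uncorrelated"):
            som_drive = np.empty_like(self.f_som.I)
            som_drive[:, self.GROUP_A] = s[:, [0]]
            som_drive[:, self.GROUP_B] = s[:, [2]]
        elif self.condition == "separation":
            som_drive = s[:, [0]] + s[:, [1]]
        else:
            som_drive = s[:, [0]] * np.ones_like(self.f_som.I)
        I_som = self.f_som.step(som_drive, dt, rng)
        I_dnd = self.f_dnd.step(self._dendritic_drive(s, t), dt, rng)
        u_som = self.phi_input * expit(I_som - self.theta_f)
        u_dnd = self.phi_input * expit(I_dnd - self.theta_f)
        return u_som, u_dnd


# ---------------------------------------------------------------------------
# behaviour schedules
# ---------------------------------------------------------------------------

#: linear-track segment table: (t0_s, t1_s, pos(t0), pos(t1))
_TRACK_SEGMENTS = [
    (0.0, 10.0, 0.0, 0.0),
    (10.0, 15.0, 0.0, 1.0),
    (15.0, 17.5, 1.0, 1.0),
    (17.5, 22.5, 1.0, 0.0),
    (22.5, 25.0, 0.0, 0.0),
    (25.0, 35.0, 0.0, 1.0),
    (35.0, 37.5, 1.0, 0.0),
    (37.5, 40.0, 0.0, 0.0),
    (40.0, 44.0, 0.0, 0.8),
    (44.0, 47.0, 0.8, 0.4),
    (47.0, 50.0, 0.4, 1.0),
]


def position_1d(t):
    """Normalised position on the linear track at time ``t`` (seconds).

    Three back-and-forth traversals between 10 s and 50 s, immobile before.
    The first outbound ramp runs over [10 s, 15 s) so that the trajectory
    is continuous and reaches the far end at 15 s.
    """
    t = np.asarray(t, dtype=float)
    pos = np.zeros_like(t)
    for t0, t1, p0, p1 in _TRACK_SEGMENTS:
        m = (t >= t0) & (t < t1)
        if np.any(m):
            pos[m] = p0 + (p1 - p0) * (t[m] - t0) / (t1 - t0)
    pos[t >= _TRACK_SEGMENTS[-1][1]] = _TRACK_SEGMENTS[-1][3]
    return pos if pos.ndim else float(pos)


def moving_1d(t):
    """True where the linear-track trajectory has non-zero velocity."""
    t = np.asarray(t, dtype=float)
    mov = np.zeros(t.shape, dtype=bool)
    for t0, t1, p0, p1 in _TRACK_SEGMENTS:
        if p0 != p1:
            mov |= (t >= t0) & (t < t1)
    return mov if mov.ndim else bool(mov)


def ymaze_position(t, immobile_s: float = 10.0, cycle_s: float = 10.0):
    """Y-maze schedule: (arm, pos, moving) at time ``t`` (seconds).

    After an initial rest at the junction the animal repeats 10-s cycles,
    visiting arms 1, 2, 3 in turn: pause at the junction, run out to the
    arm end (pos 0.5), pause, run back.
    """
    t = float(t)
    if t < immobile_s:
        return 1, 0.0, False
    tc = (t - immobile_s) % cycle_s
    arm = int((t - immobile_s) // cycle_s) % 3 + 1
    q = cycle_s / 4.0
    if tc < q:
        return arm, 0.0, False
    if tc < 2 * q:
        return arm, 0.5 * (tc - q) / q, True
    if tc < 3 * q:
        return arm, 0.5, False
    return arm, 0.5 - 0.5 * (tc - 3 * q) / q, True


def theta_drive(t_ms: float, A_theta: float = 10.0, f_theta_kHz: float = 7.0 / 1000.0) -> float:
    """Septal theta input A * sin(2 pi f t); applied during run epochs only."""
    return A_theta * np.sin(2.0 * np.pi * f_theta_kHz * t_ms)


class TriggerProcess:
    """Dentate-like trigger pulses.

    While ``active``, pulse onsets follow a Poisson process at ``rate_hz``;
    each pulse lasts ``pulse_ms`` and has the given amplitude.  ``force``
    starts a pulse deterministically (used at run onset).
    """

    def __init__(self, rate_hz: float = 1.0, pulse_ms: float = 10.0, amp: float = 10.0):
        self.rate_hz = rate_hz
        self.pulse_ms = pulse_ms
        self.amp = amp
        self._remaining = 0.0

    def force(self, duration_ms: float | None = None) -> None:
        self._remaining = self.pulse_ms if duration_ms is None else duration_ms

    def step(self, dt: float, active: bool, rng: np.random.Generator) -> float:
        if self._remaining > 0.0:
            self._remaining -= dt
            return self.amp
        if active and rng.random() < self.rate_hz * dt / 1000.0:
            self._remaining = self.pulse_ms - dt
            return self.amp
        return 0.0


class BurstGate:
    """On/off gate of EC population bursts: Poisson onsets at ``rate_hz``,
    each burst lasting exactly ``burst_ms``."""

    def __init__(self, rate_hz: float = 1.0, burst_ms: float = 200.0):
        self.rate_hz = rate_hz
        self.burst_ms = burst_ms
        self._remaining = 0.0

    def step(self, dt: float, rng: np.random.Generator) -> float:
        if self._remaining > 0.0:
            self._remaining -= dt
            return 1.0
        if rng.random() < self.rate_hz * dt / 1000.0:
            self._remaining = self.burst_ms - dt
            return 1.0
        return 0.0


# ---------------------------------------------------------------------------
# entorhinal input
# ---------------------------------------------------------------------------

class ECInput:
    """Firing rates of the EC input population.

    Modes
    -----
    ``place``
        ``n_tuned`` place-tuned neurons with evenly spaced field centres
        i/n_tuned plus ``n_dist`` position-independent distractors driven
        by slow independent OU sources.
    ``grid``
        ``n_tuned`` grid-tuned neurons (von-Mises-like spatial tuning with
        random period in [0.2, 0.6] and random phase) plus distractors.
    ``ymaze``
        Arm-specific place tuning: each neuron is assigned to one arm with
        a field centre uniform in [0, 0.5] and is silent on other arms.
    ``random``
        Place tuning with field centres sampled uniformly in [0, 1]
        (branching-track experiments); ``resample_centers`` redraws the
        centres beyond a retained prefix of the track for a second,
        reordered experience.

    During immobility every neuron receives only its OU noise current;
    during run the tuned term plus half the theta drive minus a constant
    offset is added.  Population bursts multiply a dedicated OU current by
    the burst gate.  Rates are phi_input * f(I).
    """

    def __init__(self, mode: str, n_tuned: int, n_dist: int,
                 rng: np.random.Generator, *,
                 A_F: float = 5.0, sigma_F: float = 0.1,
                 A_grid: float = 5.0, c_grid: float = 3.0,
                 sigma_n: float = 1.0, tau_n: float = TAU_L,
                 tau_dist: float = 500.0, sigma_dist: float = 0.02,
                 tau_burst: float = 100.0, sigma_burst: float = 0.1,
                 phi_input: float = 0.08, theta_f: float = THETA_F,
                 arm_assignment: np.ndarray | None = None):
        if mode not in ("place", "grid", "ymaze", "random"):
            raise ValueError(f"unknown EC mode {mode!r}")
        self.mode = mode
        self.n_tuned = n_tuned
        self.n_dist = n_dist
        self.n_ec = n_tuned + n_dist
        self.A_F, self.sigma_F = A_F, sigma_F
        self.A_grid, self.c_grid = A_grid, c_grid
        self.phi_input, self.theta_f = phi_input, theta_f
        self.noise = OUProcess(self.n_ec, tau_n, sigma_n)
        self.dist_sources = OUProcess(n_dist, tau_dist, sigma_dist) if n_dist else None
        self.burst_noise = OUProcess(self.n_ec, tau_burst, sigma_burst)
        self.burst_gate = BurstGate()
        if mode == "place":
            self.centers = (np.arange(1, n_tuned + 1)) / n_tuned
        elif mode == "random":
            self.centers = rng.uniform(0.0, 1.0, n_tuned)
        elif mode == "ymaze":
            self.centers = rng.uniform(0.0, 0.5, n_tuned)
            if arm_assignment is None:
                arm_assignment = 1 + (3 * np.arange(n_tuned)) // n_tuned
            self.center_arm = np.asarray(arm_assignment)
        else:  # grid
            self.grid_phase = rng.uniform(0.0, 2.0 * np.pi, n_tuned)
            self.grid_period = rng.uniform(0.2, 0.6, n_tuned)

    def resample_centers(self, rng: np.random.Generator, keep_below: float = 0.2) -> None:
        """Redraw field centres beyond the retained prefix of the track,
        preserving the sensory objects near the start (shared trunk)."""
        if self.mode != "random":
            raise ValueError("center resampling applies to the random-centre mode")
        redraw = self.centers > keep_below
        self.centers = np.where(redraw, rng.uniform(0.0, 1.0, self.n_tuned), self.centers)

    def tuned_current(self, pos: float, arm: int = 1) -> np.ndarray:
        """Position-tuned component of the input current during run."""
        if self.mode in ("place", "random"):
            return self.A_F * np.exp(-0.5 * ((pos - self.centers) / self.sigma_F) ** 2)
        if self.mode == "ymaze":
            cur = self.A_F * np.exp(-0.5 * ((pos - self.centers) / self.sigma_F) ** 2)
            return np.where(self.center_arm == arm, cur, 0.0)
        return self.A_grid * np.exp(
            self.c_grid * np.cos(2.0 * np.pi * pos / self.grid_period - self.grid_phase))

    def step(self, pos: float, arm: int, running: bool, theta: float,
             bursts_on: bool, dt: float, rng: np.random.Generator) -> np.ndarray:
        n = self.noise.step(dt, rng)
        I = n.copy()
        if running:
            I[: self.n_tuned] += self.tuned_current(pos, arm) + 0.5 * theta - 0.5
            if self.dist_sources is not None:
                I[self.n_tuned:] += self.dist_sources.step(dt, rng) + 0.5 * theta - 0.5
        elif self.dist_sources is not None:
            self.dist_sources.step(dt, rng)  # keep the slow sources evolving
        if bursts_on:
            gate = self.burst_gate.step(dt, rng)
            I += gate * self.burst_noise.step(dt, rng)
        return self.phi_input * expit(I - self.theta_f)


class ExtInput:
    """External somatic input: theta drive, trigger pulses and OU noise.

    Trigger pulses are delivered to ``targets``; with ``bipolar`` sign
    structure all non-target neurons receive the negative pulse (linear
    track), otherwise the pulse is purely excitatory (Y-maze, branching).
    """

    def __init__(self, n: int, targets, *, bipolar: bool = True,
                 sigma_n: float = 0.1, tau_n: float = TAU_L):
        self.n = n
        self.noise = OUProcess(n, tau_n, sigma_n)
        self.bipolar = bipolar
        self.target_mask = np.zeros(n, dtype=bool)
        self.target_mask[np.asarray(targets, dtype=int)] = True

    def step(self, theta: float, trig: float, dt: float,
             rng: np.random.Generator) -> np.ndarray:
        ext = self.noise.step(dt, rng) + theta
        if trig:
            if self.bipolar:
                ext = ext + np.where(self.target_mask, trig, -trig)
            else:
                ext = ext + np.where(self.target_mask, trig, 0.0)
        return ext


@dataclass
class BehaviorSchedule:
    """Precomputed behavioural covariates on the simulation time grid."""

    t_ms: np.ndarray
    pos: np.ndarray
    arm: np.ndarray
    moving: np.ndarray          # strict: non-zero velocity (analysis mask)
    running: np.ndarray         # run epoch: theta / tuned input / low release prob
    A_theta: float = 10.0
    f_theta_kHz: float = 7.0 / 1000.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t_ms": self.t_ms, "pos": self.pos, "arm": self.arm,
            "moving": self.moving, "running": self.running,
        })
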