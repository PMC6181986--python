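"""Config-driven experiment orchestration.

Each runner reproduces one protocol family at configurable scale:

* single-cell learning under correlated / uncorrelated input groups and
  parameter sweeps over the coincidence weight ``alpha`` and threshold
  modulation ``beta`` (including the alternative calcium-BCM rule);
* the two-cell separation protocol and the correlation-switch stability
  protocol probing plastic dendritic inhibition;
* single-trial place-field learning on a linear track with place- or
  grid-tuned EC input, including the single-compartment and
  plasticity-off controls;
* long-term stability of place fields under spontaneous replay exposure;
* orthogonal memory formation on a Y-maze;
* experience-biased replay on a branching track.

Runs are seeded: one seed spawns independent sub-streams for weight
initialisation, stimulus noise, trigger timing and weight fluctuations,
so identical configurations reproduce bit-identical records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .analysis import (
    count_branch_sequences,
    information_per_spike,
    weight_contrast,
)
from .core_dynamics import NeuronParams
from .network import CellEnsemble, NetworkConfig, RecurrentNetwork
from .plasticity import PlasticityParams
from .records import SimulationRecord
from .stimuli import (
    ECInput,
    ExtInput,
    SingleCellInputs,
    TriggerProcess,
    moving_1d,
    position_1d,
    theta_drive,
    ymaze_position,
)

__all__ = [
    "ExperimentConfig",
    "PARAMETER_TABLE",
    "PRESETS",
    "run_experiment",
    "run_single_cell",
    "run_sweep",
    "run_alt_rule_sweep",
    "run_separation",
    "run_stability",
    "run_track",
    "run_replay",
    "run_ymaze",
    "run_branching",
    "report",
    "load_config",
]

#: single source of truth for the fixed model constants (Methods values)
PARAMETER_TABLE = {
    "theta_f": 5.0,
    "tau_L_ms": 10.0,
    "tau_STD_ms": 500.0,
    "tau_STF_ms": 200.0,
    "U_STF_rest": 0.5,
    "U_STF_run": 0.03,
    "phi_two_compartment_kHz": 0.08,
    "phi_single_compartment_kHz": 0.1,
    "phi_input_kHz": 0.08,
    "c0": 70.0,
    "tau_w_ms": 1000.0,
    "sigma_w_default": 0.001,
    "eta_decay_per_ms": 1e-7,
    "tau_mean_ms": 60000.0,
    "theta_inh": 0.5,
    "network_alpha": 0.9,
    "network_beta": 2.5,
    "network_gamma": 1.0,
    "network_eta": 1.0,
    "v_som": 20.0,
    "n_inh": 100,
    "A_theta": 10.0,
    "f_theta_kHz": 7.0 / 1000.0,
    "A_F": 5.0,
    "sigma_F": 0.1,
    "sigma_input_noise": 1.0,
    "sigma_ext_noise": 0.1,
    "tau_dist_ms": 500.0,
    "sigma_dist": 0.02,
    "A_grid": 5.0,
    "c_grid": 3.0,
    "tau_burst_ms": 100.0,
    "sigma_burst": 0.1,
    "w_max_chain": 18.0,
    "w_max_ymaze": 20.0,
    "w_prime_max": 14.0,
    "w_width": 5.0,
    "w_dnd_max": 5.0,
    "trigger_amp_track": 10.0,
    "trigger_ms_track": 10.0,
    "trigger_onset_ms_track": 100.0,
    "trigger_amp_ymaze": 5.0,
    "trigger_ms_ymaze": 200.0,
    "trigger_amp_branching": 5.0,
    "trigger_ms_branching": 500.0,
    "trigger_rate_hz": 1.0,
    "fig1_alpha": 0.5,
    "fig1_eta": 0.2,
    "fig1_sigma_w": 0.005,
    "fig3_alpha": 0.9,
    "fig3_beta": 2.5,
    "fig3_eta": 0.2,
    "n_bin_track": 50,
    "n_bin_ymaze": 75,
}


def _streams(seed: int) -> dict:
    """Named independent RNG streams derived from one seed."""
    names = ("init", "inputs", "triggers", "weight_noise", "ext")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# phase-driven network simulation
# ---------------------------------------------------------------------------

@dataclass
class Phase:
    """One behavioural phase of a network protocol.

    ``pos_fn`` maps phase-relative time in seconds to (pos, arm, moving);
    immobile phases leave it None.  ``forced_triggers`` lists
    (offset_ms, duration_ms) deterministic trigger pulses.
    """

    name: str
    duration_ms: float
    running: bool = False
    pos_fn: object | None = None
    bursts: bool = False
    plasticity: bool = True
    inh_plasticity: bool = True
    poisson_trigger: bool = False
    forced_triggers: tuple = ()

    # Within a run phase the animal alternates between movement segments and
    # brief stops (track ends, maze junction).  The movement-dependent state
    # (low release probability, theta drive, position-tuned EC input) follows
    # the instantaneous movement flag, and the Poisson trigger process is
    # armed whenever the animal is not actually moving.


def _run_phases(net: RecurrentNetwork, ec: ECInput, ext_gen: ExtInput,
                trig: TriggerProcess, phases, rngs: dict,
                dt: float = 1.0, record_every: int = 10,
                meta: dict | None = None) -> SimulationRecord:
    n_steps = int(round(sum(ph.duration_ms for ph in phases) / dt))
    n_samp = n_steps // record_every + 1
    n = net.n
    t_rec = np.zeros(n_samp)
    z_rec = np.zeros((n_samp, n), dtype=np.float32)
    x_rec = np.zeros((n_samp, n), dtype=np.float32)
    y_rec = np.zeros((n_samp, n), dtype=np.float32)
    pos_rec = np.zeros(n_samp, dtype=np.float32)
    arm_rec = np.zeros(n_samp, dtype=np.int16)
    mov_rec = np.zeros(n_samp, dtype=bool)
    run_rec = np.zeros(n_samp, dtype=bool)
    phase_idx = np.zeros(n_samp, dtype=np.int16)

    weights = {"initial_w_som": net.weights.w_som.copy(),
               "initial_w_dnd": net.weights.w_dnd.copy()}
    t_abs = 0.0
    k = 0
    samp = 0
    for pi, ph in enumerate(phases):
        forced = sorted(ph.forced_triggers)
        fi = 0
        steps = int(round(ph.duration_ms / dt))
        for s in range(steps):
            t_rel = s * dt
            while fi < len(forced) and forced[fi][0] <= t_rel:
                trig.force(forced[fi][1])
                fi += 1
            if ph.running and ph.pos_fn is not None:
                pos, arm, moving = ph.pos_fn(t_rel / 1000.0)
                theta = theta_drive(t_abs) if moving else 0.0
            else:
                pos, arm, moving, theta = 0.0, 1, False, 0.0
            trig_active = ph.poisson_trigger or (ph.running and not moving)
            trig_val = trig.step(dt, trig_active, rngs["triggers"])
            u_ec = ec.step(pos, arm, moving, theta, ph.bursts, dt, rngs["inputs"])
            ext = ext_gen.step(theta, trig_val, dt, rngs["ext"])
            z = net.step(u_ec, ext, dt, running=moving,
                         plasticity_on=ph.plasticity,
                         inh_plasticity_on=ph.inh_plasticity,
                         rng=rngs["weight_noise"])
            if k % record_every == 0:
                t_rec[samp] = t_abs
                z_rec[samp] = z
                x_rec[samp] = net.x
                y_rec[samp] = net.y
                pos_rec[samp] = pos
                arm_rec[samp] = arm
                mov_rec[samp] = moving
                run_rec[samp] = ph.running
                phase_idx[samp] = pi
                samp += 1
            k += 1
            t_abs += dt
        weights[f"after_{ph.name}_w_dnd"] = net.weights.w_dnd.copy()
    weights["final_w_som"] = net.weights.w_som.copy()
    weights["final_w_dnd"] = net.weights.w_dnd.copy()
    weights["final_v_dnd"] = net.weights.v_dnd.copy()
    return SimulationRecord(
        t_ms=t_rec[:samp], z=z_rec[:samp], x=x_rec[:samp], y=y_rec[:samp],
        pos=pos_rec[:samp], arm=arm_rec[:samp], moving=mov_rec[:samp],
        running=run_rec[:samp], weights=weights,
        series={"phase": phase_idx[:samp]}, meta=meta or {})


# ---------------------------------------------------------------------------
# single-cell protocols
# ---------------------------------------------------------------------------

#: presynaptic group index sets for the 50+50 input layout
FIG1_GROUPS = {"A": np.arange(0, 10), "B": np.arange(10, 50),
               "Ap": np.arange(0, 10), "Bp": np.arange(10, 50)}


def run_single_cell(condition: str = "correlated", *, model: str = "two",
                    n_trials: int = 1, duration_s: float = 1500.0,
                    seed: int = 0, alpha: float = 0.5, beta: float = 0.0,
                    gamma: float = 1.0, eta: float = 0.2,
                    sigma_w: float = 0.005, dt: float = 1.0,
                    record_every_ms: float = 1000.0,
                    literal_mapping: bool = False) -> dict:
    """Single two-compartment (or single-compartment) neuron learning from
    grouped OU-driven inputs; returns weight trajectories and the final
    minority-vs-majority weight contrasts."""
    if model == "single":
        alpha = beta = gamma = 0.0
    rngs = _streams(seed)
    gen = SingleCellInputs(condition, n_trials, literal_mapping=literal_mapping)
    cells = CellEnsemble(n_trials, 1, 50, 50, rngs["init"], alpha=alpha,
                         beta=beta, gamma=gamma, eta=eta, sigma_w=sigma_w)
    steps = int(round(duration_s * 1000.0 / dt))
    rec_every = max(1, int(round(record_every_ms / dt)))
    times, traj = [], []
    for k in range(steps):
        u_som, u_dnd = gen.step(k * dt, dt, rngs["inputs"])
        cells.step(u_som, u_dnd, dt, rngs["weight_noise"])
        if k % rec_every == 0:
            times.append(k * dt)
            traj.append([cells.w_som[:, 0, :10].mean(axis=1),
                         cells.w_som[:, 0, 10:].mean(axis=1),
                         cells.w_dnd[:, 0, :10].mean(axis=1),
                         cells.w_dnd[:, 0, 10:].mean(axis=1)])
    w_som = cells.w_som[:, 0, :]
    w_dnd = cells.w_dnd[:, 0, :]
    som, dnd = weight_contrast(w_som, w_dnd, FIG1_GROUPS)
    return {"t_ms": np.array(times),
            "group_means": np.array(traj),  # (samples, 4, trials)
            "w_som": w_som, "w_dnd": w_dnd,
            "contrast_som": som, "contrast_dnd": dnd,
            "summary": {"contrast_som_mean": float(np.mean(som)),
                        "contrast_dnd_mean": float(np.mean(dnd))}}


def run_sweep(alphas, betas, *, duration_s: float = 1500.0, seed: int = 0,
              eta: float = 0.2, sigma_w: float = 0.005, dt: float = 1.0,
              condition: str = "correlated") -> dict:
    """Grid of single-cell runs over (alpha, beta), vectorised as a batch.

    Returns contrast matrices of shape (len(alphas), len(betas)) for both
    compartments plus the mean final weight per grid point (weights
    collapse toward zero under strong threshold modulation).
    """
    alphas = np.asarray(alphas, dtype=float)
    betas = np.asarray(betas, dtype=float)
    A, Bg = np.meshgrid(alphas, betas, indexing="ij")
    B = A.size
    rngs = _streams(seed)
    gen = SingleCellInputs(condition, B)
    cells = CellEnsemble(B, 1, 50, 50, rngs["init"], alpha=A.ravel(),
                         beta=Bg.ravel(), gamma=1.0, eta=eta, sigma_w=sigma_w)
    for k in range(int(round(duration_s * 1000.0 / dt))):
        u_som, u_dnd = gen.step(k * dt, dt, rngs["inputs"])
        cells.step(u_som, u_dnd, dt, rngs["weight_noise"])
    som, dnd = weight_contrast(cells.w_som[:, 0, :], cells.w_dnd[:, 0, :],
                               FIG1_GROUPS)
    mean_w = np.concatenate([cells.w_som, cells.w_dnd], axis=-1).mean(axis=(1, 2))
    shape = (len(alphas), len(betas))
    return {"alphas": alphas, "betas": betas,
            "contrast_som": som.reshape(shape),
            "contrast_dnd": dnd.reshape(shape),
            "mean_weight": mean_w.reshape(shape)}


def run_alt_rule_sweep(alpha_som_values, alpha_dnd_values, *,
                       duration_s: float = 1500.0, seed: int = 0,
                       eta: float = 0.2, sigma_w: float = 0.005,
                       dt: float = 1.0) -> dict:
    """Sweep of the alternative calcium-BCM rule over (alpha_som, alpha_dnd)
    at beta = 0, under correlated minority groups."""
    a_s = np.asarray(alpha_som_values, dtype=float)
    a_d = np.asarray(alpha_dnd_values, dtype=float)
    As, Ad = np.meshgrid(a_s, a_d, indexing="ij")
    B = As.size
    rngs = _streams(seed)
    gen = SingleCellInputs("correlated", B)
    cells = CellEnsemble(B, 1, 50, 50, rngs["init"], alpha=0.0, beta=0.0,
                         gamma=1.0, eta=eta, sigma_w=sigma_w, alt_rule=True,
                         alpha_som=As.ravel(), alpha_dnd=Ad.ravel())
    for k in range(int(round(duration_s * 1000.0 / dt))):
        u_som, u_dnd = gen.step(k * dt, dt, rngs["inputs"])
        cells.step(u_som, u_dnd, dt, rngs["weight_noise"])
    som, dnd = weight_contrast(cells.w_som[:, 0, :], cells.w_dnd[:, 0, :],
                               FIG1_GROUPS)
    shape = (len(a_s), len(a_d))
    return {"alpha_som": a_s, "alpha_dnd": a_d,
            "contrast_som": som.reshape(shape),
            "contrast_dnd": dnd.reshape(shape)}


#: dendritic group indices for the separation / stability protocols
FIG3_GROUPS = {"A": np.arange(0, 10), "B": np.arange(0, 10),
               "Ap": np.arange(0, 10), "Bp": np.arange(10, 20)}


def run_separation(*, eta_inh: float = 0.2, duration_s: float = 600.0,
                   seed: int = 0, n_trials: int = 1, dt: float = 1.0) -> dict:
    """Two cells sharing an interneuron receive a common somatic input and
    two uncorrelated dendritic groups, both correlated with the somatic
    group; with plastic dendritic inhibition the cells specialise on
    different dendritic groups."""
    rngs = _streams(seed)
    gen = SingleCellInputs("separation", n_trials)
    cells = CellEnsemble(n_trials, 2, 10, 20, rngs["init"], alpha=0.9,
                         beta=2.5, gamma=1.0, eta=0.2, eta_inh=eta_inh,
                         sigma_w=0.001, v_som=20.0, inhibition=True)
    for k in range(int(round(duration_s * 1000.0 / dt))):
        u_som, u_dnd = gen.step(k * dt, dt, rngs["inputs"])
        cells.step(u_som, u_dnd, dt, rngs["weight_noise"])
    # per-cell dendritic contrast: group A minus group B
    contrast = cells.w_dnd[:, :, :10].sum(axis=2) - cells.w_dnd[:, :, 10:].sum(axis=2)
    return {"dendritic_contrast": contrast, "w_dnd": cells.w_dnd,
            "v_dnd": cells.v_dnd,
            "summary": {"cells_select_different_groups": bool(
                np.all(contrast[:, 0] * contrast[:, 1] < 0))}}


def run_stability(*, inhibition: bool = True,
                  phase_s: tuple = (300.0, 300.0, 600.0), seed: int = 0,
                  n_trials: int = 1, dt: float = 1.0,
                  record_every_ms: float = 1000.0) -> dict:
    """Correlation-switch protocol for one self-inhibiting cell.

    Phase 1: all dendritic sources independent.  Phase 2: dendritic group A
    shares the somatic source (A is learned).  Phase 3: group B shares the
    somatic source instead.  Returns the dendritic A-minus-B contrast at
    the end of phase 2 and at the end of the run; their ratio measures
    retention of the learned selectivity across the correlation switch.
    """
    t1 = phase_s[0] * 1000.0
    t2 = (phase_s[0] + phase_s[1]) * 1000.0
    total = sum(phase_s) * 1000.0
    rngs = _streams(seed)
    gen = SingleCellInputs("stability", n_trials, phase_times=(t1, t2))
    cells = CellEnsemble(n_trials, 1, 10, 20, rngs["init"], alpha=0.9,
                         beta=2.5, gamma=1.0, eta=0.2,
                         eta_inh=0.2 if inhibition else 0.0,
                         sigma_w=0.001, v_som=20.0, inhibition=True)
    rec_every = max(1, int(round(record_every_ms / dt)))
    times, contrasts = [], []
    learned = None
    for k in range(int(round(total / dt))):
        t = k * dt
        u_som, u_dnd = gen.step(t, dt, rngs["inputs"])
        cells.step(u_som, u_dnd, dt, rngs["weight_noise"])
        if k % rec_every == 0:
            c = cells.w_dnd[:, 0, :10].sum(axis=1) - cells.w_dnd[:, 0, 10:].sum(axis=1)
            times.append(t)
            contrasts.append(c)
        if learned is None and t >= t2 - dt:
            learned = cells.w_dnd[:, 0, :10].sum(axis=1) \
                - cells.w_dnd[:, 0, 10:].sum(axis=1)
    final = cells.w_dnd[:, 0, :10].sum(axis=1) - cells.w_dnd[:, 0, 10:].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        retention = np.where(learned != 0, final / learned, np.nan)
    return {"t_ms": np.array(times), "contrast": np.array(contrasts),
            "learned_contrast": learned, "final_contrast": final,
            "retention": retention, "v_dnd": cells.v_dnd,
            "summary": {"retention_mean": float(np.mean(retention))}}


# ---------------------------------------------------------------------------
# recurrent-network protocols
# ---------------------------------------------------------------------------

def _track_pos(offset_s: float):
    def fn(t_rel_s: float):
        t = t_rel_s + offset_s
        return float(position_1d(t)), 1, bool(moving_1d(t))
    return fn


def _scaled_out_and_back(run_s: float):
    """First-traversal profile scaled to ``run_s`` seconds: out for 1/3 of
    the time, pause, back for 1/3, rest."""
    seg = run_s / 3.0

    def fn(t: float):
        if t < seg:
            return t / seg, 1, True
        if t < 1.5 * seg:
            return 1.0, 1, False
        if t < 2.5 * seg:
            return 1.0 - (t - 1.5 * seg) / seg, 1, True
        return 0.0, 1, False
    return fn


def _make_track_network(model: str, familiarity: str, inputs: str,
                        n_ca3: int, eta: float, eta_inh: float,
                        beta: float, gamma: float, phi: float | None,
                        w_scale: float, rngs: dict,
                        n_dist: int | None = None,
                        v_som: float = 20.0):
    if inputs == "place":
        n_tuned = n_ca3
        nd = int(round(n_ca3 * 2 / 3)) if n_dist is None else n_dist
        ec = ECInput("place", n_tuned, nd, rngs["init"])
    elif inputs == "grid":
        n_tuned = int(round(n_ca3 * 2 / 3))
        nd = int(round(n_ca3 / 3)) if n_dist is None else n_dist
        ec = ECInput("grid", n_tuned, nd, rngs["init"])
    else:
        raise ValueError("inputs must be 'place' or 'grid'")
    single = model == "single"
    if phi is None:
        phi = 0.1 if single else 0.08
    cfg = NetworkConfig(
        n_ca3=n_ca3, n_ec=ec.n_ec, topology="chain", familiarity=familiarity,
        w_scale=w_scale, single_compartment=single, v_som_value=v_som,
        neuron=NeuronParams(phi=phi, beta=beta, gamma=gamma),
        plasticity=PlasticityParams(alpha=0.9, eta=eta, eta_inh=eta_inh,
                                    sigma_w=0.001))
    net = RecurrentNetwork(cfg, rngs["init"])
    ext = ExtInput(n_ca3, targets=np.arange(10), bipolar=True)
    return net, ec, ext


def run_track(*, model: str = "two", familiarity: str = "unfamiliar",
              inputs: str = "place", n_ca3: int = 300, eta: float | None = None,
              eta_inh: float = 1.0, beta: float = 2.5, gamma: float = 1.0,
              phi: float | None = None, w_scale: float = 1.0, seed: int = 0,
              v_som: float = 20.0, dt: float = 1.0, record_every: int = 10,
              info_from_s: float = 25.0, n_bin: int = 50) -> dict:
    """Full linear-track session (10 s immobility + three traversals) and
    place-field quality measured over moving periods after the first
    traversal."""
    if eta is None:
        eta = 0.5 if model == "single" else 1.0
    rngs = _streams(seed)
    net, ec, ext = _make_track_network(model, familiarity, inputs, n_ca3,
                                       eta, eta_inh, beta, gamma, phi,
                                       w_scale, rngs, v_som=v_som)
    trig = TriggerProcess(rate_hz=1.0, pulse_ms=10.0, amp=10.0)
    phases = [
        Phase("immobility", 10_000.0, running=False, poisson_trigger=True),
        Phase("runs", 40_000.0, running=True, pos_fn=_track_pos(10.0),
              forced_triggers=((0.0, 100.0),)),
    ]
    record = _run_phases(net, ec, ext, trig, phases, rngs, dt, record_every,
                         meta={"preset": "track", "model": model, "seed": seed,
                               "familiarity": familiarity, "inputs": inputs,
                               "eta": eta, "n_ca3": n_ca3})
    mask = record.moving & (record.t_ms >= info_from_s * 1000.0)
    summary = information_per_spike(record.z, record.pos,
                                    mask, n_bin=n_bin)
    return {"record": record, "place_fields": summary,
            "summary": {"mean_info_per_spike": summary.mean_info,
                        "n_included_cells": int(summary.included.sum())}}


def run_replay(*, inhibition: bool = True, n_ca3: int = 300,
               exposure_s: float = 600.0, seed: int = 0, dt: float = 1.0,
               record_every: int = 10, n_bin: int = 50) -> dict:
    """Learn an unfamiliar track in one traversal, then expose the network
    to spontaneous activity (EC noise, population bursts, triggered CA3
    sequences), then probe place fields with one more traversal.

    The pre-exposure probe runs on a copy of the post-learning state, so
    pre and post information are measured by the same protocol.  With
    ``inhibition`` False, dendritic inhibitory weights are zeroed (and
    their plasticity disabled) for the exposure and probe.
    """
    rngs = _streams(seed)
    net, ec, ext = _make_track_network("two", "unfamiliar", "place", n_ca3,
                                       1.0, 1.0, 2.5, 1.0, None, 1.0, rngs,
                                       n_dist=0)
    trig = TriggerProcess(rate_hz=1.0, pulse_ms=10.0, amp=10.0)
    learn = [
        Phase("immobility", 10_000.0, poisson_trigger=True),
        Phase("first_run", 15_000.0, running=True, pos_fn=_track_pos(10.0),
              forced_triggers=((0.0, 100.0),)),
    ]
    _run_phases(net, ec, ext, trig, learn, rngs, dt, record_every)

    import copy as _copy

    probe_phase = [Phase("probe", 10_000.0, running=True,
                         pos_fn=_track_pos(40.0))]

    def probe(bundle, stream_seed):
        net_c, ec_c, ext_c, trig_c = bundle
        sub = _streams(stream_seed)
        rec = _run_phases(net_c, ec_c, ext_c, trig_c, probe_phase, sub,
                          dt, record_every)
        return information_per_spike(rec.z, rec.pos, rec.moving, n_bin=n_bin), rec

    pre_bundle = _copy.deepcopy((net, ec, ext, trig))
    probe_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    pre_info, pre_rec = probe(pre_bundle, probe_seed)

    if not inhibition:
        net.weights.v_dnd[:] = 0.0
        net.pp = replace(net.pp, eta_inh=0.0)
    exposure = [Phase("exposure", exposure_s * 1000.0, bursts=True,
                      poisson_trigger=True)]
    _run_phases(net, ec, ext, trig, exposure, rngs, dt, record_every)
    post_info, post_rec = probe((net, ec, ext, trig), probe_seed + 1)

    pre, post = pre_info.mean_info, post_info.mean_info
    return {"pre_info": pre, "post_info": post,
            "retention": post / pre if pre else float("nan"),
            "pre_fields": pre_info, "post_fields": post_info,
            "pre_record": pre_rec, "post_record": post_rec,
            "summary": {"pre_info": pre, "post_info": post,
                        "retention": post / pre if pre else float("nan")}}


def run_ymaze(*, inhibition: bool = True, n_per_group: int = 150,
              n_cycles: int = 3, seed: int = 0, dt: float = 1.0,
              record_every: int = 10, n_bin: int = 75) -> dict:
    """Y-maze session: rest at the junction, then one 10-s cycle per arm.

    Returns, per arm, which preexisting chain group responded most
    strongly while the animal ran on that arm; with dendritic inhibition
    the three arms recruit three distinct groups.
    """
    n_ca3 = 3 * n_per_group
    rngs = _streams(seed)
    ec = ECInput("ymaze", n_ca3, 0, rngs["init"])
    cfg = NetworkConfig(
        n_ca3=n_ca3, n_ec=n_ca3, topology="ymaze", ec_init="uniform",
        neuron=NeuronParams(phi=0.08, beta=2.5, gamma=1.0),
        plasticity=PlasticityParams(alpha=0.9, eta=1.0,
                                    eta_inh=1.0 if inhibition else 0.0,
                                    sigma_w=0.001))
    net = RecurrentNetwork(cfg, rngs["init"])
    n_trig = min(10, n_per_group)
    targets = np.concatenate([g * n_per_group + np.arange(n_trig)
                              for g in range(3)])
    ext = ExtInput(n_ca3, targets=targets, bipolar=False)
    trig = TriggerProcess(rate_hz=1.0, pulse_ms=200.0, amp=5.0)
    first_visits = tuple((c * 10_000.0 + 2_500.0, 200.0)
                         for c in range(min(3, n_cycles)))
    phases = [
        Phase("rest", 10_000.0, poisson_trigger=True),
        Phase("cycles", n_cycles * 10_000.0, running=True,
              pos_fn=lambda t: ymaze_position(t + 10.0),
              forced_triggers=first_visits),
    ]
    record = _run_phases(net, ec, ext, trig, phases, rngs, dt, record_every,
                         meta={"preset": "ymaze", "seed": seed,
                               "inhibition": inhibition})
    arm_group = {}
    group_rates = {}
    for arm in (1, 2, 3):
        mask = record.moving & (record.arm == arm)
        rates = record.z[mask].mean(axis=0) if mask.any() else np.zeros(n_ca3)
        per_group = rates.reshape(3, n_per_group).sum(axis=1)
        arm_group[arm] = int(np.argmax(per_group))
        group_rates[arm] = per_group
    distinct = len(set(arm_group.values()))
    pos_global = (record.arm - 1 + np.clip(record.pos, 0, 0.5) / 0.5) / 3.0
    info = information_per_spike(record.z, pos_global, record.moving, n_bin=n_bin)
    return {"record": record, "arm_group": arm_group,
            "group_rates": group_rates, "n_distinct_groups": distinct,
            "place_fields": info,
            "summary": {"n_distinct_groups": distinct,
                        "mean_info_per_spike": info.mean_info}}


def run_branching(*, n_root: int = 100, n_branch: int = 150,
                  pre_s: float = 60.0, run_s: float = 15.0,
                  post_s: float = 60.0, seed: int = 0, dt: float = 1.0,
                  record_every: int = 10, **count_kwargs) -> dict:
    """Branching-track protocol: count spontaneous sequences entering each
    branch before and after a single experience.

    Plasticity is disabled during the immobile counting windows so that
    the pre/post comparison isolates the effect of the experience.  The
    trained branch is the branch that carried the propagating activity
    during the run.
    """
    n_ca3 = n_root + 2 * n_branch
    rngs = _streams(seed)
    n_ec = int(round(0.75 * n_ca3))
    ec = ECInput("random", n_ec, 0, rngs["init"])
    cfg = NetworkConfig(
        n_ca3=n_ca3, n_ec=n_ec, topology="branching", n_root=n_root,
        n_branch=n_branch, ec_init="uniform",
        neuron=NeuronParams(phi=0.08, beta=2.5, gamma=1.0),
        plasticity=PlasticityParams(alpha=0.9, eta=1.0, eta_inh=1.0,
                                    sigma_w=0.001))
    net = RecurrentNetwork(cfg, rngs["init"])
    ext = ExtInput(n_ca3, targets=np.arange(min(10, n_root)), bipolar=True)
    trig = TriggerProcess(rate_hz=1.0, pulse_ms=500.0, amp=5.0)
    phases = [
        Phase("pre", pre_s * 1000.0, poisson_trigger=True, plasticity=False),
        Phase("experience", run_s * 1000.0, running=True,
              pos_fn=_scaled_out_and_back(run_s),
              forced_triggers=((0.0, 500.0),)),
        Phase("post", post_s * 1000.0, poisson_trigger=True, plasticity=False),
    ]
    record = _run_phases(net, ec, ext, trig, phases, rngs, dt, record_every,
                         meta={"preset": "branching", "seed": seed})
    root = np.arange(n_root)
    bA = np.arange(n_root, n_root + n_branch)
    bB = np.arange(n_root + n_branch, n_ca3)
    branches = {"A": np.concatenate([root, bA]), "B": np.concatenate([root, bB])}
    phase = record.series["phase"]
    sample_ms = record.sample_ms
    counts = {}
    for name, pi in (("pre", 0), ("post", 2)):
        m = phase == pi
        counts[name] = count_branch_sequences(record.z[m], sample_ms, branches,
                                              **count_kwargs).counts
    run_mask = phase == 1
    run_rate_A = float(record.z[run_mask][:, bA].sum())
    run_rate_B = float(record.z[run_mask][:, bB].sum())
    trained = "A" if run_rate_A >= run_rate_B else "B"

    def frac(c):
        tot = c["A"] + c["B"]
        return c[trained] / tot if tot else float("nan")

    return {"record": record, "counts_pre": counts["pre"],
            "counts_post": counts["post"], "trained_branch": trained,
            "fraction_pre": frac(counts["pre"]),
            "fraction_post": frac(counts["post"]),
            "summary": {"trained_branch": trained,
                        "fraction_pre": frac(counts["pre"]),
                        "fraction_post": frac(counts["post"]),
                        "n_events_pre": counts["pre"]["A"] + counts["pre"]["B"],
                        "n_events_post": counts["post"]["A"] + counts["post"]["B"]}}


# ---------------------------------------------------------------------------
# presets, config and reporting
# ---------------------------------------------------------------------------

PRESETS = {
    "fig1_correlated": (run_single_cell, {"condition": "correlated",
                                          "duration_s": 1500.0}),
    "fig1_uncorrelated": (run_single_cell, {"condition": "uncorrelated",
                                            "duration_s": 1500.0}),
    "fig1_single": (run_single_cell, {"condition": "correlated",
                                      "model": "single", "duration_s": 1500.0}),
    "fig2_sweep": (run_sweep, {"alphas": np.linspace(0.0, 1.0, 5),
                               "betas": np.linspace(0.0, 4.0, 5),
                               "duration_s": 1500.0}),
    "fig2c_altrule": (run_alt_rule_sweep, {"alpha_som_values": [0.1, 0.5, 0.9],
                                           "alpha_dnd_values": [0.1, 0.5, 0.9],
                                           "duration_s": 1500.0}),
    "fig3_separation": (run_separation, {"duration_s": 600.0}),
    "fig3_stability": (run_stability, {"phase_s": (300.0, 300.0, 600.0)}),
    "fig4_track": (run_track, {"model": "two", "familiarity": "unfamiliar"}),
    "fig4_controls": (run_track, {"model": "two", "familiarity": "unfamiliar",
                                  "eta": 0.0}),
    "fig4_single": (run_track, {"model": "single"}),
    "fig5_grid": (run_track, {"inputs": "grid"}),
    "fig6_replay": (run_replay, {"exposure_s": 600.0}),
    "fig7_ymaze": (run_ymaze, {}),
    "fig8_branching": (run_branching, {}),
}

#: kwargs that the --scale flag multiplies (durations, in seconds)
_SCALABLE = ("duration_s", "exposure_s", "pre_s", "post_s")


@dataclass
class ExperimentConfig:
    """Preset selection plus overrides, seed and output options."""

    preset: str
    seed: int = 0
    scale: float = 1.0
    overrides: dict = field(default_factory=dict)
    out: str | None = None

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; "
                             f"known: {sorted(PRESETS)}")


def load_config(path) -> ExperimentConfig:
    """Read an ExperimentConfig from a YAML file."""
    import yaml

    with open(path) as f:
        data = yaml.safe_load(f) or {}
    return ExperimentConfig(**data)


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute a preset with overrides; optionally write record/summary."""
    runner, defaults = PRESETS[config.preset]
    kwargs = dict(defaults)
    kwargs.update(config.overrides)
    if config.scale != 1.0:
        for key in _SCALABLE:
            if key in kwargs:
                kwargs[key] = kwargs[key] * config.scale
        if "phase_s" in kwargs:
            kwargs["phase_s"] = tuple(p * config.scale for p in kwargs["phase_s"])
    result = runner(seed=config.seed, **kwargs)
    if config.out:
        rec = result.get("record")
        if isinstance(rec, SimulationRecord):
            rec.to_hdf5(config.out)
        if "summary" in result:
            import json
            import pathlib

            p = pathlib.Path(config.out)
            p.with_suffix(".summary.json").write_text(
                json.dumps(result["summary"], indent=2, default=str))
    return result


def report(record: SimulationRecord, outdir) -> list:
    """Render standard figures (rate heatmap, behaviour, weight matrices)
    from a saved record, without re-simulating."""
    import pathlib

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if record.z is None or len(record.t_ms) == 0:
        raise ValueError("record is empty; nothing to report")
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True,
                             gridspec_kw={"height_ratios": [3, 1]})
    t_s = record.t_ms / 1000.0
    axes[0].imshow(record.z.T, aspect="auto", origin="lower",
                   extent=[t_s[0], t_s[-1], 0, record.z.shape[1]],
                   cmap="hot")
    axes[0].set_ylabel("neuron")
    if record.pos is not None:
        axes[1].plot(t_s, record.pos, lw=0.8)
        axes[1].set_ylabel("position")
    axes[1].set_xlabel("time (s)")
    path = outdir / "rates.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    for key in ("initial_w_som", "final_w_som", "final_w_dnd"):
        if key in record.weights:
            fig, ax = plt.subplots(figsize=(5, 4))
            im = ax.imshow(record.weights[key], aspect="auto", cmap="viridis")
            fig.colorbar(im, ax=ax)
            ax.set_title(key)
            path = outdir / f"{key}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
    return written
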