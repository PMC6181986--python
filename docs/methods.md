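# Model and methods

`preplaynet` simulates rate-based two-compartment pyramidal neurons and
recurrent networks of them, together with the stimulus and behaviour
protocols needed to study how spontaneous (preplay) firing sequences can
serve as templates for single-trial spatial learning.  This note records
the model, the numerical choices, and the places where the design was
genuinely open.

## The two-compartment neuron

Each neuron has a somatic compartment (soma plus proximal/basal dendrites,
receiving recurrent or bottom-up input) and a distal dendritic compartment
(apical tuft, receiving afferent/top-down input).  Compartment activations
are sigmoidal functions of their synaptic drive,

    x(t) = f( Σ_j w_som_j I_som_j − inh_som + β y(t−Δt) + ext ),
    y(t) = f( Σ_j w_dnd_j I_dnd_j − inh_dnd + β x(t−Δt) ),
    f(I) = 1 / (1 + exp(−(I − θ_f))),   θ_f = 5,

with a cross-compartment delay Δt = 1 ms and threshold-modulation gain β.
Coincident activation of both compartments stands in for dendritic calcium
spikes and multiplies the output gain:

    z(t) = (1 + γ y(t)) · φ · x(t),   φ = 0.08 kHz (two-compartment),
                                       φ = 0.1 kHz (single-compartment control).

Units are milliseconds and kHz throughout (0.08 kHz = 80 Hz); the "1 Hz"
analysis threshold is 0.001 kHz.

Synaptic drive is a low-pass filter of presynaptic rates, dI/dt = −I/τ_L +
u·D·F with τ_L = 10 ms, where D ∈ [0,1] and F ∈ [U_STF, 1] are short-term
depression and facilitation variables (τ_STD = 500 ms, τ_STF = 200 ms).
The baseline release probability U_STF is 0.5 at rest; at recurrent
synapses it drops to 0.03 whenever the animal is moving (a cholinergic-like
modulation that converts fast, depression-dominated preplay sequences into
slow, facilitation-gated theta-paced propagation), and F at recurrent
synapses is reset to 0.03 at each movement onset.

## Plasticity

Excitatory weights follow a second-order stochastic dynamics: the
instantaneous update target

    g_som = η [ (1−α) x (x − θ_som) + α x y ] (1−x) I_som_j
    g_dnd = η [ (1−α) y (y − θ_dnd) + α x y ] (1−y) I_dnd_j

is low-pass filtered with τ_w = 1000 ms into Δw, and the weight integrates
Δw while decaying at rate η_decay = 1e−7 /ms and fluctuating with
amplitude σ_w.  The first bracket term is BCM-style Hebbian plasticity
with sliding thresholds θ = c0 E², c0 = 70, where E is a running mean of
the compartment's activity (τ_mean = 60 s); the second term is
coincidence-driven LTP.  α ∈ [0,1] weighs the two: for α = 0 each
compartment performs variance-driven (PCA-like) learning; large α yields
correlation-driven (CCA-like) learning across the compartments.  Weights
are clipped at zero and recurrent self-connections pinned at zero every
step.  Dendrite-targeting inhibitory weights follow the same functional
form with a fixed threshold θ_inh = 0.5 and no fluctuation term.

For β = 0 and frozen thresholds the time-averaged update is exactly the
gradient of

    L = (1−α)(E[x²]/2 + E[y²]/2 − θ_som E[x] − θ_dnd E[y]) + α E[xy],

which the acceptance suite verifies by central finite differences on a
three-input toy neuron (relative error ≤ 1e−3).  Note that writing the
homeostatic term as c0 E[x]³ (as `objective_value` does) yields a factor-3
mismatch with θ = c0 E[x]² under full differentiation; the frozen-threshold
form above is the one whose gradient reproduces the implemented rule, and
is what the gradient test uses.

An alternative "calcium-BCM" rule is also implemented, in which the
coincidence product enters the effective activity z_som = (1−α_som)x +
α_som·x·y (dendritic analogue likewise) and plain BCM is applied to that
activity, with sliding thresholds computed from running means of z.

## Feedback inhibition

Pyramidal output traces are mixed by fixed random projections onto n_inh
inhibitory readouts, separately for perisomatic and dendrite-targeting
inhibition.  Two normalisations of the projection matrix are provided:

* per-source (each presynaptic column sums to 1/n_inh; the default and
  the one the network uses) — the summed readout output then equals the
  population-summed trace divided by n_inh, so a localised bump of
  activity exerts the same absolute inhibition at any network size, and
  each individual readout signal is small (~ population sum / n_inh²);
* per-readout (each row sums to 1; optional) — each readout is an O(1)
  random convex average of the population trace.

The choice matters most for the *plastic* dendritic inhibitory weights,
which are learned from zero against the readout signals: under the
per-source form inhibitory plasticity is slow, building functional
dendritic suppression over hundreds of seconds of strong coincident
activity (the replay-exposure timescale), whereas under the per-readout
form it acts within seconds and, in the recurrent network, silences the
dendritic compartments within a single session.  Somatic inhibitory
weights are fixed and uniform at v_som = 20 (the value used in the
two-cell circuit, where the single readout sums the cells' traces), so
the summed somatic feedback is 0.2 times the population-summed output
trace.

## Stimuli and behaviour

* Ornstein–Uhlenbeck sources: ds/dt = −s/τ + σ ε(t), discretised exactly
  in distribution with stationary variance σ²τ/2 (the variance implied by
  unit-variance Gaussian increments per millisecond).
* Single-cell protocols: minority/majority input groups driven by shared
  or independent OU sources through τ_L input filters, rates
  φ_input·f(I); the two-cell separation protocol and the three-phase
  correlation-switch stability protocol.
* Linear track: piecewise-linear back-and-forth trajectory (three
  traversals between 10 s and 50 s); place-tuned EC neurons with evenly
  spaced field centres (amplitude 5, width 0.1), distractor neurons driven
  by slow independent OU sources, strong OU input noise (σ = 1); theta
  (7 Hz, amplitude 10) delivered to all somata during movement and at half
  amplitude to EC; dentate-like trigger pulses (amplitude 10, 10 ms,
  Poisson at 1 Hz) during immobility and a forced 100-ms trigger at first
  run onset.  Stationary segments at the track ends are treated as
  immobility (theta off, release probability restored, triggers armed):
  the release-probability switch is tied to movement onsets, which occur
  several times per session.
* Grid-cell variant: von-Mises-like spatial tuning exp(c·cos(2π pos/λ −
  φ)) with period λ ~ U[0.2, 0.6] and phase ~ U[0, 2π] per cell.
* Replay protocol: after a single traversal, spontaneous activity with EC
  population bursts (Poisson 1 Hz, 200 ms each, multiplying an OU current)
  and triggered CA3 sequences; place fields probed by one further
  traversal on a copy of the state before and after exposure.
* Y-maze: three 150-neuron chain groups without cross-group weights
  (w_max = 20), arm-specific EC tuning, positive-only 200-ms triggers
  (amplitude 5) at each arm's first run.
* Branching track: trunk + two branches (cross-branch weights zero,
  junction couplings w′_max = 14), random EC field centres on [0,1],
  500-ms amplitude-5 triggers; plasticity disabled during the immobile
  counting windows.

## Analysis

* Spatial information per spike: Σ_i (λ_i/λ) log2(λ_i/λ) p_i over position
  bins (50 on the track, 75 = 3×25 on the Y-maze), restricted to moving
  samples, averaged over cells with mean rate > 1 Hz.  Base-2 logarithm
  (bits); unvisited bins have zero occupancy and silent bins contribute 0.
* Weight contrast: Σ_A w − Σ_B w per compartment; positive values indicate
  correlation-driven (CCA-like) learning of the minority groups.
* Sequence counting: rates smoothed with a 100-ms Gaussian; an active bout
  of a chain (summed rate above 0.003 kHz per neuron) counts as a
  propagation event if its entry centre of mass lies within the first 20%
  of the chain and the centre of mass reaches 90% within 2 s.
* Reference decompositions: scikit-learn PCA per input pathway and CCA
  across pathways, used only as external references.

## Numerical choices

* dt = 1 ms forward stepping; the 1-ms cross-compartment delay is exactly
  one step.  Linear filters (synaptic traces, running means, OU processes,
  the Δw relaxation, the multiplicative weight decay) use the exact
  exponential update, so closed-form decay curves and fixed points are
  reproduced to machine precision; the nonlinear short-term-plasticity
  pair uses forward Euler (its fixed points coincide with the ODE fixed
  points).
* The weight fluctuation σ_w ε(t) is applied every 10 steps with amplitude
  σ_w √(10·dt), preserving the injected variance per unit time; per-step
  Gaussian generation would otherwise dominate the total simulation cost.
* Initial conditions: compartment activations start at the zero-input
  fixed point f(0); synaptic traces at 0; D = 1, F = U_STF; running means
  (hence thresholds) at 0, which is maximally permissive for early LTP;
  dendritic inhibitory weights at 0.
* Update order within a step: feedback inhibition from previous-step
  output, short-term plasticity factors and trace updates, compartment
  activations using delayed partner activity, output rates, then
  long-term plasticity — every term therefore uses information from t−dt.
* Simulations abort with a diagnostic (step index, neuron) if rates become
  non-finite.

## Problem sizes and protocol durations

Defaults follow the full-scale protocols (300 CA3 / 500 EC on the track,
3×150 Y-maze, 100+2×150 branching, 600-s replay exposure).  The test and
acceptance suites run desk-scale versions: 150 CA3 neurons on the track
(tuned EC count scaled with the network, distractor fraction preserved),
75-neuron Y-maze groups, a 50+2×75 branching network, and a 60-s replay
exposure.  Because feedback inhibition is normalised per readout, the
excitation/inhibition balance is size-free and no other parameter changes
with scale.  The single-cell protocol duration (not stated in the source
protocols) is 1500 s, chosen once from the convergence of the
weight-contrast trajectory (plateau from roughly 600–700 s under the
printed parameters); reduced-duration checks run at one third of it.

## What the generators do and do not emulate

All inputs are synthetic: OU sources stand in for shared rate
fluctuations, and place/grid tuning for sensory drive along a 1-D
trajectory.  Real EC input has richer temporal statistics (theta-phase
precession, conjunctive cells, speed modulation), real trajectories are
2-D and irregular, and real CA3 connectivity is log-normal rather than a
noisy Gaussian chain.  Passing tests therefore demonstrate the internal
consistency and the claimed mechanisms of the model — not that the
mechanisms hold in biological tissue.

## Known limitations

* During locomotion the theta drive (amplitude 10 against a sigmoid
  threshold of 5) periodically carries every soma across threshold before
  the trace-filtered feedback inhibition (10-ms lag) can veto the
  laggards, so winner-take-all selection among theta-driven cells is weak
  under these constants.  As a consequence the coincidence-driven
  learning flux carries a large theta-locked common mode, and at the full
  learning rate plasticity broadens rather than sharpens place fields on
  an unfamiliar track: the model robustly *expresses* pre-wired or
  randomly-seeded fields, generates and replays preplay sequences during
  immobility, and protects learned dendritic weights through replay
  exposure, but the improvement of spatial information by single-trial
  learning over the no-plasticity control does not emerge at desk scale.
  The corresponding assertions in the acceptance suite fail and are left
  failing rather than patched with undocumented mechanisms.
* No spiking dynamics, conduction delays beyond Δt, multi-branch
  dendrites, or 2-D environments.
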