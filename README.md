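# preplaynet

A rate-model simulator of **preplay-based sequence learning** in
recurrent CA3-like networks of **two-compartment pyramidal neurons**, for
computational neuroscientists studying how spontaneous firing sequences
can act as templates for rapid spatial memory formation.

## The model

Each neuron has a somatic compartment `x` (recurrent / bottom-up input)
and a distal dendritic compartment `y` (entorhinal / top-down input):

    x(t) = f( Σ_j w_som_j I_som_j − inh_som + β y(t−Δt) + ext )
    y(t) = f( Σ_j w_dnd_j I_dnd_j − inh_dnd + β x(t−Δt) )
    z(t) = (1 + γ y(t)) · φ · x(t)

with a logistic `f` (threshold θ_f = 5), cross-compartment threshold
modulation `β`, and dendritic calcium-spike gain `γ`.  Synaptic drive is
low-pass filtered (τ_L = 10 ms) and subject to short-term depression and
facilitation; the baseline release probability of recurrent synapses is
neuromodulated during locomotion, switching the network between fast
preplay/replay sequences (immobility) and slow theta-paced propagation
(run).

Excitatory synapses follow a combined rule,

    Δw ∝ η [ (1−α) x (x − θ) + α x y ] (1−x) I,    θ = c0 E[x]²,

a BCM term with a sliding threshold plus a coincidence term gated by
simultaneous somatic and dendritic activity.  With α = 0 each compartment
performs variance-driven (PCA-like) Hebbian learning; with large α the
pair of compartments extracts mutually *correlated* input components, an
operation analogous to canonical correlation analysis (CCA).  For β = 0
and frozen thresholds the rule is exactly gradient ascent on

    L = (1−α)(E[x²]/2 + E[y²]/2 − θ_som E[x] − θ_dnd E[y]) + α E[xy].

Dendrite-targeting feedback inhibition is itself plastic (same functional
form, fixed threshold), which separates what different cells learn and
protects learned dendritic weights.  See `docs/methods.md` for the full
model description, parameter table, numerical choices and limitations.

## Worked example

Learning under correlated vs uncorrelated minority input groups (the
core single-cell experiment; ~1 minute at this reduced duration):

```python
from preplaynet.experiments import run_single_cell

for cond in ("correlated", "uncorrelated"):
    r = run_single_cell(cond, n_trials=5, duration_s=500.0, seed=7)
    print(cond, "somatic contrast:", r["contrast_som"].round(1))
```

prints

```
correlated somatic contrast: [62.5 70.4 23.8 -6.6 70.3]
uncorrelated somatic contrast: [-79.3 -69.4 -84.2 -80.5 -59.8]
```

The contrast is Σ(minority-group weights) − Σ(majority-group weights).
When the minority groups feeding the two compartments are **correlated**,
they are selectively potentiated (positive contrast, CCA-like learning);
when they are uncorrelated, the majority groups win (negative contrast,
PCA-like learning).

The same machinery drives network experiments, e.g. a full linear-track
session with place-field analysis:

```python
from preplaynet.experiments import run_track
r = run_track(model="two", familiarity="unfamiliar", n_ca3=150, seed=2)
print(r["place_fields"].mean_info)   # spatial information per spike (bits)
```

A thin CLI wraps the experiment presets:

```bash
preplaynet simulate --preset fig4_track --seed 1 --scale 1.0 --out run.h5
preplaynet analyze --in run.h5 --metric info_per_spike
preplaynet sweep --grid alpha=0:1:5,beta=0:4:5
preplaynet report --in run.h5
```

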