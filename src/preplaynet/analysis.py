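"""Quantification of simulation outcomes.

Implements the Skaggs-style spatial information per spike, the weight
contrast that summarises whether learning was correlation-driven
(CCA-like) or variance-driven (PCA-like), detection and counting of
propagating population sequences on branching topologies, and reference
PCA/CCA decompositions of input traces used to compare against learned
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "PlaceFieldSummary",
    "SequenceCount",
    "information_per_spike",
    "weight_contrast",
    "count_branch_sequences",
    "detect_sequences",
    "reference_pca_cca",
]


@dataclass
class PlaceFieldSummary:
    """Per-cell rate maps and spatial information.

    ``info_per_spike`` is reported for cells whose mean rate over moving
    periods exceeds ``rate_threshold`` (1 Hz = 0.001 kHz by default);
    ``mean_info`` averages over those cells and is nan when none qualify.
    """

    lambda_mean: np.ndarray
    lambda_pos: np.ndarray
    occupancy: np.ndarray
    info_per_spike: np.ndarray
    included: np.ndarray
    n_bin: int

    @property
    def mean_info(self) -> float:
        if not np.any(self.included):
            return float("nan")
        return float(np.mean(self.info_per_spike[self.included]))


def information_per_spike(z: np.ndarray, pos: np.ndarray, moving: np.ndarray,
                          n_bin: int = 50, rate_threshold: float = 0.001,
                          base: float = 2.0) -> PlaceFieldSummary:
    """Spatial information per spike from rate traces and positions.

    For each cell, sum over position bins of
    (lambda_i / lambda) log(lambda_i / lambda) p_i, computed over moving
    samples only; bins that were never visited carry zero occupancy and
    bins where the cell is silent contribute zero via x log x -> 0.
    ``pos`` must be normalised to [0, 1] (multi-arm tracks are mapped onto
    [0, 1] by the caller so that n_bin covers all arms).
    """
    z = np.asarray(z, dtype=float)
    pos = np.asarray(pos, dtype=float)
    moving = np.asarray(moving, dtype=bool)
    zm = z[moving]
    pm = pos[moving]
    n_cells = z.shape[1]
    bins = np.clip((pm * n_bin).astype(int), 0, n_bin - 1)
    counts = np.bincount(bins, minlength=n_bin).astype(float)
    occupancy = counts / counts.sum() if counts.sum() else counts
    lam_pos = np.zeros((n_cells, n_bin))
    visited = counts > 0
    for b in np.flatnonzero(visited):
        lam_pos[:, b] = zm[bins == b].mean(axis=0)
    lam = zm.mean(axis=0)
    info = np.zeros(n_cells)
    ok = lam > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = lam_pos[ok] / lam[ok, None]
        term = np.where(ratio > 0, ratio * np.log(ratio), 0.0) / np.log(base)
        info[ok] = (term * occupancy[None, :]).sum(axis=1)
    included = lam > rate_threshold
    return PlaceFieldSummary(lam, lam_pos, occupancy, info, included, n_bin)


def weight_contrast(w_som: np.ndarray, w_dnd: np.ndarray, groups: dict):
    """Summed-weight difference between the minority and majority groups.

    Returns (sum_A w_som - sum_B w_som, sum_A' w_dnd - sum_B' w_dnd) along
    the last (presynaptic) axis.  Positive values indicate that the
    correlation-driven (CCA-like) component dominated learning; negative
    values indicate variance-driven (PCA-like) learning.  ``groups`` maps
    'A'/'B' to somatic and 'Ap'/'Bp' to dendritic presynaptic index sets,
    which must not overlap.
    """
    for a_key, b_key in (("A", "B"), ("Ap", "Bp")):
        ia, ib = np.asarray(groups[a_key]), np.asarray(groups[b_key])
        if np.intersect1d(ia, ib).size:
            raise ValueError(f"groups {a_key} and {b_key} overlap")
    w_som = np.asarray(w_som, dtype=float)
    w_dnd = np.asarray(w_dnd, dtype=float)
    som = w_som[..., groups["A"]].sum(axis=-1) - w_som[..., groups["B"]].sum(axis=-1)
    dnd = w_dnd[..., groups["Ap"]].sum(axis=-1) - w_dnd[..., groups["Bp"]].sum(axis=-1)
    return som, dnd


@dataclass
class SequenceCount:
    """Counts of propagation events per branch plus the detected events
    (branch name, start sample, end sample)."""

    counts: dict
    events: list = field(default_factory=list)


def detect_sequences(z: np.ndarray, neuron_order: np.ndarray, sample_ms: float,
                     smooth_ms: float = 100.0, distal_frac: float = 0.25,
                     proximal_frac: float = 0.5,
                     thresh_per_neuron: float = 0.005,
                     precedence_ms: float = 500.0) -> list:
    """Detect population activity traversing an ordered neuron chain.

    The rate matrix is smoothed in time (Gaussian, ``smooth_ms``).  A
    propagation event is an arrival of activity at the distal end of the
    chain that was fed from its proximal part: an upward crossing of the
    mean smoothed rate over the last ``distal_frac`` of the chain above
    ``thresh_per_neuron`` (kHz), with hysteresis at half the threshold,
    preceded within ``precedence_ms`` by proximal activity (first
    ``proximal_frac`` of the chain above the same threshold).  This
    criterion is robust to persistent activity at the chain origin (e.g.
    trigger-driven), which keeps centre-of-mass measures away from the
    chain end.  Returns (proximal_onset_sample, arrival_sample) pairs.
    """
    zc = np.asarray(z, dtype=float)[:, neuron_order]
    nb = zc.shape[1]
    sm = gaussian_filter1d(zc, sigma=smooth_ms / sample_ms, axis=0)
    n_dist = max(1, int(round(distal_frac * nb)))
    n_prox = max(1, int(round(proximal_frac * nb)))
    distal = sm[:, nb - n_dist:].mean(axis=1)
    proximal = sm[:, :n_prox].mean(axis=1)
    look = max(1, int(precedence_ms / sample_ms))
    events = []
    armed = True
    for t in range(len(distal)):
        if armed and distal[t] > thresh_per_neuron:
            lo = max(0, t - look)
            window = proximal[lo:t + 1]
            if window.size and window.max() > thresh_per_neuron:
                onset = lo + int(np.argmax(window > thresh_per_neuron))
                events.append((onset, t))
            armed = False
        elif not armed and distal[t] < 0.5 * thresh_per_neuron:
            armed = True
    return events


def count_branch_sequences(z: np.ndarray, sample_ms: float, branches: dict,
                           **kwargs) -> SequenceCount:
    """Count propagation events per branch.

    ``branches`` maps branch names to neuron index arrays ordered along the
    propagation direction.  Counting is deterministic given the record and
    parameters.
    """
    counts = {}
    all_events = []
    for name, order in branches.items():
        ev = detect_sequences(z, np.asarray(order), sample_ms, **kwargs)
        counts[name] = len(ev)
        all_events.extend((name, a, b) for a, b in ev)
    return SequenceCount(counts, sorted(all_events, key=lambda e: e[1]))


def reference_pca_cca(I_som: np.ndarray, I_dnd: np.ndarray,
                      n_components: int = 1) -> dict:
    """Standard PCA per input pathway and CCA across pathways.

    Serves as an external reference: Hebbian/BCM learning tracks the
    leading principal component of each pathway, while the coincidence
    rule tracks the leading canonical pair.  Returns loadings, scores and
    canonical correlations.
    """
    from sklearn.cross_decomposition import CCA
    from sklearn.decomposition import PCA

    I_som = np.asarray(I_som, dtype=float)
    I_dnd = np.asarray(I_dnd, dtype=float)
    if I_som.shape[0] != I_dnd.shape[0] or I_som.shape[0] < 2:
        raise ValueError("traces must share at least two time samples")
    out = {}
    for name, X in (("som", I_som), ("dnd", I_dnd)):
        pca = PCA(n_components=n_components)
        scores = pca.fit_transform(X)
        out[f"pca_loadings_{name}"] = pca.components_
        out[f"pca_scores_{name}"] = scores
    cca = CCA(n_components=n_components, max_iter=1000)
    sx, sy = cca.fit_transform(I_som, I_dnd)
    out["cca_x_loadings"] = cca.x_weights_.T
    out["cca_y_loadings"] = cca.y_weights_.T
    out["cca_scores"] = (sx, sy)
    corr = [abs(float(np.corrcoef(sx[:, k], sy[:, k])[0, 1]))
            for k in range(n_components)]
    out["canonical_correlations"] = np.array(corr)
    return out
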