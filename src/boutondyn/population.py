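"""Population-level analyses.

* PCA embedding of boutons from concatenated trial-averaged RM and UM activity
  (a 2M × N matrix: M timepoints per condition, N boutons; each bouton is a
  point in the space of the first three principal components).
* Per-trial trajectories of the first three segment PCs and the trajectory
  selectivity index (d_other − d_own)/(d_own + d_other) built from frame-wise
  Euclidean distances to the mean RM and mean UM trajectories.
* Trial-pair statistics — population-vector pattern correlation and the
  fraction-of-activated-ensemble difference |a−b|/(0.5(a+b)) — binned against
  movement-trajectory correlation.
* Axon heterogeneity (minority-label fraction among an axon's responsive
  boutons) and axon-pair correlation with the 0.7 high/low split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

STANDARD_BINS = (-0.2, 0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


class PopulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PCA embedding of boutons


@dataclass
class EmbeddingResult:
    matrix: np.ndarray          # (2M, N) concatenated RM then UM trial means
    scores: np.ndarray          # (N, 3) bouton coordinates on the first 3 PCs
    explained_variance_ratio: np.ndarray
    bouton_ids: list[str]
    dropped: list[str]          # boutons lacking one condition


def embed_boutons(
    rm_means: dict[str, np.ndarray],
    um_means: dict[str, np.ndarray],
    n_components: int = 3,
) -> EmbeddingResult:
    """Embed boutons in PC space from their RM and UM trial-averaged activity.

    Columns of the 2M × N matrix are boutons (RM mean stacked on UM mean);
    PCA runs across the timepoints and each bouton's coordinates are its
    loadings on the first three components.  Components are oriented so the
    loading of largest magnitude is positive (signs are arbitrary otherwise).
    Boutons missing either condition are dropped and reported.
    """
    ids, dropped = [], []
    for b in sorted(set(rm_means) | set(um_means)):
        if b in rm_means and b in um_means and len(rm_means[b]) and len(um_means[b]):
            ids.append(b)
        else:
            dropped.append(b)
    if len(ids) < n_components:
        raise PopulationError(
            f"need at least {n_components} boutons with both conditions, got {len(ids)}"
        )
    matrix = np.column_stack([
        np.concatenate([rm_means[b], um_means[b]]) for b in ids
    ])
    pca = PCA(n_components=n_components)
    pca.fit(matrix)
    loadings = pca.components_.T.copy()      # (N, n_components)
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
    return EmbeddingResult(
        matrix=matrix,
        scores=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        bouton_ids=ids,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# PC trajectories and the selectivity index


def segment_pcs(z_matrix: np.ndarray, n_components: int = 3) -> np.ndarray:
    """First principal-component time courses of a continuous imaged segment.

    ``z_matrix`` is frames × boutons; returns frames × ``n_components`` scores.
    """
    if z_matrix.shape[1] < n_components:
        raise PopulationError(
            f"need at least {n_components} boutons for segment PCA, "
            f"got {z_matrix.shape[1]}"
        )
    return PCA(n_components=n_components).fit_transform(z_matrix)


def trajectory_distance(traj_a: np.ndarray, traj_b: np.ndarray) -> float:
    """Frame-wise Euclidean distance between two PC trajectories, summed.

    Trajectories are (n_components, T); at each frame the Euclidean distance
    between the two PC points is taken and the distances are summed over the
    trajectory (the index below is invariant to sum vs mean).
    """
    a = np.asarray(traj_a, dtype=float)
    b = np.asarray(traj_b, dtype=float)
    if a.shape != b.shape:
        raise PopulationError("trajectories must have identical shape")
    return float(np.sqrt(((a - b) ** 2).sum(axis=0)).sum())


def selectivity_index(d_own: float, d_other: float) -> float:
    """(d_other − d_own)/(d_own + d_other); +1 at the own mean, −1 at the other.

    Undefined (NaN) when both distances are zero, i.e. the two mean
    trajectories coincide with the trial trajectory.
    """
    denom = d_own + d_other
    if denom == 0.0:
        return float("nan")
    return (d_other - d_own) / denom


@dataclass
class SelectivityResult:
    trials: pd.DataFrame        # trial_id, label, d_rm, d_um, index
    mean_rm_trajectory: np.ndarray
    mean_um_trajectory: np.ndarray


def trajectory_selectivity(
    pcs: np.ndarray,
    onsets: list[tuple[float, str]],
    fs_hz: float,
    pre_s: float = 1.0,
    post_s: float = 3.0,
) -> SelectivityResult:
    """Per-trial trajectory selectivity from segment PCs and labelled onsets.

    Each onset yields a (3, T) trajectory over [−pre_s, post_s).  The mean RM
    and UM trajectories are averages over trials of that label; each trial's
    index is (d_to_other_mean − d_to_own_mean)/(d_to_own + d_to_other), so an
    RM trial sitting on the mean RM trajectory scores +1 and one sitting on
    the mean UM trajectory scores −1.
    """
    pcs = np.asarray(pcs, dtype=float)
    width = int(round((pre_s + post_s) * fs_hz))
    trajs, labels, ids = [], [], []
    for k, (onset, label) in enumerate(onsets):
        start = int(round((onset - pre_s) * fs_hz))
        if start < 0 or start + width > len(pcs):
            continue
        trajs.append(pcs[start:start + width].T)   # (3, T)
        labels.append(label)
        ids.append(k)
    by_label = {
        lab: [t for t, l in zip(trajs, labels) if l == lab] for lab in ("RM", "UM")
    }
    if not by_label["RM"] or not by_label["UM"]:
        raise PopulationError("need at least one RM and one UM trial for mean trajectories")
    mean_rm = np.mean(by_label["RM"], axis=0)
    mean_um = np.mean(by_label["UM"], axis=0)

    rows = []
    for tid, traj, label in zip(ids, trajs, labels):
        d_rm = trajectory_distance(traj, mean_rm)
        d_um = trajectory_distance(traj, mean_um)
        own, other = (d_rm, d_um) if label == "RM" else (d_um, d_rm)
        rows.append({
            "trial_id": tid, "label": label,
            "d_rm": d_rm, "d_um": d_um,
            "index": selectivity_index(own, other),
        })
    return SelectivityResult(
        trials=pd.DataFrame(rows),
        mean_rm_trajectory=mean_rm,
        mean_um_trajectory=mean_um,
    )


# ---------------------------------------------------------------------------
# binned trial-pair curves


@dataclass
class BinnedCurve:
    """Per-bin mean of a trial-pair statistic against movement correlation.

    Empty bins carry NaN means and zero counts (reported as missing, never 0).
    """

    bin_edges: np.ndarray
    means: np.ndarray
    counts: np.ndarray
    n_skipped: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo": self.bin_edges[:-1],
            "bin_hi": self.bin_edges[1:],
            "mean": self.means,
            "n_pairs": self.counts,
        })


def _bin_pairs(
    move_corrs: np.ndarray,
    values: np.ndarray,
    bins: tuple[float, ...] = STANDARD_BINS,
) -> BinnedCurve:
    edges = np.asarray(bins, dtype=float)
    ok = np.isfinite(move_corrs) & np.isfinite(values)
    skipped = int((~ok).sum())
    mc, vals = move_corrs[ok], values[ok]
    means = np.full(len(edges) - 1, np.nan)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for i in range(len(edges) - 1):
        hi_closed = i == len(edges) - 2
        sel = (mc >= edges[i]) & ((mc <= edges[i + 1]) if hi_closed else (mc < edges[i + 1]))
        counts[i] = int(sel.sum())
        if counts[i]:
            means[i] = float(vals[sel].mean())
    return BinnedCurve(edges, means, counts, skipped)


def pattern_correlation_curve(
    population_vectors: dict[int, np.ndarray],
    movement_correlations: dict[tuple[int, int], float],
    bins: tuple[float, ...] = STANDARD_BINS,
) -> BinnedCurve:
    """Trial-pair population-vector correlation binned by movement correlation.

    ``population_vectors`` maps trial id → concatenated aligned activity of all
    responsive boutons (same bouton order for every trial).  Pairs with a
    zero-variance vector are skipped and counted.
    """
    mcs, vals = [], []
    skipped = 0
    for (i, j), mc in movement_correlations.items():
        if i not in population_vectors or j not in population_vectors:
            continue
        vi, vj = population_vectors[i], population_vectors[j]
        if np.std(vi) == 0 or np.std(vj) == 0:
            skipped += 1
            continue
        mcs.append(mc)
        vals.append(np.corrcoef(vi, vj)[0, 1])
    curve = _bin_pairs(np.asarray(mcs, dtype=float), np.asarray(vals, dtype=float), bins)
    curve.n_skipped += skipped
    return curve


def ensemble_difference(a: int, b: int) -> float:
    """Fraction-of-activated-ensemble difference |a−b|/(0.5(a+b)) ∈ [0, 2].

    ``a`` and ``b`` are the activated-bouton counts of the two trials; the
    value is 0 iff the counts agree and 2 when one count is zero.  Undefined
    (NaN) when both are zero.
    """
    if a < 0 or b < 0:
        raise PopulationError("activated counts must be non-negative")
    if a + b == 0:
        return float("nan")
    return abs(a - b) / (0.5 * (a + b))


def ensemble_difference_curve(
    activated_counts: dict[int, int],
    movement_correlations: dict[tuple[int, int], float],
    bins: tuple[float, ...] = STANDARD_BINS,
) -> BinnedCurve:
    """Ensemble-difference values per trial pair binned by movement correlation."""
    mcs, vals = [], []
    skipped = 0
    for (i, j), mc in movement_correlations.items():
        if i not in activated_counts or j not in activated_counts:
            continue
        v = ensemble_difference(activated_counts[i], activated_counts[j])
        if not np.isfinite(v):
            skipped += 1
            continue
        mcs.append(mc)
        vals.append(v)
    curve = _bin_pairs(np.asarray(mcs, dtype=float), np.asarray(vals, dtype=float), bins)
    curve.n_skipped += skipped
    return curve


def activated_counts(
    events_by_roi: dict[str, np.ndarray],
    responsive_rois: set[str],
    onsets_by_trial: dict[int, float],
    window_s: tuple[float, float] = (0.0, 3.0),
) -> dict[int, int]:
    """Number of responsive boutons with ≥1 event in the post-onset window,
    per trial."""
    counts = {}
    for trial, onset in onsets_by_trial.items():
        lo, hi = onset + window_s[0], onset + window_s[1]
        n = 0
        for roi in responsive_rois:
            times = events_by_roi.get(roi)
            if times is not None and np.any((times >= lo) & (times < hi)):
                n += 1
        counts[trial] = n
    return counts


# ---------------------------------------------------------------------------
# axon heterogeneity and axon-pair correlation


@dataclass
class HeterogeneityResult:
    fraction: float             # minority-label fraction in [0, 0.5]
    dominant: str               # RM | UM | tie
    n_rm: int
    n_um: int
    tie: bool


def axon_heterogeneity(
    categories: list[str],
    both_policy: str = "dominant",
) -> HeterogeneityResult:
    """Minority-label fraction among the responsive boutons of one axon.

    ``categories`` are per-bouton categories.  Unresponsive boutons never
    count.  ``both_policy='dominant'`` counts 'both' boutons toward the
    dominant side; ``'exclude'`` drops them.  A RM/UM tie yields fraction 0.5
    with the tie flag set.  Raises when no responsive bouton remains.
    """
    if both_policy not in ("dominant", "exclude"):
        raise PopulationError(f"unknown both_policy {both_policy!r}")
    n_rm = sum(1 for c in categories if c == "RM_only")
    n_um = sum(1 for c in categories if c == "UM_only")
    n_both = sum(1 for c in categories if c == "both")
    if n_rm + n_um + n_both == 0:
        raise PopulationError("axon has no responsive boutons")
    if n_rm == n_um:
        total = n_rm + n_um + (n_both if both_policy == "dominant" else 0)
        if total == 0 or n_rm + n_um == 0:
            # only 'both' boutons, or excluded: axon is homogeneous
            return HeterogeneityResult(0.0, "tie" if n_rm == n_um == 0 else "tie",
                                       n_rm, n_um, n_rm > 0)
        return HeterogeneityResult(0.5, "tie", n_rm, n_um, True)
    dominant = "RM" if n_rm > n_um else "UM"
    minority = min(n_rm, n_um)
    if both_policy == "dominant":
        total = n_rm + n_um + n_both
    else:
        total = n_rm + n_um
    return HeterogeneityResult(minority / total, dominant, n_rm, n_um, False)


@dataclass
class AxonPairResult:
    pairs: pd.DataFrame         # axon_a, axon_b, r, high (r > split)
    fraction_high: float
    split: float = 0.7


def axon_pair_correlation(
    axon_traces: dict[str, np.ndarray],
    split: float = 0.7,
) -> AxonPairResult:
    """Pearson correlation for all axon pairs with the high/low split.

    Axon pairs correlated above the split likely stem from the same source
    neuron; pairs below it are presumed independent axons.
    """
    ids = sorted(axon_traces)
    if len(ids) < 2:
        raise PopulationError("need at least two axons per field of view")
    rows = []
    for a, b in combinations(ids, 2):
        r = float(np.corrcoef(axon_traces[a], axon_traces[b])[0, 1])
        rows.append({"axon_a": a, "axon_b": b, "r": r, "high": r > split})
    df = pd.DataFrame(rows)
    return AxonPairResult(pairs=df, fraction_high=float(df["high"].mean()), split=split)
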