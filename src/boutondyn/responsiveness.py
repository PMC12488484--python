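"""Trial alignment and RM/UM responsiveness classification.

Activity is aligned to movement onsets over a [−1 s, +3 s) window (the 1 s
before onset serves as baseline) and averaged across trials.  A bouton is
responsive when the peak of its trial-averaged trace inside [−0.2, 3) s minus
the 5th percentile of that trace exceeds 0.9 (z units).  Axons use a per-mouse
histogram-derived threshold instead: the mean of the modal peak bins of the RM
and UM peak distributions (0.1-unit bins), capped at 1.  Responsiveness in RM
and UM trials combines into four categories — RM_only, UM_only, both,
unresponsive — whose early→late transitions form the fate table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from boutondyn.signals import DffTrace

CATEGORY_ORDER = ("RM_only", "UM_only", "both", "unresponsive")


@dataclass
class AlignedTensor:
    """Per-trial aligned windows of one unit plus the across-trial mean."""

    data: np.ndarray            # (n_trials, n_frames)
    label: str                  # RM | UM | delay | omission
    pre_s: float
    post_s: float
    fs_hz: float
    n_dropped: int = 0          # onsets whose window fell outside the segment

    @property
    def mean_trace(self) -> np.ndarray:
        return self.data.mean(axis=0) if len(self.data) else np.empty(0)

    @property
    def n_trials(self) -> int:
        return len(self.data)

    @property
    def empty(self) -> bool:
        return len(self.data) == 0

    def time_axis(self) -> np.ndarray:
        n = self.data.shape[1] if self.data.ndim == 2 else 0
        return np.arange(n) / self.fs_hz - self.pre_s


def align_to_onsets(
    z: np.ndarray,
    onsets_s: np.ndarray,
    fs_hz: float,
    pre_s: float = 1.0,
    post_s: float = 3.0,
    label: str = "",
) -> AlignedTensor:
    """Stack [onset − pre_s, onset + post_s) windows of a z trace.

    Onsets whose window is not fully inside the segment are dropped and
    counted in ``n_dropped``.
    """
    z = np.asarray(z, dtype=float)
    width = int(round((pre_s + post_s) * fs_hz))
    rows = []
    dropped = 0
    for onset in np.asarray(onsets_s, dtype=float):
        start = int(round((onset - pre_s) * fs_hz))
        if start < 0 or start + width > len(z):
            dropped += 1
            continue
        rows.append(z[start:start + width])
    data = np.vstack(rows) if rows else np.empty((0, width))
    return AlignedTensor(data=data, label=label, pre_s=pre_s, post_s=post_s,
                         fs_hz=fs_hz, n_dropped=dropped)


def classify_bouton(
    mean_trace: np.ndarray,
    fs_hz: float,
    pre_s: float = 1.0,
    peak_window_s: tuple[float, float] = (-0.2, 3.0),
    criterion_sd: float = 0.9,
) -> bool:
    """Responsiveness of one bouton from its trial-averaged trace.

    Responsive ⇔ max over ``peak_window_s`` (relative to onset, half-open)
    minus the 5th percentile of the whole mean trace exceeds ``criterion_sd``.
    """
    mean_trace = np.asarray(mean_trace, dtype=float)
    if mean_trace.size == 0:
        return False
    lo = int(round((pre_s + peak_window_s[0]) * fs_hz))
    hi = int(round((pre_s + peak_window_s[1]) * fs_hz))
    lo = max(lo, 0)
    hi = min(hi, len(mean_trace))
    if hi <= lo:
        return False
    peak = float(mean_trace[lo:hi].max())
    floor = float(np.percentile(mean_trace, 5))
    return peak - floor > criterion_sd


def unit_peak_value(
    mean_trace: np.ndarray,
    fs_hz: float,
    pre_s: float = 1.0,
    peak_window_s: tuple[float, float] = (-0.2, 3.0),
) -> float:
    """Peak minus 5th-percentile statistic used by both classification rules."""
    mean_trace = np.asarray(mean_trace, dtype=float)
    if mean_trace.size == 0:
        return float("nan")
    lo = max(int(round((pre_s + peak_window_s[0]) * fs_hz)), 0)
    hi = min(int(round((pre_s + peak_window_s[1]) * fs_hz)), len(mean_trace))
    if hi <= lo:
        return float("nan")
    return float(mean_trace[lo:hi].max() - np.percentile(mean_trace, 5))


def axon_threshold(
    peak_values_rm: np.ndarray,
    peak_values_um: np.ndarray,
    bin_sd: float = 0.1,
    cap_sd: float = 1.0,
) -> float:
    """Histogram-mode threshold for axon responsiveness.

    The RM and UM peak-value distributions are binned at ``bin_sd``; the
    threshold is the mean of the two modal bin centres, capped at ``cap_sd``.
    Ties between modal bins resolve to the lowest-amplitude bin.
    """
    def mode_center(values: np.ndarray) -> float:
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if len(values) == 0:
            return cap_sd
        edges = np.arange(0.0, values.max() + 2 * bin_sd, bin_sd)
        counts, _ = np.histogram(values, bins=edges)
        k = int(np.argmax(counts))  # argmax takes the first (lowest) modal bin
        return float(edges[k] + bin_sd / 2.0)

    thr = 0.5 * (mode_center(peak_values_rm) + mode_center(peak_values_um))
    return min(thr, cap_sd)


def classify_axons(
    peaks_rm: dict[str, float],
    peaks_um: dict[str, float],
    bin_sd: float = 0.1,
    cap_sd: float = 1.0,
) -> tuple[dict[str, bool], dict[str, bool], float]:
    """Per-axon RM/UM responsiveness from peak values of all axons of a mouse.

    With fewer than 10 axons the histogram is not meaningful and the threshold
    falls back to ``cap_sd``.  Returns (resp_rm, resp_um, threshold).
    """
    ids = sorted(set(peaks_rm) | set(peaks_um))
    vals_rm = np.array([peaks_rm.get(i, np.nan) for i in ids])
    vals_um = np.array([peaks_um.get(i, np.nan) for i in ids])
    if len(ids) >= 10:
        thr = axon_threshold(vals_rm, vals_um, bin_sd, cap_sd)
    else:
        thr = cap_sd
    resp_rm = {i: bool(np.isfinite(peaks_rm.get(i, np.nan)) and peaks_rm[i] > thr)
               for i in ids}
    resp_um = {i: bool(np.isfinite(peaks_um.get(i, np.nan)) and peaks_um[i] > thr)
               for i in ids}
    return resp_rm, resp_um, thr


def categorize(resp_rm: bool, resp_um: bool) -> str:
    """Deterministic four-way category from the two responsiveness flags."""
    if resp_rm and resp_um:
        return "both"
    if resp_rm:
        return "RM_only"
    if resp_um:
        return "UM_only"
    return "unresponsive"


def is_rm_responsive(category: str) -> bool:
    """Convenience grouping: RM-responsive = RM_only ∪ both."""
    return category in ("RM_only", "both")


@dataclass
class FateTable:
    """Early→late category transitions: counts, row (fate) and column (origin)
    proportions."""

    counts: pd.DataFrame
    fate: pd.DataFrame          # row-normalized; empty rows are all-NaN
    origin: pd.DataFrame        # column-normalized; empty columns are all-NaN


def track_fate(early: pd.DataFrame, late: pd.DataFrame) -> FateTable:
    """Cross-tabulate unit categories between two learning stages.

    ``early`` and ``late`` are frames with columns ``unit_id`` and
    ``category`` over the same unit ids; a mismatch raises with the offending
    ids listed.
    """
    e = early.set_index("unit_id")["category"]
    l = late.set_index("unit_id")["category"]
    missing = sorted(set(e.index) ^ set(l.index))
    if missing:
        raise ValueError(f"unit ids not present in both stages: {missing[:20]}")
    counts = pd.DataFrame(0, index=list(CATEGORY_ORDER), columns=list(CATEGORY_ORDER))
    for uid in e.index:
        counts.loc[e[uid], l[uid]] += 1
    row_sums = counts.sum(axis=1)
    fate = counts.div(row_sums.where(row_sums > 0), axis=0)
    col_sums = counts.sum(axis=0)
    origin = counts.div(col_sums.where(col_sums > 0), axis=1)
    return FateTable(counts=counts, fate=fate, origin=origin)


@dataclass
class RewardModulation:
    delay_modulated: bool
    peak_shift_s: float
    delay_window_mean: float
    omission_window_mean: float


def classify_reward_modulated(
    rm_aligned: AlignedTensor,
    delay_aligned: AlignedTensor,
    omission_aligned: AlignedTensor,
    shift_s: float = 0.93,
    delay_window_s: tuple[float, float] = (1.67, 2.33),
    omission_window_s: tuple[float, float] = (0.67, 1.33),
) -> RewardModulation:
    """Delay-reward modulation of one bouton.

    The bouton is delay-modulated when the peak time of its trial-averaged
    delay-trial trace lags the RM-trial peak time by more than ``shift_s``.
    Also reports mean activity in the reward-expectation windows of delay and
    omission trials (times relative to movement onset, half-open).
    """
    if rm_aligned.empty or delay_aligned.empty:
        raise ValueError("need RM and delay trials to classify reward modulation")

    def peak_time(t: AlignedTensor) -> float:
        m = t.mean_trace
        return float(np.argmax(m) / t.fs_hz - t.pre_s)

    def window_mean(t: AlignedTensor, win: tuple[float, float]) -> float:
        if t.empty:
            return float("nan")
        lo = int(round((t.pre_s + win[0]) * t.fs_hz))
        hi = int(round((t.pre_s + win[1]) * t.fs_hz))
        m = t.mean_trace
        lo, hi = max(lo, 0), min(hi, len(m))
        return float(m[lo:hi].mean()) if hi > lo else float("nan")

    shift = peak_time(delay_aligned) - peak_time(rm_aligned)
    return RewardModulation(
        delay_modulated=bool(shift > shift_s),
        peak_shift_s=shift,
        delay_window_mean=window_mean(delay_aligned, delay_window_s),
        omission_window_mean=window_mean(omission_aligned, omission_window_s),
    )


def classify_units(
    aligned_rm: dict[str, AlignedTensor],
    aligned_um: dict[str, AlignedTensor],
    fs_hz: float,
    stage: str = "",
    level: str = "bouton",
    min_trials: int = 5,
    pre_s: float = 1.0,
    peak_window_s: tuple[float, float] = (-0.2, 3.0),
    criterion_sd: float = 0.9,
    bin_sd: float = 0.1,
    cap_sd: float = 1.0,
) -> pd.DataFrame:
    """Classify a set of units (boutons or axons) into the four categories.

    Units with fewer than ``min_trials`` trials of a label count as
    unresponsive for that label and are flagged in the ``unclassified``
    column.  Axon-level classification pools peak values across units to set
    the histogram threshold.
    """
    ids = sorted(set(aligned_rm) | set(aligned_um))
    rows = []
    if level == "axon":
        peaks_rm = {
            u: unit_peak_value(aligned_rm[u].mean_trace, fs_hz, pre_s, peak_window_s)
            for u in ids if u in aligned_rm and aligned_rm[u].n_trials >= min_trials
        }
        peaks_um = {
            u: unit_peak_value(aligned_um[u].mean_trace, fs_hz, pre_s, peak_window_s)
            for u in ids if u in aligned_um and aligned_um[u].n_trials >= min_trials
        }
        resp_rm_map, resp_um_map, _ = classify_axons(peaks_rm, peaks_um, bin_sd, cap_sd)
    for u in ids:
        t_rm = aligned_rm.get(u)
        t_um = aligned_um.get(u)
        ok_rm = t_rm is not None and t_rm.n_trials >= min_trials
        ok_um = t_um is not None and t_um.n_trials >= min_trials
        if level == "axon":
            resp_rm = resp_rm_map.get(u, False) if ok_rm else False
            resp_um = resp_um_map.get(u, False) if ok_um else False
        else:
            resp_rm = ok_rm and classify_bouton(
                t_rm.mean_trace, fs_hz, pre_s, peak_window_s, criterion_sd)
            resp_um = ok_um and classify_bouton(
                t_um.mean_trace, fs_hz, pre_s, peak_window_s, criterion_sd)
        rows.append({
            "unit_id": u,
            "level": level,
            "stage": stage,
            "resp_rm": resp_rm,
            "resp_um": resp_um,
            "category": categorize(resp_rm, resp_um),
            "unclassified": not (ok_rm or ok_um),
        })
    return pd.DataFrame(rows)
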