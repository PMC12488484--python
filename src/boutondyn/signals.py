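"""Fluorescence trace processing: ΔF/F₀, event detection, same/unique peak
matching and correlation statistics.

The baseline F₀ is a 30-s sliding-window 30th percentile of the raw trace
(centered window, truncated at the segment edges); ΔF/F = (F − F₀)/F₀ and the
z-score of ΔF/F over the segment is the working trace for all event criteria,
so thresholds expressed in "s.d." are z units.  Calcium events are strict
local maxima of z above threshold; events of two ROIs within 670 ms of each
other are matched one-to-one as the *same peak*, unmatched events are *unique
peaks*.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np


class BaselineError(ValueError):
    pass


def sliding_percentile(x: np.ndarray, window: int, q: float) -> np.ndarray:
    """Centered sliding-window percentile with truncated edges.

    Equivalent to ``np.percentile(x[max(0, i-w//2) : i+w//2+1], q)`` at every
    frame ``i`` (bitwise, including numpy's linear interpolation), computed
    with a sorted rolling window in O(n·w) time.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if window < 1:
        raise ValueError("window must be >= 1 frame")
    h = window // 2
    out = np.empty(n)
    xs = x.tolist()
    win = sorted(xs[: min(h + 1, n)])
    qf = q / 100.0
    for i in range(n):
        m = len(win)
        pos = (m - 1) * qf
        lo = int(pos)
        frac = pos - lo
        if lo + 1 >= m:
            out[i] = win[lo]
        else:
            a, b = win[lo], win[lo + 1]
            diff = b - a
            # numpy's lerp: switch form at t = 0.5 for numerical symmetry
            out[i] = b - diff * (1.0 - frac) if frac >= 0.5 else a + diff * frac
        j = i + 1 + h
        if j < n:
            bisect.insort(win, xs[j])
        k = i - h
        if k >= 0:
            del win[bisect.bisect_left(win, xs[k])]
    return out


@dataclass
class DffTrace:
    """ΔF/F₀ with its sliding baseline and segment z-score."""

    dff: np.ndarray
    f0: np.ndarray
    z: np.ndarray
    fs_hz: float


def compute_dff(
    raw_f: np.ndarray,
    fs_hz: float,
    window_s: float = 30.0,
    percentile: float = 30.0,
    zscore: bool = True,
    align: str = "centered",
) -> DffTrace:
    """ΔF/F₀ from a raw fluorescence trace.

    ``align='centered'`` uses a centered window truncated at the edges;
    ``align='trailing'`` uses only past samples (same truncation at the start).
    Raises :class:`BaselineError` naming the offending frames if F₀ ≤ 0.
    """
    raw_f = np.asarray(raw_f, dtype=float)
    if not np.all(np.isfinite(raw_f)):
        raise BaselineError("raw fluorescence contains non-finite samples")
    w = int(round(window_s * fs_hz))
    if align == "centered":
        f0 = sliding_percentile(raw_f, w, percentile)
    elif align == "trailing":
        f0 = np.array([
            np.percentile(raw_f[max(0, i - w + 1): i + 1], percentile)
            for i in range(len(raw_f))
        ])
    else:
        raise ValueError(f"unknown baseline alignment {align!r}")
    bad = np.flatnonzero(f0 <= 0)
    if len(bad):
        raise BaselineError(f"non-positive baseline at frames {bad[:10].tolist()}")
    dff = (raw_f - f0) / f0
    if zscore:
        sd = dff.std()
        z = (dff - dff.mean()) / sd if sd > 0 else np.zeros_like(dff)
    else:
        z = dff.copy()
    return DffTrace(dff=dff, f0=f0, z=z, fs_hz=fs_hz)


@dataclass
class EventSeries:
    """Detected calcium events of one ROI."""

    peak_frames: np.ndarray
    peak_times_s: np.ndarray
    amplitudes: np.ndarray
    fs_hz: float

    def __len__(self) -> int:
        return len(self.peak_frames)


def detect_events(trace: DffTrace, threshold_sd: float = 1.0) -> EventSeries:
    """Strict local maxima of the z-scored trace above ``threshold_sd``.

    A frame is a peak when it strictly exceeds both neighbours; for a plateau
    the first frame of the plateau is taken.  Endpoints are never peaks.
    """
    from scipy.signal import find_peaks

    z = trace.z
    _, props = find_peaks(z, plateau_size=1)
    peaks = np.asarray(props["left_edges"], dtype=int)
    peaks = peaks[z[peaks] > threshold_sd]  # strictly above threshold
    return EventSeries(
        peak_frames=peaks,
        peak_times_s=peaks / trace.fs_hz,
        amplitudes=z[peaks] if len(peaks) else np.empty(0),
        fs_hz=trace.fs_hz,
    )


@dataclass
class PairMatch:
    """Same/unique peak partition for one ROI pair."""

    pair: tuple[str, str]
    matches: list[tuple[int, int]]
    n_same: int
    n_unique_a: int
    n_unique_b: int
    frac_same_a: float
    frac_same_b: float


def match_event_pairs(
    a: EventSeries,
    b: EventSeries,
    tol_s: float = 0.670,
    pair: tuple[str, str] = ("a", "b"),
) -> PairMatch:
    """One-to-one matching of two event series within ``tol_s``.

    Candidate pairs are taken greedily by ascending |Δt| (ties: earlier event
    time, then lower index), each event participating in at most one match.
    Events within the tolerance of each other are the *same peak*; the rest
    are *unique peaks* of their ROI.
    """
    if tol_s < 0:
        raise ValueError("matching tolerance must be non-negative")
    ta, tb = a.peak_times_s, b.peak_times_s
    cands = []
    for i, t1 in enumerate(ta):
        lo = np.searchsorted(tb, t1 - tol_s, side="left")
        hi = np.searchsorted(tb, t1 + tol_s, side="right")
        for j in range(lo, hi):
            dt = abs(t1 - tb[j])
            if dt <= tol_s:
                cands.append((dt, min(t1, tb[j]), i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for _, _, i, j in cands:
        if i not in used_a and j not in used_b:
            matches.append((i, j))
            used_a.add(i)
            used_b.add(j)
    n_same = len(matches)
    na, nb = len(ta), len(tb)
    return PairMatch(
        pair=pair,
        matches=matches,
        n_same=n_same,
        n_unique_a=na - n_same,
        n_unique_b=nb - n_same,
        frac_same_a=n_same / na if na else float("nan"),
        frac_same_b=n_same / nb if nb else float("nan"),
    )


def label_events_by_movement(
    events: EventSeries,
    onsets: list[tuple[float, str]],
    pre_s: float = 0.330,
    post_s: float = 0.670,
) -> tuple[np.ndarray, int]:
    """Label each event RM / UM / none by the movement window containing it.

    An event at time t belongs to an onset o when t ∈ [o − pre_s, o + post_s);
    among containing onsets the nearest wins (ties: earlier onset).  Returns
    the per-event labels and the number of RM/UM window collisions.
    """
    labels = np.array(["none"] * len(events), dtype=object)
    collisions = 0
    if not onsets:
        return labels, collisions
    onsets = sorted(onsets)
    times = np.array([o for o, _ in onsets])
    labs = [lab for _, lab in onsets]
    for k, t in enumerate(events.peak_times_s):
        lo = np.searchsorted(times, t - post_s, side="left")
        hi = np.searchsorted(times, t + pre_s, side="right")
        containing = [
            (abs(t - times[i]), times[i], labs[i])
            for i in range(lo, hi)
            if times[i] - pre_s <= t < times[i] + post_s
        ]
        if not containing:
            continue
        containing.sort(key=lambda c: (c[0], c[1]))
        labels[k] = containing[0][2]
        if len({c[2] for c in containing}) > 1:
            collisions += 1
    return labels, collisions


@dataclass
class SamePeakResult:
    per_bouton: dict          # roi_id -> mean fraction over its pairings
    per_axon: dict            # axon_id -> mean over boutons
    per_mouse: float          # mean over axons
    excluded: list = field(default_factory=list)  # boutons with no events in scope
    pair_matches: list = field(default_factory=list)  # PairMatch per bouton pair


def same_peak_fraction(
    axon_events: dict[str, dict[str, EventSeries]],
    tol_s: float = 0.670,
    scope: str = "all",
    event_labels: dict[str, np.ndarray] | None = None,
) -> SamePeakResult:
    """Hierarchical same-peak fraction: bouton pairs → bouton → axon → mouse.

    ``axon_events`` maps axon id → {bouton roi id → EventSeries}.  For every
    bouton pair on an axon each bouton's fraction is matched events divided by
    its own total events; the fractions are averaged over a bouton's pairings,
    over the boutons of the axon, and over axons.  With ``scope`` 'RM' or 'UM',
    only events carrying that movement label (``event_labels``) enter.
    Boutons with no events in scope are excluded and reported.
    """
    if scope not in ("all", "RM", "UM"):
        raise ValueError(f"unknown scope {scope!r}")
    per_bouton: dict[str, float] = {}
    per_axon: dict[str, float] = {}
    excluded: list[str] = []
    pair_matches: list[PairMatch] = []

    def restricted(roi_id: str, ev: EventSeries) -> EventSeries:
        if scope == "all":
            return ev
        labels = event_labels[roi_id]
        keep = np.asarray(labels) == scope
        return EventSeries(ev.peak_frames[keep], ev.peak_times_s[keep],
                           ev.amplitudes[keep], ev.fs_hz)

    for axon_id, boutons in axon_events.items():
        if len(boutons) < 2:
            continue
        evs = {rid: restricted(rid, ev) for rid, ev in boutons.items()}
        fracs: dict[str, list[float]] = {rid: [] for rid in evs}
        rids = sorted(evs)
        for i in range(len(rids)):
            for j in range(i + 1, len(rids)):
                ra, rb = rids[i], rids[j]
                if len(evs[ra]) == 0 or len(evs[rb]) == 0:
                    continue
                m = match_event_pairs(evs[ra], evs[rb], tol_s, pair=(ra, rb))
                pair_matches.append(m)
                fracs[ra].append(m.frac_same_a)
                fracs[rb].append(m.frac_same_b)
        axon_vals = []
        for rid in rids:
            if len(evs[rid]) == 0:
                excluded.append(rid)
                continue
            if fracs[rid]:
                per_bouton[rid] = float(np.mean(fracs[rid]))
                axon_vals.append(per_bouton[rid])
        if axon_vals:
            per_axon[axon_id] = float(np.mean(axon_vals))
    per_mouse = float(np.mean(list(per_axon.values()))) if per_axon else float("nan")
    return SamePeakResult(per_bouton, per_axon, per_mouse, excluded, pair_matches)


def shaft_bouton_correlation(
    bouton: DffTrace,
    shaft: DffTrace,
    mode: str = "segment",
    events: EventSeries | None = None,
    amp_band: tuple[float, float] | None = None,
    pre_frames: int = 5,
    post_frames: int = 15,
) -> float:
    """Correlation between a bouton's and its shaft's z traces.

    ``segment`` mode is the Pearson r over the full segment.  ``peak_windows``
    mode computes r over the 20 frames around each bouton peak (``pre_frames``
    before through ``post_frames`` after, half-open), optionally restricted to
    peaks whose z amplitude lies in ``amp_band``, and averages over peaks.
    Returns NaN when no peak qualifies.
    """
    zb, zs = bouton.z, shaft.z
    if len(zb) != len(zs):
        raise ValueError("bouton and shaft traces must cover the same segment")
    if mode == "segment":
        return float(np.corrcoef(zb, zs)[0, 1])
    if mode != "peak_windows":
        raise ValueError(f"unknown mode {mode!r}")
    if events is None:
        events = detect_events(bouton)
    rs = []
    for p, amp in zip(events.peak_frames, events.amplitudes):
        if amp_band is not None and not (amp_band[0] <= amp <= amp_band[1]):
            continue
        lo, hi = p - pre_frames, p + post_frames
        if lo < 0 or hi > len(zb):
            continue
        wb, ws = zb[lo:hi], zs[lo:hi]
        if wb.std() == 0 or ws.std() == 0:
            continue
        rs.append(np.corrcoef(wb, ws)[0, 1])
    return float(np.mean(rs)) if rs else float("nan")
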