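"""Synthetic behaviour, fluorescence and structural data with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a cued lever-pushing task in which rewarded movements (RM) are supra-threshold
  pushes inside the task window and unrewarded movements (UM) are sub-threshold
  pushes or pushes during the inter-trial interval;
* axons carrying a calcium-indicator-like event train in which a controlled
  fraction of transients is shared across all boutons of the axon while the
  remainder is bouton-unique; bouton response categories (RM-only / UM-only /
  both / unresponsive) are organised around a per-axon dominant category with
  a controlled deviation probability;
* multi-session structural bouton maps with per-session formation and
  elimination, optionally spatially clustered formation.

All randomness flows from ``SimConfig.seed`` through named substreams so each
generator can be re-run independently and deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np
import pandas as pd

from boutondyn.config import CATEGORIES, ConfigError, SimConfig

_STREAMS = {"behavior": 1, "activity": 2, "structure": 3}


class GenerationError(RuntimeError):
    """Raised when a dataset cannot be generated under the given configuration."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, seed-derived random substream."""
    return np.random.default_rng([int(seed), _STREAMS[name]])


# ---------------------------------------------------------------------------
# containers


@dataclass
class BehaviorRecord:
    """Lever trace, trial table and ground-truth movement bouts for one session."""

    time_s: np.ndarray
    position_mm: np.ndarray
    trials: pd.DataFrame        # trial_id, cue_time_s, task_window_s, reward_time_s, punish_time_s, trial_type
    true_bouts: pd.DataFrame    # onset_s, offset_s, peak_mm, label, trial_id
    fs_hz: float
    push_threshold_mm: float

    def onsets(self, label: str) -> np.ndarray:
        sel = self.true_bouts[self.true_bouts["label"] == label]
        return sel["onset_s"].to_numpy(dtype=float)


@dataclass
class FluorescenceSet:
    """Raw fluorescence matrix (frames x ROIs) plus ROI metadata."""

    raw_f: np.ndarray           # (n_frames, n_rois)
    rois: pd.DataFrame          # roi_id, kind, axon_id, position_um
    fs_hz: float

    def trace(self, roi_id: str) -> np.ndarray:
        idx = self.rois.index[self.rois["roi_id"] == roi_id]
        if len(idx) == 0:
            raise KeyError(roi_id)
        return self.raw_f[:, idx[0]]


@dataclass
class GroundTruth:
    """Realized ground truth of an activity (and/or structural) dataset.

    ``events`` is a long table with one row per expressed (roi, event): an
    event counts as *shared* for a bouton when it is expressed on at least two
    boutons of the axon, otherwise it is that bouton's unique event.
    """

    bouton_categories: pd.DataFrame = field(default_factory=pd.DataFrame)
    # roi_id, axon_id, category, axon_category
    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    # roi_id, axon_id, event_id, time_s, label, shared
    formed: dict = field(default_factory=dict)       # (session, axon_id) -> set of bouton ids
    eliminated: dict = field(default_factory=dict)   # (session, axon_id) -> set of bouton ids
    cluster_centers: dict = field(default_factory=dict)  # axon_id -> position_um or None

    def events_for_roi(self, roi_id: str) -> pd.DataFrame:
        return self.events[self.events["roi_id"] == roi_id]

    def shared_fraction(self, roi_id: str) -> float:
        ev = self.events_for_roi(roi_id)
        if len(ev) == 0:
            return float("nan")
        return float(ev["shared"].mean())


@dataclass
class BoutonMapSeries:
    """Structural bouton positions across imaging sessions."""

    maps: pd.DataFrame          # session, axon_id, bouton_id, position_um
    axon_length_um: float
    n_sessions: int

    def session(self, session_id: int) -> pd.DataFrame:
        return self.maps[self.maps["session"] == session_id]


# ---------------------------------------------------------------------------
# behaviour


def _raised_cosine(t_rel: np.ndarray, dur: float, amp: float) -> np.ndarray:
    """Smooth 0 -> amp -> 0 push pulse of duration ``dur``."""
    out = np.zeros_like(t_rel)
    inside = (t_rel >= 0) & (t_rel <= dur)
    out[inside] = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * t_rel[inside] / dur))
    return out


def _crossing_time(amp: float, dur: float, thr: float) -> float:
    """Time after pulse onset at which the raised-cosine pulse first crosses thr."""
    if amp <= thr:
        return float("nan")
    return dur / (2.0 * np.pi) * float(np.arccos(1.0 - 2.0 * thr / amp))


def generate_behavior(config: SimConfig) -> BehaviorRecord:
    """Simulate one session of the cued lever-pushing task.

    Every trial begins with a cue.  With probability ``p_rm`` the animal makes
    a supra-threshold push inside the task window (RM, rewarded at threshold
    crossing); otherwise it makes a sub-threshold push (UM, punished at window
    end).  Optional trial variants: reward delivered 1 s late (``delay``),
    withheld (``omission``), or cue presented without a push (``cue_only``).
    Pushes during the ITI occur at ``iti_push_rate_per_min`` and are UM.
    """
    rng = substream(config.seed, "behavior")
    fs = config.fs_hz
    thr = config.push_threshold_mm

    trials = []
    bouts = []
    pulses = []  # (onset_s, dur_s, amp_mm)

    def add_iti_pushes(start: float, stop: float) -> None:
        gap = stop - start
        if gap <= 1.0 or config.iti_push_rate_per_min <= 0:
            return
        n = rng.poisson(config.iti_push_rate_per_min * gap / 60.0)
        times = np.sort(rng.uniform(start, stop - 1.0, size=n))
        last = -np.inf
        for onset in times:
            if onset - last < 1.0:
                continue
            dur = rng.uniform(0.4, 0.8)
            amp = thr * rng.uniform(0.5, 1.6)
            pulses.append((onset, dur, amp))
            bouts.append((onset, onset + dur, amp, "UM", None))
            last = onset

    t = 5.0
    prev_end = 0.5
    for trial_id in range(1, config.n_trials + 1):
        cue = t
        add_iti_pushes(prev_end, cue - 0.5)
        u = rng.random()
        if u < config.p_delay:
            trial_type = "delay"
        elif u < config.p_delay + config.p_omission:
            trial_type = "omission"
        elif u < config.p_delay + config.p_omission + config.p_cue_only:
            trial_type = "cue_only"
        else:
            trial_type = "standard"

        reward = np.nan
        punish = np.nan
        if trial_type == "cue_only":
            end = cue + config.task_window_s
        elif rng.random() < config.p_rm:
            latency = rng.uniform(0.3, 1.2)
            dur = rng.uniform(0.4, 0.8)
            amp = thr * rng.uniform(1.3, 1.8)
            onset = cue + latency
            cross = onset + _crossing_time(amp, dur, thr)
            pulses.append((onset, dur, amp))
            bouts.append((onset, onset + dur, amp, "RM", trial_id))
            if trial_type == "delay":
                reward = cross + 1.0
            elif trial_type == "omission":
                reward = np.nan
            else:
                reward = cross
            end = (reward if np.isfinite(reward) else cross) + 1.0
        else:
            latency = rng.uniform(0.3, 1.2)
            dur = rng.uniform(0.4, 0.8)
            amp = thr * rng.uniform(0.4, 0.9)
            onset = cue + latency
            pulses.append((onset, dur, amp))
            bouts.append((onset, onset + dur, amp, "UM", trial_id))
            punish = cue + config.task_window_s
            end = punish + 0.5

        trials.append((trial_id, cue, config.task_window_s, reward, punish, trial_type))
        prev_end = end + 0.5
        # next cue only after both the trial end and the allocated task window,
        # so task windows never overlap
        t = max(end, cue + config.task_window_s) + rng.uniform(*config.iti_range_s)

    if config.n_trials and t + 1.0 > config.segment_s:
        raise GenerationError(
            f"segment of {config.segment_s} s too short for {config.n_trials} trials "
            f"(schedule needs {t + 1.0:.1f} s)"
        )
    add_iti_pushes(prev_end, config.segment_s - 1.0)

    n_frames = int(round(config.segment_s * fs))
    time_s = np.arange(n_frames) / fs

    # resting jitter: discretized Ornstein-Uhlenbeck around 0 mm
    tau, sigma = 0.1, 0.03
    dt = 1.0 / fs
    a = np.exp(-dt / tau)
    noise = rng.normal(0.0, sigma * np.sqrt(1 - a * a), size=n_frames)
    position = np.empty(n_frames)
    position[0] = 0.0
    for i in range(1, n_frames):
        position[i] = a * position[i - 1] + noise[i]
    for onset, dur, amp in pulses:
        position += _raised_cosine(time_s - onset, dur, amp)

    trials_df = pd.DataFrame(
        trials,
        columns=["trial_id", "cue_time_s", "task_window_s",
                 "reward_time_s", "punish_time_s", "trial_type"],
    )
    bouts_df = pd.DataFrame(
        bouts, columns=["onset_s", "offset_s", "peak_mm", "label", "trial_id"]
    ).sort_values("onset_s", ignore_index=True)
    return BehaviorRecord(time_s, position, trials_df, bouts_df, fs, thr)


# ---------------------------------------------------------------------------
# activity

_ALLOWED = {
    "RM_only": {"RM"},
    "UM_only": {"UM"},
    "both": {"RM", "UM"},
    "unresponsive": set(),
}


def _kernel(fs: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials transient kernel, normalized to unit peak."""
    t = np.arange(0.0, tau_decay * 6.0, 1.0 / fs)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return k / k.max()


def _assign_categories(config: SimConfig, rng: np.random.Generator,
                       n_axons: int) -> tuple[list[str], list[list[str]]]:
    """Per-axon dominant category and per-bouton categories with deviations."""
    mix = dict(config.category_mix)
    cats = [c for c in CATEGORIES if mix.get(c, 0) > 0]
    probs = np.array([mix[c] for c in cats])
    probs = probs / probs.sum()
    axon_cats = [cats[i] for i in rng.choice(len(cats), size=n_axons, p=probs)]
    dev_p = config.deviation_p
    bouton_cats = []
    for ac in axon_cats:
        row = []
        for _ in range(config.boutons_per_axon):
            if rng.random() < dev_p:
                if ac == "RM_only":
                    row.append("UM_only")
                elif ac == "UM_only":
                    row.append("RM_only")
                else:
                    row.append("RM_only" if rng.random() < 0.5 else "UM_only")
            else:
                row.append(ac)
        bouton_cats.append(row)
    return axon_cats, bouton_cats


def generate_activity(behavior: BehaviorRecord,
                      config: SimConfig) -> tuple[FluorescenceSet, GroundTruth]:
    """Simulate bouton and shaft fluorescence driven by the behavioural record.

    Each axon carries a candidate event stream: background transients at
    ``event_rate_hz`` plus movement-locked transients emitted (with probability
    ``response_prob``) at every RM and UM onset.  Each candidate is *shared*
    with probability ``shared_event_fraction`` (expressed on every bouton whose
    category admits the event's movement label) or *unique* (expressed on one
    random admitting bouton).  The shaft expresses the shared candidates
    admitted by the axon's dominant category.  Traces are the event impulses
    convolved with a rise/decay kernel, on a positive drifting baseline with
    independent Gaussian noise per ROI.
    """
    rng = substream(config.seed, "activity")
    fs = config.fs_hz
    n_frames = len(behavior.time_s)
    if n_frames < int(round(config.segment_s * fs)):
        raise GenerationError("behaviour record shorter than the configured segment")

    n_axons = config.n_axons_per_mouse
    nb = config.boutons_per_axon
    axon_cats, bouton_cats = _assign_categories(config, rng, n_axons)

    rm_onsets = behavior.onsets("RM")
    um_onsets = behavior.onsets("UM")

    kernel = _kernel(fs, config.tau_rise_s, config.tau_decay_s)
    amp0 = config.snr * config.noise_sd

    roi_rows = []
    traces = []
    cat_rows = []
    event_rows = []
    event_counter = 0

    axon_len = config.turnover.axon_length_um
    for ax in range(n_axons):
        axon_id = f"a{ax:03d}"
        b_ids = [f"{axon_id}_b{j:02d}" for j in range(nb)]
        positions = np.sort(rng.uniform(0.0, axon_len, size=nb))

        # candidate events: shared ones occur at fraction s of the per-bouton
        # rate and are expressed on every admitting bouton; each bouton also
        # carries its own unique stream at fraction (1-s), so a bouton's
        # realized event mix is ~s shared / ~(1-s) unique
        s = config.shared_event_fraction
        cand_times: list[float] = []
        cand_labels: list[str | None] = []
        cand_kind: list[int] = []  # -1 shared, else owning bouton index

        n_bg_shared = rng.poisson(s * config.event_rate_hz * config.segment_s)
        for tt in rng.uniform(1.0, config.segment_s - 3.0, size=n_bg_shared):
            cand_times.append(float(tt))
            cand_labels.append(None)
            cand_kind.append(-1)
        for label, onsets in (("RM", rm_onsets), ("UM", um_onsets)):
            for onset in onsets:
                if rng.random() < config.response_prob * s:
                    cand_times.append(onset + rng.uniform(0.05, 0.35))
                    cand_labels.append(label)
                    cand_kind.append(-1)
        for j in range(nb):
            n_bg_u = rng.poisson((1.0 - s) * config.event_rate_hz * config.segment_s)
            for tt in rng.uniform(1.0, config.segment_s - 3.0, size=n_bg_u):
                cand_times.append(float(tt))
                cand_labels.append(None)
                cand_kind.append(j)
            for label, onsets in (("RM", rm_onsets), ("UM", um_onsets)):
                for onset in onsets:
                    if rng.random() < config.response_prob * (1.0 - s):
                        cand_times.append(onset + rng.uniform(0.05, 0.35))
                        cand_labels.append(label)
                        cand_kind.append(j)
        order = np.argsort(cand_times)
        cand_times = [cand_times[i] for i in order]
        cand_labels = [cand_labels[i] for i in order]
        cand_kind = [cand_kind[i] for i in order]
        cand_amp = amp0 * rng.lognormal(0.0, config.amp_jitter, size=len(cand_times))

        # expression per bouton
        expressed: list[list[int]] = [[] for _ in range(nb)]
        shaft_events: list[int] = []
        shaft_allowed = _ALLOWED[axon_cats[ax]]
        for k, (lab, kind) in enumerate(zip(cand_labels, cand_kind)):
            if kind < 0:  # shared
                for j in range(nb):
                    if lab is None or lab in _ALLOWED[bouton_cats[ax][j]]:
                        expressed[j].append(k)
                if lab is None or lab in shaft_allowed:
                    shaft_events.append(k)
            else:
                j = kind
                if lab is None or lab in _ALLOWED[bouton_cats[ax][j]]:
                    expressed[j].append(k)

        n_expr = np.zeros(len(cand_times), dtype=int)
        for j in range(nb):
            for k in expressed[j]:
                n_expr[k] += 1

        def synth(event_idx: list[int]) -> np.ndarray:
            impulses = np.zeros(n_frames)
            for k in event_idx:
                fr = int(round(cand_times[k] * fs))
                if 0 <= fr < n_frames:
                    impulses[fr] += cand_amp[k]
            sig = np.convolve(impulses, kernel)[:n_frames]
            drift_amp = rng.uniform(0.0, 0.5 * config.drift_frac) * config.baseline_f
            period = rng.uniform(60.0, 180.0)
            phase = rng.uniform(0.0, 2 * np.pi)
            slope = rng.uniform(-0.5, 0.5) * config.drift_frac * config.baseline_f
            tgrid = behavior.time_s
            drift = drift_amp * np.sin(2 * np.pi * tgrid / period + phase) \
                + slope * tgrid / max(tgrid[-1], 1.0)
            noise = rng.normal(0.0, config.noise_sd, size=n_frames)
            return config.baseline_f + drift + sig + noise

        for j in range(nb):
            roi_rows.append((b_ids[j], "bouton", axon_id, positions[j]))
            traces.append(synth(expressed[j]))
            cat_rows.append((b_ids[j], axon_id, bouton_cats[ax][j], axon_cats[ax]))
            for k in expressed[j]:
                event_rows.append((
                    b_ids[j], axon_id, event_counter + k, cand_times[k],
                    cand_labels[k], bool(n_expr[k] >= 2),
                ))
        shaft_id = f"{axon_id}_shaft"
        roi_rows.append((shaft_id, "shaft", axon_id, np.nan))
        traces.append(synth(shaft_events))
        for k in shaft_events:
            event_rows.append((
                shaft_id, axon_id, event_counter + k, cand_times[k],
                cand_labels[k], True,
            ))
        event_counter += len(cand_times)

    rois = pd.DataFrame(roi_rows, columns=["roi_id", "kind", "axon_id", "position_um"])
    raw_f = np.column_stack(traces)
    if raw_f.min() <= 0:
        # keep raw fluorescence positive under extreme noise settings
        raw_f = raw_f - raw_f.min() + 1.0

    truth = GroundTruth(
        bouton_categories=pd.DataFrame(
            cat_rows, columns=["roi_id", "axon_id", "category", "axon_category"]
        ),
        events=pd.DataFrame(
            event_rows,
            columns=["roi_id", "axon_id", "event_id", "time_s", "label", "shared"],
        ),
    )
    return FluorescenceSet(raw_f, rois, fs), truth


# ---------------------------------------------------------------------------
# structure


def generate_structural_sessions(config: SimConfig) -> tuple[BoutonMapSeries, GroundTruth]:
    """Simulate multi-session structural bouton maps with formation/elimination.

    Session 1 places ``boutons_per_axon`` boutons uniformly along each axon.
    Each later session eliminates every existing bouton with probability
    ``p_elim`` and forms ``Binomial(previous count, p_form)`` new boutons,
    positioned uniformly or around a per-axon Gaussian cluster centre when
    ``cluster_sigma_um`` is set.  Bouton identifiers persist across sessions.
    """
    tv = config.turnover
    tv.validate()
    rng = substream(config.seed, "structure")
    L = tv.axon_length_um

    rows = []
    truth = GroundTruth()
    for ax in range(config.n_axons_per_mouse):
        axon_id = f"a{ax:03d}"
        center = rng.uniform(0.1 * L, 0.9 * L) if tv.cluster_sigma_um else None
        truth.cluster_centers[axon_id] = center
        counter = 0
        boutons: dict[str, float] = {}
        for j in range(config.boutons_per_axon):
            boutons[f"{axon_id}_s1_{counter}"] = float(rng.uniform(0.0, L))
            counter += 1
        for bid, pos in boutons.items():
            rows.append((1, axon_id, bid, pos))
        for s in range(2, tv.n_sessions + 1):
            prev_ids = list(boutons)
            elim = {bid for bid in prev_ids if rng.random() < tv.p_elim}
            n_new = rng.binomial(len(prev_ids), tv.p_form)
            formed = set()
            for _ in range(n_new):
                if tv.cluster_sigma_um:
                    pos = rng.normal(center, tv.cluster_sigma_um)
                    pos = float(np.clip(abs(pos) if pos < 0 else pos, 0.0, L))
                    if pos > L:
                        pos = 2 * L - pos
                else:
                    pos = float(rng.uniform(0.0, L))
                bid = f"{axon_id}_s{s}_{counter}"
                counter += 1
                formed.add(bid)
                boutons[bid] = pos
            for bid in elim:
                del boutons[bid]
            truth.formed[(s, axon_id)] = formed
            truth.eliminated[(s, axon_id)] = elim
            for bid, pos in boutons.items():
                rows.append((s, axon_id, bid, pos))

    maps = pd.DataFrame(rows, columns=["session", "axon_id", "bouton_id", "position_um"])
    return BoutonMapSeries(maps, L, tv.n_sessions), truth


# ---------------------------------------------------------------------------
# dataset writing


def write_dataset(out_dir, config: SimConfig) -> dict:
    """Generate a full dataset and write it as TSV/JSON files under ``out_dir``.

    Emits ``lever.tsv``, ``trials.tsv``, ``fluor.tsv``, ``rois.tsv``,
    ``maps.tsv``, ``bouts_truth.tsv`` and ``truth.json``; returns the in-memory
    objects for convenience.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    behavior = generate_behavior(config)
    fluor, truth = generate_activity(behavior, config)
    maps, struct_truth = generate_structural_sessions(config)

    pd.DataFrame({"time_s": behavior.time_s, "position_mm": behavior.position_mm}) \
        .to_csv(out / "lever.tsv", sep="\t", index=False)
    behavior.trials.to_csv(out / "trials.tsv", sep="\t", index=False)
    behavior.true_bouts.to_csv(out / "bouts_truth.tsv", sep="\t", index=False)

    fl = pd.DataFrame(fluor.raw_f, columns=fluor.rois["roi_id"])
    fl.insert(0, "frame", np.arange(len(fl)))
    fl.to_csv(out / "fluor.tsv", sep="\t", index=False, float_format="%.4f")
    fluor.rois.to_csv(out / "rois.tsv", sep="\t", index=False)
    maps.maps.to_csv(out / "maps.tsv", sep="\t", index=False)

    truth_json = {
        "fs_hz": config.fs_hz,
        "push_threshold_mm": config.push_threshold_mm,
        "axon_length_um": maps.axon_length_um,
        "bouton_categories": truth.bouton_categories.to_dict(orient="records"),
        "formed": {f"{s}:{a}": sorted(v) for (s, a), v in struct_truth.formed.items()},
        "eliminated": {f"{s}:{a}": sorted(v) for (s, a), v in struct_truth.eliminated.items()},
        "cluster_centers": struct_truth.cluster_centers,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1)

    return {
        "behavior": behavior,
        "fluorescence": fluor,
        "truth": truth,
        "maps": maps,
        "structural_truth": struct_truth,
    }
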