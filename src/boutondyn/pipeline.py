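"""End-to-end analysis driver.

Runs the full chain on a dataset directory — behaviour segmentation, ΔF/F and
event detection, responsiveness classification, population statistics and
(when structural maps are present) turnover and NND clustering — and writes
every stage's table plus a JSON summary to a report directory.  The run is
deterministic given the configured seed; each stage logs one structured line
with its input/output counts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from boutondyn import behavior as bh
from boutondyn import population as pop
from boutondyn import responsiveness as resp
from boutondyn import signals as sig
from boutondyn import structure as st
from boutondyn.config import RunConfig
from boutondyn.io import Dataset, load_dataset

log = logging.getLogger("boutondyn")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _behavior_stage(ds: Dataset, cfg: RunConfig) -> dict:
    time_s = ds.lever["time_s"].to_numpy(dtype=float)
    pos = ds.lever["position_mm"].to_numpy(dtype=float)
    bouts = bh.detect_movement_bouts(
        time_s, pos,
        movement_threshold_mm=cfg["behavior.movement_threshold_mm"],
        merge_gap_s=cfg["behavior.merge_gap_s"],
        exclusion_window_s=cfg["behavior.exclusion_window_s"],
    )
    bouts = bh.label_movements(bouts, ds.trials, cfg["behavior.push_threshold_mm"],
                               time_s, pos)
    win = tuple(cfg["behavior.trajectory_window_s"])
    npts = cfg["behavior.trajectory_n_points"]
    trajs = {
        i: bh.extract_trajectory(time_s, pos, b.onset_s, win, npts)
        for i, b in enumerate(bouts) if b.label in ("RM", "UM")
    }
    metrics = bh.session_metrics(ds.trials, bouts)
    log.info("behavior: %d bouts (%d RM, %d UM, %d excluded)", len(bouts),
             sum(b.label == "RM" for b in bouts),
             sum(b.label == "UM" for b in bouts),
             sum(b.label == "excluded" for b in bouts))
    return {"bouts": bouts, "trajectories": trajs, "metrics": metrics}


def _signals_stage(ds: Dataset, cfg: RunConfig, onsets: list[tuple[float, str]]) -> dict:
    fs = ds.fs_hz
    dffs: dict[str, sig.DffTrace] = {}
    events: dict[str, sig.EventSeries] = {}
    labels: dict[str, np.ndarray] = {}
    for roi in ds.fluor.columns:
        tr = sig.compute_dff(
            ds.fluor[roi].to_numpy(dtype=float), fs,
            window_s=cfg["baseline.window_s"],
            percentile=cfg["baseline.percentile"],
            align=cfg["baseline.align"],
        )
        dffs[roi] = tr
        ev = sig.detect_events(tr, cfg["events.threshold_sd"])
        events[roi] = ev
        labels[roi], _ = sig.label_events_by_movement(
            ev, onsets, cfg["events.label_pre_s"], cfg["events.label_post_s"])

    bouton_rois = ds.rois[ds.rois["kind"] == "bouton"]
    axon_events = {
        axon: {r: events[r] for r in grp["roi_id"] if r in events}
        for axon, grp in bouton_rois.groupby("axon_id")
    }
    same_peak = sig.same_peak_fraction(axon_events, cfg["events.match_tol_s"])
    log.info("signals: %d rois, %d events, mouse same-peak fraction %.3f",
             len(dffs), sum(len(e) for e in events.values()), same_peak.per_mouse)
    return {"dff": dffs, "events": events, "event_labels": labels,
            "axon_events": axon_events, "same_peak": same_peak}


def _responsiveness_stage(ds: Dataset, cfg: RunConfig, dffs: dict,
                          onsets: list[tuple[float, str]]) -> dict:
    fs = ds.fs_hz
    pre, post = cfg["alignment.pre_s"], cfg["alignment.post_s"]
    rm_onsets = np.array([t for t, l in onsets if l == "RM"])
    um_onsets = np.array([t for t, l in onsets if l == "UM"])
    bouton_rois = ds.rois[ds.rois["kind"] == "bouton"]["roi_id"].tolist()
    aligned_rm = {
        r: resp.align_to_onsets(dffs[r].z, rm_onsets, fs, pre, post, "RM")
        for r in bouton_rois
    }
    aligned_um = {
        r: resp.align_to_onsets(dffs[r].z, um_onsets, fs, pre, post, "UM")
        for r in bouton_rois
    }
    labels = resp.classify_units(
        aligned_rm, aligned_um, fs, level="bouton",
        min_trials=cfg["classify.min_trials"], pre_s=pre,
        peak_window_s=tuple(cfg["classify.peak_window_s"]),
        criterion_sd=cfg["classify.criterion_sd"],
    )
    log.info("responsiveness: %d boutons classified (%s)", len(labels),
             labels["category"].value_counts().to_dict())
    return {"aligned_rm": aligned_rm, "aligned_um": aligned_um, "labels": labels}


def _population_stage(ds: Dataset, cfg: RunConfig, dffs: dict, events: dict,
                      labels: pd.DataFrame, bouts: list, trajectories: dict,
                      aligned_rm: dict, aligned_um: dict) -> dict:
    fs = ds.fs_hz
    pre, post = cfg["alignment.pre_s"], cfg["alignment.post_s"]
    onsets = [(b.onset_s, b.label) for b in bouts if b.label in ("RM", "UM")]
    bouton_rois = ds.rois[ds.rois["kind"] == "bouton"]["roi_id"].tolist()

    out: dict = {}
    z_matrix = np.column_stack([dffs[r].z for r in bouton_rois])
    try:
        pcs = pop.segment_pcs(z_matrix)
        out["selectivity"] = pop.trajectory_selectivity(pcs, onsets, fs, pre, post)
    except pop.PopulationError as exc:
        log.info("population: selectivity unavailable (%s)", exc)
        out["selectivity"] = None

    try:
        rm_means = {r: t.mean_trace for r, t in aligned_rm.items() if not t.empty}
        um_means = {r: t.mean_trace for r, t in aligned_um.items() if not t.empty}
        out["embedding"] = pop.embed_boutons(rm_means, um_means)
    except pop.PopulationError as exc:
        log.info("population: embedding unavailable (%s)", exc)
        out["embedding"] = None

    cat = dict(zip(labels["unit_id"], labels["category"]))
    responsive = {r for r in bouton_rois if cat.get(r) != "unresponsive"}

    move_corr = {}
    ids = sorted(trajectories)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            move_corr[(ids[i], ids[j])] = bh.trajectory_correlation(
                trajectories[ids[i]], trajectories[ids[j]])

    width = int(round((pre + post) * fs))
    pop_vecs = {}
    bout_list = [(i, b) for i, b in enumerate(bouts) if b.label in ("RM", "UM")]
    for i, b in bout_list:
        start = int(round((b.onset_s - pre) * fs))
        if start < 0 or start + width > len(z_matrix):
            continue
        pop_vecs[i] = np.concatenate(
            [dffs[r].z[start:start + width] for r in sorted(responsive)]
        ) if responsive else np.empty(0)
    out["pattern_curve"] = pop.pattern_correlation_curve(pop_vecs, move_corr)

    ev_times = {r: events[r].peak_times_s for r in bouton_rois}
    onset_by_trial = {i: b.onset_s for i, b in bout_list}
    counts = pop.activated_counts(
        ev_times, responsive, onset_by_trial,
        tuple(cfg["population.activation_window_s"]))
    out["ensemble_curve"] = pop.ensemble_difference_curve(counts, move_corr)

    het_rows = []
    policy = cfg["population.heterogeneity_both_policy"]
    for axon, grp in ds.rois[ds.rois["kind"] == "bouton"].groupby("axon_id"):
        cats = [cat.get(r, "unresponsive") for r in grp["roi_id"]]
        try:
            h = pop.axon_heterogeneity(cats, policy)
        except pop.PopulationError:
            continue
        het_rows.append({"axon_id": axon, "heterogeneity": h.fraction,
                         "dominant": h.dominant, "tie": h.tie})
    out["heterogeneity"] = pd.DataFrame(het_rows)

    shaft_rois = ds.rois[ds.rois["kind"].isin(["shaft", "axon"])]
    axon_traces = {row["axon_id"]: dffs[row["roi_id"]].z
                   for _, row in shaft_rois.iterrows()}
    if len(axon_traces) >= 2:
        out["axon_pairs"] = pop.axon_pair_correlation(
            axon_traces, cfg["population.axon_corr_split"])
    else:
        out["axon_pairs"] = None
    log.info("population: %d trial pairs, mean heterogeneity %.3f",
             len(move_corr),
             out["heterogeneity"]["heterogeneity"].mean()
             if len(het_rows) else float("nan"))
    return out


def _structure_stage(ds: Dataset, cfg: RunConfig, seed: int) -> dict:
    maps = ds.maps
    sessions = sorted(maps["session"].unique())
    axon_len = float(maps["position_um"].max()) if "axon_length_um" not in maps \
        else float(maps["axon_length_um"].iloc[0])
    records = {}
    for s0, s1 in zip(sessions[:-1], sessions[1:]):
        records[(s0, s1)] = st.compute_turnover(
            maps[maps["session"] == s0], maps[maps["session"] == s1], axon_len,
            match_by="id", tol_um=cfg["structure.match_tolerance_um"])
    formed_by_axon: dict[str, np.ndarray] = {}
    if len(sessions) >= 2:
        first_pair = records[(sessions[0], sessions[1])]
        curr = maps[maps["session"] == sessions[1]]
        for r in first_pair:
            if r.n_formed >= 2:
                grp = curr[curr["axon_id"] == r.axon_id]
                formed_by_axon[r.axon_id] = grp[
                    grp["bouton_id"].isin(r.formed_ids)]["position_um"].to_numpy()
    survival = None
    if len(sessions) >= 3:
        first_pair = records[(sessions[0], sessions[1])]
        cohort = set().union(*[r.formed_ids for r in first_pair]) if first_pair else set()
        later = [maps[maps["session"] == s] for s in sessions[2:]]
        survival = pd.DataFrame({
            "session": sessions[2:],
            "survival": st.survival_curve(cohort, later),
        })
    nnd = None
    if formed_by_axon:
        try:
            nnd = st.nnd_analysis(
                formed_by_axon, axon_len,
                n_shuffles=cfg["structure.n_shuffles"], seed=seed,
                grid_step_um=cfg["structure.nnd_grid_um"],
                shuffle_mode=cfg["structure.shuffle_mode"])
        except st.StructureError as exc:
            log.info("structure: NND analysis skipped (%s)", exc)
    log.info("structure: %d session pairs", len(records))
    return {"turnover": records, "nnd": nnd, "axon_length_um": axon_len,
            "survival": survival}


def run_pipeline(dataset, config: RunConfig | None = None, out_dir=None) -> dict:
    """Execute the full analysis on a dataset (directory or ``Dataset``).

    Returns a results dict; when ``out_dir`` is given, writes each stage's
    tables (bouts.tsv, events.tsv, labels.tsv, selectivity.tsv, curves.tsv,
    heterogeneity.tsv, turnover.tsv, nnd.tsv) plus summary.json.  Outputs are
    write-once per run directory.
    """
    cfg = config or RunConfig()
    ds = dataset if isinstance(dataset, Dataset) else load_dataset(dataset)
    results: dict = {}

    def run_stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # noqa: BLE001 - stage name must reach the caller
            if out_dir is not None:
                _write_outputs(Path(out_dir), cfg, results, partial=True)
            raise StageError(name, exc) from exc

    beh = run_stage("behavior", _behavior_stage, ds, cfg)
    results["behavior"] = beh
    onsets = [(b.onset_s, b.label) for b in beh["bouts"] if b.label in ("RM", "UM")]
    sigs = run_stage("signals", _signals_stage, ds, cfg, onsets)
    results["signals"] = sigs
    rsp = run_stage("responsiveness", _responsiveness_stage, ds, cfg,
                    sigs["dff"], onsets)
    results["responsiveness"] = rsp
    results["population"] = run_stage(
        "population", _population_stage, ds, cfg, sigs["dff"], sigs["events"],
        rsp["labels"], beh["bouts"], beh["trajectories"],
        rsp["aligned_rm"], rsp["aligned_um"])
    if ds.maps is not None:
        results["structure"] = run_stage("structure", _structure_stage, ds, cfg,
                                         cfg["seed"])

    if out_dir is not None:
        _write_outputs(Path(out_dir), cfg, results, partial=False)
    return results


def _write_outputs(out: Path, cfg: RunConfig, results: dict, partial: bool) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    summary: dict = {"partial": partial}

    if "behavior" in results:
        beh = results["behavior"]
        bh.bouts_to_frame(beh["bouts"]).to_csv(out / "bouts.tsv", sep="\t", index=False)
        summary["session_metrics"] = beh["metrics"]
    if "signals" in results:
        sigs = results["signals"]
        rows = []
        for roi, ev in sigs["events"].items():
            labs = sigs["event_labels"][roi]
            for t, a, l in zip(ev.peak_times_s, ev.amplitudes, labs):
                rows.append({"roi_id": roi, "peak_time_s": t,
                             "amplitude_z": a, "movement_label": l})
        pd.DataFrame(rows).to_csv(out / "events.tsv", sep="\t", index=False)
        pd.DataFrame([{
            "roi_a": m.pair[0], "roi_b": m.pair[1], "n_same": m.n_same,
            "n_unique_a": m.n_unique_a, "n_unique_b": m.n_unique_b,
            "frac_same_a": m.frac_same_a, "frac_same_b": m.frac_same_b,
        } for m in sigs["same_peak"].pair_matches]).to_csv(
            out / "pairs.tsv", sep="\t", index=False)
        summary["same_peak_fraction"] = {
            "per_mouse": sigs["same_peak"].per_mouse,
            "per_axon": sigs["same_peak"].per_axon,
        }
    if "responsiveness" in results:
        labels = results["responsiveness"]["labels"]
        labels.to_csv(out / "labels.tsv", sep="\t", index=False)
        summary["category_proportions"] = (
            labels["category"].value_counts(normalize=True).to_dict())
    if "population" in results:
        p = results["population"]
        if p["selectivity"] is not None:
            p["selectivity"].trials.to_csv(out / "selectivity.tsv", sep="\t", index=False)
            summary["mean_selectivity_index"] = {
                lab: float(grp["index"].mean())
                for lab, grp in p["selectivity"].trials.groupby("label")
            }
        if p.get("embedding") is not None:
            emb = p["embedding"]
            pd.DataFrame({
                "bouton_id": emb.bouton_ids,
                "pc1": emb.scores[:, 0], "pc2": emb.scores[:, 1],
                "pc3": emb.scores[:, 2],
            }).to_csv(out / "embedding.tsv", sep="\t", index=False)
        curves = []
        for name in ("pattern_curve", "ensemble_curve"):
            c = p[name].as_frame()
            c.insert(0, "statistic", name)
            curves.append(c)
        pd.concat(curves).to_csv(out / "curves.tsv", sep="\t", index=False)
        p["heterogeneity"].to_csv(out / "heterogeneity.tsv", sep="\t", index=False)
        if len(p["heterogeneity"]):
            summary["mean_heterogeneity"] = float(
                p["heterogeneity"]["heterogeneity"].mean())
        if p["axon_pairs"] is not None:
            summary["fraction_high_axon_pairs"] = p["axon_pairs"].fraction_high
    if "structure" in results:
        srec = results["structure"]
        tables = []
        for (s0, s1), recs in srec["turnover"].items():
            t = st.turnover_table(recs)
            t.insert(0, "session_pair", f"{s0}-{s1}")
            tables.append(t)
        if tables:
            pd.concat(tables).to_csv(out / "turnover.tsv", sep="\t", index=False)
        if srec.get("survival") is not None:
            srec["survival"].to_csv(out / "survival.tsv", sep="\t", index=False)
        if srec["nnd"] is not None:
            n = srec["nnd"]
            pd.DataFrame({
                "grid_um": n.grid_um, "observed_cdf": n.observed_cdf,
                "shuffle_mean_cdf": n.shuffle_mean_cdf,
                "band_lo": n.band_lo, "band_hi": n.band_hi,
                "exceeds": n.exceedance_mask,
            }).to_csv(out / "nnd.tsv", sep="\t", index=False)
            summary["nnd_exceedance_range_um"] = n.exceedance_range_um

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)


def compare_stages(early_report, late_report, out_path=None) -> pd.DataFrame:
    """Fate table between two run directories' labels.tsv (early -> late).

    Returns the early->late category transition counts; with ``out_path`` the
    row-normalized fate proportions are written as fate.tsv alongside them.
    """
    from boutondyn import responsiveness as rp

    early = pd.read_csv(Path(early_report) / "labels.tsv", sep="\t")
    late = pd.read_csv(Path(late_report) / "labels.tsv", sep="\t")
    ft = rp.track_fate(early, late)
    if out_path is not None:
        fate = ft.fate.copy()
        fate.insert(0, "early_category", fate.index)
        fate.to_csv(out_path, sep="\t", index=False)
    return ft.counts
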