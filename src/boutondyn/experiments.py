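"""Ground-truth recovery experiments on synthetic data.

Each function builds a synthetic dataset with :mod:`boutondyn.synthgen`,
runs the corresponding analysis stage, and returns the recovered quantity next
to the generator's ground truth.  They are the package's benchmark harness:
the test suite asserts recovery properties on them, and they document the
problem sizes at which the pipeline has been validated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from boutondyn import signals as si
from boutondyn import structure as st
from boutondyn.config import SimConfig, TurnoverParams
from boutondyn.population import selectivity_index, trajectory_distance
from boutondyn.responsiveness import align_to_onsets, classify_units
from boutondyn.synthgen import (
    generate_activity,
    generate_behavior,
    generate_structural_sessions,
)


# ---------------------------------------------------------------------------
# analytic selectivity-index cases


def selectivity_analytic(seed: int = 0, n_frames: int = 60) -> dict[str, float]:
    """Trajectory selectivity index in the two coincidence cases.

    Builds a mean RM trajectory, a distinct mean UM trajectory, and evaluates
    the RM-trial index for a trial trajectory equal to each mean: the index is
    +1 on the RM mean and −1 on the UM mean, by construction of
    (d_UM − d_RM)/(d_RM + d_UM).
    """
    rng = np.random.default_rng(seed)
    mean_rm = rng.normal(size=(3, n_frames))
    mean_um = rng.normal(size=(3, n_frames))

    def rm_trial_index(traj: np.ndarray) -> float:
        d_rm = trajectory_distance(traj, mean_rm)
        d_um = trajectory_distance(traj, mean_um)
        return selectivity_index(d_rm, d_um)

    return {
        "on_rm_mean": rm_trial_index(mean_rm.copy()),
        "on_um_mean": rm_trial_index(mean_um.copy()),
        "n_frames": n_frames,
    }


# ---------------------------------------------------------------------------
# shared-fraction recovery


def _detect_axon_events(fluor, fs_hz: float) -> dict[str, dict[str, si.EventSeries]]:
    axon_events: dict[str, dict[str, si.EventSeries]] = {}
    boutons = fluor.rois[fluor.rois["kind"] == "bouton"]
    for axon, grp in boutons.groupby("axon_id"):
        axon_events[axon] = {}
        for roi in grp["roi_id"]:
            tr = si.compute_dff(fluor.trace(roi), fs_hz)
            axon_events[axon][roi] = si.detect_events(tr)
    return axon_events


def shared_fraction_recovery(
    seed: int,
    shared_event_fraction: float,
    n_axons: int = 50,
    boutons_per_axon: int = 5,
    n_events: int = 200,
    segment_s: float = 240.0,
    snr: float = 8.0,
) -> dict[str, float]:
    """Recover the shared-transient fraction from one synthetic mouse.

    Generates ``n_axons`` axons whose boutons each carry ~``n_events``
    background transients (no task), runs ΔF/F → event detection → pairwise
    same-peak matching, and returns the per-mouse same-peak fraction next to
    the nominal and realized ground truth.
    """
    cfg = SimConfig(
        seed=seed,
        n_axons_per_mouse=n_axons,
        boutons_per_axon=boutons_per_axon,
        n_trials=0,
        segment_s=segment_s,
        event_rate_hz=n_events / segment_s,
        shared_event_fraction=shared_event_fraction,
        snr=snr,
    )
    behavior = generate_behavior(cfg)
    fluor, truth = generate_activity(behavior, cfg)
    axon_events = _detect_axon_events(fluor, cfg.fs_hz)
    result = si.same_peak_fraction(axon_events)
    bt = truth.events[truth.events["roi_id"].str.contains("_b")]
    realized = float(bt.groupby("roi_id")["shared"].mean().mean())
    return {
        "estimate": result.per_mouse,
        "nominal": shared_event_fraction,
        "realized": realized,
        "n_axons": n_axons,
    }


# ---------------------------------------------------------------------------
# category recovery


def category_recovery(
    seed: int,
    n_axons: int = 10,
    boutons_per_axon: int = 6,
    n_trials: int = 60,
    snr: float = 8.0,
) -> dict:
    """Classify boutons on a task session and score accuracy vs ground truth.

    ``n_trials`` cued trials at p_rm = 0.5 give ~n_trials/2 rewarded and
    ~n_trials/2 unrewarded movements; boutons are aligned, averaged and
    classified into the four categories, then compared to the generator's
    per-bouton truth.
    """
    cfg = SimConfig(
        seed=seed,
        n_axons_per_mouse=n_axons,
        boutons_per_axon=boutons_per_axon,
        n_trials=n_trials,
        p_rm=0.5,
        segment_s=10.0 * n_trials + 60.0,
        snr=snr,
        category_mix={"RM_only": 0.25, "UM_only": 0.25,
                      "both": 0.25, "unresponsive": 0.25},
    )
    behavior = generate_behavior(cfg)
    fluor, truth = generate_activity(behavior, cfg)
    rm, um = behavior.onsets("RM"), behavior.onsets("UM")
    aligned_rm, aligned_um = {}, {}
    for roi in fluor.rois[fluor.rois["kind"] == "bouton"]["roi_id"]:
        tr = si.compute_dff(fluor.trace(roi), cfg.fs_hz)
        aligned_rm[roi] = align_to_onsets(tr.z, rm, cfg.fs_hz, label="RM")
        aligned_um[roi] = align_to_onsets(tr.z, um, cfg.fs_hz, label="UM")
    labels = classify_units(aligned_rm, aligned_um, cfg.fs_hz)
    true_cat = truth.bouton_categories.set_index("roi_id")["category"].sort_index()
    pred_cat = labels.set_index("unit_id")["category"].sort_index()
    return {
        "accuracy": float((true_cat == pred_cat).mean()),
        "n_units": len(true_cat),
        "n_rm_trials": len(rm),
        "n_um_trials": len(um),
        "confusion": pd.crosstab(true_cat, pred_cat),
    }


# ---------------------------------------------------------------------------
# structural experiments


def _formed_positions(maps, truth) -> dict[str, np.ndarray]:
    curr = maps.session(2)
    formed = {}
    for (s, axon), ids in truth.formed.items():
        if s == 2 and len(ids) >= 2:
            grp = curr[curr["axon_id"] == axon]
            formed[axon] = grp[grp["bouton_id"].isin(ids)]["position_um"].to_numpy()
    return formed


def nnd_experiment(
    seed: int,
    clustered: bool,
    n_axons: int = 40,
    boutons_per_axon: int = 10,
    p_form: float = 0.3,
    cluster_sigma_um: float = 10.0,
    n_shuffles: int = 1000,
) -> dict:
    """One NND clustering test on newly formed boutons.

    With ``clustered`` the generator places formed boutons around a per-axon
    Gaussian centre (σ = ``cluster_sigma_um``); otherwise uniformly.  Returns
    whether the observed NND CDF exceeds the simultaneous null envelope in the
    5–30 µm range and anywhere.
    """
    cfg = SimConfig(
        seed=seed,
        n_axons_per_mouse=n_axons,
        boutons_per_axon=boutons_per_axon,
        turnover=TurnoverParams(
            p_form=p_form,
            p_elim=0.1,
            cluster_sigma_um=cluster_sigma_um if clustered else None,
            axon_length_um=100.0,
            n_sessions=2,
        ),
    )
    maps, truth = generate_structural_sessions(cfg)
    formed = _formed_positions(maps, truth)
    res = st.nnd_analysis(
        formed, maps.axon_length_um, n_shuffles=n_shuffles, seed=seed + 1
    )
    return {
        "exceeds_5_30": st.exceeds_in_range(res, 5.0, 30.0),
        "exceeds_anywhere": bool(res.exceedance_mask.any()),
        "exceedance_range_um": res.exceedance_range_um,
    }


def turnover_exactness(seed: int, n_sessions: int = 4) -> dict:
    """Compare turnover counts on noiseless maps against generator truth."""
    cfg = SimConfig(
        seed=seed,
        n_axons_per_mouse=20,
        boutons_per_axon=8,
        turnover=TurnoverParams(p_form=0.25, p_elim=0.2, axon_length_um=100.0,
                                n_sessions=n_sessions),
    )
    maps, truth = generate_structural_sessions(cfg)
    exact = True
    for s0, s1 in zip(range(1, n_sessions), range(2, n_sessions + 1)):
        recs = st.compute_turnover(maps.session(s0), maps.session(s1),
                                   maps.axon_length_um)
        for r in recs:
            if r.formed_ids != frozenset(truth.formed[(s1, r.axon_id)]):
                exact = False
            if r.eliminated_ids != frozenset(truth.eliminated[(s1, r.axon_id)]):
                exact = False
    return {"exact": exact, "n_sessions": n_sessions}


# ---------------------------------------------------------------------------
# learning-stage contrast


def stage_contrast(
    seed: int,
    unique_fraction_early: float = 0.35,
    unique_fraction_late: float = 0.20,
    n_axons: int = 20,
    boutons_per_axon: int = 6,
    n_trials: int = 60,
    snr: float = 8.0,
) -> dict:
    """Heterogeneity and same-peak fraction for an early vs a late stage.

    The two stages differ only in the bouton-unique event fraction (and hence
    the category-deviation probability tied to it).  Learning is expected to
    lower same-axon heterogeneity and raise the same-peak fraction.
    """
    from boutondyn.population import axon_heterogeneity

    out = {}
    for stage, uf in (("early", unique_fraction_early),
                      ("late", unique_fraction_late)):
        cfg = SimConfig(
            seed=seed,
            n_axons_per_mouse=n_axons,
            boutons_per_axon=boutons_per_axon,
            n_trials=n_trials,
            p_rm=0.5,
            segment_s=10.0 * n_trials + 60.0,
            snr=snr,
            shared_event_fraction=1.0 - uf,
            category_mix={"RM_only": 0.5, "UM_only": 0.3,
                          "both": 0.1, "unresponsive": 0.1},
        )
        behavior = generate_behavior(cfg)
        fluor, truth = generate_activity(behavior, cfg)
        rm, um = behavior.onsets("RM"), behavior.onsets("UM")

        aligned_rm, aligned_um = {}, {}
        events_by_axon: dict[str, dict[str, si.EventSeries]] = {}
        boutons = fluor.rois[fluor.rois["kind"] == "bouton"]
        for axon, grp in boutons.groupby("axon_id"):
            events_by_axon[axon] = {}
            for roi in grp["roi_id"]:
                tr = si.compute_dff(fluor.trace(roi), cfg.fs_hz)
                aligned_rm[roi] = align_to_onsets(tr.z, rm, cfg.fs_hz, label="RM")
                aligned_um[roi] = align_to_onsets(tr.z, um, cfg.fs_hz, label="UM")
                events_by_axon[axon][roi] = si.detect_events(tr)

        labels = classify_units(aligned_rm, aligned_um, cfg.fs_hz)
        cat = dict(zip(labels["unit_id"], labels["category"]))
        hets = []
        for axon, grp in boutons.groupby("axon_id"):
            cats = [cat[r] for r in grp["roi_id"]]
            try:
                hets.append(axon_heterogeneity(cats).fraction)
            except Exception:
                continue
        same_peak = si.same_peak_fraction(events_by_axon)
        out[stage] = {
            "heterogeneity": float(np.mean(hets)) if hets else float("nan"),
            "same_peak": same_peak.per_mouse,
        }
    out["heterogeneity_decreases"] = (
        out["late"]["heterogeneity"] < out["early"]["heterogeneity"])
    out["same_peak_increases"] = (
        out["late"]["same_peak"] > out["early"]["same_peak"])
    return out
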