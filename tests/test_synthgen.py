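"""Generator correctness: determinism, degenerate settings, binomial rates,
conservation, and signal-to-noise monotonicity of downstream detection."""

import numpy as np
import pytest

from boutondyn.config import ConfigError, SimConfig, TurnoverParams
from boutondyn.signals import compute_dff, detect_events
from boutondyn.synthgen import (
    generate_activity,
    generate_behavior,
    generate_structural_sessions,
)


def test_identical_config_gives_identical_datasets():
    cfg = SimConfig(seed=42, n_axons_per_mouse=2, boutons_per_axon=3,
                    n_trials=10, segment_s=150.0)
    a_beh = generate_behavior(cfg)
    b_beh = generate_behavior(SimConfig(seed=42, n_axons_per_mouse=2,
                                        boutons_per_axon=3, n_trials=10,
                                        segment_s=150.0))
    assert np.array_equal(a_beh.position_mm, b_beh.position_mm)
    a_fl, _ = generate_activity(a_beh, cfg)
    b_fl, _ = generate_activity(b_beh, cfg)
    assert np.array_equal(a_fl.raw_f, b_fl.raw_f)


def test_certain_reward_yields_only_rewarded_movements():
    cfg = SimConfig(seed=3, n_trials=10, p_rm=1.0, segment_s=150.0)
    beh = generate_behavior(cfg)
    counts = beh.true_bouts["label"].value_counts()
    assert counts.get("RM", 0) == 10
    assert counts.get("UM", 0) == 0


def test_rewarded_fraction_matches_binomial_rate():
    """Across seeds the realized RM fraction stays within 3 binomial SEs."""
    p, n = 0.6, 200
    fracs = []
    for seed in range(20):
        cfg = SimConfig(seed=seed, n_trials=n, p_rm=p, segment_s=2200.0)
        beh = generate_behavior(cfg)
        trial_bouts = beh.true_bouts[beh.true_bouts["trial_id"].notna()]
        fracs.append((trial_bouts["label"] == "RM").mean())
    se = np.sqrt(p * (1 - p) / n)
    assert abs(np.mean(fracs) - p) < 3 * se


def test_trial_schedule_respects_task_windows():
    cfg = SimConfig(seed=5, n_trials=20, segment_s=260.0)
    tr = generate_behavior(cfg).trials
    ends = tr["cue_time_s"] + tr["task_window_s"]
    assert (tr["cue_time_s"].to_numpy()[1:] >= ends.to_numpy()[:-1]).all()


def test_segment_too_short_raises():
    from boutondyn.synthgen import GenerationError

    with pytest.raises(GenerationError):
        generate_behavior(SimConfig(seed=0, n_trials=50, segment_s=100.0))


def test_fully_shared_events_equal_shaft_series():
    """shared_event_fraction=1 with no task: every bouton carries the shaft's
    events."""
    cfg = SimConfig(seed=9, n_axons_per_mouse=2, boutons_per_axon=4,
                    n_trials=0, shared_event_fraction=1.0,
                    event_rate_hz=0.3, segment_s=120.0)
    beh = generate_behavior(cfg)
    _, truth = generate_activity(beh, cfg)
    for axon, grp in truth.events.groupby("axon_id"):
        shaft_times = set(grp[grp["roi_id"].str.endswith("shaft")]["time_s"])
        for roi, sub in grp[grp["roi_id"].str.contains("_b")].groupby("roi_id"):
            assert set(sub["time_s"]) == shaft_times
            assert sub["shared"].all()


def test_zero_snr_gives_no_recoverable_events():
    """With snr 0 the traces are noise + drift; any agreement between detected
    peaks and ground-truth times is chance coincidence."""
    cfg = SimConfig(seed=9, n_axons_per_mouse=3, boutons_per_axon=3,
                    n_trials=0, snr=0.0, event_rate_hz=0.3, segment_s=200.0)
    assert _detection_f1(cfg) < 0.25


def _detection_f1(cfg: SimConfig) -> float:
    beh = generate_behavior(cfg)
    fl, truth = generate_activity(beh, cfg)
    tp = fp = fn = 0
    for roi in fl.rois[fl.rois["kind"] == "bouton"]["roi_id"]:
        ev = detect_events(compute_dff(fl.trace(roi), cfg.fs_hz))
        true_t = np.sort(truth.events[truth.events["roi_id"] == roi]["time_s"])
        used = np.zeros(len(true_t), dtype=bool)
        for t in ev.peak_times_s:
            k = np.searchsorted(true_t, t)
            best, bestd = -1, np.inf
            for j in (k - 1, k):
                if 0 <= j < len(true_t) and not used[j] and abs(true_t[j] - t) < bestd:
                    best, bestd = j, abs(true_t[j] - t)
            if best >= 0 and bestd < 0.35:
                used[best] = True
                tp += 1
            else:
                fp += 1
        fn += (~used).sum()
    return 2 * tp / (2 * tp + fp + fn) if tp else 0.0


def test_detection_f1_monotone_in_snr():
    f1s = []
    for snr in (1.0, 4.0, 8.0):
        cfg = SimConfig(seed=21, n_axons_per_mouse=3, boutons_per_axon=3,
                        n_trials=0, snr=snr, event_rate_hz=0.3, segment_s=200.0)
        f1s.append(_detection_f1(cfg))
    assert f1s[0] <= f1s[1] + 0.02 <= f1s[2] + 0.04
    assert f1s[2] > 0.45


def test_event_truth_bookkeeping(small_session):
    """Every ground-truth event row is flagged shared xor unique, and shared
    rows appear on at least two ROIs of the axon."""
    ev = small_session["truth"].events
    assert ev["shared"].isin([True, False]).all()
    counts = ev.groupby("event_id")["roi_id"].nunique()
    shared_ids = ev[ev["shared"]]["event_id"].unique()
    assert (counts.loc[shared_ids] >= 2).all()


# ---------------------------------------------------------------------------
# structural generator


def test_frozen_map_without_turnover():
    cfg = SimConfig(seed=2, n_axons_per_mouse=5, boutons_per_axon=6,
                    turnover=TurnoverParams(p_form=0.0, p_elim=0.0, n_sessions=4))
    maps, truth = generate_structural_sessions(cfg)
    s1 = maps.session(1).sort_values("bouton_id")
    for s in range(2, 5):
        ss = maps.session(s).sort_values("bouton_id")
        assert list(ss["bouton_id"]) == list(s1["bouton_id"])
        assert np.allclose(ss["position_um"].to_numpy(), s1["position_um"].to_numpy())


def test_total_elimination_leaves_no_persistent_boutons():
    cfg = SimConfig(seed=2, n_axons_per_mouse=3, boutons_per_axon=5,
                    turnover=TurnoverParams(p_form=0.0, p_elim=1.0, n_sessions=2))
    maps, truth = generate_structural_sessions(cfg)
    s1_ids = set(maps.session(1)["bouton_id"])
    s2_ids = set(maps.session(2)["bouton_id"])
    assert s1_ids & s2_ids == set()


def test_formation_rate_matches_binomial_oracle():
    """Mean realized formation rate over many seeds is within 3 SE of p_form."""
    p_form, nb = 0.3, 10
    rates = []
    for seed in range(100):
        cfg = SimConfig(seed=seed, n_axons_per_mouse=50, boutons_per_axon=nb,
                        turnover=TurnoverParams(p_form=p_form, p_elim=0.0,
                                                n_sessions=2))
        _, truth = generate_structural_sessions(cfg)
        for (s, a), ids in truth.formed.items():
            rates.append(len(ids) / nb)
    se = np.sqrt(p_form * (1 - p_form) / nb / len(rates))
    assert abs(np.mean(rates) - p_form) < 3 * se


def test_session_conservation_identities():
    """persistent + eliminated = previous count; persistent + formed = current."""
    cfg = SimConfig(seed=7, n_axons_per_mouse=10, boutons_per_axon=8,
                    turnover=TurnoverParams(p_form=0.3, p_elim=0.25, n_sessions=4))
    maps, truth = generate_structural_sessions(cfg)
    for s in range(2, 5):
        for axon in maps.maps["axon_id"].unique():
            prev = set(maps.session(s - 1).query("axon_id == @axon")["bouton_id"])
            curr = set(maps.session(s).query("axon_id == @axon")["bouton_id"])
            formed = truth.formed[(s, axon)]
            elim = truth.eliminated[(s, axon)]
            assert formed & elim == set()
            assert len(prev & curr) + len(elim) == len(prev)
            assert len(prev & curr) + len(formed) == len(curr)


def test_clustered_formation_requires_positive_sigma():
    with pytest.raises(ConfigError):
        TurnoverParams(cluster_sigma_um=-1.0).validate()


def test_config_validation_names_fields():
    with pytest.raises(ConfigError, match="p_rm"):
        SimConfig(p_rm=1.5)
    with pytest.raises(ConfigError, match="category_mix"):
        SimConfig(category_mix={"RM_only": 0.5, "UM_only": 0.2})
    with pytest.raises(ConfigError, match="fs_hz"):
        SimConfig(fs_hz=0.0)
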