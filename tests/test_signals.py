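"""ΔF/F baseline, event detection, same/unique peak matching and
correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hyp_np

from boutondyn import signals as si

FS = 15.0


def brute_force_percentile(x, window, q):
    h = window // 2
    return np.array([
        np.percentile(x[max(0, i - h): i + h + 1], q) for i in range(len(x))
    ])


def brute_force_peaks(z, threshold):
    return [i for i in range(1, len(z) - 1)
            if z[i] > z[i - 1] and z[i] > z[i + 1] and z[i] > threshold]


def _dff_from_z(z, fs=FS):
    z = np.asarray(z, dtype=float)
    return si.DffTrace(dff=z, f0=np.ones_like(z), z=z, fs_hz=fs)


class TestComputeDff:
    def test_constant_trace_gives_zero_dff(self):
        tr = si.compute_dff(np.full(900, 7.0), FS)
        assert np.allclose(tr.dff, 0.0)

    def test_dff_is_scale_invariant(self, rng):
        raw = 100.0 + rng.normal(0, 1, 900) + 5 * np.sin(np.arange(900) / 80)
        a = si.compute_dff(raw, FS)
        b = si.compute_dff(3.7 * raw, FS)
        assert np.allclose(a.dff, b.dff, atol=1e-12)

    def test_baseline_matches_brute_force_oracle(self, rng):
        """Ramp and random traces against the independent sliding-percentile
        implementation, bitwise."""
        ramp = np.linspace(1.0, 10.0, 600)
        tr = si.compute_dff(ramp, FS)
        assert np.array_equal(tr.f0, brute_force_percentile(ramp, 450, 30.0))
        raw = 50.0 + rng.normal(0, 2, 700)
        tr = si.compute_dff(raw, FS, window_s=10.0, percentile=30.0)
        assert np.array_equal(tr.f0, brute_force_percentile(raw, 150, 30.0))

    def test_z_score_is_standardized(self, rng):
        raw = 100.0 + rng.normal(0, 1, 2000)
        tr = si.compute_dff(raw, FS)
        assert tr.z.mean() == pytest.approx(0.0, abs=1e-6)
        assert tr.z.std() == pytest.approx(1.0, abs=1e-6)

    def test_non_positive_baseline_names_frames(self):
        raw = np.full(600, 5.0)
        raw[100:300] = -1.0
        with pytest.raises(si.BaselineError, match="frames"):
            si.compute_dff(raw, FS)

    def test_trailing_alignment_uses_past_samples_only(self):
        raw = np.concatenate([np.full(300, 10.0), np.full(300, 20.0)])
        tr = si.compute_dff(raw, FS, window_s=10.0, align="trailing")
        # right after the step the trailing baseline still reflects the past
        assert tr.f0[300] < 20.0
        assert tr.f0[0] == 10.0


class TestDetectEvents:
    def test_flat_trace_has_no_events(self):
        assert len(si.detect_events(_dff_from_z(np.zeros(100)))) == 0

    def test_single_bump_detected_at_apex(self):
        x = np.arange(200)
        z = 3.0 * np.exp(-0.5 * ((x - 80) / 5.0) ** 2)
        ev = si.detect_events(_dff_from_z(z))
        assert list(ev.peak_frames) == [80]
        assert ev.amplitudes[0] == pytest.approx(3.0)

    def test_subthreshold_bump_ignored(self):
        x = np.arange(200)
        z = 0.5 * np.exp(-0.5 * ((x - 80) / 5.0) ** 2)
        assert len(si.detect_events(_dff_from_z(z))) == 0

    def test_plateau_takes_first_frame(self):
        z = np.zeros(50)
        z[20:23] = 2.0
        ev = si.detect_events(_dff_from_z(z))
        assert list(ev.peak_frames) == [20]

    def test_matches_brute_force_on_random_traces(self, rng):
        for _ in range(25):
            z = rng.normal(size=rng.integers(50, 2000))
            ev = si.detect_events(_dff_from_z(z), threshold_sd=1.0)
            assert list(ev.peak_frames) == brute_force_peaks(z, 1.0)


def _series(times, fs=FS):
    times = np.asarray(times, dtype=float)
    return si.EventSeries(np.round(times * fs).astype(int), times,
                          np.ones(len(times)), fs)


class TestMatching:
    def test_identical_series_fully_matched(self):
        a = _series([1.0, 5.0, 9.0])
        m = si.match_event_pairs(a, _series([1.0, 5.0, 9.0]))
        assert m.n_same == 3
        assert m.frac_same_a == 1.0 and m.frac_same_b == 1.0

    @pytest.mark.parametrize("tb,n_expected", [([10.5], 1), ([11.0], 0)])
    def test_tolerance_rule(self, tb, n_expected):
        m = si.match_event_pairs(_series([10.0]), _series(tb))
        assert m.n_same == n_expected
        assert m.n_unique_a == 1 - n_expected
        assert m.n_unique_b == 1 - n_expected

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            si.match_event_pairs(_series([1.0]), _series([1.0]), tol_s=-1.0)

    def test_one_to_one_with_competing_events(self):
        """Two a-events near one b-event: only the closer one matches."""
        m = si.match_event_pairs(_series([10.0, 10.4]), _series([10.1]))
        assert m.n_same == 1
        assert m.matches == [(0, 0)]

    @given(
        ta=hyp_np.arrays(np.float64, st.integers(0, 25),
                         elements=st.floats(0, 60, allow_nan=False)),
        tb=hyp_np.arrays(np.float64, st.integers(0, 25),
                         elements=st.floats(0, 60, allow_nan=False)),
        tol=st.floats(0.0, 2.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_symmetry_and_conservation(self, ta, tb, tol):
        ta, tb = np.sort(ta), np.sort(tb)
        ab = si.match_event_pairs(_series(ta), _series(tb), tol_s=tol)
        ba = si.match_event_pairs(_series(tb), _series(ta), tol_s=tol)
        assert ab.n_same == ba.n_same
        assert ab.n_same + ab.n_unique_a == len(ta)
        assert ab.n_same + ab.n_unique_b == len(tb)
        seen_a = [i for i, _ in ab.matches]
        seen_b = [j for _, j in ab.matches]
        assert len(seen_a) == len(set(seen_a))
        assert len(seen_b) == len(set(seen_b))
        for i, j in ab.matches:
            assert abs(ta[i] - tb[j]) <= tol


class TestEventLabels:
    def test_window_rule(self):
        ev = _series([10.5, 9.5, 30.0])
        labels, collisions = si.label_events_by_movement(
            ev, [(10.0, "RM")], pre_s=0.330, post_s=0.670)
        # event at onset+0.5 s inside [onset-0.33, onset+0.67) -> RM;
        # event at onset-0.5 s outside the pre-window -> none
        assert list(labels) == ["RM", "none", "none"]
        assert collisions == 0

    def test_no_onsets_labels_nothing(self):
        labels, _ = si.label_events_by_movement(_series([1.0, 2.0]), [])
        assert list(labels) == ["none", "none"]

    def test_collision_resolved_by_nearest_onset(self):
        labels, collisions = si.label_events_by_movement(
            _series([10.3]), [(10.0, "RM"), (10.5, "UM")])
        assert list(labels) == ["UM"]  # 0.2 s to the UM onset vs 0.3 s to RM
        assert collisions == 1


class TestSamePeakFraction:
    def test_fully_shared_gives_one(self):
        evs = {"b0": _series([1.0, 2.0, 3.0]), "b1": _series([1.0, 2.0, 3.0])}
        res = si.same_peak_fraction({"a0": evs})
        assert res.per_mouse == 1.0

    def test_disjoint_gives_zero(self):
        evs = {"b0": _series([1.0, 3.0]), "b1": _series([10.0, 13.0])}
        res = si.same_peak_fraction({"a0": evs})
        assert res.per_mouse == 0.0

    def test_invariant_to_bouton_relabelling(self, rng):
        times = {f"b{i}": np.sort(rng.uniform(0, 100, 30)) for i in range(4)}
        evs = {k: _series(v) for k, v in times.items()}
        renamed = {f"z{i}": evs[f"b{3 - i}"] for i in range(4)}
        a = si.same_peak_fraction({"a0": evs})
        b = si.same_peak_fraction({"a0": renamed})
        assert a.per_mouse == pytest.approx(b.per_mouse)

    def test_zero_event_bouton_excluded_and_reported(self):
        evs = {"b0": _series([1.0]), "b1": _series([]), "b2": _series([1.0])}
        res = si.same_peak_fraction({"a0": evs})
        assert "b1" in res.excluded
        assert res.per_mouse == 1.0

    def test_scoped_fraction_uses_labelled_events_only(self):
        evs = {"b0": _series([1.0, 20.0]), "b1": _series([1.0, 40.0])}
        labels = {"b0": np.array(["RM", "UM"], dtype=object),
                  "b1": np.array(["RM", "UM"], dtype=object)}
        res = si.same_peak_fraction({"a0": evs}, scope="RM", event_labels=labels)
        assert res.per_mouse == 1.0  # the RM events coincide, the UM ones differ
        res = si.same_peak_fraction({"a0": evs}, scope="UM", event_labels=labels)
        assert res.per_mouse == 0.0


class TestShaftBoutonCorrelation:
    def test_identical_traces_correlate_fully(self, rng):
        z = rng.normal(size=500)
        tr = _dff_from_z(z)
        assert si.shaft_bouton_correlation(tr, _dff_from_z(z.copy())) == pytest.approx(1.0)

    def test_independent_traces_correlate_weakly(self, rng):
        a = _dff_from_z(rng.normal(size=4000))
        b = _dff_from_z(rng.normal(size=4000))
        assert abs(si.shaft_bouton_correlation(a, b)) < 0.1

    def test_peak_window_covers_five_before_fifteen_after(self, rng):
        """A peak at frame 100 is correlated over frames [95, 110+5)."""
        zb = rng.normal(size=300) * 0.1
        zb[100] = 5.0
        zs = np.zeros(300)
        zs[95:115] = np.linspace(1, 2, 20)  # structure only inside the window
        events = _series([100 / FS])
        r = si.shaft_bouton_correlation(
            _dff_from_z(zb), _dff_from_z(zs), mode="peak_windows", events=events)
        expected = np.corrcoef(zb[95:115], zs[95:115])[0, 1]
        assert r == pytest.approx(expected)

    def test_no_peaks_in_band_is_flagged(self, rng):
        zb = _dff_from_z(rng.normal(size=300) * 0.1)
        zs = _dff_from_z(rng.normal(size=300))
        r = si.shaft_bouton_correlation(zb, zs, mode="peak_windows",
                                        events=_series([]), amp_band=(8.5, 9.5))
        assert np.isnan(r)
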