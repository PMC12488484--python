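"""PCA embedding, trajectory selectivity, binned trial-pair curves, axon
heterogeneity and axon-pair correlations."""

import numpy as np
import pytest

from boutondyn import population as pop

FS = 15.0


class TestEmbedding:
    def test_matrix_shape_is_2m_by_n(self, rng):
        m, n = 60, 50
        rm = {f"b{i}": rng.normal(size=m) for i in range(n)}
        um = {f"b{i}": rng.normal(size=m) for i in range(n)}
        res = pop.embed_boutons(rm, um)
        assert res.matrix.shape == (2 * m, n)
        assert res.scores.shape == (n, 3)

    def test_identical_boutons_collapse_to_one_point(self, rng):
        """Identical columns leave rank 1: all boutons coincide on PC1 and the
        remaining components carry no variance."""
        trace = rng.normal(size=40)
        rm = {f"b{i}": trace for i in range(6)}
        um = {f"b{i}": -trace for i in range(6)}
        res = pop.embed_boutons(rm, um)
        assert np.allclose(res.scores[:, 0], res.scores[0, 0], atol=1e-9)
        assert np.allclose(res.explained_variance_ratio[1:], 0.0, atol=1e-9)

    def test_condition_locked_groups_separate(self, rng):
        """RM-locked vs UM-locked response groups split in PC space."""
        m = 60
        bump = np.exp(-0.5 * ((np.arange(m) - 25) / 4.0) ** 2)
        rm, um = {}, {}
        for i in range(20):
            noise = rng.normal(0, 0.1, size=(2, m))
            if i < 10:  # RM-locked
                rm[f"b{i}"] = 3 * bump + noise[0]
                um[f"b{i}"] = noise[1]
            else:       # UM-locked
                rm[f"b{i}"] = noise[0]
                um[f"b{i}"] = 3 * bump + noise[1]
        res = pop.embed_boutons(rm, um)
        # the two response blocks are uncorrelated, so the first two PCs carry
        # the group contrast while later components are noise
        in_g1 = np.array([int(b[1:]) < 10 for b in res.bouton_ids])
        g1 = res.scores[in_g1, :2]
        g2 = res.scores[~in_g1, :2]
        centroid_gap = np.linalg.norm(g1.mean(0) - g2.mean(0))
        spread = max(np.linalg.norm(g1 - g1.mean(0), axis=1).max(),
                     np.linalg.norm(g2 - g2.mean(0), axis=1).max())
        assert centroid_gap > spread

    def test_rank3_matrix_fully_explained(self, rng):
        basis = rng.normal(size=(120, 3))
        weights = rng.normal(size=(3, 30))
        mat = basis @ weights
        rm = {f"b{i}": mat[:60, i] for i in range(30)}
        um = {f"b{i}": mat[60:, i] for i in range(30)}
        res = pop.embed_boutons(rm, um)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-8)

    def test_sign_convention_largest_loading_positive(self, rng):
        rm = {f"b{i}": rng.normal(size=40) for i in range(8)}
        um = {f"b{i}": rng.normal(size=40) for i in range(8)}
        res = pop.embed_boutons(rm, um)
        for k in range(res.scores.shape[1]):
            j = np.argmax(np.abs(res.scores[:, k]))
            assert res.scores[j, k] > 0

    def test_boutons_missing_a_condition_dropped(self, rng):
        rm = {f"b{i}": rng.normal(size=30) for i in range(5)}
        um = {f"b{i}": rng.normal(size=30) for i in range(4)}
        res = pop.embed_boutons(rm, um)
        assert res.dropped == ["b4"]

    def test_too_few_boutons_raises(self, rng):
        rm = {"b0": rng.normal(size=30), "b1": rng.normal(size=30)}
        with pytest.raises(pop.PopulationError):
            pop.embed_boutons(rm, rm)


class TestSelectivityIndex:
    def test_coincidence_with_own_mean_scores_one(self, rng):
        from boutondyn.experiments import selectivity_analytic

        res = selectivity_analytic(seed=5)
        assert res["on_rm_mean"] == 1.0
        assert res["on_um_mean"] == -1.0

    def test_equidistant_trajectory_scores_zero(self):
        assert pop.selectivity_index(3.0, 3.0) == 0.0

    def test_undefined_when_both_distances_zero(self):
        assert np.isnan(pop.selectivity_index(0.0, 0.0))

    def test_bounded_and_antisymmetric(self, rng):
        for _ in range(50):
            d1, d2 = rng.uniform(0, 10, 2)
            if d1 + d2 == 0:
                continue
            idx = pop.selectivity_index(d1, d2)
            assert -1.0 <= idx <= 1.0
            assert pop.selectivity_index(d2, d1) == pytest.approx(-idx)

    def test_trajectory_selectivity_separates_conditions(self, rng):
        """Segment PCs that differ around RM vs UM onsets yield positive
        per-trial indices for both conditions."""
        n = 1800
        pcs = rng.normal(0, 0.05, size=(n, 3))
        rm_onsets = [20.0, 50.0, 80.0]
        um_onsets = [35.0, 65.0, 95.0]
        for o in rm_onsets:
            fr = int(o * FS)
            pcs[fr:fr + 30, 0] += 2.0
        for o in um_onsets:
            fr = int(o * FS)
            pcs[fr:fr + 30, 1] += 2.0
        onsets = [(o, "RM") for o in rm_onsets] + [(o, "UM") for o in um_onsets]
        res = pop.trajectory_selectivity(pcs, onsets, FS)
        assert (res.trials["index"] > 0).all()

    def test_needs_both_trial_labels(self, rng):
        pcs = rng.normal(size=(600, 3))
        with pytest.raises(pop.PopulationError):
            pop.trajectory_selectivity(pcs, [(10.0, "RM")], FS)


class TestEnsembleDifference:
    @pytest.mark.parametrize("a,b,expected", [
        (4, 4, 0.0),
        (3, 1, 1.0),
        (0, 5, 2.0),
    ])
    def test_formula_values(self, a, b, expected):
        assert pop.ensemble_difference(a, b) == pytest.approx(expected)

    def test_undefined_for_two_silent_trials(self):
        assert np.isnan(pop.ensemble_difference(0, 0))

    def test_symmetric_scale_invariant_bounded(self, rng):
        for _ in range(50):
            a, b = int(rng.integers(0, 50)), int(rng.integers(0, 50))
            if a + b == 0:
                continue
            v = pop.ensemble_difference(a, b)
            assert 0.0 <= v <= 2.0
            assert v == pytest.approx(pop.ensemble_difference(b, a))
            assert v == pytest.approx(pop.ensemble_difference(3 * a, 3 * b))
            assert (v == 0.0) == (a == b)


class TestBinnedCurves:
    def test_identical_trials_fill_bins_with_one(self, rng):
        vec = rng.normal(size=100)
        vectors = {i: vec.copy() for i in range(5)}
        mc = {(i, j): 0.1 + 0.18 * i for i in range(5) for j in range(i + 1, 5)}
        curve = pop.pattern_correlation_curve(vectors, mc)
        occupied = curve.counts > 0
        assert occupied.any()
        assert np.allclose(curve.means[occupied], 1.0)

    def test_empty_bins_reported_missing(self, rng):
        vectors = {0: rng.normal(size=50), 1: rng.normal(size=50)}
        curve = pop.pattern_correlation_curve(vectors, {(0, 1): 0.95})
        assert curve.counts[-1] == 1
        assert np.isnan(curve.means[:-1]).all()
        assert (curve.counts[:-1] == 0).all()

    def test_independent_population_vectors_average_near_zero(self, rng):
        vectors = {i: rng.normal(size=2000) for i in range(12)}
        mc = {(i, j): rng.uniform(-0.2, 1.0)
              for i in range(12) for j in range(i + 1, 12)}
        curve = pop.pattern_correlation_curve(vectors, mc)
        occ = curve.counts > 0
        assert np.nanmax(np.abs(curve.means[occ])) < 0.15

    def test_activity_tracks_movement_similarity(self, rng):
        """When activity is a noisy function of the trajectory, pattern
        correlation rises across movement-correlation bins."""
        base = rng.normal(size=(8, 60))
        trajs = {}
        vectors = {}
        for i in range(40):
            w = rng.uniform(0, 1)
            traj = w * base[0] + (1 - w) * base[i % 7 + 1]
            trajs[i] = traj
            vectors[i] = np.concatenate([traj, traj]) + rng.normal(0, 0.2, 120)
        mc = {}
        for i in range(40):
            for j in range(i + 1, 40):
                mc[(i, j)] = np.corrcoef(trajs[i], trajs[j])[0, 1]
        curve = pop.pattern_correlation_curve(vectors, mc)
        occ = np.flatnonzero(curve.counts > 3)
        means = curve.means[occ]
        assert len(means) >= 3
        assert means[-1] > means[0]
        # largely increasing across occupied bins
        assert np.sum(np.diff(means) > 0) >= len(means) - 2

    def test_zero_variance_vectors_skipped(self, rng):
        vectors = {0: np.zeros(50), 1: rng.normal(size=50)}
        curve = pop.pattern_correlation_curve(vectors, {(0, 1): 0.5})
        assert curve.counts.sum() == 0
        assert curve.n_skipped == 1

    def test_ensemble_curve_binning(self):
        counts = {0: 3, 1: 1, 2: 4}
        mc = {(0, 1): 0.1, (0, 2): 0.5, (1, 2): 0.9}
        curve = pop.ensemble_difference_curve(counts, mc)
        assert curve.means[1] == pytest.approx(1.0)        # |3-1|/2
        assert curve.means[3] == pytest.approx(2 / 7)      # |3-4|/3.5
        assert curve.means[5] == pytest.approx(1.2)        # |1-4|/2.5


class TestHeterogeneity:
    def test_homogeneous_axon_scores_zero(self):
        res = pop.axon_heterogeneity(["RM_only"] * 5)
        assert res.fraction == 0.0 and res.dominant == "RM"

    def test_minority_fraction(self):
        res = pop.axon_heterogeneity(["RM_only"] * 9 + ["UM_only"])
        assert res.fraction == pytest.approx(0.1)

    def test_tie_flagged_at_half(self):
        res = pop.axon_heterogeneity(["RM_only", "RM_only", "UM_only", "UM_only"])
        assert res.fraction == 0.5 and res.tie

    def test_no_responsive_boutons_is_undefined(self):
        with pytest.raises(pop.PopulationError):
            pop.axon_heterogeneity(["unresponsive"] * 4)

    def test_both_policy(self):
        cats = ["RM_only"] * 6 + ["UM_only"] * 2 + ["both"] * 2
        dom = pop.axon_heterogeneity(cats, "dominant")
        exc = pop.axon_heterogeneity(cats, "exclude")
        assert dom.fraction == pytest.approx(0.2)
        assert exc.fraction == pytest.approx(0.25)

    def test_homogenized_axon_scores_zero(self, rng):
        cats = ["RM_only"] * 7 + ["UM_only"] * 3
        dominant = pop.axon_heterogeneity(cats).dominant + "_only"
        res = pop.axon_heterogeneity([dominant] * len(cats))
        assert res.fraction == 0.0


class TestAxonPairs:
    def test_identical_axons_classified_high(self, rng):
        z = rng.normal(size=1000)
        res = pop.axon_pair_correlation({"a0": z, "a1": z.copy()})
        assert res.pairs["r"].iloc[0] == pytest.approx(1.0)
        assert res.fraction_high == 1.0

    def test_shared_source_pair_exceeds_split(self, rng):
        signal = np.convolve(rng.poisson(0.05, 4000) * 8.0,
                             np.exp(-np.arange(20) / 6.0))[:4000]
        a = signal + rng.normal(0, 1, 4000)
        b = signal + rng.normal(0, 1, 4000)
        res = pop.axon_pair_correlation({"a0": a, "a1": b})
        assert res.pairs["r"].iloc[0] > 0.7

    def test_independent_axons_fall_below_split(self, rng):
        res = pop.axon_pair_correlation(
            {"a0": rng.normal(size=4000), "a1": rng.normal(size=4000)})
        assert res.pairs["r"].iloc[0] < 0.7
        assert res.fraction_high == 0.0

    def test_single_axon_rejected(self, rng):
        with pytest.raises(pop.PopulationError):
            pop.axon_pair_correlation({"a0": rng.normal(size=100)})
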