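import numpy as np
import pytest
from scipy.stats import wilcoxon

from gradientflow import (
    AllegianceMatrix,
    AssignmentStack,
    Parcellation,
    SynthParams,
    ValidationError,
    WindowScheme,
    allegiance,
    compare_to_static_null,
    correlation_matrix,
    flexibility,
    group_average,
    network_weighted_mean,
    phase_randomized_surrogate,
    plan_windows,
    recruitment,
    simulate_cohort,
    subject_allegiance,
)
from gradientflow.gradients import bin_gradient
from gradientflow.pipeline import RunConfig, cohort_assignments, embed_connectivity


def brute_force_allegiance(bins):
    """Exhaustive pair enumeration over every (subject, window)."""
    s, w, r = bins.shape
    out = np.zeros((r, r))
    for i in range(r):
        for j in range(r):
            hits = sum(
                1
                for a in range(s)
                for b in range(w)
                if bins[a, b, i] == bins[a, b, j]
            )
            out[i, j] = hits / (s * w)
    return out


class TestAllegiance:
    def test_single_observation_is_same_bin_indicator(self):
        stack = AssignmentStack(bins=np.array([[[0, 1, 0]]]), n_bins=2)
        m = allegiance(stack)
        np.testing.assert_array_equal(
            m.values, [[1, 0, 1], [0, 1, 0], [1, 0, 1]]
        )
        assert m.n_observations == 1

    def test_identical_windows_reduce_to_indicator(self):
        row = np.array([0, 0, 1, 2])
        stack = AssignmentStack(bins=np.tile(row, (2, 3, 1)), n_bins=3)
        expected = (row[:, None] == row[None, :]).astype(float)
        np.testing.assert_array_equal(allegiance(stack).values, expected)

    def test_matches_bruteforce_enumeration(self, rng):
        bins = rng.integers(0, 3, size=(2, 2, 3))
        stack = AssignmentStack(bins=bins, n_bins=3)
        np.testing.assert_allclose(
            allegiance(stack).values, brute_force_allegiance(bins)
        )

    def test_random_stacks_identity_property(self, rng):
        for _ in range(5):
            bins = rng.integers(0, 4, size=(3, 5, 8))
            stack = AssignmentStack(bins=bins, n_bins=4)
            np.testing.assert_allclose(
                allegiance(stack).values, brute_force_allegiance(bins)
            )

    def test_empty_stack_rejected(self):
        stack = AssignmentStack(bins=np.empty((0, 0, 0), dtype=int), n_bins=2)
        with pytest.raises(ValidationError):
            allegiance(stack)


class TestFlexibility:
    def test_constant_assignment_is_zero(self):
        stack = AssignmentStack(bins=np.zeros((1, 14, 3), dtype=int), n_bins=2)
        np.testing.assert_array_equal(flexibility(stack), 0.0)

    def test_alternating_assignment_is_one(self):
        bins = np.tile(np.array([[0], [1]] * 7).reshape(1, 14, 1), (1, 1, 2))
        stack = AssignmentStack(bins=bins, n_bins=2)
        np.testing.assert_array_equal(flexibility(stack), 1.0)

    def test_single_change_in_fourteen_windows(self):
        bins = np.zeros((1, 14, 1), dtype=int)
        bins[0, 7:, 0] = 1  # one transition
        stack = AssignmentStack(bins=bins, n_bins=2)
        assert flexibility(stack)[0, 0] == pytest.approx(1 / 13)

    def test_needs_two_windows(self):
        stack = AssignmentStack(bins=np.zeros((1, 1, 2), dtype=int), n_bins=1)
        with pytest.raises(ValidationError):
            flexibility(stack)


class TestRecruitment:
    def _parc(self, labels):
        return Parcellation(
            roi_ids=tuple(f"r{i}" for i in range(len(labels))),
            network_labels=tuple(labels),
            voxel_counts=(1,) * len(labels),
        )

    def test_whole_network_in_one_bin_is_one(self):
        parc = self._parc(["DMN", "DMN", "DMN", "SMC", "SMC"])
        bins = np.array([[[0, 0, 0, 1, 2]] * 3])
        rec = recruitment(AssignmentStack(bins=bins, n_bins=3), parc)
        np.testing.assert_array_equal(rec[0, :3], 1.0)
        np.testing.assert_array_equal(rec[0, 3:], 0.0)

    def test_matches_bruteforce_enumeration(self, rng):
        parc = self._parc(["DMN"] * 4 + ["SMC"] * 2)
        bins = rng.integers(0, 3, size=(1, 3, 6))
        rec = recruitment(AssignmentStack(bins=bins, n_bins=3), parc)
        for i in range(4):
            peers = [j for j in range(4) if j != i]
            expected = np.mean(
                [
                    bins[0, w, i] == bins[0, w, j]
                    for w in range(3)
                    for j in peers
                ]
            )
            assert rec[0, i] == pytest.approx(expected)

    def test_consistency_with_subject_allegiance(self, rng):
        # recruitment of ROI i equals the same-network (i excluded) row mean
        # of that subject's allegiance matrix
        parc = self._parc(["DMN"] * 3 + ["SMC"] * 3 + ["VIS"] * 2)
        bins = rng.integers(0, 4, size=(2, 5, 8))
        stack = AssignmentStack(bins=bins, n_bins=4)
        rec = recruitment(stack, parc)
        for s in range(2):
            m = subject_allegiance(stack, s).values
            for net in ("DMN", "SMC", "VIS"):
                idx = parc.network_indices(net)
                for i in idx:
                    peers = [j for j in idx if j != i]
                    assert rec[s, i] == pytest.approx(m[i, peers].mean())

    def test_singleton_network_reported_missing(self):
        parc = self._parc(["DMN", "SMC", "SMC"])
        bins = np.zeros((1, 2, 3), dtype=int)
        with pytest.warns(RuntimeWarning, match="singleton|single ROI"):
            rec = recruitment(AssignmentStack(bins=bins, n_bins=1), parc)
        assert np.isnan(rec[0, 0])
        assert not np.isnan(rec[0, 1:]).any()

    def test_measures_invariant_to_bin_relabeling(self, rng):
        # allegiance and recruitment only compare bins within one window, so
        # independent per-window relabelings leave them unchanged;
        # flexibility compares across windows and is invariant under a
        # single global relabeling
        parc = self._parc(["DMN"] * 3 + ["SMC"] * 3)
        bins = rng.integers(0, 4, size=(2, 4, 6))
        stack = AssignmentStack(bins=bins, n_bins=4)
        per_window = bins.copy()
        for s in range(2):
            for w in range(4):
                perm = rng.permutation(4)
                per_window[s, w] = perm[bins[s, w]]
        stack_pw = AssignmentStack(bins=per_window, n_bins=4)
        np.testing.assert_allclose(
            allegiance(stack).values, allegiance(stack_pw).values
        )
        np.testing.assert_allclose(
            recruitment(stack, parc), recruitment(stack_pw, parc)
        )
        global_perm = rng.permutation(4)
        stack_gl = AssignmentStack(bins=global_perm[bins], n_bins=4)
        np.testing.assert_allclose(flexibility(stack), flexibility(stack_gl))
        np.testing.assert_allclose(
            allegiance(stack).values, allegiance(stack_gl).values
        )


class TestNetworkWeightedMean:
    def test_equal_weights_reduce_to_mean(self):
        parc = Parcellation(
            roi_ids=("a", "b", "c"),
            network_labels=("DMN", "DMN", "DMN"),
            voxel_counts=(5, 5, 5),
        )
        out = network_weighted_mean(np.array([1.0, 2.0, 6.0]), parc)
        assert out["DMN"] == pytest.approx(3.0)

    def test_hand_computed_weighted_mean(self):
        parc = Parcellation(
            roi_ids=("a", "b", "c"),
            network_labels=("DMN", "DMN", "DMN"),
            voxel_counts=(1, 2, 3),
        )
        out = network_weighted_mean(np.array([0.0, 1.0, 1.0]), parc)
        assert out["DMN"] == pytest.approx(5 / 6)

    def test_dominant_weight_limit(self):
        parc = Parcellation(
            roi_ids=("a", "b"),
            network_labels=("DMN", "DMN"),
            voxel_counts=(1, 10**9),
        )
        out = network_weighted_mean(np.array([0.0, 7.0]), parc)
        assert out["DMN"] == pytest.approx(7.0, abs=1e-6)

    def test_nan_entries_excluded(self):
        parc = Parcellation(
            roi_ids=("a", "b", "c"),
            network_labels=("DMN", "DMN", "DMN"),
            voxel_counts=(1, 2, 3),
        )
        out = network_weighted_mean(np.array([np.nan, 1.0, 0.0]), parc)
        assert out["DMN"] == pytest.approx(2 / 5)


class TestCompareToStaticNull:
    def _alleg(self, values):
        return AllegianceMatrix(values=np.asarray(values, float), n_observations=1)

    def test_identical_distributions_give_zero_distance(self, rng):
        v = rng.uniform(size=(6, 6))
        v = (v + v.T) / 2
        res = compare_to_static_null(self._alleg(v), [self._alleg(v)] * 3)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_supports_give_unit_distance(self):
        lo = np.zeros((4, 4)) + 0.1
        hi = np.zeros((4, 4)) + 0.9
        res = compare_to_static_null(self._alleg(hi), [self._alleg(lo)] * 2)
        assert res.statistic == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compare_to_static_null(
                self._alleg(np.zeros((3, 3))), [self._alleg(np.zeros((4, 4)))]
            )

    def test_empty_null_list_rejected(self):
        with pytest.raises(ValidationError):
            compare_to_static_null(self._alleg(np.zeros((3, 3))), [])


class TestNullFlexibilityMatchesSurrogates:
    def test_stationary_data_indistinguishable_from_surrogates(self):
        """Without planted switching, real and surrogate flexibility agree
        (paired across seeds, aggregate Wilcoxon p > 0.05)."""
        diffs = []
        windows = plan_windows(WindowScheme(total_s=300))
        for seed in range(20):
            p = SynthParams(
                n_roi=21,
                n_subjects_per_group=(1, 1),
                seed=seed,
                state_switch_rate=0.0,
            )
            c = simulate_cohort(p)
            cfg = RunConfig(synth=p, seed=seed)
            ts = c.timeseries[0]
            surr = phase_randomized_surrogate(ts, seed=seed + 1000)
            ref = embed_connectivity(correlation_matrix(ts))
            real = cohort_assignments([ts], windows, cfg, ref)
            null = cohort_assignments([surr], windows, cfg, ref)
            diffs.append(
                flexibility(real).mean() - flexibility(null).mean()
            )
        assert wilcoxon(diffs).pvalue > 0.05
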