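import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import orthogonal_procrustes
from scipy.stats import special_ortho_group

from gradientflow import (
    GradientSet,
    Parcellation,
    SynthParams,
    ValidationError,
    align_gradients,
    bin_gradient,
    correlation_matrix,
    diffusion_embedding,
    gradient_similarity,
    group_average,
    network_gradient_distribution,
    normalized_angle_affinity,
    simulate_cohort,
)
from gradientflow.pipeline import embed_connectivity


def random_affinity(n, rng):
    """Symmetric, connected, non-negative affinity with unit diagonal."""
    base = rng.uniform(0.2, 1.0, size=(n, n))
    a = (base + base.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


def dense_markov_oracle(affinity, n_components, alpha=0.5):
    """Independent reference: eigendecompose the Markov matrix directly with
    the general (non-symmetric) solver, normalize eigenvectors in the
    stationary-distribution inner product (the diffusion-map convention,
    under which the trivial eigenvector is the constant 1), and apply the
    automatic-time scaling."""
    d = affinity.sum(axis=1)
    w = affinity * np.outer(d**-alpha, d**-alpha)
    d2 = w.sum(axis=1)
    m = w / d2[:, None]
    pi = d2 / d2.sum()
    evals, evecs = np.linalg.eig(m)
    order = np.argsort(evals.real)[::-1]
    evals = evals.real[order]
    evecs = evecs.real[:, order]
    psi = evecs / np.sqrt(pi @ evecs**2)[None, :]
    lam = evals[1 : n_components + 1]
    return psi[:, 1 : n_components + 1] * (lam / (1 - lam)), lam


class TestNormalizedAngleAffinity:
    def test_identical_rows_have_unit_affinity(self):
        m = np.array([[1.0, 2.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 1.0]])
        a = normalized_angle_affinity(m)
        assert a[0, 1] == pytest.approx(1.0)

    def test_orthogonal_rows_map_to_half(self):
        m = np.array([[1.0, 0.0], [0.0, 1.0]])
        a = normalized_angle_affinity(m)
        assert a[0, 1] == pytest.approx(0.5)

    def test_opposite_rows_map_to_zero(self):
        m = np.array([[1.0, 0.0], [-1.0, 0.0]])
        a = normalized_angle_affinity(m)
        assert a[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_row_names_roi(self):
        m = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValidationError, match=r"\[1\]"):
            normalized_angle_affinity(m)

    @given(n=st.integers(3, 8))
    def test_bounds_symmetry_unit_diagonal(self, n):
        rng = np.random.default_rng(n)
        a = normalized_angle_affinity(rng.normal(size=(n, n)))
        assert a.min() >= 0.0 and a.max() <= 1.0
        np.testing.assert_allclose(a, a.T)
        np.testing.assert_allclose(np.diag(a), 1.0)


class TestDiffusionEmbedding:
    @pytest.mark.parametrize("n", [10, 30, 50])
    def test_matches_dense_markov_oracle(self, n):
        rng = np.random.default_rng(n)
        a = random_affinity(n, rng)
        g = diffusion_embedding(a, n_components=2)
        expected, lam = dense_markov_oracle(a, 2)
        np.testing.assert_allclose(g.eigenvalues, lam, atol=1e-10)
        # sign/rotation-free comparison
        rot, _ = orthogonal_procrustes(g.components, expected)
        residual = np.linalg.norm(g.components @ rot - expected)
        assert residual < 1e-6

    def test_two_block_affinity_separates_blocks_by_sign(self):
        n = 20
        a = np.full((n, n), 0.05)
        a[:10, :10] = 1.0
        a[10:, 10:] = 1.0
        g = diffusion_embedding(a, n_components=1)
        signs = np.sign(g.principal)
        assert len(set(signs[:10])) == 1
        assert len(set(signs[10:])) == 1
        assert signs[0] != signs[-1]

    def test_permutation_equivariance(self, rng):
        a = random_affinity(15, rng)
        perm = rng.permutation(15)
        g = diffusion_embedding(a, n_components=2)
        gp = diffusion_embedding(a[np.ix_(perm, perm)], n_components=2)
        np.testing.assert_allclose(
            gp.components, g.components[perm], atol=1e-8
        )

    def test_degenerate_spectrum_flagged(self):
        a = np.full((6, 6), 0.5)
        np.fill_diagonal(a, 1.0)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            diffusion_embedding(a, n_components=2)

    def test_disconnected_graph_advises_lower_sparsity(self):
        a = np.zeros((6, 6))
        a[:3, :3] = 1.0
        a[3:, 3:] = 1.0
        with pytest.raises(ValidationError, match="sparsity"):
            diffusion_embedding(a, n_components=1)


class TestAlignGradients:
    def _gset(self, comps):
        k = comps.shape[1]
        return GradientSet(
            components=comps, eigenvalues=np.linspace(0.5, 0.4, k)
        )

    def test_identity_alignment(self, rng):
        ref = self._gset(rng.normal(size=(10, 2)))
        out = align_gradients(ref, ref)
        np.testing.assert_allclose(out.components, ref.components, atol=1e-10)

    def test_sign_flip_restored(self, rng):
        ref = self._gset(rng.normal(size=(10, 2)))
        flipped = self._gset(ref.components * np.array([-1.0, 1.0]))
        out = align_gradients(flipped, ref)
        np.testing.assert_allclose(out.components, ref.components, atol=1e-8)

    def test_random_rotation_recovered(self, rng):
        ref = self._gset(rng.normal(size=(12, 2)))
        q = special_ortho_group.rvs(2, random_state=3)
        rotated = self._gset(ref.components @ q)
        out = align_gradients(rotated, ref)
        assert np.linalg.norm(out.components - ref.components) < 1e-8
        assert out.aligned_to == "reference"

    def test_shape_mismatch_rejected(self, rng):
        a = self._gset(rng.normal(size=(10, 2)))
        b = self._gset(rng.normal(size=(11, 2)))
        with pytest.raises(ValidationError):
            align_gradients(a, b)


class TestBinGradient:
    def test_monotone_values_chunked_in_order(self):
        b = bin_gradient(np.arange(1.0, 11.0), 5)
        np.testing.assert_array_equal(b.bins, [0, 0, 1, 1, 2, 2, 3, 3, 4, 4])

    def test_study_scale_bins_equal_count(self, rng):
        vals = rng.normal(size=400)
        b = bin_gradient(vals, 20)
        counts = np.bincount(b.bins, minlength=20)
        np.testing.assert_array_equal(counts, 20)

    def test_all_equal_values_tie_break_by_index(self):
        b = bin_gradient(np.zeros(7), 2)
        np.testing.assert_array_equal(b.bins, [0, 0, 0, 0, 1, 1, 1])

    def test_equal_width_alternative(self):
        b = bin_gradient(np.array([0.0, 0.1, 0.9, 1.0]), 2, method="width")
        np.testing.assert_array_equal(b.bins, [0, 0, 1, 1])

    @given(n=st.integers(4, 40), k=st.integers(2, 4))
    def test_sizes_differ_by_at_most_one_and_monotone_invariance(self, n, k):
        rng = np.random.default_rng(n * 10 + k)
        vals = rng.normal(size=n)
        b = bin_gradient(vals, k)
        counts = np.bincount(b.bins, minlength=k)
        assert counts.max() - counts.min() <= 1
        # strictly monotone transform leaves the assignment unchanged
        b2 = bin_gradient(np.exp(2 * vals) + 5, k)
        np.testing.assert_array_equal(b.bins, b2.bins)


class TestGradientSimilarity:
    def test_self_similarity_is_one(self, rng):
        v = rng.normal(size=30)
        r, p = gradient_similarity(v, v)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_negation_gives_minus_one(self, rng):
        v = rng.normal(size=30)
        r, _ = gradient_similarity(v, -v)
        assert r == pytest.approx(-1.0)

    def test_static_gradient_recovers_planted_structure(self):
        # control-group static gradient vs the model-implied gradient of
        # the noise-free planted connectivity
        p = SynthParams(n_roi=100, n_subjects_per_group=(10, 1), seed=6)
        c = simulate_cohort(p)
        hc = [t for t in c.timeseries if t.subject_id.startswith("HC")]
        avg = group_average([correlation_matrix(t) for t in hc])
        g = embed_connectivity(avg)
        r, _ = gradient_similarity(g.principal, c.ground_truth.model_gradient)
        assert abs(r) > 0.9


class TestNetworkGradientDistribution:
    def test_singleton_network_has_zero_span(self):
        parc = Parcellation(
            roi_ids=("a", "b", "c"),
            network_labels=("DMN", "DMN", "SMC"),
            voxel_counts=(1, 1, 1),
        )
        _, summary = network_gradient_distribution(
            np.array([0.1, 0.9, 0.5]), parc
        )
        summary = summary.set_index("network")
        assert summary.loc["SMC", "span"] == 0.0
        assert summary.loc["DMN", "span"] == pytest.approx(0.8)

    def test_permuting_within_network_leaves_summaries_unchanged(self, rng):
        parc = Parcellation(
            roi_ids=tuple(f"r{i}" for i in range(8)),
            network_labels=("DMN",) * 4 + ("SMC",) * 4,
            voxel_counts=(1,) * 8,
        )
        vals = rng.normal(size=8)
        _, s1 = network_gradient_distribution(vals, parc)
        shuffled = vals.copy()
        shuffled[:4] = vals[[2, 0, 3, 1]]
        _, s2 = network_gradient_distribution(shuffled, parc)
        assert s1.equals(s2)
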