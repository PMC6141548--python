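"""Adjacency, topological overlap, module detection, eigengenes."""

import numpy as np
import pytest

from circage import (
    NumericError,
    adjacency,
    detect_modules,
    module_eigengene,
    simulate_module_matrix,
    tom_similarity,
)
from circage.coexpression import AdjacencyMatrix


def tom_oracle(a):
    """Triple-loop topological overlap, coded independently."""
    a = np.asarray(a, float).copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    out = np.eye(n)
    k = a.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


def latent_matrix(rng, n_rows, n_samples, make_matrix_fn, profiles=None):
    z = rng.standard_normal((n_rows, n_samples)) if profiles is None else profiles
    return make_matrix_fn(2.0 ** (z + 10.0) - 1.0, [f"S{j}" for j in range(z.shape[1])])


class TestAdjacency:
    def test_duplicated_row_has_unit_adjacency(self, rng, make_matrix_fn):
        z = rng.standard_normal(12)
        m = latent_matrix(rng, 2, 12, make_matrix_fn, profiles=np.vstack([z, z]))
        a = adjacency(m, beta=3)
        assert np.isclose(a.values[0, 1], 1.0)

    def test_matches_elementwise_oracle(self, rng, make_matrix_fn):
        m = latent_matrix(rng, 15, 10, make_matrix_fn)
        a = adjacency(m, beta=3)
        x = np.log2(m.values + 1.0)
        expected = np.abs(np.corrcoef(x)) ** 3
        np.fill_diagonal(expected, 1.0)
        assert np.allclose(a.values, expected, atol=1e-12)

    def test_affine_rescaling_of_a_row_is_invariant(self, rng, make_matrix_fn):
        z = rng.standard_normal((6, 16))
        a1 = adjacency(latent_matrix(rng, 6, 16, make_matrix_fn, z), beta=3)
        z2 = z.copy()
        z2[0] = 3.0 * z2[0] + 2.0
        a2 = adjacency(latent_matrix(rng, 6, 16, make_matrix_fn, z2), beta=3)
        assert np.allclose(a1.values, a2.values, atol=1e-9)

    def test_zero_variance_row_is_error(self, rng, make_matrix_fn):
        z = rng.standard_normal((3, 10))
        z[1] = 0.0
        with pytest.raises(NumericError, match="zero-variance"):
            adjacency(latent_matrix(rng, 3, 10, make_matrix_fn, z))


class TestTom:
    def test_full_overlap_pair(self):
        # two nodes tied at a_ij=1 sharing identical unit-weight neighbours
        a = np.array(
            [[1, 1, 1, 1], [1, 1, 1, 1], [1, 1, 1, 0], [1, 1, 0, 1]], dtype=float
        )
        tom = tom_similarity(AdjacencyMatrix(values=a, ids=list("abcd"), beta=1))
        assert np.isclose(tom.iloc[0, 1], 1.0)

    def test_isolated_pair_is_zero(self):
        a = np.eye(4)
        tom = tom_similarity(AdjacencyMatrix(values=a, ids=list("abcd"), beta=1))
        assert np.isclose(tom.iloc[0, 1], 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(5):
            c = rng.random((10, 10))
            a = (c + c.T) / 2
            np.fill_diagonal(a, 1.0)
            adj = AdjacencyMatrix(values=a, ids=[f"n{i}" for i in range(10)], beta=1)
            assert np.allclose(tom_similarity(adj).to_numpy(), tom_oracle(a), atol=1e-12)

    def test_bounds_symmetry_and_unit_diagonal(self, rng):
        c = rng.random((25, 25))
        a = (c + c.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(
            AdjacencyMatrix(values=a, ids=[f"n{i}" for i in range(25)], beta=1)
        ).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0
        assert np.allclose(np.diag(tom), 1.0)


class TestModules:
    def test_two_planted_blocks_found(self, rng, make_matrix_fn):
        m, truth = simulate_module_matrix([40, 35], n_noise=0, n_samples=20,
                                          within_cor=0.95, seed=4)
        tom = tom_similarity(adjacency(m, beta=3))
        assignment = detect_modules(tom, min_module_size=30, cut_height=0.6)
        assert len(assignment.module_ids()) == 2
        # labels ordered by decreasing size
        sizes = assignment.labels.value_counts()
        assert sizes[1] >= sizes[2]

    def test_unstructured_rows_fall_in_module_zero(self, rng, make_matrix_fn):
        m = latent_matrix(rng, 25, 20, make_matrix_fn)
        tom = tom_similarity(adjacency(m, beta=3))
        assignment = detect_modules(tom, min_module_size=30, cut_height=0.25)
        assert (assignment.labels == 0).all()

    def test_three_module_recovery_ari(self):
        from sklearn.metrics import adjusted_rand_score

        m, truth = simulate_module_matrix([60, 50, 40], n_noise=60, n_samples=32,
                                          within_cor=0.9, seed=11)
        tom = tom_similarity(adjacency(m, beta=3))
        assignment = detect_modules(tom, min_module_size=30, cut_height=0.6)
        planted = truth[truth > 0].index
        ari = adjusted_rand_score(truth[planted], assignment.labels[planted])
        assert ari >= 0.9

    def test_single_row_is_error(self, rng, make_matrix_fn):
        m = latent_matrix(rng, 1, 10, make_matrix_fn)
        import pandas as pd

        tom = pd.DataFrame([[1.0]], index=m.circ_ids, columns=m.circ_ids)
        with pytest.raises(NumericError):
            detect_modules(tom)


class TestEigengene:
    def build(self, rng, make_matrix_fn, profiles):
        import pandas as pd

        m = latent_matrix(rng, len(profiles), profiles.shape[1], make_matrix_fn, profiles)
        from circage.coexpression import ModuleAssignment

        labels = pd.Series(1, index=m.circ_ids, name="module")
        return m, ModuleAssignment(labels=labels)

    def test_identical_profiles_full_variance_explained(self, rng, make_matrix_fn):
        z = rng.standard_normal(16)
        m, assignment = self.build(rng, make_matrix_fn, np.vstack([z] * 5))
        out = module_eigengene(m, assignment)
        assert np.isclose(out.variance_explained[1], 1.0)
        eig = out.eigengenes.loc[1].to_numpy()
        zc = (z - z.mean()) / z.std()
        assert abs(abs(np.corrcoef(eig, zc)[0, 1]) - 1.0) < 1e-9

    def test_sign_oriented_to_mean_profile(self, rng, make_matrix_fn):
        z = rng.standard_normal((8, 20))
        z += rng.standard_normal(20) * 2  # shared component
        m, assignment = self.build(rng, make_matrix_fn, z)
        out = module_eigengene(m, assignment)
        eig = out.eigengenes.loc[1].to_numpy()
        x = np.log2(m.values + 1.0)
        zstd = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        assert np.dot(eig, zstd.mean(0)) > 0

    def test_matches_svd_oracle_up_to_sign(self, rng, make_matrix_fn):
        z = rng.standard_normal((12, 18))
        m, assignment = self.build(rng, make_matrix_fn, z)
        out = module_eigengene(m, assignment)
        eig = out.eigengenes.loc[1].to_numpy()
        x = np.log2(m.values + 1.0)
        zstd = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        # independent decomposition of the standardized module matrix
        w, v = np.linalg.eigh(zstd.T @ zstd)
        lead = v[:, np.argmax(w)]
        align = np.sign(np.dot(lead, eig))
        assert np.allclose(eig, align * lead, atol=1e-10)
        assert 0 < out.variance_explained[1] <= 1

    def test_unit_norm(self, rng, make_matrix_fn):
        z = rng.standard_normal((6, 14))
        m, assignment = self.build(rng, make_matrix_fn, z)
        out = module_eigengene(m, assignment)
        assert np.isclose(np.linalg.norm(out.eigengenes.loc[1]), 1.0)
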