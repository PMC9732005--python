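import numpy as np
import pytest

from tdfuse.decomposition import (
    ReducedProfile,
    align_signs,
    hosvd,
    hosvd_reduce,
    integrate,
    nested_hosvd_drug,
    stack_profiles,
    svd_reduce,
    unfold,
)
from tdfuse.io_formats import ExpressionMatrix, ExpressionTensor
from tdfuse.preprocess import normalize_per_sample


def _study(rng, n, m):
    return normalize_per_sample(
        ExpressionMatrix(
            gene_ids=[f"G{i}" for i in range(n)],
            sample_ids=[f"S{j}" for j in range(m)],
            values=rng.normal(size=(n, m)),
        )
    )


class TestSvdReduce:
    def test_reduced_equals_lambda_scaled_gene_factors(self, rng):
        X = _study(rng, 100, 7)
        svd, prof = svd_reduce(X, 7)
        np.testing.assert_allclose(
            prof.values,
            svd.gene_factors[:, :7] * svd.singular_values[:7],
            atol=1e-10,
        )

    def test_reduced_equals_direct_projection_oracle(self, rng):
        X = _study(rng, 100, 7)
        svd, prof = svd_reduce(X, 5)
        direct = X.values @ svd.sample_factors[:, :5]
        np.testing.assert_allclose(prof.values, direct, atol=1e-10)

    def test_component_count_and_ordering(self, rng):
        X = _study(rng, 60, 8)
        svd, prof = svd_reduce(X, 8)
        assert prof.n_components == 8
        assert np.all(np.diff(svd.singular_values) <= 1e-12)

    def test_factors_orthonormal(self, rng):
        X = _study(rng, 40, 6)
        svd, _ = svd_reduce(X, 6)
        np.testing.assert_allclose(
            svd.gene_factors.T @ svd.gene_factors, np.eye(6), atol=1e-8
        )
        np.testing.assert_allclose(
            svd.sample_factors.T @ svd.sample_factors, np.eye(6), atol=1e-8
        )

    def test_rank_one_matrix_has_single_component(self):
        a = np.arange(1, 21, dtype=float)
        b = np.array([1.0, -2.0, 3.0])
        X = ExpressionMatrix(
            gene_ids=[f"G{i}" for i in range(20)],
            sample_ids=["x", "y", "z"],
            values=np.outer(a, b),
        )
        _, prof = svd_reduce(X, 3)
        assert np.all(np.abs(prof.values[:, 1:]) <= 1e-10)

    def test_rank_limit_enforced(self, rng):
        X = _study(rng, 30, 4)
        with pytest.raises(ValueError, match="L cannot exceed"):
            svd_reduce(X, 5)


class TestHosvd:
    def test_full_rank_recomposition_is_exact(self, rng):
        T = rng.normal(size=(20, 6, 5))
        res = hosvd(T)
        err = np.linalg.norm(res.recompose() - T) / np.linalg.norm(T)
        assert err <= 1e-8

    def test_factor_orthonormality_and_core_all_orthogonality(self, rng):
        T = rng.normal(size=(15, 6, 4))
        res = hosvd(T)
        for U in res.factors:
            np.testing.assert_allclose(U.T @ U, np.eye(U.shape[1]), atol=1e-8)
        # slices of the core along each mode are mutually orthogonal
        for mode in range(3):
            G = unfold(res.core, mode)
            gram = G @ G.T
            off = gram - np.diag(np.diag(gram))
            assert np.max(np.abs(off)) <= 1e-6 * max(1.0, np.max(np.abs(gram)))

    def test_superdiagonal_tensor_recovered(self):
        T = np.zeros((3, 3, 3))
        for i, v in enumerate((3.0, 2.0, 1.0)):
            T[i, i, i] = v
        res = hosvd(T)
        # factors are signed permutations of the identity
        for U in res.factors:
            np.testing.assert_allclose(np.abs(U), np.eye(3), atol=1e-10)
        core_diag = np.array([abs(res.core[i, i, i]) for i in range(3)])
        np.testing.assert_allclose(core_diag, [3.0, 2.0, 1.0], atol=1e-10)
        off = res.core.copy()
        for i in range(3):
            off[i, i, i] = 0.0
        assert np.max(np.abs(off)) <= 1e-10

    def test_zero_tensor_gives_zero_core_orthonormal_factors(self):
        res = hosvd(np.zeros((4, 3, 2)))
        assert np.all(res.core == 0)
        for U in res.factors:
            np.testing.assert_allclose(U.T @ U, np.eye(U.shape[1]), atol=1e-8)

    def test_rank_exceeding_mode_size_raises(self, rng):
        with pytest.raises(ValueError, match="rank"):
            hosvd(rng.normal(size=(4, 3, 2)), ranks=[4, 5, 2])


class TestHosvdReduce:
    def _tensor(self, rng, shape):
        return normalize_per_sample(
            ExpressionTensor(
                gene_ids=[f"G{i}" for i in range(shape[0])],
                values=rng.normal(size=shape),
            )
        )

    def test_drug_study_shape_gives_eight_columns(self, rng):
        T = self._tensor(rng, (50, 10, 4, 3))
        prof = hosvd_reduce(T, (4, 2, 1))
        assert prof.values.shape == (50, 8)

    def test_paired_perturbation_shape_gives_eight_columns(self, rng):
        T = self._tensor(rng, (50, 3, 2, 3))
        prof = hosvd_reduce(T, (2, 2, 2))
        assert prof.values.shape == (50, 8)

    def test_all_ones_ranks_equal_leading_contraction_oracle(self, rng):
        T = self._tensor(rng, (40, 5, 3))
        prof = hosvd_reduce(T, (1, 1))
        u1 = np.linalg.svd(unfold(T.values, 1), full_matrices=False)[0][:, 0]
        u2 = np.linalg.svd(unfold(T.values, 2), full_matrices=False)[0][:, 0]
        direct = np.einsum("ijk,j,k->i", T.values, u1, u2)
        np.testing.assert_allclose(
            np.abs(prof.values[:, 0]), np.abs(direct), atol=1e-10
        )

    def test_column_order_is_row_major_over_mode_tuples(self, rng):
        T = self._tensor(rng, (30, 4, 3))
        prof = hosvd_reduce(T, (2, 2))
        single = {
            (i, j): hosvd_reduce(T, (i + 1, j + 1)).values[:, -1]
            for i in range(2)
            for j in range(2)
        }
        # column index l = i*2 + j for mode tuple (i, j)
        np.testing.assert_allclose(prof.values[:, 3], single[(1, 1)], atol=1e-10)
        np.testing.assert_allclose(prof.values[:, 1], single[(0, 1)], atol=1e-10)


class TestAlignSigns:
    def _profiles(self, rng, k=3, n=80, L=4):
        base = rng.normal(size=(n, L))
        out = []
        for _ in range(k):
            vals = base + 0.1 * rng.normal(size=(n, L))
            out.append(
                ReducedProfile(
                    gene_ids=[f"G{i}" for i in range(n)],
                    values=vals,
                    sample_factors=rng.normal(size=(5, L)),
                )
            )
        return out

    def test_negated_study_is_flipped_back(self, rng):
        profs = self._profiles(rng, k=2)
        profs[1].values = -profs[0].values.copy()
        aligned = align_signs(profs, reference=0)
        for l in range(4):
            r = np.corrcoef(aligned[0].values[:, l], aligned[1].values[:, l])[0, 1]
            assert r >= 0.99

    def test_identical_studies_not_flipped_relative_to_reference(self, rng):
        profs = self._profiles(rng, k=2)
        profs[1].values = profs[0].values.copy()
        aligned = align_signs(profs, reference=0)
        # both studies end up with identical columns: no relative flip
        np.testing.assert_array_equal(aligned[0].values, aligned[1].values)

    def test_sample_factors_flip_with_gene_columns(self, rng):
        profs = self._profiles(rng, k=2)
        profs[1].values = -profs[0].values.copy()
        v_before = profs[1].sample_factors.copy()
        aligned = align_signs(profs, reference=0)
        np.testing.assert_allclose(
            aligned[1].sample_factors, v_before * aligned[1].flips, atol=0
        )

    def test_post_correlations_nonnegative(self, rng):
        profs = self._profiles(rng)
        signs = rng.choice([-1.0, 1.0], size=(3, 4))
        for k in range(3):
            profs[k].values *= signs[k]
        aligned = align_signs(profs, reference=0)
        for k in (1, 2):
            for l in range(4):
                r = np.corrcoef(
                    aligned[0].values[:, l], aligned[k].values[:, l]
                )[0, 1]
                assert r >= 0


class TestStackAndIntegrate:
    def test_stack_shape_and_truncation(self, rng):
        profs = [
            ReducedProfile(
                gene_ids=[f"G{i}" for i in range(30)],
                values=rng.normal(size=(30, 8)),
            )
            for _ in range(3)
        ]
        stacked = stack_profiles(profs, 6)
        assert stacked.shape == (30, 6, 3)

    def test_too_few_columns_raises(self, rng):
        profs = [
            ReducedProfile(
                gene_ids=["a", "b"], values=rng.normal(size=(2, 3))
            )
        ]
        with pytest.raises(ValueError, match="columns"):
            stack_profiles(profs, 4)

    def test_stacking_order_permutes_study_mode_only(self, rng):
        profs = [
            ReducedProfile(
                gene_ids=[f"G{i}" for i in range(20)],
                values=rng.normal(size=(20, 4)),
            )
            for _ in range(3)
        ]
        s1 = stack_profiles(profs, 4)
        s2 = stack_profiles([profs[2], profs[0], profs[1]], 4)
        np.testing.assert_array_equal(
            s1.values, s2.values[:, :, [1, 2, 0]]
        )

    def test_single_study_gene_factors_span_svd_subspace(self, rng):
        X = _study(rng, 60, 6)
        svd, prof = svd_reduce(X, 4)
        stacked = stack_profiles([prof], 4)
        res = integrate(stacked)
        # leading 4 integrated gene factors span the same subspace as the
        # study's own leading gene factors
        U_own = svd.gene_factors[:, :4]
        U_int = res.gene_factors[:, :4]
        proj = U_own @ (U_own.T @ U_int)
        np.testing.assert_allclose(proj, U_int, atol=1e-8)

    def test_planted_rank_one_tensor_recovers_gene_pattern(self, rng):
        g = rng.normal(size=200)
        a = rng.normal(size=6)
        b = rng.normal(size=3)
        T = np.einsum("i,j,k->ijk", g, a, b)
        stacked = stack_profiles(
            [
                ReducedProfile(
                    gene_ids=[f"G{i}" for i in range(200)], values=T[:, :, k]
                )
                for k in range(3)
            ],
            6,
        )
        res = integrate(stacked)
        r = np.corrcoef(res.gene_factors[:, 0], g)[0, 1]
        assert abs(r) >= 0.99

    def test_zero_tensor_zero_core(self):
        stacked = stack_profiles(
            [
                ReducedProfile(
                    gene_ids=["a", "b", "c"], values=np.zeros((3, 2))
                )
                for _ in range(2)
            ],
            2,
        )
        assert np.all(integrate(stacked).core == 0)


class TestNestedDrugRanking:
    def test_factor_shapes_are_full_square(self, rng):
        P = rng.normal(size=(2, 94, 4, 3))
        res = nested_hosvd_drug(P, top_components=5)
        assert res.drug_factors[0].shape == (94, 94)
        assert res.dose_factors[0].shape == (4, 4)
        assert res.replicate_factors[0].shape == (3, 3)
        assert res.drug_scores.shape == (2, 94)

    def test_all_zero_slice_scores_zero(self):
        res = nested_hosvd_drug(np.zeros((1, 10, 4, 3)), top_components=3)
        # score rows of an arbitrary orthonormal completion still sum to
        # top_components overall, but planted structure is absent; the
        # ranking is then meaningless and scores must be <= 1 each
        assert np.all(res.drug_scores <= 1.0 + 1e-12)

    def test_planted_drugs_occupy_top_scores(self, rng):
        P = rng.normal(size=(1, 10, 4, 3))
        curves = np.array(
            [[0.9, 1.0, 1.0, 1.0], [0.1, 0.5, 0.9, 1.0], [0.0, 0.05, 0.3, 1.0]]
        )
        effective = [2, 5, 7]
        for d, c in zip(effective, curves):
            P[0, d] += 20.0 * c[:, None]
        res = nested_hosvd_drug(P, top_components=5)
        assert set(res.rankings[0][:3].tolist()) == set(effective)

    def test_t_exceeding_drug_count_raises(self, rng):
        with pytest.raises(ValueError, match="top_components"):
            nested_hosvd_drug(rng.normal(size=(1, 4, 4, 3)), top_components=5)
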