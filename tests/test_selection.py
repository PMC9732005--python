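import numpy as np
import pytest
from scipy import integrate as sp_integrate
from scipy.special import gamma
from statsmodels.stats.multitest import multipletests

from tdfuse.selection import (
    GeneSelection,
    bh_adjust,
    choose_factors,
    gene_pvalues,
    select_genes,
)


def chi2_sf_by_quadrature(x: float, df: int) -> float:
    """Independent oracle: numerically integrate the chi-squared density."""

    def dens(t):
        return t ** (df / 2 - 1) * np.exp(-t / 2) / (2 ** (df / 2) * gamma(df / 2))

    val, _ = sp_integrate.quad(dens, x, np.inf, limit=200)
    return val


def bh_brute_force(p: np.ndarray) -> np.ndarray:
    """O(n^2) literal step-up definition, independent of the implementation."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    rank_of = np.empty(n, dtype=int)
    rank_of[order] = np.arange(1, n + 1)
    cand = p * n / rank_of
    adj = np.empty(n)
    for i in range(n):
        adj[i] = min(1.0, min(cand[j] for j in range(n) if rank_of[j] >= rank_of[i]))
    return adj


class TestChooseFactors:
    def test_single_nonzero_entry_wins(self):
        core = np.zeros((5, 3, 2))
        core[2, 1, 0] = 7.0
        assert choose_factors(core, top_n=1) == [2]

    def test_fixed_mode_constraint_changes_ranking(self):
        core = np.zeros((6, 2, 4))
        core[0, :, :] = 2.0       # globally dominant
        core[4, 0, 3] = 50.0      # dominates slice l3=3
        assert choose_factors(core, top_n=1) == [4]  # 50^2 beats spread 2s
        core[4, 0, 3] = 5.0
        assert choose_factors(core, top_n=1) == [0]
        assert choose_factors(core, top_n=1, fixed_modes={2: 3}) == [4]

    def test_matches_brute_force_enumeration(self, rng):
        core = rng.normal(size=(6, 4, 3))
        weights = [(core[l] ** 2).sum() for l in range(6)]
        expected = sorted(range(6), key=lambda l: (-weights[l], l))
        assert choose_factors(core, top_n=6) == expected

    def test_out_of_range_constraint_raises(self, rng):
        with pytest.raises(ValueError, match="out of range"):
            choose_factors(rng.normal(size=(4, 3, 2)), fixed_modes={2: 5})


class TestGenePvalues:
    def test_zero_loading_gene_has_p_one(self, rng):
        U = rng.normal(size=(50, 3))
        U[7] = 0.0
        sel = gene_pvalues(U, [f"G{i}" for i in range(50)], omega=[0, 1, 2])
        assert sel.p_values[7] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "df,stat", [(1, 3.841), (2, 5.991)], ids=["chi2_1", "chi2_2"]
    )
    def test_known_quantiles_give_p_005(self, df, stat):
        # build loadings whose statistic for gene 0 is exactly `stat`
        n = 1000
        U = np.zeros((n, df))
        sigma = np.ones(df)
        U[0, :] = np.sqrt(stat / df) * sigma
        sel = gene_pvalues(U, [f"G{i}" for i in range(n)], omega=list(range(df)),
                           sigma=sigma)
        assert sel.p_values[0] == pytest.approx(0.05, abs=1e-3)

    def test_agrees_with_quadrature_oracle(self, rng):
        stats = rng.uniform(0.1, 25.0, size=20)
        for df in (1, 3, 7):
            sigma = np.ones(df)
            U = np.sqrt(stats[:, None] / df) * sigma
            sel = gene_pvalues(U, [str(i) for i in range(20)],
                               omega=list(range(df)), sigma=sigma)
            oracle = [chi2_sf_by_quadrature(s, df) for s in stats]
            np.testing.assert_allclose(sel.p_values, oracle, atol=1e-8)

    def test_invariant_to_factor_sign_flip(self, rng):
        U = rng.normal(size=(100, 4))
        ids = [f"G{i}" for i in range(100)]
        a = gene_pvalues(U, ids, omega=[0, 2])
        b = gene_pvalues(U * np.array([-1, 1, -1, 1.0]), ids, omega=[0, 2])
        np.testing.assert_array_equal(a.p_values, b.p_values)

    def test_empty_omega_and_zero_sigma_raise(self, rng):
        U = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="omega"):
            gene_pvalues(U, [str(i) for i in range(10)], omega=[])
        U[:, 0] = 5.0  # constant column -> zero SD
        with pytest.raises(ValueError, match="standard deviation"):
            gene_pvalues(U, [str(i) for i in range(10)], omega=[0])


class TestBhAdjust:
    def test_single_value_unchanged(self):
        np.testing.assert_array_equal(bh_adjust(np.array([0.3])), [0.3])

    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])),
            [0.04, 0.04, 0.04, 0.04],
        )

    def test_all_equal_p_unchanged(self):
        p = np.full(7, 0.2)
        np.testing.assert_allclose(bh_adjust(p), p)

    def test_matches_brute_force_and_statsmodels(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 60))
            p = rng.uniform(size=n)
            mine = bh_adjust(p)
            np.testing.assert_allclose(mine, bh_brute_force(p), atol=1e-14)
            sm = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(mine, sm, atol=1e-12)

    def test_monotone_and_dominates_raw(self, rng):
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust(np.array([0.5, 1.2]))


class TestSelectGenes:
    def _selection(self, p):
        p = np.asarray(p, dtype=float)
        return GeneSelection(
            gene_ids=[f"G{i}" for i in range(len(p))],
            omega=[0],
            sigma=np.array([1.0]),
            statistic=np.zeros(len(p)),
            p_values=p,
        )

    def test_threshold_is_strict(self):
        sel = self._selection([0.004, 0.5])  # BH-adjusted to (0.008, 0.5)
        chosen = select_genes(sel, threshold=0.01)
        assert chosen == ["G0"]
        sel2 = self._selection([0.01, 0.01])
        assert select_genes(sel2, threshold=0.01) == []  # adjP == 0.01 not <

    def test_empty_result_allowed(self):
        sel = self._selection([0.9, 0.8, 0.7])
        assert select_genes(sel) == []

    def test_output_ordered_by_adj_p(self):
        sel = self._selection([0.004, 0.0001, 0.002, 0.9])
        chosen = select_genes(sel, threshold=0.05)
        assert chosen == ["G1", "G2", "G0"]
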