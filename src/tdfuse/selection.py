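"""Gene selection from integrated gene-mode factors.

Informative gene-mode factors are identified from the core tensor: the
squared core entries G(l1, l2, l3)^2, summed over the non-gene indices
(optionally restricted to fixed values of some modes), measure how much
weight gene factor l1 carries, and the top factors form the set Omega.

Each gene i is then scored against a Gaussian null: assuming the entries
of a gene factor u_{l1 i} are normally distributed over genes with
standard deviation sigma_{l1}, the statistic

    T_i = sum_{l1 in Omega} (u_{l1 i} / sigma_{l1})^2

is chi-squared with |Omega| degrees of freedom under the null, giving
P_i = P(chi2_{|Omega|} > T_i). P-values are Benjamini-Hochberg adjusted
and genes with adjusted P below the threshold (default 0.01, strict
inequality) are selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GeneSelection",
    "choose_factors",
    "gene_pvalues",
    "bh_adjust",
    "select_genes",
]


@dataclass
class GeneSelection:
    """Per-gene chi-squared statistics, P-values and the selection flag."""

    gene_ids: list[str]
    omega: list[int]
    sigma: np.ndarray
    statistic: np.ndarray
    p_values: np.ndarray
    adj_p_values: np.ndarray | None = None
    selected: np.ndarray | None = None
    threshold: float = 0.01

    def selected_gene_ids(self) -> list[str]:
        """Selected genes ordered ascending by adjusted P (gene_id tie-break)."""
        if self.selected is None:
            raise ValueError("selection not thresholded yet")
        idx = np.flatnonzero(self.selected)
        order = sorted(idx, key=lambda i: (self.adj_p_values[i], self.gene_ids[i]))
        return [self.gene_ids[i] for i in order]


def choose_factors(
    core: np.ndarray,
    top_n: int = 5,
    fixed_modes: dict[int, int | list[int]] | None = None,
    gene_mode: int = 0,
) -> list[int]:
    """Rank gene-mode factor indices by squared core-tensor weight.

    Factor l1 is scored by ``sum G(l1, ...)^2`` over all non-gene
    indices; ``fixed_modes`` restricts which indices of the other modes
    enter the sum, e.g. ``{2: 5}`` keeps only slices with the mode-2
    index equal to 5 (0-based). Returns the ``top_n`` gene-factor
    indices, descending by weight (index as tie-break, so the order is
    deterministic).
    """
    core = np.asarray(core, dtype=float)
    sq = core**2
    if fixed_modes:
        for mode, keep in fixed_modes.items():
            if mode == gene_mode:
                raise ValueError("cannot fix the gene mode itself")
            keep_idx = np.atleast_1d(np.asarray(keep, dtype=int))
            if keep_idx.min() < 0 or keep_idx.max() >= core.shape[mode]:
                raise ValueError(
                    f"constraint index out of range for mode {mode} "
                    f"(size {core.shape[mode]})"
                )
            sq = np.take(sq, keep_idx, axis=mode)
    other = tuple(m for m in range(core.ndim) if m != gene_mode)
    weights = sq.sum(axis=other)
    order = np.lexsort((np.arange(len(weights)), -weights))
    return [int(i) for i in order[:top_n]]


def gene_pvalues(
    U: np.ndarray,
    gene_ids: list[str],
    omega: list[int],
    sigma: np.ndarray | None = None,
    exclude: np.ndarray | None = None,
) -> GeneSelection:
    """Chi-squared upper-tail P-values from gene-factor loadings.

    Parameters
    ----------
    U:
        Gene factor matrix (genes x factors), columns u_{l1 i}.
    omega:
        Factor indices (0-based) entering the statistic; non-empty.
    sigma:
        Per-factor standard deviations; by default the sample standard
        deviation of each factor column over all genes in the universe.
    exclude:
        Optional boolean mask of genes to exclude from the sigma
        estimate (e.g. zero-padded genes); P-values are still assigned
        to every gene.
    """
    U = np.asarray(U, dtype=float)
    if not omega:
        raise ValueError("omega must be non-empty")
    omega = [int(i) for i in omega]
    cols = U[:, omega]
    if sigma is None:
        est = cols if exclude is None else cols[~np.asarray(exclude, bool)]
        sigma = est.std(axis=0, ddof=1)
    else:
        sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        bad = omega[int(np.argmin(sigma))]
        raise ValueError(f"zero standard deviation for factor {bad}")
    statistic = ((cols / sigma) ** 2).sum(axis=1)
    p = stats.chi2.sf(statistic, df=len(omega))
    return GeneSelection(
        gene_ids=list(gene_ids),
        omega=omega,
        sigma=sigma,
        statistic=statistic,
        p_values=p,
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values.

    adj_p[(r)] = min over r' >= r of p[(r')] * n / r', capped at 1, with
    the original input order restored.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of P-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("P-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def select_genes(selection: GeneSelection, threshold: float = 0.01) -> list[str]:
    """Threshold a selection at adjusted P strictly below ``threshold``.

    Fills in ``adj_p_values``/``selected`` on the object and returns the
    selected gene ids ordered ascending by adjusted P.
    """
    selection.adj_p_values = bh_adjust(selection.p_values)
    selection.threshold = threshold
    selection.selected = selection.adj_p_values < threshold
    return selection.selected_gene_ids()
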