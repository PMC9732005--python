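"""Comparison methods: concatenation-SVD and per-study PCA overlap.

Concatenation is the naive alternative to tensor stacking: align the K
studies to the shared universe, column-concatenate them into one
genes x (sum_k M_k) matrix, and take a single SVD. Each study's latent
sample variables are then the column slice of the joint right singular
vectors belonging to that study.

The PCA-overlap comparison quantifies how poorly *separate* analyses
agree: PCA is applied to each study on its own, the top-n genes by
absolute gene-side loading are taken per component, and gene-set
overlaps between studies (and loading correlations against the
integrated gene factors) are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decomposition import _fix_column_signs
from .io_formats import ExpressionMatrix
from .selection import GeneSelection, gene_pvalues

__all__ = ["ConcatResult", "concat_svd", "concat_select", "pca_overlap", "PcaOverlap"]


@dataclass
class ConcatResult:
    """SVD of the column-concatenated studies.

    ``slices[k]`` is the (start, stop) column range of study k inside
    the joint sample factors; ranges are disjoint, covering and in
    input order.
    """

    gene_factors: np.ndarray
    sample_factors: np.ndarray
    singular_values: np.ndarray
    slices: list[tuple[int, int]]
    gene_ids: list[str]

    def study_sample_factors(self, k: int) -> np.ndarray:
        a, b = self.slices[k]
        return self.sample_factors[a:b]


def concat_svd(studies: list[ExpressionMatrix]) -> ConcatResult:
    """One SVD of the studies' column concatenation.

    Studies must already share the gene universe (equal gene lists) and
    be normalized.
    """
    if not studies:
        raise ValueError("no studies")
    gene_ids = studies[0].gene_ids
    for k, s in enumerate(studies):
        if s.gene_ids != gene_ids:
            raise ValueError(f"study {k} is not on the shared gene universe")
    joint = np.hstack([s.values for s in studies])
    U, sv, Vt = np.linalg.svd(joint, full_matrices=False)
    signs = _fix_column_signs(U)
    U = U * signs
    V = Vt.T * signs
    slices, start = [], 0
    for s in studies:
        slices.append((start, start + s.n_samples))
        start += s.n_samples
    return ConcatResult(
        gene_factors=U,
        sample_factors=V,
        singular_values=sv,
        slices=slices,
        gene_ids=list(gene_ids),
    )


def concat_select(
    result: ConcatResult, factor_indices: list[int]
) -> GeneSelection:
    """Gene selection with concatenation gene factors in place of the
    integrated ones; same chi-squared / BH machinery."""
    if not factor_indices:
        raise ValueError("factor_indices must be non-empty")
    return gene_pvalues(
        result.gene_factors, result.gene_ids, omega=list(factor_indices)
    )


@dataclass
class PcaOverlap:
    """Pairwise top-gene overlaps and loading correlations per component."""

    top_gene_sets: list[list[list[str]]]  # [study][component] -> gene ids
    overlap_counts: np.ndarray  # (components, K, K)
    loading_correlations: np.ndarray | None  # (components, K) vs reference
    top_n: int


def pca_overlap(
    studies: list[ExpressionMatrix],
    top_n: int = 100,
    n_components: int = 5,
    reference_factors: np.ndarray | None = None,
) -> PcaOverlap:
    """Per-study PCA, top-|loading| gene sets and their pairwise overlap.

    Each (normalized, aligned) study gets its own SVD; "PC scores
    attributed to genes" are the unit-norm gene-side loadings. For each
    of the first ``n_components`` components, the ``top_n`` genes by
    absolute loading are collected per study, all pairwise overlap
    counts form a K x K matrix, and, when ``reference_factors`` (the
    integrated gene factors) are given, the absolute Pearson correlation
    of each study's loading with the corresponding reference factor is
    reported.
    """
    if len(studies) < 2:
        raise ValueError("need at least two studies")
    gene_ids = studies[0].gene_ids
    n = len(gene_ids)
    if top_n > n:
        raise ValueError(f"top_n={top_n} exceeds gene count {n}")
    K = len(studies)
    loadings = []
    for s in studies:
        U = np.linalg.svd(s.values, full_matrices=False)[0][:, :n_components]
        loadings.append(U * _fix_column_signs(U))
    top_sets: list[list[list[str]]] = []
    for U in loadings:
        per_comp = []
        for c in range(min(n_components, U.shape[1])):
            idx = np.argsort(-np.abs(U[:, c]), kind="stable")[:top_n]
            per_comp.append([gene_ids[i] for i in idx])
        top_sets.append(per_comp)
    n_comp = min(len(ts) for ts in top_sets)
    counts = np.zeros((n_comp, K, K), dtype=int)
    for c in range(n_comp):
        sets = [set(ts[c]) for ts in top_sets]
        for a in range(K):
            for b in range(K):
                counts[c, a, b] = len(sets[a] & sets[b])
    corr = None
    if reference_factors is not None:
        R = np.asarray(reference_factors, dtype=float)
        corr = np.zeros((n_comp, K))
        for c in range(min(n_comp, R.shape[1])):
            r = R[:, c] - R[:, c].mean()
            for k in range(K):
                u = loadings[k][:, c] - loadings[k][:, c].mean()
                denom = np.linalg.norm(r) * np.linalg.norm(u)
                corr[c, k] = abs(r @ u / denom) if denom else 0.0
    return PcaOverlap(
        top_gene_sets=top_sets,
        overlap_counts=counts,
        loading_correlations=corr,
        top_n=top_n,
    )
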