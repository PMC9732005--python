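"""SVD/HOSVD machinery for integrating unmatched expression studies.

The integration trick is dimensional: a study with M_k samples is first
compressed, by its own SVD (matrix layout) or HOSVD (tensor layout), to a
genes x L "reduced profile"

    x_{i l} = sum_j x_{i j} v_{l j}   (= lambda_l * u_{l i}),

which no longer references the study's samples at all. Reduced profiles
from K studies that share only their gene universe can then be stacked
into a genes x L x K tensor and decomposed jointly with a second HOSVD,
yielding gene-mode factors common to all studies.

Singular vectors carry a sign ambiguity (u, v) -> (-u, -v). Two
conventions resolve it: within each study, the largest-magnitude entry
of every gene-side factor is made positive; across studies, factor signs
are flipped so each study's gene factors correlate positively with a
reference study's (:func:`align_signs`) before stacking.

HOSVD here is the classical truncated higher-order SVD: each mode's
factor matrix holds the leading left singular vectors of that mode's
unfolding, and the core is the tensor contracted with the transposed
factors. It is deterministic and exact at full ranks; no HOOI iteration
is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import ExpressionMatrix, ExpressionTensor

__all__ = [
    "SVDResult",
    "ReducedProfile",
    "StackedTensor",
    "HOSVDResult",
    "NestedDrugResult",
    "svd_reduce",
    "hosvd",
    "hosvd_reduce",
    "align_signs",
    "stack_profiles",
    "integrate",
    "nested_hosvd_drug",
    "unfold",
    "multi_mode_dot",
]

logger = logging.getLogger(__name__)

ZERO_CORR_TOL = 1e-8


# ---------------------------------------------------------------------------
# containers


@dataclass
class SVDResult:
    """Economy SVD of one study: X = U diag(s) V^T.

    ``gene_factors`` (N x r) and ``sample_factors`` (M x r) have
    orthonormal columns; ``singular_values`` are non-increasing.
    """

    gene_factors: np.ndarray
    sample_factors: np.ndarray
    singular_values: np.ndarray


@dataclass
class ReducedProfile:
    """One study compressed to genes x L latent components.

    ``values[:, l]`` equals the l-th singular value times the l-th gene
    factor (matrix studies) or the tensor contracted with one
    combination of condition-mode factors (tensor studies, column order
    row-major over the mode-component tuple). ``flips`` records the
    cross-study sign fixes applied, so the paired sample-side factors
    can be kept consistent.
    """

    gene_ids: list[str]
    values: np.ndarray
    sample_factors: np.ndarray | list[np.ndarray] | None = None
    singular_values: np.ndarray | None = None
    mode_ranks: tuple[int, ...] | None = None
    study_id: str = ""
    flips: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("reduced profile must be 2-D (genes x L)")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length does not match values")
        if self.flips is None:
            self.flips = np.ones(self.values.shape[1])

    @property
    def n_components(self) -> int:
        return self.values.shape[1]


@dataclass
class StackedTensor:
    """Genes x L x K tensor of stacked reduced profiles."""

    gene_ids: list[str]
    values: np.ndarray
    study_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("stacked tensor must be 3-D (genes x L x K)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stacked tensor must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class HOSVDResult:
    """Core tensor G plus one orthonormal factor matrix per mode.

    ``factors[m]`` has shape (mode_size_m, rank_m); the core has shape
    (rank_0, ..., rank_{D-1}) and satisfies
    ``X ~= core x_0 factors[0] x_1 factors[1] ...``.
    """

    core: np.ndarray
    factors: list[np.ndarray]

    @property
    def gene_factors(self) -> np.ndarray:
        """Mode-0 factor matrix (genes x rank), columns u_{l1 i}."""
        return self.factors[0]

    def recompose(self) -> np.ndarray:
        return multi_mode_dot(self.core, self.factors, transpose=False)


@dataclass
class NestedDrugResult:
    """Per-gene-factor nested HOSVD over (drug, dose, replicate) modes.

    ``drug_scores[f, d]`` is sum over the top ``top_components`` drug-mode
    singular vectors of their squared d-th entries, for the f-th kept
    gene factor; rankings are descending by score.
    """

    cores: list[np.ndarray]
    drug_factors: list[np.ndarray]
    dose_factors: list[np.ndarray]
    replicate_factors: list[np.ndarray]
    drug_scores: np.ndarray
    rankings: np.ndarray
    top_components: int


# ---------------------------------------------------------------------------
# primitives


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-m unfolding: rows index mode m, columns the other modes."""
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def _mode_dot(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    out = np.tensordot(matrix, tensor, axes=(1, mode))
    return np.moveaxis(out, 0, mode)


def multi_mode_dot(
    tensor: np.ndarray, matrices: list[np.ndarray], transpose: bool = True
) -> np.ndarray:
    """Contract ``tensor`` with one matrix per mode.

    With ``transpose=True`` each matrix is applied as M^T (projection to
    factor coordinates); with ``False`` as M (reconstruction).
    """
    out = tensor
    for mode, M in enumerate(matrices):
        out = _mode_dot(out, M.T if transpose else M, mode)
    return out


def _fix_column_signs(U: np.ndarray) -> np.ndarray:
    """Deterministic signs: largest-magnitude entry of each column positive."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return signs


def svd_reduce(X: ExpressionMatrix, L: int) -> tuple[SVDResult, ReducedProfile]:
    """SVD a study and keep its first L gene-side components.

    The reduced profile column l is ``sum_j x_{ij} v_{lj}``, identically
    ``lambda_l u_{li}``. ``L`` may not exceed the number of samples.
    """
    n, m = X.values.shape
    if L > min(n, m):
        raise ValueError(
            f"L cannot exceed M_k: requested L={L} with N={n}, M_k={m}"
        )
    U, s, Vt = np.linalg.svd(X.values, full_matrices=False)
    signs = _fix_column_signs(U)
    U = U * signs
    V = Vt.T * signs
    svd = SVDResult(gene_factors=U, sample_factors=V, singular_values=s)
    reduced = ReducedProfile(
        gene_ids=list(X.gene_ids),
        values=U[:, :L] * s[:L],
        sample_factors=V[:, :L],
        singular_values=s[:L].copy(),
        study_id="",
    )
    return svd, reduced


def hosvd(
    tensor: np.ndarray,
    ranks: list[int] | tuple[int, ...] | None = None,
    full_factors: bool = False,
) -> HOSVDResult:
    """Classical truncated HOSVD of a dense tensor.

    ``ranks[m]`` may not exceed the size of mode m. With
    ``full_factors=True`` every factor matrix is completed to a full
    square orthogonal matrix (rank = mode size), even when the mode's
    unfolding has fewer columns than rows.
    """
    tensor = np.asarray(tensor, dtype=float)
    shape = tensor.shape
    if ranks is None:
        ranks = list(shape)
    if len(ranks) != tensor.ndim:
        raise ValueError("one rank per mode required")
    for m, (r, s) in enumerate(zip(ranks, shape)):
        if r > s:
            raise ValueError(f"rank {r} exceeds size {s} of mode {m}")
    factors = []
    for mode in range(tensor.ndim):
        unf = unfold(tensor, mode)
        want_full = full_factors or ranks[mode] > min(unf.shape)
        U = np.linalg.svd(unf, full_matrices=want_full)[0]
        U = U[:, : ranks[mode]]
        U = U * _fix_column_signs(U)
        factors.append(U)
    core = multi_mode_dot(tensor, factors, transpose=True)
    return HOSVDResult(core=core, factors=factors)


def hosvd_reduce(
    X: ExpressionTensor, mode_ranks: list[int] | tuple[int, ...]
) -> ReducedProfile:
    """Compress a tensor study to genes x prod(mode_ranks) columns.

    The study's HOSVD is taken, then the tensor is contracted with the
    leading ``mode_ranks[s]`` factors of each condition mode. Column l
    enumerates the mode-component tuples (l_1, ..., l_S) in row-major
    order.
    """
    mode_ranks = tuple(int(r) for r in mode_ranks)
    if len(mode_ranks) != X.n_condition_modes:
        raise ValueError("one rank per condition mode required")
    for s, (r, m) in enumerate(zip(mode_ranks, X.mode_sizes)):
        if r > m:
            raise ValueError(
                f"rank {r} exceeds size {m} of condition mode {s + 1}"
            )
    n = X.n_genes
    # factor matrices of the condition modes only; the gene mode is not
    # decomposed (its factors are never used by the reduction)
    cond_factors = []
    for mode in range(1, X.values.ndim):
        unf = unfold(X.values, mode)
        U = np.linalg.svd(unf, full_matrices=False)[0][:, : mode_ranks[mode - 1]]
        U = U * _fix_column_signs(U)
        cond_factors.append(U)
    reduced = X.values
    for mode, U in enumerate(cond_factors, start=1):
        reduced = _mode_dot(reduced, U.T, mode)
    reduced = reduced.reshape(n, -1)  # row-major over (l_1, ..., l_S)
    return ReducedProfile(
        gene_ids=list(X.gene_ids),
        values=reduced,
        sample_factors=cond_factors,
        mode_ranks=mode_ranks,
        study_id="",
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def align_signs(
    profiles: list[ReducedProfile], reference: int = 0
) -> list[ReducedProfile]:
    """Fix cross-study signs against a reference study.

    The reference profile is first put in the canonical within-study
    convention (largest-magnitude entry of each column positive), which
    makes the whole alignment — and everything downstream — exactly
    invariant to arbitrary sign flips applied to any study beforehand.
    For each component l and study k != reference, the sign of study k's
    l-th reduced column (equivalently its l-th gene factor) is flipped if
    its Pearson correlation with the reference's l-th column is negative;
    the paired sample-side factor column is flipped with it. Near-zero
    correlations (|r| < 1e-8) keep the within-study convention and log a
    warning. Returns new profiles; inputs are not modified.
    """
    ref_fix = _fix_column_signs(profiles[reference].values)
    ref_values = profiles[reference].values * ref_fix
    out = []
    for k, prof in enumerate(profiles):
        n_common = min(prof.n_components, ref_values.shape[1])
        flips = np.ones(prof.n_components)
        if k == reference:
            flips[: ref_fix.size] = ref_fix
        else:
            for l in range(n_common):
                r = _pearson(prof.values[:, l], ref_values[:, l])
                if abs(r) < ZERO_CORR_TOL:
                    logger.warning(
                        "study %d component %d: |corr|=%.2e with reference; "
                        "keeping within-study sign convention",
                        k,
                        l,
                        abs(r),
                    )
                elif r < 0:
                    flips[l] = -1.0
        values = prof.values * flips
        sample_factors = prof.sample_factors
        if isinstance(sample_factors, np.ndarray):
            sample_factors = sample_factors * flips[: sample_factors.shape[1]]
        out.append(
            ReducedProfile(
                gene_ids=list(prof.gene_ids),
                values=values,
                sample_factors=sample_factors,
                singular_values=None
                if prof.singular_values is None
                else prof.singular_values.copy(),
                mode_ranks=prof.mode_ranks,
                study_id=prof.study_id,
                flips=flips * prof.flips,
            )
        )
    return out


def stack_profiles(profiles: list[ReducedProfile], L: int) -> StackedTensor:
    """Stack K aligned reduced profiles into a genes x L x K tensor.

    Profiles must share the gene universe; columns beyond L are
    discarded, and a profile with fewer than L columns is an error.
    """
    if not profiles:
        raise ValueError("no profiles to stack")
    gene_ids = profiles[0].gene_ids
    for k, prof in enumerate(profiles):
        if prof.n_components < L:
            raise ValueError(
                f"profile {k} has {prof.n_components} columns, needs >= {L}"
            )
        if prof.gene_ids != gene_ids:
            raise ValueError(f"profile {k} is not on the shared gene universe")
    values = np.stack([p.values[:, :L] for p in profiles], axis=2)
    return StackedTensor(
        gene_ids=list(gene_ids),
        values=values,
        study_ids=[p.study_id or f"study{k}" for k, p in enumerate(profiles)],
    )


def integrate(T: StackedTensor, gene_rank: int | None = None) -> HOSVDResult:
    """HOSVD of the stacked tensor: the integration step.

    Modes 2 (component) and 3 (study) keep full rank; the gene mode is
    truncated to ``gene_rank`` (default L*K, which spans the nonzero
    spectrum of the mode-1 unfolding exactly, so nothing is lost).
    """
    n, L, K = T.values.shape
    if gene_rank is None:
        gene_rank = min(n, L * K)
    return hosvd(T.values, ranks=[gene_rank, L, K])


def nested_hosvd_drug(
    P: np.ndarray, top_components: int = 5
) -> NestedDrugResult:
    """Rank drugs by nested HOSVD of a projected response tensor.

    ``P`` has shape (kept gene factors, drugs, doses, replicates): the
    drug-response tensor projected onto the integrated gene factors. For
    each kept gene factor, the 3-mode (drug x dose x replicate) slice is
    decomposed with full square factors, and each drug d is scored by

        score(d) = sum_{t=1}^{top_components} u_drug[d, t]^2,

    the energy of d in the leading drug-mode singular vectors; ranking is
    descending by score.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 4:
        raise ValueError("expected a 4-mode tensor (factors x drug x dose x rep)")
    n_factors, n_drugs = P.shape[0], P.shape[1]
    if top_components > n_drugs:
        raise ValueError(
            f"top_components={top_components} exceeds drug-mode size {n_drugs}"
        )
    cores, drug_f, dose_f, rep_f = [], [], [], []
    scores = np.empty((n_factors, n_drugs))
    for f in range(n_factors):
        res = hosvd(P[f], full_factors=True)
        cores.append(res.core)
        drug_f.append(res.factors[0])
        dose_f.append(res.factors[1])
        rep_f.append(res.factors[2])
        scores[f] = (res.factors[0][:, :top_components] ** 2).sum(axis=1)
    rankings = np.argsort(-scores, axis=1, kind="stable")
    return NestedDrugResult(
        cores=cores,
        drug_factors=drug_f,
        dose_factors=dose_f,
        replicate_factors=rep_f,
        drug_scores=scores,
        rankings=rankings,
        top_components=top_components,
    )
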