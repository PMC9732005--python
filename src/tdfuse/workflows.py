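"""End-to-end pipelines wiring the stages together.

These are the four analyses the package exists for, expressed over the
library modules:

1. ``integrate_studies`` — normalize each study on its native genes,
   compress it with its own SVD/HOSVD, zero-pad the reduced profiles to
   the shared gene universe, fix signs against a reference study, stack,
   and HOSVD the stack.
2. ``select_from_integration`` — pick gene-mode factors by core-tensor
   weight and convert their loadings to BH-adjusted chi-squared
   P-values.
3. ``associate_studies`` — project each study's samples onto the shared
   gene factors and screen factor coordinates against class labels.
4. ``rank_drugs`` — project a drug-response tensor onto the gene
   factors and rank drugs by the nested HOSVD score.

Plus ``integrate_scrna`` for the single-cell path: each measurement is
compressed to its top L=10 components before anything else touches it,
so memory never scales with the number of cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import (
    AssociationReport,
    SampleProjection,
    project_samples,
    test_factor_label_association,
)
from .decomposition import (
    HOSVDResult,
    ReducedProfile,
    StackedTensor,
    align_signs,
    hosvd_reduce,
    integrate,
    nested_hosvd_drug,
    stack_profiles,
    svd_reduce,
    NestedDrugResult,
)
from .io_formats import ExpressionMatrix, ExpressionTensor, ScrnaBundle
from .preprocess import GeneUniverse, build_gene_universe, normalize_per_sample
from .selection import (
    GeneSelection,
    bh_adjust,
    choose_factors,
    gene_pvalues,
    select_genes,
)

__all__ = [
    "IntegrationResult",
    "integrate_studies",
    "select_from_integration",
    "associate_studies",
    "run_full_pipeline",
    "rank_drugs",
    "integrate_scrna",
    "select_scrna_genes",
    "AssociationScreen",
    "ScrnaIntegration",
]


@dataclass
class IntegrationResult:
    """Everything the downstream stages need from an integration."""

    universe: GeneUniverse
    normalized: list[ExpressionMatrix | ExpressionTensor]
    profiles: list[ReducedProfile]
    stacked: StackedTensor
    hosvd: HOSVDResult

    @property
    def gene_factors(self) -> np.ndarray:
        return self.hosvd.factors[0]

    @property
    def core(self) -> np.ndarray:
        return self.hosvd.core


def _pad_rows(values: np.ndarray, idx: np.ndarray, n_star: int) -> np.ndarray:
    out = np.zeros((n_star,) + values.shape[1:], dtype=float)
    keep = idx >= 0
    out[idx[keep]] = values[keep]
    return out


def _reduce_study(
    study, L: int, tensor_mode_ranks: dict[int, tuple[int, ...]] | None, k: int
) -> ReducedProfile:
    if isinstance(study, ExpressionTensor):
        ranks = None if tensor_mode_ranks is None else tensor_mode_ranks.get(k)
        if ranks is None:
            raise ValueError(f"tensor study {k} needs per-mode ranks")
        profile = hosvd_reduce(study, ranks)
    else:
        profile = svd_reduce(study, min(L, study.n_samples))[1]
    profile.study_id = f"study{k}"
    return profile


def integrate_studies(
    studies: list[ExpressionMatrix | ExpressionTensor],
    L: int = 8,
    universe_mode: str = "reference",
    reference: int = 0,
    tensor_mode_ranks: dict[int, tuple[int, ...]] | None = None,
    pre_normalized: bool = False,
) -> IntegrationResult:
    """Full integration: normalize, reduce, pad, sign-fix, stack, HOSVD.

    Matrix studies are compressed with SVD to ``min(L, M_k)`` columns;
    tensor studies need ``tensor_mode_ranks[k]`` whose product must be
    >= L. Reduction happens on each study's native genes; only the
    reduced profiles are padded to the universe.
    """
    if not studies:
        raise ValueError("no studies")
    normalized = (
        list(studies)
        if pre_normalized
        else [normalize_per_sample(s) for s in studies]
    )
    universe = build_gene_universe(normalized, mode=universe_mode)
    profiles = []
    for k, study in enumerate(normalized):
        prof = _reduce_study(study, L, tensor_mode_ranks, k)
        prof = ReducedProfile(
            gene_ids=list(universe.gene_ids),
            values=_pad_rows(prof.values, universe.index_maps[k], universe.n_genes),
            sample_factors=prof.sample_factors,
            singular_values=prof.singular_values,
            mode_ranks=prof.mode_ranks,
            study_id=prof.study_id,
        )
        profiles.append(prof)
    profiles = align_signs(profiles, reference=reference)
    stacked = stack_profiles(profiles, L)
    return IntegrationResult(
        universe=universe,
        normalized=normalized,
        profiles=profiles,
        stacked=stacked,
        hosvd=integrate(stacked),
    )


def select_from_integration(
    result: IntegrationResult,
    omega: list[int] | None = None,
    top_n: int = 5,
    fixed_modes: dict[int, int | list[int]] | None = None,
    threshold: float = 0.01,
) -> GeneSelection:
    """Factor choice + chi-squared gene selection on an integration.

    ``omega`` pins the factor set explicitly; otherwise the ``top_n``
    gene-mode factors by squared core weight (optionally restricted by
    ``fixed_modes``) are used.
    """
    if omega is None:
        omega = choose_factors(result.core, top_n=top_n, fixed_modes=fixed_modes)
    selection = gene_pvalues(
        result.gene_factors, result.universe.gene_ids, omega=omega
    )
    select_genes(selection, threshold=threshold)
    return selection


def _aligned_normalized_study(result: IntegrationResult, k: int):
    study = result.normalized[k]
    idx = result.universe.index_maps[k]
    n_star = result.universe.n_genes
    padded = _pad_rows(np.asarray(study.values, dtype=float), idx, n_star)
    if isinstance(study, ExpressionMatrix):
        return ExpressionMatrix(
            gene_ids=list(result.universe.gene_ids),
            sample_ids=list(study.sample_ids),
            values=padded,
            labels=list(study.labels) if study.labels is not None else None,
        )
    return ExpressionTensor(
        gene_ids=list(result.universe.gene_ids),
        values=padded,
        mode_labels=study.mode_labels,
    )


@dataclass
class AssociationScreen:
    """Per-study association reports plus one joint BH screen."""

    projections: list[SampleProjection]
    per_study: list[AssociationReport]
    joint_adj_p: np.ndarray  # (n_factors, K)
    threshold: float = 0.05

    def significant_pairs(self) -> list[tuple[int, int]]:
        """(factor, study) pairs passing the joint screen."""
        f, k = np.nonzero(self.joint_adj_p < self.threshold)
        return list(zip(f.tolist(), k.tolist()))


def associate_studies(
    result: IntegrationResult,
    n_factors: int = 5,
    labels: list[list[str]] | None = None,
    threshold: float = 0.05,
) -> AssociationScreen:
    """Project every study and test factor coordinates against labels.

    Reports are produced per study (BH across that study's factors, the
    convention used for per-study tables) and jointly (one BH across all
    factor x study P-values — the screen that controls the error of the
    whole run and the one the null-calibration checks use).
    """
    projections, reports = [], []
    for k in range(len(result.normalized)):
        study = _aligned_normalized_study(result, k)
        lab = labels[k] if labels is not None else getattr(study, "labels", None)
        proj = project_samples(result.gene_factors, study, n_factors=n_factors)
        projections.append(proj)
        reports.append(
            test_factor_label_association(proj, labels=lab, threshold=threshold)
        )
    raw = np.column_stack([r.p_values for r in reports])
    joint = bh_adjust(raw.ravel()).reshape(raw.shape)
    return AssociationScreen(
        projections=projections,
        per_study=reports,
        joint_adj_p=joint,
        threshold=threshold,
    )


def run_full_pipeline(
    studies: list[ExpressionMatrix],
    L: int = 8,
    n_factors: int = 5,
    universe_mode: str = "reference",
    gene_threshold: float = 0.01,
    factor_threshold: float = 0.05,
) -> tuple[GeneSelection, IntegrationResult, "AssociationScreen"]:
    """Integrate, pick label-associated factors, select genes.

    This is the complete analysis: the factor set Omega is the set of
    gene-mode factors whose sample-projection coordinates pass the joint
    association screen against the studies' own class labels — the same
    logic by which the method's original analyses settled on their
    factor sets. If no factor passes (e.g. label-free data), Omega falls
    back to the top ``n_factors`` factors by squared core weight.
    """
    result = integrate_studies(studies, L=L, universe_mode=universe_mode)
    screen = associate_studies(
        result, n_factors=n_factors, threshold=factor_threshold
    )
    omega = sorted({f for f, _k in screen.significant_pairs()})
    selection = select_from_integration(
        result,
        omega=omega or None,
        top_n=n_factors,
        threshold=gene_threshold,
    )
    return selection, result, screen


def rank_drugs(
    result: IntegrationResult,
    drug_tensor: ExpressionTensor,
    n_factors: int = 4,
    top_components: int = 5,
    pre_normalized: bool = False,
) -> tuple[NestedDrugResult, np.ndarray]:
    """Project a drug-response tensor and rank drugs.

    The tensor is normalized per sample, zero-padded to the integration
    universe, projected onto the leading ``n_factors`` gene factors, and
    the nested HOSVD score is computed per kept factor. Returns the
    nested result and the projected tensor.
    """
    tensor = drug_tensor if pre_normalized else normalize_per_sample(drug_tensor)
    pos = {g: p for p, g in enumerate(result.universe.gene_ids)}
    idx = np.array([pos.get(g, -1) for g in tensor.gene_ids], dtype=int)
    padded = _pad_rows(tensor.values, idx, result.universe.n_genes)
    U = result.gene_factors[:, :n_factors]
    projected = np.tensordot(U.T, padded, axes=(1, 0))
    nested = nested_hosvd_drug(projected, top_components=top_components)
    return nested, projected


@dataclass
class ScrnaIntegration:
    """Single-cell integration: stacked profiles plus the study-mode screen."""

    integration: IntegrationResult
    measurement_report: AssociationReport
    group_labels: list[str]

    @property
    def measurement_factors(self) -> np.ndarray:
        """Study-mode factor matrix u_{l3 c} (measurements x factors)."""
        return self.integration.hosvd.factors[2]


def integrate_scrna(
    bundles: list[ScrnaBundle],
    L: int = 10,
    threshold: float = 0.05,
) -> ScrnaIntegration:
    """Compress, stack and integrate single-cell measurements.

    Each bundle is densified one at a time, normalized per cell and
    immediately compressed to its top L components, so nothing that
    scales with the cell count survives past this loop. The measurement
    mode's factor matrix u_{l3 c} is screened against the bundles'
    group annotations by categorical regression with BH across factors.
    """
    if len(bundles) < 2:
        raise ValueError("need at least two measurements")
    groups = [b.group or "unknown" for b in bundles]
    profiles, gene_ids = [], bundles[0].gene_ids
    for b in bundles:
        if b.gene_ids != gene_ids:
            raise ValueError("bundles must share the gene list")
        dense = normalize_per_sample(b.to_dense())
        prof = svd_reduce(dense, min(L, dense.n_samples))[1]
        prof.study_id = f"measurement{b.measurement_id}"
        profiles.append(prof)
    profiles = align_signs(profiles, reference=0)
    stacked = stack_profiles(profiles, L)
    hosvd_res = integrate(stacked)
    integration = IntegrationResult(
        universe=GeneUniverse(
            gene_ids=list(gene_ids),
            index_maps=[np.arange(len(gene_ids)) for _ in bundles],
        ),
        normalized=[],
        profiles=profiles,
        stacked=stacked,
        hosvd=hosvd_res,
    )
    # screen u_{l3 c}: factors x measurements
    report = test_factor_label_association(
        hosvd_res.factors[2].T, labels=groups, threshold=threshold
    )
    return ScrnaIntegration(
        integration=integration, measurement_report=report, group_labels=groups
    )


def select_scrna_genes(
    scrna: ScrnaIntegration, threshold: float = 0.01
) -> GeneSelection:
    """Gene selection for the single-cell path.

    The measurement-mode factor(s) passing the association screen fix
    the l3 constraint; the single gene-mode factor with the largest
    constrained squared core weight forms Omega.
    """
    sig = scrna.measurement_report.significant_factors()
    if not sig:
        raise ValueError("no measurement-mode factor passed the screen")
    integ = scrna.integration
    omega = choose_factors(integ.core, top_n=1, fixed_modes={2: sig})
    selection = gene_pvalues(
        integ.gene_factors, integ.universe.gene_ids, omega=omega
    )
    select_genes(selection, threshold=threshold)
    return selection
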