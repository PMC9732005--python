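"""Sample projection and factor-label association screening.

Once the integration produces gene-mode factors u_{l1 i}, every study's
samples acquire coordinates in the shared factor space,

    v_{l1 j k} = sum_i u_{l1 i} x_{i j k},

computable for any study on the same gene universe — including studies
that were never part of the integration (this is the projection step the
drug-ranking workflow uses). Whether a factor coordinate tracks a
categorical classification of the samples is tested per factor by
one-way categorical regression — the linear model with class indicators,
equivalently the ANOVA F-test of coordinate on class — with
Benjamini-Hochberg correction across the factors of one screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ExpressionMatrix, ExpressionTensor
from .selection import bh_adjust

__all__ = [
    "SampleProjection",
    "AssociationReport",
    "project_samples",
    "test_factor_label_association",
]


@dataclass
class SampleProjection:
    """Coordinates of one study's samples in the shared factor space.

    ``coords`` has shape (n_factors, M_k) for matrix studies, or
    (n_factors, M^[1], ..., M^[S]) for tensor studies.
    """

    coords: np.ndarray
    sample_ids: list[str] | None = None
    labels: list[str] | None = None
    study_id: str = ""

    @property
    def n_factors(self) -> int:
        return self.coords.shape[0]

    def factor_matrix(self) -> np.ndarray:
        """Coordinates flattened to (n_factors, n_samples)."""
        return self.coords.reshape(self.n_factors, -1)


@dataclass
class AssociationReport:
    """Per-factor ANOVA of coordinate against a categorical label."""

    f_statistics: np.ndarray
    p_values: np.ndarray
    adj_p_values: np.ndarray
    significant: np.ndarray
    classes: list[str]
    threshold: float = 0.05

    def significant_factors(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.significant)]


def project_samples(
    U: np.ndarray,
    X: ExpressionMatrix | ExpressionTensor,
    n_factors: int | None = None,
) -> SampleProjection:
    """Project a study onto the integrated gene factors.

    ``U`` is the gene-factor matrix (universe genes x rank); ``X`` must
    be an aligned, normalized study on the same universe. Coordinates
    are the contraction over genes of the factors with the study values.
    """
    U = np.asarray(U, dtype=float)
    if X.values.shape[0] != U.shape[0]:
        raise ValueError(
            f"gene universe mismatch: study has {X.values.shape[0]} genes, "
            f"factors have {U.shape[0]}"
        )
    if n_factors is not None:
        U = U[:, :n_factors]
    coords = np.tensordot(U.T, X.values, axes=(1, 0))
    if isinstance(X, ExpressionMatrix):
        return SampleProjection(
            coords=coords,
            sample_ids=list(X.sample_ids),
            labels=list(X.labels) if X.labels is not None else None,
        )
    return SampleProjection(coords=coords)


def test_factor_label_association(
    proj: SampleProjection | np.ndarray,
    labels: list[str] | np.ndarray | None = None,
    threshold: float = 0.05,
) -> AssociationReport:
    """One-way categorical regression of each factor coordinate on class.

    Accepts either a :class:`SampleProjection` (using its own labels if
    ``labels`` is None) or a raw (n_factors x n_samples) matrix such as
    the study-mode factor matrix u_{l3 c} of an scRNA-seq integration.
    P-values are BH-corrected across the factors of this screen and
    flagged at adjusted P < ``threshold``.
    """
    if isinstance(proj, SampleProjection):
        coords = proj.factor_matrix()
        if labels is None:
            labels = proj.labels
    else:
        coords = np.asarray(proj, dtype=float)
        if coords.ndim != 2:
            raise ValueError("expected factors x samples matrix")
    if labels is None:
        raise ValueError("labels required")
    labels = np.asarray(labels)
    if labels.size != coords.shape[1]:
        raise ValueError("label count does not match sample count")
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least two label classes")
    if coords.shape[1] <= len(classes):
        raise ValueError("need more observations than classes")
    groups_idx = [np.flatnonzero(labels == c) for c in classes]
    f_stats = np.empty(coords.shape[0])
    p_vals = np.empty(coords.shape[0])
    for f in range(coords.shape[0]):
        groups = [coords[f, idx] for idx in groups_idx]
        if all(np.ptp(g) == 0 for g in groups):
            # degenerate: no within-group variance; constant coordinates
            means = [g.mean() for g in groups]
            if np.ptp(means) == 0:
                f_stats[f], p_vals[f] = 0.0, 1.0
            else:
                f_stats[f], p_vals[f] = np.inf, 0.0
            continue
        res = stats.f_oneway(*groups)
        f_stats[f] = res.statistic
        p_vals[f] = res.pvalue
    adj = bh_adjust(p_vals)
    return AssociationReport(
        f_statistics=f_stats,
        p_values=p_vals,
        adj_p_values=adj,
        significant=adj < threshold,
        classes=[str(c) for c in classes],
        threshold=threshold,
    )
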