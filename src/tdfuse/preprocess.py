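"""Per-sample normalization and gene-universe alignment.

Each study is normalized so that, within every sample (every column of a
matrix study; every gene fiber of a tensor study), expression has zero
mean and sum of squares equal to the number of genes N measured in that
study:

    sum_i x_{ij} = 0    and    sum_i x_{ij}^2 = N.

Studies measuring different gene sets are then placed on a common gene
universe, with genes a study did not measure filled with exact zeros.
Normalization happens on each study's native genes *before* padding, so
padded rows carry no signal and the moment conditions above continue to
hold over the native gene set; the padded rows are excluded from the
sums by construction. We do not re-normalize after padding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import ExpressionMatrix, ExpressionTensor

__all__ = ["GeneUniverse", "normalize_per_sample", "align_gene_universe"]

logger = logging.getLogger(__name__)


@dataclass
class GeneUniverse:
    """Common ordered gene list plus per-study index maps.

    ``index_maps[k]`` maps positions in study ``k``'s native gene list to
    positions in ``gene_ids``; a value of ``-1`` marks a native gene that
    is absent from the universe (possible only in reference mode).
    """

    gene_ids: list[str]
    index_maps: list[np.ndarray]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def _normalize_columns(values: np.ndarray, sample_names) -> np.ndarray:
    """Zero-mean, sum-of-squares-N scaling of each column of a 2-D array."""
    n = values.shape[0]
    centered = values - values.mean(axis=0, keepdims=True)
    # population SD: sum_i x^2 = N  <=>  divide by sqrt(mean of squares)
    scale = np.sqrt((centered**2).mean(axis=0, keepdims=True))
    zero = np.flatnonzero(scale.ravel() == 0)
    if zero.size:
        name = sample_names[zero[0]]
        raise ValueError(f"zero-variance sample: {name!r}")
    return centered / scale


def normalize_per_sample(X: ExpressionMatrix | ExpressionTensor):
    """Normalize every sample to zero mean and unit per-gene variance.

    Returns a new object of the same type. For tensors, every cell of the
    condition-mode grid is one "sample" and its gene fiber is normalized.
    """
    if isinstance(X, ExpressionMatrix):
        values = _normalize_columns(X.values, X.sample_ids)
        return ExpressionMatrix(
            gene_ids=list(X.gene_ids),
            sample_ids=list(X.sample_ids),
            values=values,
            labels=list(X.labels) if X.labels is not None else None,
        )
    if isinstance(X, ExpressionTensor):
        n = X.values.shape[0]
        flat = X.values.reshape(n, -1)
        names = [
            str(tuple(int(v) for v in np.unravel_index(j, X.mode_sizes)))
            for j in range(flat.shape[1])
        ]
        values = _normalize_columns(flat, names).reshape(X.values.shape)
        return ExpressionTensor(
            gene_ids=list(X.gene_ids),
            values=values,
            mode_labels=[list(m) for m in X.mode_labels]
            if X.mode_labels is not None
            else None,
        )
    raise TypeError(f"unsupported type: {type(X).__name__}")


def _native_gene_ids(study) -> list[str]:
    return study.gene_ids


def build_gene_universe(studies, mode: str = "union") -> GeneUniverse:
    """Construct the common gene list.

    ``mode`` is ``"union"`` (first-seen order across studies) or
    ``"reference:<k>"`` / ``"reference"`` with an explicit index, in which
    case the universe is exactly study ``k``'s gene list and genes outside
    it are dropped from the other studies.
    """
    if mode == "union":
        universe: list[str] = []
        seen: set[str] = set()
        for study in studies:
            for g in _native_gene_ids(study):
                if g not in seen:
                    seen.add(g)
                    universe.append(g)
    elif mode.startswith("reference"):
        if ":" in mode:
            ref = int(mode.split(":", 1)[1])
        else:
            ref = int(np.argmax([len(_native_gene_ids(s)) for s in studies]))
        universe = list(_native_gene_ids(studies[ref]))
    else:
        raise ValueError(f"unknown universe mode: {mode!r}")

    pos = {g: p for p, g in enumerate(universe)}
    index_maps = []
    for k, study in enumerate(studies):
        native = _native_gene_ids(study)
        idx = np.array([pos.get(g, -1) for g in native], dtype=int)
        n_hit = int((idx >= 0).sum())
        if n_hit == 0:
            logger.warning(
                "study %d shares no genes with the universe; it will be all zero",
                k,
            )
        index_maps.append(idx)
    return GeneUniverse(gene_ids=universe, index_maps=index_maps)


def _pad_values(values: np.ndarray, idx: np.ndarray, n_star: int) -> np.ndarray:
    out = np.zeros((n_star,) + values.shape[1:], dtype=float)
    keep = idx >= 0
    out[idx[keep]] = values[keep]
    return out


def align_gene_universe(studies, mode: str = "reference"):
    """Place all studies on a shared gene universe with zero-filling.

    Parameters
    ----------
    studies:
        List of :class:`ExpressionMatrix` / :class:`ExpressionTensor`.
    mode:
        ``"union"``, ``"reference"`` (largest study, the default — the
        integration described in the docs keeps the largest study's gene
        list), or ``"reference:<k>"``.

    Returns
    -------
    (GeneUniverse, list of aligned studies)
        Every aligned study has ``n_genes == universe.n_genes``; rows a
        study did not measure are exactly zero.
    """
    if not studies:
        raise ValueError("at least one study required")
    universe = build_gene_universe(studies, mode=mode)
    aligned = []
    for study, idx in zip(studies, universe.index_maps):
        padded = _pad_values(np.asarray(study.values, dtype=float), idx, universe.n_genes)
        if isinstance(study, ExpressionMatrix):
            aligned.append(
                ExpressionMatrix(
                    gene_ids=list(universe.gene_ids),
                    sample_ids=list(study.sample_ids),
                    values=padded,
                    labels=list(study.labels) if study.labels is not None else None,
                )
            )
        else:
            aligned.append(
                ExpressionTensor(
                    gene_ids=list(universe.gene_ids),
                    values=padded,
                    mode_labels=[list(m) for m in study.mode_labels]
                    if study.mode_labels is not None
                    else None,
                )
            )
    return universe, aligned
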