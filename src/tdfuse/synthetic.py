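"""Synthetic data with planted ground truth.

Every generator emulates the structure the integration method targets —
several studies that share a gene program but no samples — at a scale
where the full pipeline runs in seconds:

* :func:`generate_unmatched_studies` — K bulk studies over a common gene
  universe with disjoint sample sets and study-private class labels. A
  planted set of genes carries a shared program: in a sample of class c,
  planted gene i is shifted by ``sign_i * effect * w_c``, where the
  class weights w_c are evenly spaced on [-1, +1] (so the extreme
  classes differ by ``2 * effect`` gene-level standard deviations) and
  ``sign_i`` is a per-gene random sign. Background is i.i.d. Gaussian
  noise; a per-study scale jitters the program amplitude so studies are
  similar but not identical.
* :func:`generate_drug_tensor` — a genes x drugs x doses x replicates
  response tensor in which a subset of "effective" drugs modulate the
  planted program monotonically in dose while replicates share means.
* :func:`generate_scrna_collection` — sparse count bundles for several
  single-cell measurements, each belonging to one of a few groups, with
  a planted log-scale program whose weight differs by group; counts are
  Poisson draws thinned by Bernoulli dropout.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io_formats import ExpressionMatrix, ExpressionTensor, ScrnaBundle

__all__ = [
    "SyntheticTruth",
    "generate_unmatched_studies",
    "generate_drug_tensor",
    "generate_scrna_collection",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic instance."""

    planted_gene_ids: list[str]
    planted_signs: np.ndarray
    effect: float
    noise_sd: float
    seed: int
    study_labels: list[list[str]] | None = None
    effective_drug_ids: list[str] | None = None
    group_labels: list[str] | None = None


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(n)]


def _class_weights(n_classes: int) -> np.ndarray:
    if n_classes < 2:
        raise ValueError("need at least two classes")
    return np.linspace(-1.0, 1.0, n_classes)


def generate_unmatched_studies(
    n_genes: int = 2000,
    sizes: tuple[int, ...] = (9, 23, 8),
    classes_per_study: tuple[int, ...] | int = 2,
    n_planted: int = 100,
    effect: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[list[ExpressionMatrix], SyntheticTruth]:
    """K studies sharing only a planted gene program.

    Sample counts default to (9, 23, 8), the sizes of the three bulk
    case/control studies the method was designed around. Each study gets
    its own balanced class assignment (shuffled deterministically by
    seed); no sample, label, or scaling is shared across studies.
    """
    if n_planted > n_genes:
        raise ValueError("cannot plant more genes than the universe holds")
    if any(m < 2 for m in sizes):
        raise ValueError("every study needs at least two samples")
    rng = np.random.default_rng(seed)
    K = len(sizes)
    if isinstance(classes_per_study, int):
        classes_per_study = (classes_per_study,) * K
    gene_ids = _gene_ids(n_genes)
    planted_idx = np.sort(rng.choice(n_genes, size=n_planted, replace=False))
    signs = rng.choice([-1.0, 1.0], size=n_planted)

    studies: list[ExpressionMatrix] = []
    all_labels: list[list[str]] = []
    for k, (m, n_classes) in enumerate(zip(sizes, classes_per_study)):
        classes = np.array([c % n_classes for c in range(m)])
        rng.shuffle(classes)
        weights = _class_weights(n_classes)[classes]
        scale = rng.uniform(0.75, 1.25)  # study-private program amplitude
        values = rng.normal(0.0, noise_sd, size=(n_genes, m))
        values[planted_idx] += (
            effect * scale * np.outer(signs, weights)
        )
        labels = [f"class{c}" for c in classes]
        studies.append(
            ExpressionMatrix(
                gene_ids=list(gene_ids),
                sample_ids=[f"S{k}_{j:03d}" for j in range(m)],
                values=values,
                labels=labels,
            )
        )
        all_labels.append(labels)
    truth = SyntheticTruth(
        planted_gene_ids=[gene_ids[i] for i in planted_idx],
        planted_signs=signs,
        effect=effect,
        noise_sd=noise_sd,
        seed=seed,
        study_labels=all_labels,
    )
    return studies, truth


# EC50 bands (relative to the top tested dose = 1) from which effective
# drugs draw their potency: one saturates near the lowest dose, one
# responds mid-range, one only at the highest doses
_EC50_BANDS = ((0.08, 0.18), (0.30, 0.55), (1.10, 2.00))


def generate_drug_tensor(
    n_genes: int = 2000,
    n_drugs: int = 94,
    n_doses: int = 4,
    n_replicates: int = 3,
    n_planted: int = 100,
    effective: int | list[int] = 3,
    effect: float = 3.0,
    noise_sd: float = 1.0,
    planted_idx: np.ndarray | None = None,
    planted_signs: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[ExpressionTensor, SyntheticTruth]:
    """Drug-response tensor with a few dose-responsive drugs.

    Effective drug d adds ``effect * scale_d * sign_i * hill_d(level)``
    to the planted genes, where ``hill_d`` is a Hill-type saturation
    curve, normalized to full response at the top tested dose, with a
    drug-specific EC50 and slope. EC50s are stratified across the tested
    dose range (effective drugs cycle through early-, mid- and
    late-responding potency bands), emulating the potency spread of a
    compound panel in a dose-ranging screen; the Hill slope is drawn
    from [2, 5]. The default top-dose response of 3 gene-level standard
    deviations matches the strong signatures active compounds show at
    maximal dose. Replicates share means and differ only by noise. Pass
    ``planted_idx`` / ``planted_signs`` to reuse the program of a study
    collection (the drug-ranking workflow projects this tensor onto
    factors learned from those studies).
    """
    rng = np.random.default_rng(seed)
    gene_ids = _gene_ids(n_genes)
    if planted_idx is None:
        planted_idx = np.sort(rng.choice(n_genes, size=n_planted, replace=False))
    if planted_signs is None:
        planted_signs = rng.choice([-1.0, 1.0], size=len(planted_idx))
    if isinstance(effective, int):
        eff_idx = np.sort(rng.choice(n_drugs, size=effective, replace=False))
    else:
        eff_idx = np.asarray(sorted(effective), dtype=int)
    if eff_idx.size and (eff_idx.min() < 0 or eff_idx.max() >= n_drugs):
        raise ValueError("effective drug index out of range")
    dose_levels = np.arange(1, n_doses + 1) / n_doses
    values = rng.normal(
        0.0, noise_sd, size=(n_genes, n_drugs, n_doses, n_replicates)
    )
    ec50 = np.array(
        [rng.uniform(*_EC50_BANDS[j % len(_EC50_BANDS)]) for j in range(eff_idx.size)]
    )
    rng.shuffle(ec50)
    drug_scale = rng.uniform(0.75, 1.25, size=eff_idx.size)
    hill_slope = rng.uniform(2.0, 5.0, size=eff_idx.size)
    for d, scale, e, h in zip(eff_idx, drug_scale, ec50, hill_slope):
        curve = dose_levels**h / (dose_levels**h + e**h)
        curve = curve / curve[-1]  # full response at the top tested dose
        # replicates share the mean response: add the same dose profile
        # to every replicate slice
        response = effect * scale * np.outer(planted_signs, curve)
        values[planted_idx, d] += response[:, :, None]
    drug_ids = [f"drug{d:03d}" for d in range(n_drugs)]
    tensor = ExpressionTensor(
        gene_ids=list(gene_ids),
        values=values,
        mode_labels=[
            drug_ids,
            [f"dose{j}" for j in range(n_doses)],
            [f"rep{j}" for j in range(n_replicates)],
        ],
    )
    truth = SyntheticTruth(
        planted_gene_ids=[gene_ids[i] for i in planted_idx],
        planted_signs=planted_signs,
        effect=effect,
        noise_sd=noise_sd,
        seed=seed,
        effective_drug_ids=[drug_ids[d] for d in eff_idx],
    )
    return tensor, truth


# disease status alternates along the cycle so collections of even size
# stay case/control balanced (an unbalanced design leaks the disease
# contrast into the baseline factor of the joint decomposition)
_DEFAULT_GROUPS = ("ctl_hip", "ad_hip", "ctl_ctx", "ad_ctx")


def generate_scrna_collection(
    n_genes: int = 2000,
    n_measurements: int = 6,
    cells_per_measurement: int = 500,
    n_groups: int = 4,
    n_planted: int = 100,
    effect: float = 1.0,
    dropout: float = 0.5,
    donor_sd: float = 0.05,
    seed: int = 0,
) -> tuple[list[ScrnaBundle], SyntheticTruth]:
    """Sparse single-cell bundles with a disease-linked planted program.

    Planted genes form up/down pairs with equal baseline rates; in a
    disease measurement the up member's Poisson rate is multiplied by
    ``exp(effect)`` and the down member's by ``exp(-effect)`` (reversed
    for controls). The pairing makes every symmetric functional of the
    expression profile — total counts, concentration, library size —
    identical in distribution across groups, so the only systematic
    group difference is the program direction itself. Each measurement
    additionally gets per-gene donor variability (log-normal,
    ``donor_sd``), and counts are thinned entrywise by
    Bernoulli(1 - dropout). The default effect of 1.0 puts two log
    units (~7.4-fold) between disease and control on planted genes, the
    magnitude of a strong disease signature. Measurements cycle through
    the groups with alternating disease status (see ``_DEFAULT_GROUPS``).
    """
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    if n_planted % 2:
        raise ValueError("n_planted must be even (up/down pairs)")
    rng = np.random.default_rng(seed)
    gene_ids = _gene_ids(n_genes)
    planted_idx = np.sort(rng.choice(n_genes, size=n_planted, replace=False))
    half = n_planted // 2
    signs = np.concatenate([np.ones(half), -np.ones(half)])
    base_rate = np.exp(rng.normal(-0.5, 1.0, size=n_genes))
    pair_rates = np.exp(rng.normal(-0.5, 1.0, size=half))
    base_rate[planted_idx] = np.concatenate([pair_rates, pair_rates])
    # disease weight per group: +1 for case groups, -1 for control groups
    weights = np.array([1.0 if g % 2 else -1.0 for g in range(n_groups)])
    group_names = (
        list(_DEFAULT_GROUPS)
        if n_groups == len(_DEFAULT_GROUPS)
        else [f"grp{g}" for g in range(n_groups)]
    )
    bundles: list[ScrnaBundle] = []
    group_labels: list[str] = []
    for c in range(n_measurements):
        g = c % n_groups
        donor = base_rate * (
            np.exp(rng.normal(0.0, donor_sd, size=n_genes)) if donor_sd > 0 else 1.0
        )
        rate = donor.copy()
        rate[planted_idx] = donor[planted_idx] * np.exp(effect * weights[g] * signs)
        counts = rng.poisson(rate[:, None], size=(n_genes, cells_per_measurement))
        if dropout > 0:
            counts = rng.binomial(counts, 1.0 - dropout)
        bundles.append(
            ScrnaBundle(
                gene_ids=list(gene_ids),
                cell_ids=[f"M{c}_C{j:04d}" for j in range(cells_per_measurement)],
                counts=sp.csc_matrix(counts),
                measurement_id=c,
                group=group_names[g],
            )
        )
        group_labels.append(group_names[g])
    truth = SyntheticTruth(
        planted_gene_ids=[gene_ids[i] for i in planted_idx],
        planted_signs=signs,
        effect=effect,
        noise_sd=0.0,
        seed=seed,
        group_labels=group_labels,
    )
    return bundles, truth
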