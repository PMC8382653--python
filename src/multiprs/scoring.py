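"""Weight/genotype harmonisation, trait-group wPRS computation, ancestry PCA.

The weighted PRS for individual i and trait group k is

    raw_ik    = sum_j X_ij * beta_j                (over group-k variants)
    scaled_ik = raw_ik / sum_j beta_j * m_k

where X_ij is the effect-allele dosage in [0, 2], beta_j the per-allele
effect size and m_k the number of variant records scored in the group. The
scaling gives every trait group an equivalent weight at an equivalent number
of loci: a constant dosage c across a group maps to a score of exactly c*m_k
regardless of the group's effect-size scale.

The divisor is only meaningful with all beta positive, so alignment first
flips any negative-weight record to its other allele (beta -> -beta, the
dosage read as 2 - dosage), the standard trait-increasing-allele convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .types import (
    EmptyTraitGroupError,
    GenotypeMatrix,
    ProjectionOverlapError,
    TraitGroupScores,
    VariantWeight,
    WeightSet,
)


@dataclass
class AlignmentResult:
    """Harmonised weights and dosages plus the per-variant exclusion report."""

    weights: WeightSet
    genotypes: GenotypeMatrix
    exclusions: pd.DataFrame  # columns: variant_id, trait_group, reason
    n_flipped: int
    nominal_counts: dict[str, int]  # scoring-file m_k before exclusions

    @property
    def aligned_counts(self) -> dict[str, int]:
        """m_k on the data actually scored (exact [0, 2 m_k] range holds here)."""
        return self.weights.group_counts


def align_weights(weights: WeightSet, genotypes: GenotypeMatrix) -> AlignmentResult:
    """Harmonise a weight set against a genotype matrix.

    Retained weights all have beta > 0, achieved by swapping effect/other
    allele and negating beta where needed; the aligned genotype matrix
    carries one oriented dosage column per matched variant, and the scorer
    re-orients per weight record through the allele annotation (the same
    variant may sit in two trait groups with opposite trait-increasing
    alleles). Variants are matched by variant_id first, then by chrom:pos
    with order-insensitive allele-pair agreement; strand-ambiguous (A/T,
    C/G) variants only ever match by id. Unmatched or allele-mismatched
    weights are excluded with reasons; a trait group losing all variants is
    an error because the scaling rule is undefined at m_k = 0.
    """
    geno_by_id = {vid: j for j, vid in enumerate(genotypes.variant_ids)}
    geno_by_pos: dict[tuple[str, int], int] = {}
    if genotypes.chrom is not None and genotypes.pos is not None:
        for j, (c, p) in enumerate(zip(genotypes.chrom, genotypes.pos)):
            geno_by_pos.setdefault((str(c), int(p)), j)

    def locate(w: VariantWeight):
        j = geno_by_id.get(w.variant_id)
        if j is None and not w.is_strand_ambiguous:
            j = geno_by_pos.get((w.chrom, w.pos))
        return j

    kept: list[VariantWeight] = []
    kept_col: list[int] = []
    excluded: list[tuple[str, str, str]] = []
    n_flipped = 0
    for w in weights.weights:
        j = locate(w)
        if j is None:
            excluded.append((w.variant_id, w.trait_group, "not in genotypes"))
            continue
        if {genotypes.effect_allele[j], genotypes.other_allele[j]} != {
            w.effect_allele,
            w.other_allele,
        }:
            excluded.append((w.variant_id, w.trait_group, "allele mismatch"))
            continue
        if w.beta == 0:
            excluded.append((w.variant_id, w.trait_group, "zero effect weight"))
            continue
        if w.beta < 0:
            w = replace(
                w,
                effect_allele=w.other_allele,
                other_allele=w.effect_allele,
                beta=-w.beta,
            )
            n_flipped += 1
        kept.append(w)
        kept_col.append(j)

    # one column per distinct variant, oriented to the first retained record
    cols, vids, eff, oth, chroms, poss = [], [], [], [], [], []
    first_orientation: dict[str, str] = {}
    for w, j in zip(kept, kept_col):
        if w.variant_id in first_orientation:
            continue
        first_orientation[w.variant_id] = w.effect_allele
        col = genotypes.dosage[:, j]
        if genotypes.effect_allele[j] != w.effect_allele:
            col = 2.0 - col
        cols.append(col)
        vids.append(w.variant_id)
        eff.append(w.effect_allele)
        oth.append(w.other_allele)
        chroms.append(w.chrom)
        poss.append(w.pos)
    aligned_geno = GenotypeMatrix(
        individual_ids=list(genotypes.individual_ids),
        variant_ids=vids,
        dosage=np.column_stack(cols) if cols else np.empty((genotypes.n_individuals, 0)),
        effect_allele=eff,
        other_allele=oth,
        chrom=chroms,
        pos=poss,
    )

    aligned_groups = tuple(g for g in weights.groups if any(w.trait_group == g for w in kept))
    lost = [g for g in weights.groups if g not in aligned_groups]
    if lost:
        raise EmptyTraitGroupError(f"trait group(s) lost all variants during alignment: {lost}")
    report = pd.DataFrame(excluded, columns=["variant_id", "trait_group", "reason"])
    return AlignmentResult(
        weights=WeightSet(weights=kept, groups=aligned_groups),
        genotypes=aligned_geno,
        exclusions=report,
        n_flipped=n_flipped,
        nominal_counts=weights.group_counts,
    )


def compute_wprs(genotypes: GenotypeMatrix, weights: WeightSet) -> TraitGroupScores:
    """Compute raw and scaled wPRS per trait group.

    Requires aligned weights (all beta > 0). Missing dosages are mean-imputed
    per variant on the scored cohort before summation, keeping the sum-beta
    denominator constant across individuals.
    """
    if any(w.beta <= 0 for w in weights.weights):
        raise ValueError("weights must be aligned (all beta > 0) before scoring")
    idx = {vid: j for j, vid in enumerate(genotypes.variant_ids)}

    filled = genotypes.dosage.copy()
    if filled.size:
        col_mean = np.nanmean(filled, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(filled))
        filled[nan_r, nan_c] = col_mean[nan_c]

    raw, scaled = {}, {}
    m_k: dict[str, int] = {}
    sum_beta: dict[str, float] = {}
    for g in weights.groups:
        gw = weights.group_weights(g)
        cols, betas = [], []
        for w in gw:
            j = idx[w.variant_id]
            col = filled[:, j]
            if genotypes.effect_allele[j] != w.effect_allele:
                col = 2.0 - col
            cols.append(col)
            betas.append(w.beta)
        betas = np.asarray(betas)
        sb = float(betas.sum())
        assert sb > 0, f"sum of effect sizes non-positive for group {g}"
        r = np.column_stack(cols) @ betas
        raw[f"raw_{g}"] = r
        scaled[f"wPRS_{g}"] = r / sb * len(gw)
        m_k[g] = len(gw)
        sum_beta[g] = sb

    return TraitGroupScores(
        individual_ids=list(genotypes.individual_ids),
        groups=weights.groups,
        raw=pd.DataFrame(raw),
        scaled=pd.DataFrame(scaled),
        m_k=m_k,
        sum_beta=sum_beta,
    )


# ---------------------------------------------------------------------------
# Ancestry principal components
# ---------------------------------------------------------------------------


@dataclass
class PCModel:
    """Genotype PCA fit on a reference cohort, reusable for projection.

    Dosages are standardised per variant by (x - mean) / sqrt(2 p (1 - p))
    with p = mean/2 (binomial allele-frequency scaling); missing values
    become 0 after standardisation. New cohorts are projected with the
    MODEL's means and scales, never their own.
    """

    variant_ids: list[str]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray      # variants x components, column-orthonormal
    eigenvalues: np.ndarray
    excluded: list[str]       # zero-variance variants dropped at fit time
    n_components: int

    def component_columns(self) -> list[str]:
        return [f"pc{i + 1}" for i in range(self.n_components)]


def fit_pc_model(
    reference: GenotypeMatrix, n_components: int = 10
) -> tuple[PCModel, pd.DataFrame]:
    """Fit a PCA model of genotype variation; returns (model, reference scores).

    Each component's sign is fixed so its largest-|loading| entry is
    positive, making runs reproducible. Monomorphic variants are excluded
    and listed on the model.
    """
    if reference.n_individuals < 2:
        raise ValueError("need at least 2 individuals to fit PCs")
    X = reference.dosage
    means = np.nanmean(X, axis=0)
    p = means / 2.0
    with np.errstate(invalid="ignore"):
        scales = np.sqrt(2.0 * p * (1.0 - p))
    ok = np.nan_to_num(scales) > 0
    excluded = [v for v, keep in zip(reference.variant_ids, ok) if not keep]
    if not ok.any():
        raise ValueError("all variants monomorphic; PCA undefined")
    Z = (X[:, ok] - means[ok]) / scales[ok]
    Z = np.where(np.isnan(Z), 0.0, Z)
    k = min(n_components, min(Z.shape))
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    for c in range(k):  # deterministic sign convention
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    model = PCModel(
        variant_ids=[v for v, keep in zip(reference.variant_ids, ok) if keep],
        means=means[ok],
        scales=scales[ok],
        loadings=Vt.T,
        eigenvalues=s**2 / (Z.shape[0] - 1),
        excluded=excluded,
        n_components=k,
    )
    scores = pd.DataFrame(U * s, columns=model.component_columns())
    scores.insert(0, "individual_id", reference.individual_ids)
    return model, scores


def project_pcs(
    model: PCModel, genotypes: GenotypeMatrix, min_overlap: float = 0.5
) -> pd.DataFrame:
    """Project a cohort onto a fitted PC model.

    Standardisation uses the model's per-variant means and scales; model
    variants absent from the cohort contribute 0. Fails if fewer than
    ``min_overlap`` of the model's variants are present.
    """
    idx = {vid: j for j, vid in enumerate(genotypes.variant_ids)}
    present = [vid in idx for vid in model.variant_ids]
    overlap = float(np.mean(present)) if model.variant_ids else 0.0
    if overlap < min_overlap:
        raise ProjectionOverlapError(overlap, min_overlap)

    cols = np.array([idx.get(vid, -1) for vid in model.variant_ids])
    have = cols >= 0
    Z = np.zeros((genotypes.n_individuals, len(model.variant_ids)))
    X = genotypes.dosage[:, cols[have]]
    Zs = (X - model.means[have]) / model.scales[have]
    Z[:, have] = np.where(np.isnan(Zs), 0.0, Zs)
    scores = pd.DataFrame(Z @ model.loadings, columns=model.component_columns())
    scores.insert(0, "individual_id", genotypes.individual_ids)
    return scores
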