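"""Readers and writers for scoring files, genotypes and cohort tables.

Formats are deliberately plain: tab-separated text throughout, VCF v4.x for
genotypes (GT hard calls or DS dosages). Scoring files accept PGS-Catalog
column names (rsID, effect_allele, effect_weight) as aliases, plus the
mandatory trait_group column that drives the ten-group design.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ARM_COLUMNS,
    COHORT_COVARIATES,
    CohortTableError,
    DuplicateWeightError,
    GenotypeMatrix,
    ScoringFileError,
    TrialCohort,
    UnknownTraitGroupError,
    VariantWeight,
    WeightSet,
)

logger = logging.getLogger("multiprs")

_SCORING_ALIASES = {
    "rsid": "variant_id",
    "rsID": "variant_id",
    "chr_name": "chrom",
    "chr_position": "pos",
}
_SCORING_REQUIRED = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "effect_weight",
    "trait_group",
)


def read_scoring_file(path: str | Path, group_vocabulary: list[str] | None = None) -> WeightSet:
    """Read a tab-separated variant-weight file into a :class:`WeightSet`.

    Rows whose trait_group is not in ``group_vocabulary`` are rejected with
    the offending labels named; duplicate (variant_id, trait_group) pairs are
    rejected. Groups in the returned set follow the vocabulary's order,
    restricted to groups actually present. ``group_vocabulary=None`` accepts
    the file's own groups, ordered by first appearance.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df = df.rename(columns=_SCORING_ALIASES)
    missing = [c for c in _SCORING_REQUIRED if c not in df.columns]
    if missing:
        raise ScoringFileError(f"scoring file missing mandatory column(s): {missing}")
    if df.empty:
        return WeightSet(weights=[], groups=())

    if group_vocabulary is None:
        group_vocabulary = list(dict.fromkeys(df["trait_group"]))
    unknown = set(df["trait_group"]) - set(group_vocabulary)
    if unknown:
        raise UnknownTraitGroupError(unknown)
    dup = df.duplicated(subset=["variant_id", "trait_group"])
    if dup.any():
        pairs = df.loc[dup, ["variant_id", "trait_group"]].itertuples(index=False)
        raise DuplicateWeightError(
            "duplicate (variant_id, trait_group) rows: "
            + ", ".join(f"({v}, {g})" for v, g in pairs)
        )
    try:
        betas = df["effect_weight"].astype(float)
    except ValueError as exc:
        raise ScoringFileError(f"non-numeric effect_weight: {exc}") from exc
    try:
        positions = df["pos"].astype(int)
    except ValueError as exc:
        raise ScoringFileError(f"non-integer pos: {exc}") from exc

    weights = [
        VariantWeight(
            variant_id=row.variant_id,
            chrom=str(row.chrom),
            pos=int(p),
            effect_allele=row.effect_allele,
            other_allele=row.other_allele,
            beta=float(b),
            trait_group=row.trait_group,
        )
        for row, b, p in zip(df.itertuples(index=False), betas, positions)
    ]
    present = {w.trait_group for w in weights}
    groups = tuple(g for g in group_vocabulary if g in present)
    return WeightSet(weights=weights, groups=groups)


def write_scoring_file(weights: WeightSet, path: str | Path) -> None:
    weights.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


def _weight_index(weights: WeightSet):
    """Lookup tables: by variant_id, and by (chrom, pos) for the fallback."""
    by_id: dict[str, VariantWeight] = {}
    by_pos: dict[tuple[str, int], VariantWeight] = {}
    for w in weights.weights:
        by_id.setdefault(w.variant_id, w)
        by_pos.setdefault((w.chrom, w.pos), w)
    return by_id, by_pos


def read_genotypes(
    path: str | Path,
    weights: WeightSet,
    drop_ambiguous: bool = False,
) -> GenotypeMatrix:
    """Read genotypes as counts of the scoring file's effect alleles.

    Accepts a VCF (GT or DS) or a TSV dosage matrix (individual rows, variant
    columns; dosages already count the scoring file's effect allele).
    Variants absent from ``weights`` are ignored. VCF records are matched to
    weights by variant_id first, then by chrom:pos with order-insensitive
    allele-pair agreement; strand-ambiguous variants (A/T, C/G) match by id
    only and are excluded entirely under ``drop_ambiguous``. Irreconcilable
    REF/ALT pairs are excluded and logged, never fatal.
    """
    path = Path(path)
    if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        return _read_vcf(path, weights, drop_ambiguous)
    return _read_dosage_tsv(path, weights, drop_ambiguous)


def _read_dosage_tsv(path: Path, weights: WeightSet, drop_ambiguous: bool) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    by_id, _ = _weight_index(weights)
    keep, eff, oth, chroms, poss = [], [], [], [], []
    for vid in df.columns:
        w = by_id.get(vid)
        if w is None:
            logger.info("dosage column %s not in weights; ignored", vid)
            continue
        if drop_ambiguous and w.is_strand_ambiguous:
            logger.info("variant %s strand-ambiguous; dropped", vid)
            continue
        keep.append(vid)
        eff.append(w.effect_allele)
        oth.append(w.other_allele)
        chroms.append(w.chrom)
        poss.append(w.pos)
    sub = df[keep].astype(float)
    return GenotypeMatrix(
        individual_ids=[str(i) for i in df.index],
        variant_ids=keep,
        dosage=sub.to_numpy(),
        effect_allele=eff,
        other_allele=oth,
        chrom=chroms,
        pos=poss,
    )


def _read_vcf(path: Path, weights: WeightSet, drop_ambiguous: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF

    by_id, by_pos = _weight_index(weights)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    vids, eff, oth, chroms, poss = [], [], [], [], []
    seen: set[str] = set()
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("multi-allelic record %s skipped", rec.ID or rec.POS)
            continue
        ref, alt = rec.REF, rec.ALT[0]
        w = by_id.get(rec.ID) if rec.ID else None
        matched_by = "variant_id"
        if w is None:
            w = by_pos.get((str(rec.CHROM), rec.POS))
            matched_by = "position"
            if w is not None and w.is_strand_ambiguous:
                # ambiguous variants may never match positionally
                logger.info("variant at %s:%s ambiguous; id match required", rec.CHROM, rec.POS)
                continue
        if w is None:
            continue
        if drop_ambiguous and w.is_strand_ambiguous:
            logger.info("variant %s strand-ambiguous; dropped", w.variant_id)
            continue
        if {ref, alt} != {w.effect_allele, w.other_allele}:
            logger.warning(
                "variant %s: REF/ALT %s/%s irreconcilable with %s/%s; excluded",
                w.variant_id, ref, alt, w.effect_allele, w.other_allele,
            )
            continue
        if w.variant_id in seen:
            continue
        seen.add(w.variant_id)
        alt_dose = _record_alt_dosage(rec, len(samples))
        dose = alt_dose if w.effect_allele == alt else 2.0 - alt_dose
        cols.append(dose)
        vids.append(w.variant_id)
        eff.append(w.effect_allele)
        oth.append(w.other_allele)
        chroms.append(str(rec.CHROM))
        poss.append(rec.POS)
        logger.info("variant %s matched by %s", w.variant_id, matched_by)
    dosage = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(
        individual_ids=samples,
        variant_ids=vids,
        dosage=dosage,
        effect_allele=eff,
        other_allele=oth,
        chrom=chroms,
        pos=poss,
    )


def _record_alt_dosage(rec, n_samples: int) -> np.ndarray:
    """Per-sample ALT-allele dosage from DS if present, else from GT."""
    try:
        ds = rec.format("DS")
    except KeyError:
        ds = None
    if ds is not None:
        out = np.asarray(ds, dtype=float).reshape(n_samples)
        out[out < 0] = np.nan
        return out
    gts = rec.genotype.array()  # (n, ploidy+1); -1 encodes missing
    alleles = gts[:, :2].astype(float)
    missing = (alleles < 0).any(axis=1)
    out = alleles.sum(axis=1)
    out[missing] = np.nan
    return out


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    genotypes.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------


def read_cohort_table(path: str | Path, outcomes: list[str] | None = None) -> TrialCohort:
    """Read a TSV phenotype table into a typed :class:`TrialCohort`.

    Outcome columns are any non-reserved columns (survival outcomes are
    declared by ``<name>_time`` / ``<name>_event`` pairs) unless ``outcomes``
    is given explicitly. Rows failing invariants are rejected with their row
    numbers. Cohorts lacking arm columns load fine; treatment analysis is
    disabled downstream with a logged warning.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_COVARIATES if c not in df.columns]
    if missing:
        raise CohortTableError(f"missing mandatory column(s): {missing}")
    df["individual_id"] = df["individual_id"].astype(str)

    reserved = set(COHORT_COVARIATES) | set(ARM_COLUMNS)
    pc_cols = [c for c in df.columns if c.startswith("pc") and c[2:].isdigit()]
    reserved |= set(pc_cols)
    survival = sorted(
        c[: -len("_time")]
        for c in df.columns
        if c.endswith("_time") and c[: -len("_time")] + "_event" in df.columns
    )
    suffixed = {o + s for o in survival for s in ("_time", "_event")}
    if outcomes is None:
        outcomes = [c for c in df.columns if c not in reserved and c not in suffixed]
    else:
        unknown = [o for o in outcomes if o not in df.columns]
        if unknown:
            raise CohortTableError(f"unknown outcome column(s): {unknown}")
    survival = [s for s in survival if s in outcomes]

    if not all(c in df.columns for c in ARM_COLUMNS):
        logger.warning("cohort table lacks arm columns %s; treatment analysis disabled", ARM_COLUMNS)
    return TrialCohort(table=df, outcomes=list(outcomes), survival_outcomes=survival)


def write_cohort_table(cohort: TrialCohort, path: str | Path) -> None:
    cohort.table.to_csv(path, sep="\t", index=False)
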