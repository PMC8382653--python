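"""Core domain containers shared across the pipeline.

The containers are deliberately thin: pandas/numpy hold the data, the
dataclasses pin down the contracts (allele conventions, group vocabularies,
alignment state) that the numerical code relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: The ten trait groups of the default scoring-variant vocabulary.
DEFAULT_GROUPS: tuple[str, ...] = (
    "diabetes",
    "obesity",
    "blood_pressure",
    "albuminuria",
    "gfr",
    "biomarkers",
    "lipids",
    "stroke",
    "cvd",
    "low_birthweight",
)

#: Predictor order of the joint risk model: ten trait-group wPRS, the first
#: ancestry principal component, sex, age at diabetes onset, diabetes duration.
def predictor_names(groups: tuple[str, ...] = DEFAULT_GROUPS) -> list[str]:
    return [f"wPRS_{g}" for g in groups] + ["pc1", "sex", "age_at_onset", "diabetes_duration"]


class ScoringFileError(ValueError):
    """Malformed scoring file (missing columns, bad alleles, bad groups...)."""


class UnknownTraitGroupError(ScoringFileError):
    def __init__(self, labels):
        self.labels = sorted(set(labels))
        super().__init__(f"unknown trait_group labels: {', '.join(self.labels)}")


class DuplicateWeightError(ScoringFileError):
    pass


class CohortTableError(ValueError):
    """Cohort table rows violating invariants, with offending row numbers."""


class EmptyTraitGroupError(ValueError):
    """A trait group lost all variants during alignment; scaling is undefined."""


class ProjectionOverlapError(ValueError):
    """Too few of a PC model's variants are present in the target cohort."""

    def __init__(self, overlap: float, required: float):
        self.overlap = overlap
        self.required = required
        super().__init__(
            f"only {overlap:.1%} of PC-model variants present; {required:.1%} required"
        )


class PrevalenceCalibrationError(ValueError):
    """Target outcome prevalence unreachable for the given linear predictor."""


class PerfectSeparationError(ValueError):
    """Logistic fit aborted: a predictor separates the outcome perfectly."""


@dataclass(frozen=True)
class VariantWeight:
    """One scoring-file record: an effect allele and its per-allele weight.

    ``beta`` is on the source GWAS scale (log-odds or per-unit effect per
    effect allele). The same variant may legitimately appear in two trait
    groups with different weights.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    trait_group: str

    def __post_init__(self):
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ScoringFileError(
                f"{self.variant_id}: alleles must be single bases A/C/G/T, got "
                f"{self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise ScoringFileError(f"{self.variant_id}: effect and other allele identical")
        if self.pos < 1:
            raise ScoringFileError(f"{self.variant_id}: position must be 1-based positive")

    @property
    def is_strand_ambiguous(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class WeightSet:
    """An ordered collection of variant weights grouped into trait groups."""

    weights: list[VariantWeight]
    groups: tuple[str, ...]  # ordered vocabulary of retained groups

    def __post_init__(self):
        seen = set()
        for w in self.weights:
            key = (w.variant_id, w.trait_group)
            if key in seen:
                raise DuplicateWeightError(f"duplicate (variant_id, trait_group): {key}")
            seen.add(key)
        present = {w.trait_group for w in self.weights}
        unknown = present - set(self.groups)
        if unknown:
            raise UnknownTraitGroupError(unknown)

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def group_counts(self) -> dict[str, int]:
        """Variant records per retained group (the m_k of the scaling rule)."""
        counts = {g: 0 for g in self.groups}
        for w in self.weights:
            counts[w.trait_group] += 1
        return {g: c for g, c in counts.items() if c > 0}

    def group_weights(self, group: str) -> list[VariantWeight]:
        return [w for w in self.weights if w.trait_group == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [w.variant_id for w in self.weights],
                "chrom": [w.chrom for w in self.weights],
                "pos": [w.pos for w in self.weights],
                "effect_allele": [w.effect_allele for w in self.weights],
                "other_allele": [w.other_allele for w in self.weights],
                "effect_weight": [w.beta for w in self.weights],
                "trait_group": [w.trait_group for w in self.weights],
            }
        )


@dataclass
class GenotypeMatrix:
    """Effect-allele dosages, individuals x variants, NaN marking missingness.

    ``effect_allele[j]`` is the allele that column ``j`` counts; dosages are
    in [0, 2] (hard calls 0/1/2 or imputed real dosages).
    """

    individual_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray  # float, shape (n_individuals, n_variants), NaN = missing
    effect_allele: list[str]
    other_allele: list[str]
    chrom: list[str] | None = None
    pos: list[int] | None = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.individual_ids) or m != len(self.variant_ids):
            raise ValueError("dosage shape does not match id lists")
        if len(set(self.variant_ids)) != m:
            raise ValueError("variant_ids must be unique")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosage < 0) | (self.dosage > 2))
        if bad:
            raise ValueError(f"{int(bad)} dosages outside [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self.variant_ids.index(variant_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosage, index=pd.Index(self.individual_ids, name="individual_id"),
            columns=self.variant_ids,
        )


#: Reserved cohort-table columns that are never treated as outcomes.
COHORT_COVARIATES = ("individual_id", "sex", "age_at_onset", "diabetes_duration")
ARM_COLUMNS = ("arm_bp", "arm_glucose")


@dataclass
class TrialCohort:
    """Phenotype table of a 2x2 factorial trial cohort.

    ``table`` columns: individual_id, sex (0 female / 1 male), age_at_onset,
    diabetes_duration, pc1 (.. pcK), arm_bp, arm_glucose (absent when the
    cohort carries no trial arms), one binary column per outcome, and for
    time-to-event outcomes ``<outcome>_time`` / ``<outcome>_event`` columns.
    """

    table: pd.DataFrame
    outcomes: list[str]
    survival_outcomes: list[str] = field(default_factory=list)

    def __post_init__(self):
        t = self.table
        for col in COHORT_COVARIATES:
            if col not in t.columns:
                raise CohortTableError(f"missing mandatory column: {col}")
        bad = t.index[t["age_at_onset"] <= 0].tolist()
        if bad:
            raise CohortTableError(f"age_at_onset must be > 0; offending rows: {bad}")
        bad = t.index[t["diabetes_duration"] < 0].tolist()
        if bad:
            raise CohortTableError(f"diabetes_duration must be >= 0; offending rows: {bad}")
        for o in self.outcomes:
            if o not in t.columns:
                raise CohortTableError(f"outcome column missing: {o}")
        for o in self.survival_outcomes:
            for suffix in ("_time", "_event"):
                if o + suffix not in t.columns:
                    raise CohortTableError(f"survival column missing: {o}{suffix}")
            tt = t[o + "_time"]
            if (tt < 0).any():
                rows = t.index[tt < 0].tolist()
                raise CohortTableError(f"negative event_time for {o}; rows: {rows}")

    @property
    def has_arms(self) -> bool:
        return all(c in self.table.columns for c in ARM_COLUMNS)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def individual_ids(self) -> list[str]:
        return self.table["individual_id"].tolist()

    def outcome_vector(self, outcome: str) -> np.ndarray:
        return self.table[outcome].to_numpy(dtype=int)

    def survival_arrays(self, outcome: str) -> tuple[np.ndarray, np.ndarray]:
        """(event_time, event_indicator) for a time-to-event outcome."""
        if outcome not in self.survival_outcomes:
            raise KeyError(f"{outcome} is not a time-to-event outcome")
        return (
            self.table[outcome + "_time"].to_numpy(dtype=float),
            self.table[outcome + "_event"].to_numpy(dtype=int),
        )


@dataclass
class TraitGroupScores:
    """Per-individual raw and scaled wPRS for each trait group.

    raw_k(i)    = sum_j X_ij * beta_j over the group's variants
    scaled_k(i) = raw_k(i) / sum_j beta_j * m_k

    with m_k the number of variant records actually scored in group k. With
    all beta > 0 and dosages in [0, 2] the scaled score lives in [0, 2 m_k].
    """

    individual_ids: list[str]
    groups: tuple[str, ...]
    raw: pd.DataFrame       # columns raw_<group>
    scaled: pd.DataFrame    # columns wPRS_<group>
    m_k: dict[str, int]
    sum_beta: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        out = pd.concat([self.scaled, self.raw], axis=1)
        out.insert(0, "individual_id", self.individual_ids)
        return out.reset_index(drop=True)
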