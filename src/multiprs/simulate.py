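"""Synthetic trial-cohort generator with known ground truth.

Emulates the data structure of a large type 2 diabetes outcome trial with a
2x2 factorial treatment design (intensive vs standard glucose control x
active vs placebo blood-pressure lowering), ~4.5 years of in-trial follow-up
plus ~5 years of post-trial extension:

* a scoring file of 598 variants in ten trait groups with GWAS-style
  half-normal effect sizes,
* genotypes with two-subpopulation ancestry structure (Balding-Nichols
  allele-frequency divergence, Hardy-Weinberg within subpopulation), plus a
  separate panel of null reference variants for ancestry PCA,
* binary outcomes drawn from a logistic model on the ten scaled wPRS, PC1,
  sex, age at diabetes onset and diabetes duration, with the intercept
  calibrated by bisection to a target prevalence,
* time-to-event outcomes drawn from an exponential model with per-individual
  rate proportional to exp(gamma'z), multiplied by arm- and risk-stratum-
  specific hazard ratios, under administrative (and optionally random
  exponential) censoring.

True coefficients are specified per standard deviation of each predictor
("std_effects") and resolved to natural units against the cohort being
simulated; the resolved coefficients, intercepts/baseline rates, stratum
boundaries and subpopulation labels are recorded in :class:`GroundTruth` so
every downstream estimate can be checked against an oracle. Everything is
deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import rankdata

from . import scoring
from .types import (
    DEFAULT_GROUPS,
    GenotypeMatrix,
    PrevalenceCalibrationError,
    TraitGroupScores,
    TrialCohort,
    VariantWeight,
    WeightSet,
    predictor_names,
)

# per-group variant counts summing to 598, in the ten-group vocabulary
DEFAULT_GROUP_SPEC: tuple[tuple[str, int], ...] = (
    ("diabetes", 129),
    ("obesity", 96),
    ("blood_pressure", 107),
    ("albuminuria", 28),
    ("gfr", 62),
    ("biomarkers", 53),
    ("lipids", 65),
    ("stroke", 15),
    ("cvd", 29),
    ("low_birthweight", 14),
)

_BASES = np.array(list("ACGT"))

StratumHRs = tuple[float, float, float]  # hazard ratios in (low, medium, high) thirds


@dataclass(frozen=True)
class OutcomeSpec:
    """Target prevalence and true per-SD effects for one outcome.

    ``std_effects`` maps predictor names (the ten group labels plus ``pc1``,
    ``sex``, ``age_at_onset``, ``diabetes_duration``) to effects per SD of
    that predictor; unlisted predictors get 0. ``mechanism`` is ``binary``
    (pure logistic draw) or ``survival`` (exponential time-to-event whose
    in-trial event defines the binary indicator).
    """

    name: str
    prevalence: float
    std_effects: tuple[tuple[str, float], ...] = ()
    mechanism: str = "binary"

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValueError(f"{self.name}: prevalence must be in (0, 1)")
        if self.mechanism not in ("binary", "survival"):
            raise ValueError(f"{self.name}: unknown mechanism {self.mechanism}")

    def effects(self) -> dict[str, float]:
        return dict(self.std_effects)


def _profile(main: Mapping[str, float], sigma: float) -> tuple[tuple[str, float], ...]:
    """Scale a relative effect profile so the linear predictor SD is sigma."""
    items = tuple(main.items())
    norm = np.sqrt(sum(v * v for _, v in items))
    return tuple((k, v / norm * sigma) for k, v in items)


# Relative effect shapes: each outcome leans on its matching trait group(s),
# with clinical covariates contributing as in the study cohorts. The sigma
# values set oracle discrimination in the published AUC range (~0.64-0.72).
_BASE = {
    "diabetes": 0.3, "obesity": 0.2, "blood_pressure": 0.3, "albuminuria": 0.2,
    "gfr": 0.2, "biomarkers": 0.2, "lipids": 0.25, "stroke": 0.15, "cvd": 0.25,
    "low_birthweight": 0.1, "pc1": 0.25, "sex": 0.35, "age_at_onset": 0.35,
    "diabetes_duration": 0.5,
}


def _outcome(name, prev, sigma, emphasis: Mapping[str, float] | None = None,
             mechanism="binary") -> OutcomeSpec:
    prof = dict(_BASE)
    for k, v in (emphasis or {}).items():
        prof[k] = v
    return OutcomeSpec(name, prev, _profile(prof, sigma), mechanism)


def default_outcomes() -> tuple[OutcomeSpec, ...]:
    return (
        _outcome("combined_micro_macro", 0.40, 0.62),
        _outcome("major_micro", 0.13, 0.62, {"albuminuria": 0.5, "gfr": 0.5}),
        _outcome("major_macro", 0.21, 0.66, {"cvd": 0.6, "stroke": 0.35}),
        _outcome("stroke", 0.04, 0.58, {"stroke": 0.6, "blood_pressure": 0.45}),
        _outcome("myocardial_infarction", 0.07, 0.62, {"cvd": 0.6, "lipids": 0.45}),
        _outcome("heart_failure", 0.06, 0.66, {"cvd": 0.5}),
        _outcome("macroalbuminuria", 0.04, 0.55, {"albuminuria": 0.7}),
        _outcome("low_egfr", 0.41, 0.51, {"gfr": 0.7}),
        _outcome("nephropathy", 0.05, 0.51, {"albuminuria": 0.5, "gfr": 0.5}),
        _outcome("cardiovascular_death", 0.07, 0.86, {"cvd": 0.6}, mechanism="survival"),
        _outcome("all_cause_death", 0.13, 0.73, {"cvd": 0.5}, mechanism="survival"),
        _outcome("esrd", 0.02, 0.80, {"gfr": 0.7, "albuminuria": 0.5}, mechanism="survival"),
    )


# (outcome, (("bp", (L, M, H)), ("glucose", (L, M, H)))): hazard-ratio
# multipliers by treatment factor within true-risk thirds. Defaults plant a
# benefit concentrated in the high-risk third (combined ~0.61 for CV death).
DEFAULT_TREATMENT_EFFECTS: tuple = (
    ("cardiovascular_death", (("bp", (1.0, 0.90, 0.68)), ("glucose", (1.0, 0.95, 0.90)))),
    ("all_cause_death", (("bp", (1.0, 0.95, 0.80)), ("glucose", (1.0, 1.0, 0.95)))),
    ("esrd", (("bp", (1.0, 1.0, 1.0)), ("glucose", (1.0, 0.70, 0.35)))),
)


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic study; hashable and immutable."""

    seed: int = 0
    n_individuals: int = 4000
    group_spec: tuple[tuple[str, int], ...] = DEFAULT_GROUP_SPEC
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_scale: float = 0.08  # half-normal scale of simulated GWAS effects
    n_subpops: int = 2
    subpop_divergence: float = 0.01  # Fst-like Balding-Nichols parameter
    n_pca_variants: int = 2000
    outcomes: tuple[OutcomeSpec, ...] = field(default_factory=default_outcomes)
    trial_years: float = 4.5
    extension_years: float = 5.0
    treatment_effects: tuple = DEFAULT_TREATMENT_EFFECTS
    censoring_rate: float = 0.0  # random (non-administrative) censoring hazard
    missing_rate: float = 0.0
    male_fraction: float = 0.58

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.subpop_divergence < 0:
            raise ValueError("subpop_divergence must be >= 0")
        for _, count in self.group_spec:
            if count < 1:
                raise ValueError("per-group variant counts must be positive")
        for _, factors in self.treatment_effects:
            for _, hrs in factors:
                if any(h <= 0 for h in hrs):
                    raise ValueError("hazard ratios must be > 0")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.group_spec)

    def outcome(self, name: str) -> OutcomeSpec:
        for o in self.outcomes:
            if o.name == name:
                return o
        raise KeyError(f"outcome {name} not in config")

    def arm_hrs(self, outcome: str) -> dict[str, StratumHRs]:
        for name, factors in self.treatment_effects:
            if name == outcome:
                return dict(factors)
        return {"bp": (1.0, 1.0, 1.0), "glucose": (1.0, 1.0, 1.0)}


def default_config(seed: int = 0, n_individuals: int = 4000, **overrides) -> SimConfig:
    return replace(SimConfig(seed=seed, n_individuals=n_individuals), **overrides)


def _rng(config: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), tag])


@dataclass
class GenotypeTruth:
    """Generative parameters behind one genotype panel."""

    ancestral_freq: np.ndarray          # per variant
    subpop_freq: np.ndarray             # subpops x variants
    subpop_labels: np.ndarray           # per individual


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst must estimate."""

    beta: dict[str, float]                         # (variant_id, group)-keyed? see note
    gamma: dict[str, dict[str, float]]             # outcome -> predictor -> natural-unit coef
    intercept: dict[str, float]                    # outcome -> alpha (binary)
    baseline_rate: dict[str, float]                # outcome -> lambda0 (survival)
    eta: pd.DataFrame                              # per-individual true linear predictors
    stratum_cuts: dict[str, tuple[float, float]]   # outcome -> tertile boundaries of eta
    stratum: dict[str, np.ndarray]                 # outcome -> 0/1/2 labels
    subpop_labels: np.ndarray
    predictor_sd: dict[str, float]


@dataclass
class Study:
    """A fully simulated study: inputs, intermediates and ground truth."""

    config: SimConfig
    weights: WeightSet
    genotypes: GenotypeMatrix
    pca_genotypes: GenotypeMatrix
    genotype_truth: GenotypeTruth
    pc_model: scoring.PCModel
    pcs: pd.DataFrame
    scores: TraitGroupScores
    cohort: TrialCohort
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Stage generators
# ---------------------------------------------------------------------------


def simulate_weights(config: SimConfig) -> WeightSet:
    """Draw a scoring file: per-group counts as specified, beta = |N(0, tau)|."""
    rng = _rng(config, 1)
    weights: list[VariantWeight] = []
    i = 0
    for group, count in config.group_spec:
        for _ in range(count):
            a = rng.choice(4, size=2, replace=False)
            beta = abs(rng.normal(0.0, config.beta_scale))
            beta = max(beta, 1e-9)  # the zero boundary is disallowed
            weights.append(
                VariantWeight(
                    variant_id=f"rs{100000 + i}",
                    chrom=str(i % 22 + 1),
                    pos=10_000 + 1000 * i,
                    effect_allele=str(_BASES[a[0]]),
                    other_allele=str(_BASES[a[1]]),
                    beta=float(beta),
                    trait_group=group,
                )
            )
            i += 1
    return WeightSet(weights=weights, groups=config.groups)


def simulate_subpops(config: SimConfig, n: int | None = None) -> np.ndarray:
    """Balanced subpopulation labels, shuffled deterministically."""
    rng = _rng(config, 2)
    n = n or config.n_individuals
    labels = np.arange(n) % config.n_subpops
    return rng.permutation(labels)


def _balding_nichols_freqs(rng, ancestral: np.ndarray, fst: float, n_subpops: int):
    if fst <= 0:
        return np.tile(ancestral, (n_subpops, 1))
    a = ancestral * (1 - fst) / fst
    b = (1 - ancestral) * (1 - fst) / fst
    return rng.beta(a, b, size=(n_subpops, len(ancestral)))


def _draw_panel(config, rng, n_variants, subpops, n_individuals):
    lo, hi = config.maf_range
    ancestral = rng.uniform(lo, hi, n_variants)
    subpop_freq = _balding_nichols_freqs(rng, ancestral, config.subpop_divergence,
                                         config.n_subpops)
    p = subpop_freq[subpops]  # individuals x variants
    dosage = rng.binomial(2, p).astype(float)
    if config.missing_rate > 0:
        dosage[rng.random(dosage.shape) < config.missing_rate] = np.nan
    return dosage, ancestral, subpop_freq


def simulate_genotypes(
    config: SimConfig,
    weights: WeightSet,
    subpops: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, GenotypeTruth]:
    """Effect-allele dosages for the scoring variants, HWE within subpopulation."""
    if config.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if subpops is None:
        subpops = simulate_subpops(config)
    rng = _rng(config, 3)
    dosage, ancestral, subpop_freq = _draw_panel(
        config, rng, len(weights), subpops, len(subpops)
    )
    geno = GenotypeMatrix(
        individual_ids=[f"ind{i:06d}" for i in range(len(subpops))],
        variant_ids=[w.variant_id for w in weights.weights],
        dosage=dosage,
        effect_allele=[w.effect_allele for w in weights.weights],
        other_allele=[w.other_allele for w in weights.weights],
        chrom=[w.chrom for w in weights.weights],
        pos=[w.pos for w in weights.weights],
    )
    return geno, GenotypeTruth(ancestral, subpop_freq, subpops)


def simulate_reference_genotypes(
    config: SimConfig, subpops: np.ndarray | None = None
) -> tuple[GenotypeMatrix, GenotypeTruth]:
    """A null variant panel for ancestry PCA (no phenotype effects)."""
    if subpops is None:
        subpops = simulate_subpops(config)
    rng = _rng(config, 4)
    dosage, ancestral, subpop_freq = _draw_panel(
        config, rng, config.n_pca_variants, subpops, len(subpops)
    )
    bases = rng.choice(4, size=(config.n_pca_variants, 2))
    bases[:, 1] = (bases[:, 0] + 1 + bases[:, 1] % 3) % 4  # distinct other allele
    geno = GenotypeMatrix(
        individual_ids=[f"ind{i:06d}" for i in range(len(subpops))],
        variant_ids=[f"ref{j:06d}" for j in range(config.n_pca_variants)],
        dosage=dosage,
        effect_allele=[str(_BASES[b]) for b in bases[:, 0]],
        other_allele=[str(_BASES[b]) for b in bases[:, 1]],
    )
    return geno, GenotypeTruth(ancestral, subpop_freq, subpops)


def _covariates(config: SimConfig, n: int, rng) -> pd.DataFrame:
    sex = (rng.random(n) < config.male_fraction).astype(int)
    age = np.clip(rng.normal(58.0, 9.0, n), 25.0, 90.0)
    duration = np.clip(rng.normal(8.0, 6.0, n), 0.0, 40.0)
    return pd.DataFrame({"sex": sex, "age_at_onset": age, "diabetes_duration": duration})


def _design(scores: TraitGroupScores, pcs: pd.DataFrame, covs: pd.DataFrame,
            groups: tuple[str, ...]) -> pd.DataFrame:
    z = scores.scaled[[f"wPRS_{g}" for g in groups]].reset_index(drop=True).copy()
    z["pc1"] = pcs["pc1"].to_numpy()
    for c in ("sex", "age_at_onset", "diabetes_duration"):
        z[c] = covs[c].to_numpy()
    return z


def _natural_gamma(spec: OutcomeSpec, z: pd.DataFrame, groups) -> dict[str, float]:
    """Per-SD effects -> natural-unit coefficients using the cohort's SDs."""
    eff = spec.effects()
    gamma = {}
    for col in z.columns:
        key = col[len("wPRS_"):] if col.startswith("wPRS_") else col
        e = eff.get(key, 0.0)
        sd = float(z[col].std(ddof=0))
        gamma[col] = 0.0 if e == 0 else e / sd if sd > 0 else 0.0
    return gamma


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    try:
        return brentq(lambda a: float(np.mean(expit(a + eta))) - target, -40, 40)
    except ValueError as exc:
        raise PrevalenceCalibrationError(
            f"prevalence {target} unreachable for given linear predictor"
        ) from exc


def _calibrate_rate(eta: np.ndarray, mult: np.ndarray, target: float, horizon: float) -> float:
    def f(log_l0):
        lam = np.exp(log_l0 + eta) * mult
        return float(np.mean(-np.expm1(-lam * horizon))) - target

    try:
        return float(np.exp(brentq(f, -30, 10)))
    except ValueError as exc:
        raise PrevalenceCalibrationError(
            f"prevalence {target} unreachable under the exponential model"
        ) from exc


def _tertile_cuts(eta: np.ndarray) -> tuple[float, float]:
    return tuple(np.quantile(eta, [1 / 3, 2 / 3]))


def _stratum_from_cuts(eta: np.ndarray, cuts: tuple[float, float]) -> np.ndarray:
    return np.searchsorted(np.asarray(cuts), eta, side="right")


def simulate_phenotypes(
    config: SimConfig,
    scores: TraitGroupScores,
    pcs: pd.DataFrame,
    subpops: np.ndarray | None = None,
) -> tuple[TrialCohort, GroundTruth]:
    """Draw covariates, treatment arms, outcomes and survival times.

    Binary outcomes follow logit(P) = alpha + gamma'z with alpha calibrated
    by bisection to the target prevalence. Survival outcomes follow an
    exponential model with rate lambda0 * exp(gamma'z) scaled by arm- and
    stratum-specific hazard ratios, lambda0 calibrated so the expected
    in-trial event fraction hits the target prevalence; their binary
    indicator is the in-trial event. Administrative censoring at
    trial + extension years; optional random exponential censoring.
    """
    n = len(scores.individual_ids)
    if list(pcs["individual_id"]) != list(scores.individual_ids):
        raise ValueError("scores and PC scores must be aligned on individual_id")
    rng_cov = _rng(config, 5)
    rng_arm = _rng(config, 6)
    covs = _covariates(config, n, rng_cov)
    z = _design(scores, pcs, covs, config.groups)

    table = pd.DataFrame({"individual_id": scores.individual_ids})
    for c in ("sex", "age_at_onset", "diabetes_duration"):
        table[c] = covs[c].to_numpy()
    table["pc1"] = z["pc1"].to_numpy()
    table["arm_bp"] = rng_arm.integers(0, 2, n)
    table["arm_glucose"] = rng_arm.integers(0, 2, n)

    follow_up = config.trial_years + config.extension_years
    gamma_all, alpha_all, lam0_all = {}, {}, {}
    eta_all = {}
    cuts_all, stratum_all = {}, {}
    outcomes, survival_outcomes = [], []
    for k, spec in enumerate(config.outcomes):
        rng_o = _rng(config, 100 + k)
        gamma = _natural_gamma(spec, z, config.groups)
        eta = (z.to_numpy() * np.array([gamma[c] for c in z.columns])).sum(axis=1)
        gamma_all[spec.name] = gamma
        eta_all[spec.name] = eta
        outcomes.append(spec.name)
        if spec.mechanism == "binary":
            alpha = _calibrate_intercept(eta, spec.prevalence)
            alpha_all[spec.name] = alpha
            table[spec.name] = (rng_o.random(n) < expit(alpha + eta)).astype(int)
        else:
            cuts = _tertile_cuts(eta)
            stratum = _stratum_from_cuts(eta, cuts)
            cuts_all[spec.name] = cuts
            stratum_all[spec.name] = stratum
            hrs = config.arm_hrs(spec.name)
            mult = (
                np.asarray(hrs["bp"])[stratum] ** table["arm_bp"].to_numpy()
                * np.asarray(hrs["glucose"])[stratum] ** table["arm_glucose"].to_numpy()
            )
            lam0 = _calibrate_rate(eta, mult, spec.prevalence, config.trial_years)
            lam0_all[spec.name] = lam0
            lam = lam0 * np.exp(eta) * mult
            t_event = rng_o.exponential(1.0 / lam)
            censor = np.full(n, follow_up)
            if config.censoring_rate > 0:
                censor = np.minimum(
                    censor, rng_o.exponential(1.0 / config.censoring_rate, n)
                )
            observed = np.minimum(t_event, censor)
            event = (t_event <= censor).astype(int)
            trial_window = np.minimum(censor, config.trial_years)
            table[spec.name] = (t_event <= trial_window).astype(int)
            table[spec.name + "_time"] = observed
            table[spec.name + "_event"] = event
            survival_outcomes.append(spec.name)

    truth = GroundTruth(
        beta={},
        gamma=gamma_all,
        intercept=alpha_all,
        baseline_rate=lam0_all,
        eta=pd.DataFrame(eta_all),
        stratum_cuts=cuts_all,
        stratum=stratum_all,
        subpop_labels=subpops if subpops is not None else np.array([]),
        predictor_sd={c: float(z[c].std(ddof=0)) for c in z.columns},
    )
    cohort = TrialCohort(table=table, outcomes=outcomes,
                         survival_outcomes=survival_outcomes)
    return cohort, truth


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=4)
def simulate_study(config: SimConfig) -> Study:
    """Generate the canonical study for a config: all inputs + ground truth."""
    weights = simulate_weights(config)
    subpops = simulate_subpops(config)
    genotypes, geno_truth = simulate_genotypes(config, weights, subpops)
    pca_geno, _ = simulate_reference_genotypes(config, subpops)
    aligned = scoring.align_weights(weights, genotypes)
    scores = scoring.compute_wprs(aligned.genotypes, aligned.weights)
    pc_model, pcs = scoring.fit_pc_model(pca_geno, n_components=2)
    cohort, truth = simulate_phenotypes(config, scores, pcs, subpops)
    truth.beta = {(w.variant_id, w.trait_group): w.beta for w in weights.weights}
    return Study(
        config=config,
        weights=weights,
        genotypes=genotypes,
        pca_genotypes=pca_geno,
        genotype_truth=geno_truth,
        pc_model=pc_model,
        pcs=pcs,
        scores=scores,
        cohort=cohort,
        truth=truth,
    )


def _mann_whitney_auc(score: np.ndarray, y: np.ndarray) -> float:
    r = rankdata(score)
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def oracle_auc(config: SimConfig, outcome: str, n_mc: int = 50_000, seed: int = 0) -> float:
    """Monte-Carlo AUC of the TRUE linear predictor under the generative model.

    Draws a fresh cohort of ``n_mc`` individuals from the same generative
    process (genotypes from the stored subpopulation frequencies, PC1 through
    the canonical PC model, the recorded natural-unit coefficients and
    calibrated intercept/baseline rate) and scores the true eta against the
    drawn outcomes. This is the reference value downstream cross-validated
    AUCs are compared to.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be at least 1000")
    study = simulate_study(config)
    spec = config.outcome(outcome)
    truth = study.truth
    rng = np.random.default_rng([int(seed) % (2**31), 90001])

    n_sub = config.n_subpops
    subpops = rng.integers(0, n_sub, n_mc)
    # scoring-panel genotypes from stored per-subpop frequencies
    p = study.genotype_truth.subpop_freq[subpops]
    dosage = rng.binomial(2, p).astype(float)
    geno = GenotypeMatrix(
        individual_ids=[f"mc{i}" for i in range(n_mc)],
        variant_ids=list(study.genotypes.variant_ids),
        dosage=dosage,
        effect_allele=list(study.genotypes.effect_allele),
        other_allele=list(study.genotypes.other_allele),
        chrom=list(study.genotypes.chrom),
        pos=list(study.genotypes.pos),
    )
    aligned = scoring.align_weights(study.weights, geno)
    scores = scoring.compute_wprs(aligned.genotypes, aligned.weights)
    # reference panel for PC projection: regenerate the canonical panel's
    # per-subpop frequencies deterministically, draw fresh genotypes from them
    rng_ref = _rng(config, 4)
    lo, hi = config.maf_range
    ancestral = rng_ref.uniform(lo, hi, config.n_pca_variants)
    subpop_freq = _balding_nichols_freqs(
        rng_ref, ancestral, config.subpop_divergence, config.n_subpops
    )
    ref_dosage = rng.binomial(2, subpop_freq[subpops]).astype(float)
    ref_geno = GenotypeMatrix(
        individual_ids=geno.individual_ids,
        variant_ids=list(study.pca_genotypes.variant_ids),
        dosage=ref_dosage,
        effect_allele=list(study.pca_genotypes.effect_allele),
        other_allele=list(study.pca_genotypes.other_allele),
    )
    pcs = scoring.project_pcs(study.pc_model, ref_geno)
    covs = _covariates(config, n_mc, rng)
    z = _design(scores, pcs, covs, config.groups)
    gamma = truth.gamma[outcome]
    eta = (z.to_numpy() * np.array([gamma[c] for c in z.columns])).sum(axis=1)

    if spec.mechanism == "binary":
        y = (rng.random(n_mc) < expit(truth.intercept[outcome] + eta)).astype(int)
    else:
        cuts = truth.stratum_cuts[outcome]
        stratum = _stratum_from_cuts(eta, cuts)
        hrs = config.arm_hrs(outcome)
        arm_bp = rng.integers(0, 2, n_mc)
        arm_glu = rng.integers(0, 2, n_mc)
        mult = (
            np.asarray(hrs["bp"])[stratum] ** arm_bp
            * np.asarray(hrs["glucose"])[stratum] ** arm_glu
        )
        lam = truth.baseline_rate[outcome] * np.exp(eta) * mult
        t = rng.exponential(1.0 / lam)
        y = (t <= config.trial_years).astype(int)
    if y.sum() in (0, len(y)):
        raise PrevalenceCalibrationError("degenerate Monte-Carlo outcome draw")
    return _mann_whitney_auc(eta, y)
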