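"""The joint multiPRS logistic model and its evaluation machinery.

The model regresses a binary complication outcome on the ten scaled
trait-group wPRS, the first ancestry principal component, sex, age at
diabetes onset and diabetes duration (15 coefficients with the intercept).
Its predicted probability is the multiPRS score used for all downstream
ranking and stratification. Out-of-sample prediction uses stratified
ten-fold cross-validation; discrimination is the Mann-Whitney AUC with a
case-resampling percentile bootstrap CI; calibration is the
Hosmer-Lemeshow chi-square over deciles of predicted risk (its p-value
reported as ``pi``); model comparison uses the continuous net
reclassification improvement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .types import (
    PerfectSeparationError,
    TraitGroupScores,
    TrialCohort,
)

GENOMIC_PREDICTORS = ("pc1",)  # plus the wPRS columns, see genomic_subset()


@dataclass
class MultiPRSModel:
    predictors: list[str]
    coef: dict[str, float]           # includes "intercept"
    bse: dict[str, float]
    n: int
    events: int
    converged: bool
    outcome: str
    standardised: bool = False

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.coef["intercept"])
        for p in self.predictors:
            eta += self.coef[p] * X[p].to_numpy(dtype=float)
        return eta

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(X)))

    def wald_ci(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        z = stats.norm.ppf(0.5 + level / 2)
        return {
            p: (self.coef[p] - z * self.bse[p], self.coef[p] + z * self.bse[p])
            for p in ["intercept", *self.predictors]
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "outcome": self.outcome,
            "predictors": self.predictors,
            "coef": self.coef,
            "bse": self.bse,
            "n": self.n,
            "events": self.events,
            "converged": self.converged,
            "standardised": self.standardised,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MultiPRSModel":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def design_matrix(
    scores: TraitGroupScores, cohort: TrialCohort, predictors: list[str] | None = None
) -> pd.DataFrame:
    """Merge wPRS columns with cohort covariates in the model's column order."""
    df = scores.scaled.reset_index(drop=True).copy()
    df.insert(0, "individual_id", scores.individual_ids)
    merged = df.merge(cohort.table, on="individual_id", how="inner", validate="1:1")
    if len(merged) != len(cohort.table):
        raise ValueError("scores and cohort do not cover the same individuals")
    if predictors is None:
        predictors = default_predictors(scores)
    return merged[["individual_id", *predictors]]


def default_predictors(scores: TraitGroupScores) -> list[str]:
    return [f"wPRS_{g}" for g in scores.groups] + [
        "pc1",
        "sex",
        "age_at_onset",
        "diabetes_duration",
    ]


def genomic_subset(scores: TraitGroupScores) -> list[str]:
    """The genomic component: the ten wPRS plus PC1."""
    return [f"wPRS_{g}" for g in scores.groups] + list(GENOMIC_PREDICTORS)


def fit_logistic(X: np.ndarray, y: np.ndarray, names: list[str], outcome: str,
               standardised: bool = False) -> MultiPRSModel:
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {outcome} has a single class; cannot fit")
    exog = sm.add_constant(X, prepend=True, has_constant="add")
    try:
        res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on hard separation
        raise PerfectSeparationError(f"logistic fit failed for {outcome}: {exc}") from exc
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    fitted = np.asarray(res.predict(exog))
    if not np.all(np.isfinite(params)) or not np.all(np.isfinite(bse)):
        raise PerfectSeparationError(
            f"non-finite coefficients for {outcome}: likely perfect separation"
        )
    eps = 1e-10
    if np.all((fitted < eps) | (fitted > 1 - eps)):
        raise PerfectSeparationError(f"fitted probabilities degenerate for {outcome}")
    coef = {"intercept": float(params[0])}
    se = {"intercept": float(bse[0])}
    for name, c, s in zip(names, params[1:], bse[1:]):
        coef[name] = float(c)
        se[name] = float(s)
    return MultiPRSModel(
        predictors=list(names),
        coef=coef,
        bse=se,
        n=len(y),
        events=int(y.sum()),
        converged=bool(res.mle_retvals.get("converged", False)),
        outcome=outcome,
        standardised=standardised,
    )


def fit_multiprs(
    scores: TraitGroupScores,
    cohort: TrialCohort,
    outcome: str,
    predictors: list[str] | None = None,
    standardise: bool = False,
) -> MultiPRSModel:
    """Maximum-likelihood logistic fit of the multiPRS model.

    ``standardise`` rescales predictors to unit SD before fitting (useful for
    comparing contributions); by default coefficients stay on natural units.
    """
    X = design_matrix(scores, cohort, predictors)
    names = [c for c in X.columns if c != "individual_id"]
    mat = X[names].to_numpy(dtype=float)
    if standardise:
        sd = mat.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        mat = (mat - mat.mean(axis=0)) / sd
    y = cohort.outcome_vector(outcome)
    return fit_logistic(mat, y, names, outcome, standardised=standardise)


def crossval_predict(
    scores: TraitGroupScores,
    cohort: TrialCohort,
    outcome: str,
    folds: int = 10,
    seed: int = 0,
    predictors: list[str] | None = None,
) -> pd.DataFrame:
    """Out-of-fold predicted probability per individual.

    Folds are stratified by outcome and shuffled with ``seed``; each
    individual receives exactly one out-of-fold prediction. A fold whose
    training data happens to be single-class triggers one re-randomisation;
    a second failure is an error.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if cohort.n < folds:
        raise ValueError("need at least as many individuals as folds")
    X = design_matrix(scores, cohort, predictors)
    names = [c for c in X.columns if c != "individual_id"]
    mat = X[names].to_numpy(dtype=float)
    y = cohort.outcome_vector(outcome)

    # stratification needs every class at least `folds` times; degenerate
    # cases (e.g. leave-one-out) fall back to plain shuffled folds
    stratify = np.bincount(y).min() >= folds
    for attempt, s in enumerate((seed, seed + 1)):
        if stratify:
            kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=s % (2**31))
        else:
            from sklearn.model_selection import KFold

            kf = KFold(n_splits=folds, shuffle=True, random_state=s % (2**31))
        prob = np.full(len(y), np.nan)
        fold_id = np.full(len(y), -1)
        try:
            for f, (tr, te) in enumerate(kf.split(mat, y)):
                model = fit_logistic(mat[tr], y[tr], names, outcome)
                prob[te] = model.predict_proba(pd.DataFrame(mat[te], columns=names))
                fold_id[te] = f
            break
        except ValueError:
            if attempt == 1:
                raise
    assert not np.isnan(prob).any()
    return pd.DataFrame(
        {
            "individual_id": X["individual_id"].to_numpy(),
            "prob": prob,
            "fold": fold_id,
            "outcome_value": y,
        }
    )


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------


@dataclass
class DiscriminationResult:
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    roc: pd.DataFrame = field(repr=False)  # columns fpr, tpr


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC with tie correction (Mann-Whitney U / (n1 n0))."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    r = stats.rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def auc_with_ci(
    probs: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> DiscriminationResult:
    """AUC with a case-resampling percentile bootstrap 95% CI."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = mann_whitney_auc(probs, labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = labels[idx]
        if yb.sum() in (0, n):  # degenerate resample: redraw
            boots[b] = np.nan
            continue
        boots[b] = mann_whitney_auc(probs[idx], yb)
    ok = boots[~np.isnan(boots)]
    lo, hi = np.percentile(ok, [2.5, 97.5])
    return DiscriminationResult(
        auc=auc,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
        roc=roc_points(probs, labels),
    )


# ---------------------------------------------------------------------------
# Calibration (Hosmer-Lemeshow)
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    statistic: float
    df: int
    pi: float  # the Hosmer-Lemeshow p-value
    bins: pd.DataFrame  # n, mean_predicted, observed_events, expected_events


def hosmer_lemeshow(
    probs: np.ndarray, labels: np.ndarray, bins: int = 10
) -> CalibrationResult:
    """Hosmer-Lemeshow chi-square over quantile bins of predicted risk.

    statistic = sum_g (O_g - E_g)^2 / (E_g (1 - pbar_g)), df = bins - 2.
    The p-value is reported as ``pi``: the closer to 1, the better the fit.
    """
    if bins < 3:
        raise ValueError("need at least 3 bins")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(probs) < 5 * bins:
        import warnings

        warnings.warn(f"fewer than {5 * bins} observations for {bins} bins", stacklevel=2)
    order = np.argsort(probs, kind="stable")
    groups = np.array_split(order, bins)
    rows = []
    statistic = 0.0
    for g_idx in groups:
        n_g = len(g_idx)
        if n_g == 0:
            continue
        p_bar = probs[g_idx].mean()
        e_g = probs[g_idx].sum()
        o_g = labels[g_idx].sum()
        rows.append((n_g, p_bar, int(o_g), e_g))
        denom = e_g * (1 - p_bar)
        if denom > 0:
            statistic += (o_g - e_g) ** 2 / denom
    table = pd.DataFrame(rows, columns=["n", "mean_predicted", "observed_events",
                                        "expected_events"])
    df = len(table) - 2
    pi = float(stats.chi2.sf(statistic, df))
    return CalibrationResult(statistic=float(statistic), df=df, pi=pi, bins=table)


# ---------------------------------------------------------------------------
# Reclassification (continuous NRI)
# ---------------------------------------------------------------------------


@dataclass
class ReclassificationResult:
    nri_total: float
    nri_events: float
    nri_nonevents: float


def continuous_nri(
    old_probs: np.ndarray, new_probs: np.ndarray, labels: np.ndarray
) -> ReclassificationResult:
    """Continuous net reclassification improvement of new over old scores.

    events component:     P(new > old | event)    - P(new < old | event)
    non-events component: P(new < old | nonevent) - P(new > old | nonevent)
    Ties contribute zero; the total is the sum of the two components.
    """
    old = np.asarray(old_probs, dtype=float)
    new = np.asarray(new_probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (len(old) == len(new) == len(y)):
        raise ValueError("old_probs, new_probs and labels must have equal length")
    if y.sum() in (0, len(y)):
        raise ValueError("both classes must be present")
    direction = np.sign(new - old)
    nri_events = float(direction[y == 1].mean())
    nri_nonevents = float(-direction[y == 0].mean())
    return ReclassificationResult(
        nri_total=nri_events + nri_nonevents,
        nri_events=nri_events,
        nri_nonevents=nri_nonevents,
    )


# ---------------------------------------------------------------------------
# AUC decomposition over predictor subsets
# ---------------------------------------------------------------------------


def auc_decomposition(
    scores: TraitGroupScores,
    cohort: TrialCohort,
    outcome: str,
    folds: int = 10,
    seed: int = 0,
    n_boot: int = 500,
) -> pd.DataFrame:
    """Cross-validated AUC of predictor subsets: the genomic component
    (ten wPRS + PC1), sex alone, age at onset alone, diabetes duration
    alone, and the full model."""
    subsets = {
        "genomic": genomic_subset(scores),
        "sex": ["sex"],
        "age_at_onset": ["age_at_onset"],
        "diabetes_duration": ["diabetes_duration"],
        "full": default_predictors(scores),
    }
    rows = []
    y = cohort.outcome_vector(outcome)
    for name, preds in subsets.items():
        oof = crossval_predict(scores, cohort, outcome, folds=folds, seed=seed,
                               predictors=preds)
        res = auc_with_ci(oof["prob"].to_numpy(), y, n_boot=n_boot, seed=seed)
        rows.append((name, ", ".join(preds), res.auc, res.ci_low, res.ci_high))
    return pd.DataFrame(rows, columns=["component", "predictors", "auc",
                                       "ci_low", "ci_high"])
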