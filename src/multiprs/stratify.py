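"""Risk stratification: deciles, top-k% thresholds, tertile grids, trend test.

The "frequency ratio" reported here is outcome frequency in the high-risk
set divided by frequency in the remainder of the cohort (what the study
tables label OR); a conventional odds ratio is reported alongside to avoid
ambiguity. Positive and negative predictive values are prevalence-adjusted
through Bayes' rule from sensitivity and specificity, so they can be
recomputed for any stated target-population prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


def assign_quantile_groups(scores: np.ndarray, q: int) -> np.ndarray:
    """Equal-count quantile group labels 0..q-1 (sizes differ by <= 1).

    Individuals are ranked by score with ties broken by stable input order;
    group 0 holds the lowest scores. Permutation-equivariant up to that
    stable tie-breaking.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n < q:
        raise ValueError(f"need at least {q} individuals for {q} groups")
    order = np.argsort(scores, kind="stable")
    labels = np.empty(n, dtype=int)
    # first (n mod q) groups get the extra individual, matching equal-thirds
    sizes = np.full(q, n // q)
    sizes[: n % q] += 1
    start = 0
    for g, s in enumerate(sizes):
        labels[order[start : start + s]] = g
        start += s
    return labels


def assign_deciles(scores: np.ndarray) -> np.ndarray:
    """Decile labels 1..10 along the score (1 = lowest risk)."""
    return assign_quantile_groups(scores, 10) + 1


def decile_event_table(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Per-decile n, events and event rate (%) of a binary outcome."""
    dec = assign_deciles(scores)
    y = np.asarray(labels, dtype=int)
    rows = []
    for d in range(1, 11):
        m = dec == d
        rows.append((d, int(m.sum()), int(y[m].sum()), 100.0 * y[m].mean()))
    return pd.DataFrame(rows, columns=["decile", "n", "events", "event_rate_pct"])


@dataclass
class ThresholdMetrics:
    top_fraction: float
    n_high: int
    n_rest: int
    events_high: int
    events_rest: int
    freq_ratio: float          # frequency in high set / frequency in remainder
    odds_ratio: float          # conventional OR, reported alongside
    sensitivity: float
    specificity: float
    ppv_adj: float
    npv_adj: float
    prevalence: float
    freq_ratio_undefined: bool = False


def threshold_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    top_fraction: float,
    prevalence: float | None = None,
) -> ThresholdMetrics:
    """Enrichment and prevalence-adjusted predictive values of a top-k% cut.

    The high-risk set is the top ceil(n * top_fraction) individuals by score
    (ties broken by stable input order). With pi0 the prevalence (in-sample
    by default, user-overridable):

        ppv_adj = sens * pi0 / (sens * pi0 + (1 - spec) (1 - pi0))
        npv_adj = spec (1 - pi0) / ((1 - sens) pi0 + spec (1 - pi0))
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    if y.sum() in (0, len(y)):
        raise ValueError("both classes must be present")
    n = len(y)
    n_high = math.ceil(n * top_fraction)
    order = np.argsort(-scores, kind="stable")
    high = np.zeros(n, dtype=bool)
    high[order[:n_high]] = True

    events_high = int(y[high].sum())
    events_rest = int(y[~high].sum())
    n_rest = n - n_high
    rate_high = events_high / n_high
    undefined = events_rest == 0
    freq_ratio = math.inf if undefined else rate_high / (events_rest / n_rest)
    ne_high = n_high - events_high
    ne_rest = n_rest - events_rest
    if events_rest == 0 or ne_high == 0:
        odds_ratio = math.inf
    else:
        odds_ratio = (events_high / ne_high) / (events_rest / ne_rest)

    sens = events_high / y.sum()
    spec = ne_rest / (n - y.sum())
    pi0 = float(prevalence) if prevalence is not None else y.mean()
    ppv = sens * pi0 / (sens * pi0 + (1 - spec) * (1 - pi0))
    npv = spec * (1 - pi0) / ((1 - sens) * pi0 + spec * (1 - pi0))
    return ThresholdMetrics(
        top_fraction=top_fraction,
        n_high=n_high,
        n_rest=n_rest,
        events_high=events_high,
        events_rest=events_rest,
        freq_ratio=freq_ratio,
        odds_ratio=odds_ratio,
        sensitivity=sens,
        specificity=spec,
        ppv_adj=ppv,
        npv_adj=npv,
        prevalence=pi0,
        freq_ratio_undefined=undefined,
    )


def threshold_table(
    scores: np.ndarray,
    labels: np.ndarray,
    fractions: tuple[float, ...] = (0.10, 0.30),
    prevalence: float | None = None,
) -> pd.DataFrame:
    """A table of threshold metrics, one row per top fraction."""
    rows = []
    for f in fractions:
        m = threshold_metrics(scores, labels, f, prevalence)
        rows.append(
            {
                "top_fraction": f,
                "pp_pct": 100.0 * m.prevalence,
                "freq_ratio": m.freq_ratio,
                "odds_ratio": m.odds_ratio,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "ppv_pct": 100.0 * m.ppv_adj,
                "npv_pct": 100.0 * m.npv_adj,
                "events_high": m.events_high,
                "n_high": m.n_high,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class StratumTable:
    counts: pd.DataFrame       # 3x3 n per (genomic third, age band)
    frequencies: pd.DataFrame  # 3x3 outcome frequency
    genomic_cuts: tuple[float, float]
    age_cuts: tuple[float, float]


def tertile_strata(
    genomic_scores: np.ndarray,
    age_at_onset: np.ndarray,
    labels: np.ndarray,
    age_cuts: tuple[float, float] | None = None,
) -> StratumTable:
    """3x3 grid of outcome frequency over genomic-risk and age-at-onset thirds.

    Both axes are cut into equal thirds by rank (sizes differ by <= 1);
    ``age_cuts`` fixes the age bands instead (e.g. the published <55 / 55-63 /
    >63 grouping). Constant values on an axis make tertiles degenerate and
    raise, naming the axis.
    """
    g = np.asarray(genomic_scores, dtype=float)
    a = np.asarray(age_at_onset, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(g) < 9:
        raise ValueError("need at least 9 individuals for a 3x3 grid")
    if np.ptp(g) == 0:
        raise ValueError("degenerate tertiles on axis: genomic_scores (constant values)")
    g_lab = assign_quantile_groups(g, 3)
    g_cuts = tuple(np.quantile(g, [1 / 3, 2 / 3]))
    if age_cuts is not None:
        a_lab = np.searchsorted(np.asarray(age_cuts, dtype=float), a, side="right")
        a_cuts = tuple(age_cuts)
    else:
        if np.ptp(a) == 0:
            raise ValueError("degenerate tertiles on axis: age_at_onset (constant values)")
        a_lab = assign_quantile_groups(a, 3)
        a_cuts = tuple(np.quantile(a, [1 / 3, 2 / 3]))

    idx = ["low", "medium", "high"]
    cols = ["young", "middle", "old"]
    counts = pd.DataFrame(0, index=idx, columns=cols)
    freqs = pd.DataFrame(np.nan, index=idx, columns=cols)
    for i in range(3):
        for j in range(3):
            m = (g_lab == i) & (a_lab == j)
            counts.iloc[i, j] = int(m.sum())
            if m.any():
                freqs.iloc[i, j] = float(y[m].mean())
    assert counts.to_numpy().sum() == len(y)
    return StratumTable(counts=counts, frequencies=freqs,
                        genomic_cuts=g_cuts, age_cuts=a_cuts)


@dataclass
class TrendResult:
    slope: float
    p_value: float
    direction: int  # sign of the slope
    z: float


def trend_test(labels: np.ndarray, ordered_stratum: np.ndarray) -> TrendResult:
    """Parametric trend test within formal regression.

    Logistic regression of the outcome on the stratum index (0/1/2) as a
    numeric covariate; Wald test of the slope.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(ordered_stratum, dtype=float)
    if len(np.unique(s)) < 2:
        raise ValueError("need at least 2 distinct strata for a trend test")
    exog = sm.add_constant(s, prepend=True)
    res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
    slope = float(res.params[1])
    z = float(slope / res.bse[1])
    p = float(2 * stats.norm.sf(abs(z)))
    return TrendResult(slope=slope, p_value=p, direction=int(np.sign(slope)), z=z)
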