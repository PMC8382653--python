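"""Unsupervised clustering of per-individual predicted-risk profiles.

Each individual carries a vector of predicted risks, one per outcome model
(e.g. myocardial infarction, stroke, heart failure, major macrovascular
events, cardiovascular and all-cause death). Columns are z-scored so no
single outcome dominates the Euclidean metric, complete-linkage hierarchical
clustering is run on the z-scored profiles, and the tree is cut into three
groups relabelled low/medium/high by ascending mean predicted risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .model import MultiPRSModel, design_matrix
from .types import TraitGroupScores, TrialCohort


@dataclass
class RiskProfileMatrix:
    individual_ids: list[str]
    outcomes: list[str]
    risks: pd.DataFrame                      # raw predicted probabilities
    z: pd.DataFrame                          # per-outcome standardised copy
    constant_columns: list[str] = field(default_factory=list)


def build_profile_matrix(
    models: list[MultiPRSModel],
    scores: TraitGroupScores,
    cohort: TrialCohort,
) -> RiskProfileMatrix:
    """One predicted-risk column per outcome model, plus its z-scored copy.

    A column with zero SD cannot be standardised; it is kept as-is and
    flagged in ``constant_columns``.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 outcome models for a risk profile")
    X = design_matrix(scores, cohort)
    risks = {}
    for m in models:
        risks[m.outcome] = m.predict_proba(X)
    risks = pd.DataFrame(risks)
    z = risks.copy()
    constant = []
    for c in z.columns:
        sd = z[c].std(ddof=0)
        if sd > 0:
            z[c] = (z[c] - z[c].mean()) / sd
        else:
            constant.append(c)
    return RiskProfileMatrix(
        individual_ids=X["individual_id"].tolist(),
        outcomes=list(risks.columns),
        risks=risks,
        z=z,
        constant_columns=constant,
    )


@dataclass
class ClusterResult:
    labels: np.ndarray                   # "L"/"M"/"H" per individual (k=3)
    sizes: dict[str, int]
    fractions: dict[str, float]
    linkage_tree: np.ndarray = field(repr=False)
    mean_risk: pd.DataFrame = field(repr=False)  # cluster x outcome raw risks
    k: int = 3


def cluster_profiles(matrix: RiskProfileMatrix, k: int = 3) -> ClusterResult:
    """Complete-linkage agglomeration on Euclidean distances of z profiles.

    The tree is cut into ``k`` flat clusters; clusters are relabelled by
    ascending mean predicted risk (averaged over outcomes), "L" < "M" < "H"
    for k = 3, else "C1" < "C2" < ... The relabelling is deterministic given
    the partition, and the partition is invariant to row order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    Z = matrix.z.to_numpy(dtype=float)
    if len(Z) <= k:
        raise ValueError("need more individuals than clusters")
    tree = linkage(Z, method="complete", metric="euclidean")
    raw = fcluster(tree, t=k, criterion="maxclust")

    overall = matrix.risks.mean(axis=1).to_numpy()
    order = sorted(np.unique(raw), key=lambda c: overall[raw == c].mean())
    if k == 3:
        names = ["L", "M", "H"]
    else:
        names = [f"C{i + 1}" for i in range(len(order))]
    rename = {c: names[i] for i, c in enumerate(order)}
    labels = np.array([rename[c] for c in raw])

    sizes = {name: int((labels == name).sum()) for name in names}
    n = len(labels)
    fractions = {name: sizes[name] / n for name in names}
    mean_risk = pd.DataFrame(
        {name: matrix.risks[labels == name].mean() for name in names}
    ).T
    return ClusterResult(
        labels=labels,
        sizes=sizes,
        fractions=fractions,
        linkage_tree=tree,
        mean_risk=mean_risk,
        k=k,
    )


@dataclass
class ClusterComparison:
    variable: str
    kind: str                  # "binary" or "continuous"
    value_high: float          # rate or median in the high cluster
    value_low: float
    difference: float
    direction: int
    p_value: float
    test: str


def compare_clusters(
    result: ClusterResult,
    cohort: TrialCohort,
    variable: str,
) -> ClusterComparison:
    """High-vs-low cluster comparison of an outcome or continuous variable.

    Binary variables are compared with a two-proportion test of the binomial
    rates; continuous variables (UACR/eGFR-like measures) with the
    Wilcoxon-Mann-Whitney rank-sum test.
    """
    if variable not in cohort.table.columns:
        raise KeyError(f"variable {variable} not in cohort table")
    labels = result.labels
    hi_name = "H" if "H" in result.sizes else max(result.sizes)
    lo_name = "L" if "L" in result.sizes else min(result.sizes)
    hi = labels == hi_name
    lo = labels == lo_name
    if not hi.any() or not lo.any():
        raise ValueError("high or low cluster is empty")
    v = cohort.table[variable].to_numpy(dtype=float)
    vals = np.unique(v[~np.isnan(v)])
    binary = np.isin(vals, [0.0, 1.0]).all()
    if binary:
        x_hi, n_hi = v[hi].sum(), hi.sum()
        x_lo, n_lo = v[lo].sum(), lo.sum()
        p_hi, p_lo = x_hi / n_hi, x_lo / n_lo
        pool = (x_hi + x_lo) / (n_hi + n_lo)
        se = np.sqrt(pool * (1 - pool) * (1 / n_hi + 1 / n_lo))
        z = 0.0 if se == 0 else (p_hi - p_lo) / se
        p = float(2 * stats.norm.sf(abs(z)))
        return ClusterComparison(
            variable=variable,
            kind="binary",
            value_high=float(p_hi),
            value_low=float(p_lo),
            difference=float(p_hi - p_lo),
            direction=int(np.sign(p_hi - p_lo)),
            p_value=p,
            test="two-proportion z",
        )
    res = stats.mannwhitneyu(v[hi], v[lo], alternative="two-sided")
    med_hi, med_lo = float(np.median(v[hi])), float(np.median(v[lo]))
    return ClusterComparison(
        variable=variable,
        kind="continuous",
        value_high=med_hi,
        value_low=med_lo,
        difference=med_hi - med_lo,
        direction=int(np.sign(med_hi - med_lo)),
        p_value=float(res.pvalue),
        test="rank-sum",
    )


def export_heatmap_table(
    matrix: RiskProfileMatrix, result: ClusterResult, path
) -> None:
    """Lossless TSV of the z matrix plus cluster labels (heat-map-ready)."""
    out = matrix.z.copy()
    out.insert(0, "individual_id", matrix.individual_ids)
    out["cluster"] = result.labels
    out.to_csv(path, sep="\t", index=False)
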