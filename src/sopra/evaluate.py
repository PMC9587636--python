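"""Benchmarking: ROC against KS/t-test baselines and replicate reproducibility.

The regression workflow is scored per well as the rank of
``(1 - adjusted p, R-squared)`` — higher is more hit-like, with R-squared
breaking p-value ties. Baselines score each well directly on the
plate-normalized object values against the pooled control objects of the
same plate: the two-sample Kolmogorov-Smirnov D statistic and the absolute
Welch t statistic. ROC curves sweep the unique score thresholds; AUC is the
trapezoidal area, equal to the probability that a random positive well
outranks a random negative one.

Reproducibility is assessed leave-one-replicate-out: with r replicates, r
groups are formed, each omitting one replicate; the pipeline is re-run per
group with all filters off (alfa = 1, Q = 1, rsq threshold = 0) and the
Pearson correlation matrix of per-well R-squared values between groups
measures how reproducible the profile statistics are.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import compute_profiles
from .screen_io import ContentType
from .sigreg import SigParams, run_sigreg

__all__ = [
    "RocCurve",
    "ReplicateGroupResult",
    "ks_score",
    "t_score",
    "roc_curve",
    "sopra_scores",
    "baseline_scores",
    "replicate_group_rsq",
]


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class ReplicateGroupResult:
    group_ids: tuple[str, ...]  # e.g. ("R1", ..., "R4"); Ri omits replicate i
    rsq: pd.DataFrame  # wells x groups
    correlation: np.ndarray


def ks_score(values: Sequence[float], control_values: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D and asymptotic p-value."""
    x = np.asarray(values, float)
    y = np.asarray(control_values, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def t_score(values: Sequence[float], control_values: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p-value.

    Degenerate variances are resolved by the limit: equal constant samples
    give t = 0, p = 1; distinct constant samples give infinite t, p = 0.
    """
    x = np.asarray(values, float)
    y = np.asarray(control_values, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least two observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        return (0.0, 1.0) if x.mean() == y.mean() else (np.inf, 0.0)
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """ROC by threshold sweep over the unique scores (higher = more hit-like).

    AUC is the trapezoidal area under the curve; with ties this equals the
    pair-ranking probability counting ties as one half.
    """
    s = np.asarray(scores, float)
    lab = np.asarray(labels, bool)
    n_pos = int(lab.sum())
    n_neg = int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be present")
    thresholds = np.unique(s)[::-1]
    tpr = np.empty(len(thresholds) + 1)
    fpr = np.empty(len(thresholds) + 1)
    tpr[0] = fpr[0] = 0.0
    for i, t in enumerate(thresholds, start=1):
        called = s >= t
        tpr[i] = (called & lab).sum() / n_pos
        fpr[i] = (called & ~lab).sum() / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def sopra_scores(sig_table: pd.DataFrame, feature: str) -> pd.Series:
    """Per-well hit-likeness score for one feature from the regression results.

    Wells are ranked lexicographically by (1 - adjusted p, rsq) and the rank
    is returned as the score, so R-squared breaks adjusted-p ties without
    perturbing the primary ordering.
    """
    sub = sig_table[sig_table["feature"] == feature]
    key = pd.MultiIndex.from_frame(sub[["plate", "well"]])
    order = np.lexsort((sub["rsq"].to_numpy(), -sub["p_adjusted"].to_numpy()))
    ranks = np.empty(len(sub))
    ranks[order] = np.arange(1, len(sub) + 1)
    # average ranks over exact (p_adjusted, rsq) ties to keep scoring ordinal
    df = pd.DataFrame({"p": sub["p_adjusted"].to_numpy(), "r": sub["rsq"].to_numpy(), "rank": ranks})
    ranks = df.groupby(["p", "r"])["rank"].transform("mean").to_numpy()
    return pd.Series(ranks, index=key, name="sopra_score")


def baseline_scores(
    cells: pd.DataFrame,
    feature: str,
    control_type: ContentType = ContentType.NEUTRAL_CONTROL,
) -> pd.DataFrame:
    """KS D and |Welch t| per (plate, well) on plate-normalized object values.

    Object values are divided by the plate pass's control median (the same
    input the histograms see, pooled over replicates); each well's pooled
    objects are compared against the pooled control objects of its plate.
    """
    from .profiles import platewise_normalize

    normed, _ = platewise_normalize(cells, feature, control_type)
    col = f"{feature}__norm"
    rows = []
    for plate, plate_sub in normed.groupby("plate", sort=True):
        ctrl = plate_sub.loc[plate_sub["content"] == control_type.value, col].to_numpy()
        for well, sub in plate_sub.groupby("well", sort=True):
            vals = sub[col].to_numpy()
            d, ks_p = ks_score(vals, ctrl)
            t, t_p = t_score(vals, ctrl)
            rows.append((plate, well, d, ks_p, abs(t), t_p))
    return pd.DataFrame(
        rows, columns=["plate", "well", "ks_d", "ks_p", "t_abs", "t_p"]
    ).set_index(["plate", "well"])


def replicate_group_rsq(
    cells: pd.DataFrame,
    feature: str,
    n_bins: int = 7,
    scale: str = "log2",
) -> ReplicateGroupResult:
    """Leave-one-replicate-out reproducibility of the per-well R-squared.

    Group Ri contains every replicate except i. The pipeline (profiles +
    regression) is re-run per group with alfa = 1, Q = 1 and rsq threshold 0
    so every profile's statistics are retained unfiltered; the Pearson
    correlation matrix of R-squared values across groups is computed on the
    sample wells present in all groups.
    """
    replicates = sorted(cells["replicate"].unique())
    if len(replicates) < 3:
        raise ValueError("need at least 3 replicates for leave-one-out groups")
    params = SigParams(q=1.0, alfa=1.0, rsq_threshold=0.0)
    columns = {}
    group_ids = []
    for i, omit in enumerate(replicates, start=1):
        gid = f"R{i}"
        group_ids.append(gid)
        sub = cells[cells["replicate"] != omit]
        profs, _ = compute_profiles(sub, [feature], n_bins=n_bins, scale=scale)
        sig = run_sigreg(profs, params)
        sample = sig[sig["content"] == ContentType.SAMPLE.value]
        columns[gid] = sample.set_index(["plate", "well"])["rsq"]
    rsq = pd.DataFrame(columns).dropna()
    corr = np.corrcoef(rsq.to_numpy().T)
    return ReplicateGroupResult(group_ids=tuple(group_ids), rsq=rsq, correlation=corr)
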