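"""Significance testing of normalized profiles by polynomial regression over bins.

Each well's control-normalized profile (all replicates stacked) is treated as
a short series over the bin index, the way single-series time-course
expression profiles are analyzed: a polynomial of the bin position is fit by
ordinary least squares and tested globally against the intercept-only model
with an F-test. Under the null (well distributed like the controls) the log2
profile is flat around zero, so any polynomial trend is evidence of a shifted
or reshaped population. P-values are adjusted per feature across the screen
with the Benjamini-Hochberg step-up procedure, and a profile is called
significant when the adjusted p-value is below the FDR level ``Q`` *and* the
selected model's R-squared exceeds ``rsq_threshold``. A backward-elimination
variable-selection step (per-term t-tests at level ``alfa``) reduces the full
polynomial to its significant terms and supplies the reported R-squared.

Bin positions enter the design as centered integer indices (1..n minus their
mean) so profiles are unit-free and screens comparable; centering also keeps
the polynomial columns well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SigParams",
    "ProfileObservations",
    "SigResult",
    "build_design",
    "fit_global",
    "adjust_fdr_bh",
    "stepwise_select",
    "call_significant",
    "run_sigreg",
]

_EPS = 1e-12


@dataclass(frozen=True)
class SigParams:
    """Tuning of the significance engine.

    q: FDR level for the global F-test (default 0.05).
    alfa: per-term significance level for backward elimination (default 0.05).
    rsq_threshold: minimum R-squared of the selected model (default 0.7).
    degree: polynomial degree of the bin trend (default 2, quadratic).
    scale: scale of the profile values the engine receives.
    """

    q: float = 0.05
    alfa: float = 0.05
    rsq_threshold: float = 0.7
    degree: int = 2
    scale: Literal["ratio", "log2"] = "log2"

    def __post_init__(self) -> None:
        if not 0 < self.q <= 1:
            raise ValueError(f"q must be in (0, 1], got {self.q}")
        if not 0 < self.alfa <= 1:
            raise ValueError(f"alfa must be in (0, 1], got {self.alfa}")
        if not 0 <= self.rsq_threshold < 1:
            raise ValueError(f"rsq_threshold must be in [0, 1), got {self.rsq_threshold}")
        if self.degree < 1:
            raise ValueError(f"degree must be >= 1, got {self.degree}")


@dataclass(frozen=True)
class ProfileObservations:
    """Stacked observations of one well/feature profile across replicates."""

    key: tuple
    feature: str
    y: np.ndarray
    b: np.ndarray  # bin positions 1..n, repeated per replicate
    n_replicates: int

    def __post_init__(self) -> None:
        if len(self.y) != len(self.b):
            raise ValueError("y and b must have equal length")


@dataclass
class SigResult:
    key: tuple
    feature: str
    p_value: float
    rsq: float
    coefficients: dict[str, float]
    selected_terms: tuple[str, ...]
    p_adjusted: float = np.nan
    is_significant: bool = False
    annotation: dict = field(default_factory=dict)


def build_design(
    n_bins: int, degree: int, n_replicates: int, b: np.ndarray | None = None
) -> tuple[np.ndarray, list[str]]:
    """Design matrix {intercept, b, b^2, ..., b^degree} on centered bin indices.

    Rows are replicate-major (replicate 1 bins 1..n, replicate 2 bins 1..n,
    ...) unless explicit positions ``b`` are given (missing replicates).
    """
    if b is None:
        b = np.tile(np.arange(1, n_bins + 1, dtype=float), n_replicates)
    b = np.asarray(b, dtype=float)
    n = len(b)
    if n < degree + 2:
        raise ValueError(
            f"{n} observations cannot support degree {degree} (need >= {degree + 2})"
        )
    centered = b - b.mean()
    X = np.column_stack([centered**p for p in range(degree + 1)])
    names = ["intercept"] + [f"b^{p}" if p > 1 else "b" for p in range(1, degree + 1)]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (too few distinct bin positions)")
    return X, names


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def fit_global(obs: ProfileObservations, params: SigParams) -> dict:
    """Fit the full polynomial and F-test it against the intercept-only model.

    Returns coefficients, RSS of full and null models, the F statistic, its
    upper-tail p-value on F(degree, N - degree - 1), and the full-model
    R-squared. A zero-variance profile (all y equal) is defined to have
    p = 1 and rsq = 0 so empty/identical wells flow through.
    """
    y = np.asarray(obs.y, dtype=float)
    N = len(y)
    if N <= params.degree + 1:
        raise ValueError(f"insufficient data: N={N} for degree {params.degree}")
    X, names = build_design(0, params.degree, 0, b=obs.b)
    rss_null = float(np.sum((y - y.mean()) ** 2))
    if rss_null <= _EPS:
        return {
            "coefficients": dict.fromkeys(names, 0.0) | {"intercept": float(y.mean())},
            "rss_full": 0.0,
            "rss_null": rss_null,
            "F": 0.0,
            "p_value": 1.0,
            "rsq_full": 0.0,
            "names": names,
        }
    beta, rss_full = _ols(X, y)
    df1 = params.degree
    df2 = N - params.degree - 1
    F = ((rss_null - rss_full) / df1) / (rss_full / df2) if rss_full > _EPS else np.inf
    p_value = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return {
        "coefficients": dict(zip(names, map(float, beta))),
        "rss_full": rss_full,
        "rss_null": rss_null,
        "F": float(F),
        "p_value": p_value,
        "rsq_full": 1.0 - rss_full / rss_null,
        "names": names,
    }


def adjust_fdr_bh(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg linear step-up adjusted p-values.

    Sort ascending, scale p_(i) by m/i, enforce monotonicity from the largest
    rank down, cap at 1 and restore the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def stepwise_select(obs: ProfileObservations, params: SigParams) -> dict:
    """Backward elimination of polynomial terms by per-term t-tests.

    Starting from the full model, repeatedly drop the non-intercept term
    whose t-test p-value is largest and exceeds ``alfa``; stop when all
    remaining terms are significant at ``alfa``. The intercept is never
    dropped. The reported R-squared is the selected model's, against the
    intercept-only null; if every term drops, the model is intercept-only
    with rsq = 0.
    """
    y = np.asarray(obs.y, dtype=float)
    b = np.asarray(obs.b, dtype=float)
    centered = b - b.mean()
    rss_null = float(np.sum((y - y.mean()) ** 2))
    active = list(range(1, params.degree + 1))  # powers of the centered bin index

    def term_name(p: int) -> str:
        return f"b^{p}" if p > 1 else "b"

    if rss_null <= _EPS:
        return {"selected_terms": (), "coefficients": {"intercept": float(y.mean())}, "rsq": 0.0}

    while active:
        X = np.column_stack([np.ones_like(centered)] + [centered**p for p in active])
        N, k = X.shape
        beta, rss = _ols(X, y)
        df = N - k
        if df <= 0:
            raise ValueError("no residual degrees of freedom in selection step")
        sigma2 = rss / df
        xtx_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.inf)
        p_terms = 2.0 * stats.t.sf(np.abs(t[1:]), df)  # skip intercept
        worst = int(np.argmax(p_terms))
        if p_terms[worst] > params.alfa:
            active.pop(worst)
            continue
        coeffs = {"intercept": float(beta[0])}
        coeffs.update({term_name(p): float(c) for p, c in zip(active, beta[1:])})
        return {
            "selected_terms": tuple(term_name(p) for p in active),
            "coefficients": coeffs,
            "rsq": 1.0 - rss / rss_null,
        }
    return {"selected_terms": (), "coefficients": {"intercept": float(y.mean())}, "rsq": 0.0}


def call_significant(results: Sequence[SigResult], params: SigParams) -> list[SigResult]:
    """BH-adjust p-values per feature and apply the significance rule.

    Adjustment pools all profiles of one feature across the whole screen.
    ``is_significant = (p_adjusted < Q) and (rsq > rsq_threshold)``.
    """
    by_feature: dict[str, list[SigResult]] = {}
    for r in results:
        by_feature.setdefault(r.feature, []).append(r)
    for feature_results in by_feature.values():
        adjusted = adjust_fdr_bh([r.p_value for r in feature_results])
        for r, p_adj in zip(feature_results, adjusted):
            r.p_adjusted = float(p_adj)
            r.is_significant = bool(p_adj < params.q and r.rsq > params.rsq_threshold)
    return list(results)


def run_sigreg(profiles: pd.DataFrame, params: SigParams | None = None) -> pd.DataFrame:
    """Run the full significance analysis on a tidy profile table.

    ``profiles`` is the frame produced by :func:`sopra.profiles.compute_profiles`
    (or read back from AllDataTable.txt). One regression is fit per
    (plate, well, feature) with all replicate observations stacked. Returns a
    frame with one row per profile: ``plate, well, feature, content, rna_id,
    gene, n_replicates, p_value, p_adjusted, rsq, selected_terms,
    significant``.
    """
    params = params or SigParams()
    results: list[SigResult] = []
    for (plate, well, feature), sub in profiles.groupby(["plate", "well", "feature"], sort=True):
        sub = sub.sort_values(["replicate", "bin"])
        obs = ProfileObservations(
            key=(plate, well),
            feature=feature,
            y=sub["value"].to_numpy(float),
            b=sub["bin"].to_numpy(float),
            n_replicates=sub["replicate"].nunique(),
        )
        glob = fit_global(obs, params)
        sel = stepwise_select(obs, params)
        first = sub.iloc[0]
        results.append(
            SigResult(
                key=(plate, well),
                feature=feature,
                p_value=glob["p_value"],
                rsq=sel["rsq"],
                coefficients=sel["coefficients"],
                selected_terms=sel["selected_terms"],
                annotation={
                    "content": first["content"],
                    "rna_id": first["rna_id"],
                    "gene": first["gene"],
                    "n_replicates": obs.n_replicates,
                },
            )
        )
    call_significant(results, params)
    return pd.DataFrame(
        {
            "plate": [r.key[0] for r in results],
            "well": [r.key[1] for r in results],
            "feature": [r.feature for r in results],
            "content": [r.annotation["content"] for r in results],
            "rna_id": [r.annotation["rna_id"] for r in results],
            "gene": [r.annotation["gene"] for r in results],
            "n_replicates": [r.annotation["n_replicates"] for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "rsq": [r.rsq for r in results],
            "selected_terms": [",".join(r.selected_terms) for r in results],
            "significant": [r.is_significant for r in results],
        }
    )
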