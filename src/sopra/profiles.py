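"""Plate-wise normalization, shared binning and control-based profile normalization.

The pipeline turns per-object feature values into one *normalized frequency
distribution profile* per (plate, replicate, well, feature):

1. **Plate-wise normalization** — every object's value is divided by the
   median value of the neutral-control objects on the same plate pass,
   removing multiplicative plate effects (staining, exposure).
2. **Shared bin axis** — a single equal-width binning grid per feature is
   built from the pooled normalized values of the whole screen, so profiles
   from different plates are directly comparable. With ``n`` bins the width
   is ``L = (upper - lower) / n`` and the split points are
   ``s_k = lower + L*k`` for ``k = 1..n-1``; by default ``lower``/``upper``
   are the min and max, optionally percentiles with out-of-range values
   clamped into the edge bins.
3. **Histogram + pseudocount** — objects are counted per bin and a
   pseudocount of 1 is added to every bin so no bin is empty; counts are
   converted to relative frequencies (divide by the population size).
4. **Bin-wise control normalization** — each bin's relative frequency is
   divided by the median relative frequency of the neutral-control wells in
   the same bin. On the log2 scale a well distributed exactly like the
   controls therefore has an all-zero profile, the null the downstream
   regression tests against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .screen_io import ContentType

__all__ = [
    "BinAxis",
    "WellKey",
    "RawHistogram",
    "RelFreqProfile",
    "NormalizedProfile",
    "DegenerateAxisError",
    "NormalizationError",
    "platewise_normalize",
    "compute_bin_axis",
    "histogram_well",
    "relative_freq",
    "control_reference",
    "binwise_normalize",
    "compute_profiles",
]

DEFAULT_N_BINS = 7

Scale = Literal["ratio", "log2"]


class DegenerateAxisError(ValueError):
    """All pooled values identical: no binning grid can be built."""


class NormalizationError(ValueError):
    """Control-based normalization is impossible (no/zero-median controls)."""


@dataclass(frozen=True)
class WellKey:
    plate: str
    replicate: int
    well: int


@dataclass(frozen=True)
class BinAxis:
    """Equal-width binning grid shared by every well of a screen/feature."""

    feature: str
    n: int
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"need at least one bin, got {self.n}")
        if not self.upper > self.lower:
            raise DegenerateAxisError(
                f"{self.feature}: axis limits degenerate ({self.lower} .. {self.upper})"
            )

    @property
    def width_L(self) -> float:
        return (self.upper - self.lower) / self.n

    @property
    def split_points(self) -> np.ndarray:
        return self.lower + self.width_L * np.arange(1, self.n)


@dataclass(frozen=True)
class RawHistogram:
    """Per-well bin counts *after* the +1 pseudocount."""

    key: WellKey
    feature: str
    counts: np.ndarray

    @property
    def population_size(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class RelFreqProfile:
    key: WellKey
    feature: str
    rel_freq: np.ndarray


@dataclass(frozen=True)
class NormalizedProfile:
    key: WellKey
    feature: str
    values: np.ndarray
    scale: Scale
    annotation: dict = field(default_factory=dict)


def platewise_normalize(
    cells: pd.DataFrame,
    feature: str,
    control_type: ContentType = ContentType.NEUTRAL_CONTROL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Divide each object's feature value by its plate pass's control median.

    The control median is taken over all objects of ``control_type`` wells on
    the same (plate, replicate). Plate passes without control objects, or
    whose control median is zero, are excluded and recorded in the report.

    Returns the cell table with an added ``<feature>__norm`` column and a
    report frame (plate, replicate, control_median, n_control_objects,
    error) with one row per plate pass.
    """
    out = cells.reset_index(drop=True).copy()
    norm_col = f"{feature}__norm"
    out[norm_col] = np.nan
    records = []
    keep = np.zeros(len(out), dtype=bool)
    for (plate, rep), idx in out.groupby(["plate", "replicate"]).groups.items():
        sub = out.loc[idx]
        ctrl = sub.loc[sub["content"] == control_type.value, feature].to_numpy(float)
        if ctrl.size == 0:
            records.append((plate, rep, np.nan, 0, "no control objects"))
            continue
        med = float(np.median(ctrl))
        if med == 0.0:
            records.append((plate, rep, med, ctrl.size, "control median is zero"))
            continue
        out.loc[idx, norm_col] = sub[feature].to_numpy(float) / med
        keep[out.index.get_indexer(idx)] = True
        records.append((plate, rep, med, ctrl.size, ""))
    report = pd.DataFrame(
        records, columns=["plate", "replicate", "control_median", "n_control_objects", "error"]
    )
    if not keep.any():
        raise NormalizationError(f"{feature}: no plate pass has usable control objects")
    return out[keep].reset_index(drop=True), report


def compute_bin_axis(
    values: Sequence[float] | np.ndarray,
    feature: str = "",
    n: int = DEFAULT_N_BINS,
    lower_pct: float = 0.0,
    upper_pct: float = 100.0,
) -> BinAxis:
    """Build the screen-wide bin axis from all pooled (normalized) values.

    Defaults (percentiles 0/100) use the min and max of the pooled data;
    trimming percentiles clamp tail values into the edge bins downstream.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise DegenerateAxisError(f"{feature}: need at least two values to build an axis")
    lower = float(np.percentile(arr, lower_pct))
    upper = float(np.percentile(arr, upper_pct))
    if not upper > lower:
        raise DegenerateAxisError(f"{feature}: axis limits degenerate ({lower} .. {upper})")
    return BinAxis(feature=feature, n=n, lower=lower, upper=upper)


def _bin_indices(values: np.ndarray, axis: BinAxis) -> np.ndarray:
    # Half-open bins [s_{k-1}, s_k), last bin closed; values at a split point
    # go to the upper bin; out-of-range values are clamped into edge bins.
    idx = np.floor((values - axis.lower) / axis.width_L).astype(int)
    return np.clip(idx, 0, axis.n - 1)


def histogram_well(values: Sequence[float] | np.ndarray, axis: BinAxis) -> np.ndarray:
    """Count values per bin and add the +1 pseudocount to every bin.

    An empty well therefore yields all-ones counts (population size ``n``).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size:
        counts = np.bincount(_bin_indices(arr, axis), minlength=axis.n)
    else:
        counts = np.zeros(axis.n, dtype=int)
    return counts + 1


def relative_freq(counts: np.ndarray | RawHistogram) -> np.ndarray:
    """Relative frequency per bin: counts divided by the population size."""
    arr = counts.counts if isinstance(counts, RawHistogram) else np.asarray(counts)
    total = arr.sum()
    if total <= 0:
        raise ValueError("population size must be positive")
    return arr / total


def control_reference(control_rel_freqs: Sequence[np.ndarray]) -> np.ndarray:
    """Bin-wise median profile over the control wells in scope."""
    if len(control_rel_freqs) == 0:
        raise NormalizationError("no control profiles in scope")
    return np.median(np.vstack(control_rel_freqs), axis=0)


def binwise_normalize(
    test_rel_freq: np.ndarray, reference: np.ndarray, scale: Scale = "log2"
) -> np.ndarray:
    """Divide a well's relative frequencies bin-by-bin by the control reference.

    With ``scale='log2'`` the ratio is log2-transformed, so a test
    distribution equal to the reference gives an exactly-zero profile.
    """
    reference = np.asarray(reference, dtype=float)
    if np.any(reference <= 0):
        raise NormalizationError("reference profile has non-positive bins")
    ratio = np.asarray(test_rel_freq, dtype=float) / reference
    return np.log2(ratio) if scale == "log2" else ratio


def compute_profiles(
    cells: pd.DataFrame,
    features: Sequence[str],
    n_bins: int = DEFAULT_N_BINS,
    lower_pct: float = 0.5,
    upper_pct: float = 99.5,
    scale: Scale = "log2",
    reference_scope: Literal["per_plate", "screen_wide"] = "per_plate",
    control_type: ContentType = ContentType.NEUTRAL_CONTROL,
) -> tuple[pd.DataFrame, dict[str, BinAxis]]:
    """Run the full normalization chain for every feature of a cell table.

    Returns a tidy frame with one row per (plate, replicate, well, feature,
    bin) — columns ``plate, replicate, well, content, rna_id, gene, feature,
    bin, count, rel_freq, value, scale`` — plus the per-feature bin axes.
    Replicates are never pooled: each plate pass yields its own profile.
    """
    if cells.empty:
        raise ValueError("empty cell table")
    rows: list[dict] = []
    axes: dict[str, BinAxis] = {}
    for feature in features:
        normed, _report = platewise_normalize(cells, feature, control_type)
        col = f"{feature}__norm"
        axis = compute_bin_axis(normed[col].to_numpy(), feature, n_bins, lower_pct, upper_pct)
        axes[feature] = axis

        well_groups = normed.groupby(["plate", "replicate", "well"], sort=True)
        meta: dict[tuple, tuple] = {}
        rel: dict[tuple, np.ndarray] = {}
        cnt: dict[tuple, np.ndarray] = {}
        for key, sub in well_groups:
            counts = histogram_well(sub[col].to_numpy(), axis)
            cnt[key] = counts
            rel[key] = relative_freq(counts)
            first = sub.iloc[0]
            meta[key] = (first["content"], first.get("rna_id"), first.get("gene"))

        ctrl_keys = [k for k, m in meta.items() if m[0] == control_type.value]
        if reference_scope == "screen_wide":
            ref_all = control_reference([rel[k] for k in ctrl_keys])
            references = {None: ref_all}
        else:
            references = {}
            for k in ctrl_keys:
                references.setdefault(k[:2], []).append(rel[k])
            references = {pk: control_reference(v) for pk, v in references.items()}

        for key in sorted(rel):
            if reference_scope == "screen_wide":
                ref = references[None]
            else:
                ref = references.get(key[:2])
                if ref is None:
                    raise NormalizationError(
                        f"{feature}: plate pass {key[:2]} has no control profiles"
                    )
            values = binwise_normalize(rel[key], ref, scale)
            content, rna_id, gene = meta[key]
            for b in range(axis.n):
                rows.append(
                    {
                        "plate": key[0],
                        "replicate": key[1],
                        "well": key[2],
                        "content": content,
                        "rna_id": rna_id,
                        "gene": gene,
                        "feature": feature,
                        "bin": b + 1,
                        "count": int(cnt[key][b]),
                        "rel_freq": float(rel[key][b]),
                        "value": float(values[b]),
                        "scale": scale,
                    }
                )
    return pd.DataFrame(rows), axes
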