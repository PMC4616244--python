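"""Reanalysis of tabulated grid-period data.

Procedure for estimating the adjacent-scale ratio from per-animal lists
of grid periods: periods within 20% of each other are grouped into
modules ("scales"), each scale being the group mean; adjacent-scale
ratios are computed per animal and pooled across animals; animals with a
single scale are excluded.  A separate helper converts published
period-to-field-radius ratios to period-to-field-diameter ratios by
halving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "RatioStatistics",
    "group_periods",
    "adjacent_ratios",
    "ratio_statistics",
    "radius_to_diameter_ratio",
    "load_period_table",
    "per_animal_scales",
]

TableLike = Union[pd.DataFrame, Mapping[str, Sequence[float]]]


@dataclass(frozen=True)
class RatioStatistics:
    """Pooled adjacent-ratio statistics: mean, sample sd (n-1), count."""

    mean: float
    sd: Optional[float]
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("need at least one ratio")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be nonnegative")


def group_periods(periods: Iterable[float], rel_threshold: float = 0.2) -> list:
    """Group similar periods into scales; return group means, descending.

    Periods are sorted ascending and chained greedily: a period joins the
    current group when it lies within ``rel_threshold`` (relative) of the
    running group mean, otherwise it starts a new group.  Sorting first
    makes the result independent of input order.
    """
    vals = sorted(float(p) for p in periods)
    if not vals:
        raise ValueError("empty period list")
    if vals[0] <= 0:
        raise ValueError("periods must be positive")
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must lie in (0, 1)")
    groups = [[vals[0]]]
    for p in vals[1:]:
        mean = sum(groups[-1]) / len(groups[-1])
        if abs(p - mean) / mean < rel_threshold:
            groups[-1].append(p)
        else:
            groups.append([p])
    return sorted((sum(g) / len(g) for g in groups), reverse=True)


def adjacent_ratios(scales: Sequence[float]) -> list:
    """Ratios λ_i/λ_{i+1} of a strictly descending scale list."""
    scales = [float(s) for s in scales]
    if any(b >= a for a, b in zip(scales, scales[1:])):
        raise ValueError("scales must be strictly descending")
    return [a / b for a, b in zip(scales, scales[1:])]


def _iter_animals(tables: TableLike):
    if isinstance(tables, pd.DataFrame):
        cols = {c.lower(): c for c in tables.columns}
        id_col = cols.get("animal_id")
        period_col = cols.get("period_cm") or cols.get("period")
        if id_col is None or period_col is None:
            raise ValueError("table needs columns animal_id and period_cm")
        for aid, sub in tables.groupby(id_col, sort=True):
            yield str(aid), list(sub[period_col].astype(float))
    else:
        for aid in sorted(tables):
            yield str(aid), [float(p) for p in tables[aid]]


def per_animal_scales(tables: TableLike, rel_threshold: float = 0.2) -> dict:
    """Grouped scales (descending means) per animal."""
    return {
        aid: group_periods(periods, rel_threshold)
        for aid, periods in _iter_animals(tables)
    }


def ratio_statistics(tables: TableLike, rel_threshold: float = 0.2) -> RatioStatistics:
    """Pool adjacent-scale ratios across animals and summarize.

    Animals whose grouped periods yield fewer than two scales contribute
    no ratios and are excluded.  The sd is the sample standard deviation
    (n-1 denominator), reported as None for a single pooled ratio.
    """
    pooled = []
    for aid, periods in _iter_animals(tables):
        scales = group_periods(periods, rel_threshold)
        pooled.extend(adjacent_ratios(scales))
    if not pooled:
        raise ValueError("no animal produced two or more scales")
    n = len(pooled)
    mean = float(np.mean(pooled))
    sd = float(np.std(pooled, ddof=1)) if n >= 2 else None
    return RatioStatistics(mean=mean, sd=sd, n=n)


def radius_to_diameter_ratio(period_over_radius: float) -> float:
    """Convert a period/field-radius ratio to period/field-diameter: halve it."""
    if period_over_radius <= 0:
        raise ValueError("ratio must be positive")
    return period_over_radius / 2.0


def load_period_table(path) -> pd.DataFrame:
    """Read a per-animal period table (CSV with columns animal_id, period_cm)."""
    df = pd.read_csv(path)
    cols = {c.lower() for c in df.columns}
    if "animal_id" not in cols or not ({"period_cm", "period"} & cols):
        raise ValueError("CSV must have columns animal_id and period_cm")
    return df
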