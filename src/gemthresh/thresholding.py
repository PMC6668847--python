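"""Expression thresholding: global and local percentile-bounded schemes.

A *global* scheme applies one cutoff — a percentile of the pooled
distribution of all matrix entries — to every gene (two states, OFF/ON).
A *local* scheme gives each gene its own cutoff, its mean across samples,
clamped from below by a global lower percentile bound (T1: OFF / MAYBE-ON)
and, for the three-state T2 variant, from above by a global upper bound
(OFF / MAYBE-ON / ON).  The clamps guarantee that genes always below the
lower bound are never called ON and, under T2, genes always above the upper
bound are always ON.

Named presets: global50, global75, local25, local25-75, local25-90
(numbers are pooled-distribution percentiles).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import ExpressionMatrix

__all__ = [
    "ThresholdScheme",
    "ThresholdSet",
    "PRESETS",
    "percentile_bounds",
    "local_thresholds",
    "apply_thresholds",
    "gene_states",
    "OFF",
    "ON",
    "ALWAYS_OFF",
    "MAYBE_ON",
    "ALWAYS_ON",
]

GLOBAL = "global"
LOCAL = "local"

OFF = "OFF"
ON = "ON"
ALWAYS_OFF = "always-OFF"
MAYBE_ON = "MAYBE-ON"
ALWAYS_ON = "always-ON"


@dataclass(frozen=True)
class ThresholdScheme:
    """approach ('global'|'local'), lower percentile, optional upper percentile.

    An upper percentile is only legal for local schemes (the three-state T2
    definition); a global scheme is single-threshold by construction.
    """

    approach: str
    p_low: float
    p_up: float | None = None

    def __post_init__(self) -> None:
        if self.approach not in (GLOBAL, LOCAL):
            raise ValueError(f"unknown approach {self.approach!r}")
        if not 0 < self.p_low < 100:
            raise ValueError("p_low must be in (0, 100)")
        if self.p_up is not None:
            if self.approach == GLOBAL:
                raise ValueError("global schemes take a single threshold (no upper bound)")
            if not self.p_low < self.p_up < 100:
                raise ValueError("p_up must be in (p_low, 100)")

    @property
    def is_t2(self) -> bool:
        return self.p_up is not None

    @property
    def name(self) -> str:
        if self.approach == GLOBAL:
            return f"global{self.p_low:g}"
        if self.p_up is None:
            return f"local{self.p_low:g}"
        return f"local{self.p_low:g}-{self.p_up:g}"


PRESETS: dict[str, ThresholdScheme] = {
    "global50": ThresholdScheme(GLOBAL, 50),
    "global75": ThresholdScheme(GLOBAL, 75),
    "local25": ThresholdScheme(LOCAL, 25),
    "local25-75": ThresholdScheme(LOCAL, 25, 75),
    "local25-90": ThresholdScheme(LOCAL, 25, 90),
}


@dataclass
class ThresholdSet:
    """Per-entity thresholds plus the global bound value(s) that shaped them."""

    thresholds: pd.Series  # entity -> threshold value
    lower: float
    upper: float | None = None


def percentile_bounds(expr: ExpressionMatrix, percentiles) -> np.ndarray:
    """Percentiles of the pooled distribution of *all* matrix entries.

    Linear sorted-order interpolation (index h = (n-1) * p / 100), zeros
    included in the pool.
    """
    pooled = expr.pooled_values()
    if pooled.size == 0:
        raise ValueError("empty expression matrix")
    return np.percentile(pooled, np.asarray(percentiles, dtype=float), method="linear")


def local_thresholds(
    gene_means: pd.Series, lower: float, upper: float | None = None
) -> ThresholdSet:
    """Clamp per-gene means into [lower, upper]: t_g = min(upper, max(lower, mean_g)).

    With ``upper=None`` (T1) only the lower clamp applies.
    """
    if upper is not None and lower > upper:
        raise ValueError("lower bound exceeds upper bound")
    t = gene_means.clip(lower=lower)
    if upper is not None:
        t = t.clip(upper=upper)
    return ThresholdSet(thresholds=t.astype(float), lower=lower, upper=upper)


def apply_thresholds(values: pd.DataFrame, thresholds: ThresholdSet | float) -> pd.DataFrame:
    """Zero out sub-threshold entries: activity = value if value >= t else 0.

    An entity is "active" in a sample iff its activity is > 0 (a value of 0
    never counts as active even when the threshold is 0).  NaN (no-data)
    entries pass through unchanged.
    """
    if isinstance(thresholds, ThresholdSet):
        t = thresholds.thresholds.reindex(values.index)
        if t.isna().any():
            missing = list(t.index[t.isna()])[:5]
            raise ValueError(f"no threshold for entities {missing}")
        arr = t.to_numpy(dtype=float)[:, None]
    else:
        arr = float(thresholds)
    vals = values.to_numpy(dtype=float)
    out = np.where(vals >= arr, vals, 0.0)
    out[np.isnan(vals)] = np.nan
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def scheme_thresholds(expr: ExpressionMatrix, scheme: ThresholdScheme) -> ThresholdSet:
    """Gene-level thresholds for a scheme applied to an expression matrix."""
    if scheme.approach == GLOBAL:
        (bound,) = percentile_bounds(expr, [scheme.p_low])
        t = pd.Series(bound, index=expr.data.index, dtype=float)
        return ThresholdSet(thresholds=t, lower=float(bound))
    ps = [scheme.p_low] + ([scheme.p_up] if scheme.is_t2 else [])
    bounds = percentile_bounds(expr, ps)
    lower = float(bounds[0])
    upper = float(bounds[1]) if scheme.is_t2 else None
    means = expr.data.mean(axis=1)
    return local_thresholds(means, lower, upper)


def gene_states(
    expr: ExpressionMatrix, scheme: ThresholdScheme
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene per-sample ON/OFF states plus a per-gene category.

    Categories: ``always-OFF`` (expression never reaches the effective
    threshold region), ``always-ON`` (T2 only: min expression at or above
    the upper bound), otherwise ``MAYBE-ON``.  States agree with
    :func:`apply_thresholds`.
    """
    tset = scheme_thresholds(expr, scheme)
    activity = apply_thresholds(expr.data, tset)
    states = activity.gt(0).replace({True: ON, False: OFF})

    gmax = expr.data.max(axis=1)
    gmin = expr.data.min(axis=1)
    if scheme.approach == GLOBAL:
        cat = pd.Series(MAYBE_ON, index=expr.data.index)
        cat[gmax < tset.lower] = ALWAYS_OFF
    else:
        means = expr.data.mean(axis=1)
        cat = pd.Series(MAYBE_ON, index=expr.data.index)
        cat[(means <= tset.lower) & (gmax < tset.lower)] = ALWAYS_OFF
        if tset.upper is not None:
            cat[(means >= tset.upper) & (gmin >= tset.upper)] = ALWAYS_ON
    return states, cat
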