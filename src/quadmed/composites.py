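"""Measurement composites: reverse scoring, scale scoring, internal consistency."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CompositeSpec", "CompositeResult", "reverse_score", "build_composite",
           "cronbach_alpha"]


@dataclass
class CompositeSpec:
    """How to score a set of indicators into one composite.

    ``mode`` is ``"mean_raw"`` (mean of possibly reverse-scored raw
    indicators, requires scale bounds) or ``"standardize_average"``
    (mean of per-indicator z scores).
    """

    indicator_names: list
    reverse_flags: list = field(default_factory=list)
    scale_min: float | None = None
    scale_max: float | None = None
    mode: str = "mean_raw"
    min_prop_observed: float = 0.5

    def __post_init__(self) -> None:
        if not self.indicator_names:
            raise ValueError("at least one indicator is required")
        if not self.reverse_flags:
            self.reverse_flags = [False] * len(self.indicator_names)
        if len(self.reverse_flags) != len(self.indicator_names):
            raise ValueError("reverse_flags length must equal indicator count")
        if self.mode not in ("mean_raw", "standardize_average"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "mean_raw" and (self.scale_min is None or self.scale_max is None):
            raise ValueError("mean_raw mode requires scale_min and scale_max")
        if any(self.reverse_flags) and (self.scale_min is None or self.scale_max is None):
            raise ValueError("reverse scoring requires scale_min and scale_max")


@dataclass
class CompositeResult:
    scores: pd.Series
    alpha: float
    n_used: int


def reverse_score(values, scale_min: float, scale_max: float):
    """Reflect values about the scale midpoint: ``min + max - value``.

    Missing values propagate.  Out-of-bounds observed values raise,
    naming the offending positions.
    """
    arr = np.asarray(values, dtype=float)
    observed = ~np.isnan(arr)
    bad = observed & ((arr < scale_min) | (arr > scale_max))
    if bad.any():
        where = np.argwhere(bad).ravel().tolist()
        raise ValueError(
            f"values outside [{scale_min}, {scale_max}] at positions {where}"
        )
    out = scale_min + scale_max - arr
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def cronbach_alpha(indicators: pd.DataFrame) -> float:
    """Cronbach's alpha, ``(k/(k-1)) * (1 - sum item var / var of total)``.

    Computed on listwise-complete cases with unbiased (n-1) variances.
    Negative values are reported as-is, never clipped.
    """
    df = pd.DataFrame(indicators)
    k = df.shape[1]
    if k < 2:
        raise ValueError("cronbach_alpha is undefined for fewer than 2 indicators")
    complete = df.dropna()
    if len(complete) < 3:
        raise ValueError("cronbach_alpha needs at least 3 complete cases")
    item_vars = complete.var(ddof=1)
    total_var = complete.sum(axis=1).var(ddof=1)
    if total_var == 0:
        if item_vars.sum() == 0:
            raise ValueError("all indicators are constant")
        return float("-inf")  # perfectly anticorrelated items: alpha diverges
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def build_composite(indicators: pd.DataFrame, spec: CompositeSpec) -> CompositeResult:
    """Score indicators into a composite per ``spec``.

    A case's composite is the mean over its observed (transformed)
    indicators when at least ``min_prop_observed`` of them are present,
    else missing.  Alpha is computed on the same transformed indicators.
    """
    df = pd.DataFrame(indicators)[list(spec.indicator_names)].astype(float)

    for name, flip in zip(spec.indicator_names, spec.reverse_flags):
        if flip:
            try:
                df[name] = reverse_score(df[name], spec.scale_min, spec.scale_max)
            except ValueError as err:
                raise ValueError(f"indicator {name!r}: {err}") from err

    if spec.mode == "standardize_average":
        for name in spec.indicator_names:
            col = df[name]
            sd = col.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(
                    f"indicator {name!r} has zero variance; cannot standardize"
                )
            df[name] = (col - col.mean()) / sd

    n_obs = df.notna().sum(axis=1)
    enough = n_obs >= max(1, int(np.ceil(spec.min_prop_observed * df.shape[1])))
    scores = df.mean(axis=1).where(enough)

    if df.shape[1] >= 2:
        try:
            alpha = cronbach_alpha(df)
        except ValueError:
            alpha = float("nan")
    else:
        alpha = float("nan")
    return CompositeResult(scores=scores, alpha=alpha, n_used=int(scores.notna().sum()))
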