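"""Bootstrapped regions of significance for the slope of a quadratic curve.

Cases are resampled with replacement; each replicate refits
``y ~ b0 + b1*x + b2*x^2`` and records the instantaneous slope
``b1 + 2*b2*x`` on a fixed grid spanning the observed predictor range.
Grid points whose percentile interval excludes zero form the regions of
significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .path_fiml import PathModelSpec, fit_path_model
from .synthetic import LongitudinalDataset

__all__ = ["RoSConfig", "RoSResult", "residualize", "ros", "region_coverage"]

# absolute guard against floating noise when all replicates agree exactly
_SIG_ATOL = 1e-12


@dataclass
class RoSConfig:
    n_boot: int = 1000
    grid_n: int = 100
    level: float = 0.95
    seed: int = 0
    refit_method: str = "complete_case_ls"
    max_redraws_per_replicate: int = 100

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.grid_n < 2:
            raise ValueError("grid_n must be >= 2")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        if self.refit_method not in ("complete_case_ls", "fiml"):
            raise ValueError(f"unknown refit_method {self.refit_method!r}")


@dataclass
class RoSResult:
    grid_x: np.ndarray
    mean_slope: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray
    regions: list = field(default_factory=list)
    sample_proportions: list = field(default_factory=list)
    n_failed_boot: int = 0
    n_cases: int = 0
    config: RoSConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grid_x": self.grid_x,
                "mean_slope": self.mean_slope,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "significant": self.significant,
            }
        )


def residualize(
    data: LongitudinalDataset,
    outcome: str,
    covariates: list,
    method: str = "fiml",
) -> pd.Series:
    """Residuals of ``outcome`` after regressing it on ``covariates``.

    The regression is estimated by FIML by default so every partially
    observed case informs the coefficients; residuals themselves are
    defined only where the outcome and all covariates are observed.
    With no covariates this is mean-centering.
    """
    frame = data.values
    for v in [outcome, *covariates]:
        if v not in frame.columns:
            raise ValueError(f"variable {v!r} not in data")
    if not covariates:
        return frame[outcome] - frame[outcome].mean()

    complete = frame[list(covariates)].dropna()
    design = np.column_stack([np.ones(len(complete)), complete.to_numpy(float)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"covariates are rank deficient: {list(covariates)}")

    if method == "fiml":
        spec = PathModelSpec(equations=[(outcome, list(covariates))])
        fitted = fit_path_model(data, spec, compute_se=False)
        intercept = fitted.get(f"{outcome}~1")
        coefs = np.array([fitted.get(f"{outcome}~{v}") for v in covariates])
    elif method == "ols":
        rows = frame[[outcome, *covariates]].dropna()
        X = np.column_stack([np.ones(len(rows)), rows[list(covariates)].to_numpy(float)])
        beta, *_ = np.linalg.lstsq(X, rows[outcome].to_numpy(float), rcond=None)
        intercept, coefs = beta[0], beta[1:]
    else:
        raise ValueError(f"unknown method {method!r}")

    predicted = intercept + frame[list(covariates)].to_numpy(float) @ coefs
    residuals = frame[outcome] - predicted
    return pd.Series(residuals, index=frame.index, name=f"{outcome}_resid")


def _fit_quadratic_ls(x: np.ndarray, y: np.ndarray):
    if np.unique(x).size < 3:
        raise np.linalg.LinAlgError("fewer than 3 distinct predictor values")
    X = np.column_stack([np.ones_like(x), x, x * x])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise np.linalg.LinAlgError("rank-deficient quadratic design")
    return beta


def _fit_quadratic_fiml(x: np.ndarray, y: np.ndarray):
    frame = pd.DataFrame({"y": y, "x": x, "x2": x * x})
    spec = PathModelSpec(equations=[("y", ["x", "x2"])])
    fitted = fit_path_model(LongitudinalDataset.from_frame(frame), spec,
                            compute_se=False)
    return np.array([fitted.get("y~1"), fitted.get("y~x"), fitted.get("y~x2")])


def ros(x, y, config: RoSConfig) -> RoSResult:
    """Bootstrap the quadratic slope ``b1 + 2 b2 x`` over a predictor grid.

    The grid has ``grid_n`` evenly spaced points from min(x) to max(x)
    inclusive.  Per grid point the replicate mean slope and the
    ``(1-level)/2`` / ``1-(1-level)/2`` empirical percentiles are
    reported; a point is significant when that interval excludes zero.
    Degenerate resamples are redrawn (and counted) up to a cap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if config.refit_method == "complete_case_ls":
        keep = ~(np.isnan(x) | np.isnan(y))
    else:
        keep = ~np.isnan(x)  # FIML refits tolerate missing y
    x, y = x[keep], y[keep]
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 paired observations")
    if np.nanstd(x) == 0:
        raise ValueError("predictor has zero variance")

    grid = np.linspace(np.nanmin(x), np.nanmax(x), config.grid_n)
    fit_one = (
        _fit_quadratic_ls if config.refit_method == "complete_case_ls"
        else _fit_quadratic_fiml
    )
    rng = np.random.default_rng(config.seed)
    slopes = np.empty((config.n_boot, config.grid_n))
    n_failed = 0
    for rep in range(config.n_boot):
        for _ in range(config.max_redraws_per_replicate):
            idx = rng.integers(0, n, size=n)
            try:
                b0, b1, b2 = fit_one(x[idx], y[idx])
            except np.linalg.LinAlgError:
                n_failed += 1
                continue
            slopes[rep] = b1 + 2.0 * b2 * grid
            break
        else:
            raise RuntimeError(
                f"replicate {rep}: exceeded {config.max_redraws_per_replicate} redraws"
            )

    tail = (1.0 - config.level) / 2.0
    mean_slope = slopes.mean(axis=0)
    ci_low = np.quantile(slopes, tail, axis=0)
    ci_high = np.quantile(slopes, 1.0 - tail, axis=0)
    significant = (ci_low > _SIG_ATOL) | (ci_high < -_SIG_ATOL)

    result = RoSResult(
        grid_x=grid,
        mean_slope=mean_slope,
        ci_low=ci_low,
        ci_high=ci_high,
        significant=significant,
        n_failed_boot=n_failed,
        n_cases=n,
        config=config,
    )
    result.regions = _contiguous_regions(grid, mean_slope, significant)
    result.sample_proportions = region_coverage(result, x)
    return result


def _contiguous_regions(grid, mean_slope, significant):
    """Maximal runs of significant grid points, split on slope sign change."""
    regions = []
    start = None
    sign = 0
    for i in range(len(grid)):
        s = int(np.sign(mean_slope[i])) if significant[i] else 0
        if significant[i] and (start is None or s != sign):
            if start is not None:
                regions.append(_region(grid, start, i - 1, sign))
            start, sign = i, s
        elif not significant[i] and start is not None:
            regions.append(_region(grid, start, i - 1, sign))
            start = None
    if start is not None:
        regions.append(_region(grid, start, len(grid) - 1, sign))
    return regions


def _region(grid, i0, i1, sign):
    return {
        "x_low": float(grid[i0]),
        "x_high": float(grid[i1]),
        "slope_sign": "positive" if sign > 0 else "negative",
    }


def region_coverage(result: RoSResult, x) -> list:
    """Proportion of observed cases falling inside each significant region."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    out = []
    for region in result.regions:
        inside = (x >= region["x_low"]) & (x <= region["x_high"])
        out.append(float(inside.mean()) if x.size else float("nan"))
    return out
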