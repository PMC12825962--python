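"""Geometry of inverted-U quadratic dose-response curves.

Given a fitted quadratic ``y = b0 + b1*x + b2*x^2`` on a centered
predictor, locates the vertex (turning point), reflects a low-dose
reference point about it to find the inflection beyond which the curve
falls below the low-dose level, and partitions cases into
strengthening / buffering / toxic zones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["QuadraticFit", "HormesisZones", "vertex", "zone_boundaries",
           "classify_zones", "curve_profile", "plot_zones"]

ZONE_ORDER = ("strengthening", "buffering", "toxic")


@dataclass
class QuadraticFit:
    """Coefficients of ``y ~ b0 + b1*x + b2*x^2`` on a centered predictor.

    ``x_mean``/``x_sd`` are the raw-predictor moments used for centering,
    so results can be reported on both centered and raw scales.
    """

    b0: float
    b1: float
    b2: float
    x_mean: float
    x_sd: float

    def __post_init__(self) -> None:
        if self.x_sd <= 0:
            raise ValueError("x_sd must be > 0")

    def predict(self, x_centered):
        x = np.asarray(x_centered, dtype=float)
        return self.b0 + self.b1 * x + self.b2 * x**2

    @property
    def orientation(self) -> str:
        if self.b2 < 0:
            return "inverted_u"
        if self.b2 > 0:
            return "u_shaped"
        return "linear"


@dataclass
class HormesisZones:
    vertex_centered: float
    vertex_raw: float
    inflection_centered: float
    inflection_raw: float
    reference_low_raw: float
    orientation: str
    extrapolated: bool = False
    zone_labels: pd.Series | None = None
    zone_percentages: dict = field(default_factory=dict)


def vertex(fit: QuadraticFit):
    """Turning point of the parabola: ``-b1/(2 b2)`` centered, plus raw.

    Returns ``(vertex_centered, vertex_raw)``; both are None when the
    curve is linear (``b2 == 0``).
    """
    if fit.b2 == 0:
        return None, None
    vc = -fit.b1 / (2.0 * fit.b2)
    return float(vc), float(vc + fit.x_mean)


def zone_boundaries(
    fit: QuadraticFit,
    reference_low: float | None = None,
    x_range: tuple | None = None,
) -> HormesisZones:
    """Vertex and resilience inflection point of an inverted-U curve.

    ``reference_low`` is the raw-scale low-dose comparison point,
    defaulting to ``x_mean - x_sd``.  The inflection is its reflection
    about the vertex -- the far-side solution of
    ``f(x) = f(reference_low)`` -- so curve values beyond it fall below
    the low-dose level.
    """
    if fit.b2 >= 0:
        raise ValueError(
            f"zone boundaries require an inverted-U curve (b2 < 0); "
            f"orientation is {fit.orientation!r}"
        )
    if reference_low is None:
        reference_low = fit.x_mean - fit.x_sd
    vc, vr = vertex(fit)
    if reference_low >= vr:
        raise ValueError(
            f"reference_low ({reference_low}) must lie below the raw vertex ({vr})"
        )
    inflection_raw = 2.0 * vr - reference_low
    inflection_centered = inflection_raw - fit.x_mean
    extrapolated = False
    if x_range is not None:
        lo, hi = x_range
        extrapolated = not (lo <= vr <= hi)
    return HormesisZones(
        vertex_centered=vc,
        vertex_raw=vr,
        inflection_centered=inflection_centered,
        inflection_raw=inflection_raw,
        reference_low_raw=float(reference_low),
        orientation=fit.orientation,
        extrapolated=extrapolated,
    )


def classify_zones(x_raw, zones: HormesisZones) -> HormesisZones:
    """Label each observed case by zone and attach zone percentages.

    Intervals are half-open with boundary cases assigned to the
    right-hand zone: strengthening ``(-inf, vertex)``, buffering
    ``[vertex, inflection)``, toxic ``[inflection, inf)``.  Percentages
    are over non-missing cases and sum to 100.
    """
    x = pd.Series(np.asarray(x_raw, dtype=float))
    observed = x.notna()
    if not observed.any():
        raise ValueError("all predictor values are missing")
    labels = pd.Series(pd.NA, index=x.index, dtype="object")
    labels[observed & (x < zones.vertex_raw)] = "strengthening"
    labels[observed & (x >= zones.vertex_raw) & (x < zones.inflection_raw)] = "buffering"
    labels[observed & (x >= zones.inflection_raw)] = "toxic"
    n = int(observed.sum())
    percentages = {
        zone: 100.0 * float((labels == zone).sum()) / n for zone in ZONE_ORDER
    }
    zones.zone_labels = labels
    zones.zone_percentages = percentages
    return zones


def curve_profile(
    fit: QuadraticFit, half_width_sd: float = 1.0, n_points: int = 101
) -> pd.DataFrame:
    """Model-implied curve over ``mean +/- half_width_sd * SD`` of x.

    Returns a table of ``(x_raw, x_centered, y)`` suitable for plotting.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    half = half_width_sd * fit.x_sd
    x_centered = np.linspace(-half, half, n_points)
    return pd.DataFrame(
        {
            "x_raw": x_centered + fit.x_mean,
            "x_centered": x_centered,
            "y": fit.predict(x_centered),
        }
    )


def plot_zones(fit: QuadraticFit, zones: HormesisZones, path,
               half_width_sd: float = 2.0, title: str | None = None) -> None:
    """Render the curve with shaded strengthening/buffering/toxic zones.

    Writes SVG or PNG depending on the ``path`` suffix; headless-safe.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prof = curve_profile(fit, half_width_sd=half_width_sd, n_points=201)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(prof["x_raw"], prof["y"], color="black", lw=2)
    x_lo, x_hi = prof["x_raw"].iloc[0], prof["x_raw"].iloc[-1]
    shading = [
        (x_lo, zones.vertex_raw, "#74c476", "strengthening"),
        (zones.vertex_raw, zones.inflection_raw, "#fee391", "buffering"),
        (zones.inflection_raw, x_hi, "#fb6a4a", "toxic"),
    ]
    for lo, hi, color, label in shading:
        if hi > lo:
            ax.axvspan(lo, hi, color=color, alpha=0.35, label=label)
    ax.axvline(zones.vertex_raw, ls="--", color="gray", lw=1)
    ax.axvline(zones.inflection_raw, ls=":", color="gray", lw=1)
    ax.set_xlabel("predictor (raw scale)")
    ax.set_ylabel("model-implied outcome")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower center", ncol=3, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
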