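"""Synthetic three-wave family panel data.

Generates case-by-variable tables with the structure the downstream
analysis assumes: a bounded adversity composite at wave 1 whose centered
linear and quadratic terms drive two wave-2 mediators, which in turn
drive two wave-3 outcomes, with autoregression, demographic covariates,
correlated within-tier residuals, and MCAR cell-wise missingness.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenerativeConfig",
    "LongitudinalDataset",
    "generate",
    "apply_mcar",
    "MEDIATORS",
    "OUTCOMES",
    "COVARIATES",
]

#: wave-2 mediators and their wave-1 autoregressive baselines
MEDIATORS = {"ec_w2": "ec_w1", "ek_w2": "ek_w1"}
#: wave-3 outcomes and their wave-1 baselines
OUTCOMES = {"int_w3": "int_w1", "ext_w3": "ext_w1"}
#: demographic covariates, never endogenous
COVARIATES = ("sex", "age", "income")

_COLUMNS = (
    "adversity_w1",
    "ec_w1",
    "ec_w2",
    "ek_w1",
    "ek_w2",
    "int_w1",
    "int_w3",
    "ext_w1",
    "ext_w3",
    "sex",
    "age",
    "income",
)


def _default_a_lin() -> dict:
    return {"ec_w2": 0.02, "ek_w2": 0.03}


def _default_a_quad() -> dict:
    return {"ec_w2": -0.18, "ek_w2": -0.12}


def _default_ar() -> dict:
    return {"ec_w2": 0.40, "ek_w2": 0.44, "int_w3": 0.15, "ext_w3": 0.24}


def _default_m_to_y() -> dict:
    return {
        "int_w3": {"ec_w2": -0.05, "ek_w2": -0.14},
        "ext_w3": {"ec_w2": -0.13, "ek_w2": -0.06},
    }


def _default_cov_effects() -> dict:
    base = {"sex": 0.05, "age": 0.10, "income": 0.001}
    return {v: dict(base) for v in ("ec_w2", "ek_w2", "int_w3", "ext_w3")}


def _default_resid_sd() -> dict:
    return {"ec_w2": 0.80, "ek_w2": 0.85, "int_w3": 0.38, "ext_w3": 0.40}


@dataclass
class GenerativeConfig:
    """Parameters of the generative three-wave cascade.

    Structural coefficients are keyed by endogenous variable name
    (mediators ``ec_w2``/``ek_w2``, outcomes ``int_w3``/``ext_w3``).
    ``a_lin``/``a_quad`` act on the sample-centered adversity composite
    and its square; ``m_to_y`` maps each outcome to its two mediator
    coefficients.
    """

    n_cases: int = 238
    adversity_mean: float = 4.62
    adversity_sd: float = 1.04
    scale_min: float = 1.0
    scale_max: float = 9.0
    a_lin: dict = field(default_factory=_default_a_lin)
    a_quad: dict = field(default_factory=_default_a_quad)
    ar_mediator: dict = field(default_factory=lambda: {})
    ar_outcome: dict = field(default_factory=lambda: {})
    m_to_y: dict = field(default_factory=_default_m_to_y)
    cov_effects: dict = field(default_factory=_default_cov_effects)
    resid_sd: dict = field(default_factory=_default_resid_sd)
    resid_corr_mediators: float = 0.25
    resid_corr_outcomes: float = 0.20
    missing_rate: float = 0.137
    seed: int = 0
    # wave-1 baselines: loading on centered adversity and residual SD
    baseline_loading: dict = field(
        default_factory=lambda: {
            "ec_w1": -0.20,
            "ek_w1": -0.15,
            "int_w1": 0.06,
            "ext_w1": 0.08,
        }
    )
    baseline_sd: dict = field(
        default_factory=lambda: {
            "ec_w1": 0.95,
            "ek_w1": 0.95,
            "int_w1": 0.38,
            "ext_w1": 0.42,
        }
    )

    def __post_init__(self) -> None:
        ar = dict(_default_ar())
        ar.update(self.ar_mediator)
        ar.update(self.ar_outcome)
        self.ar_mediator = {m: ar[m] for m in MEDIATORS}
        self.ar_outcome = {y: ar[y] for y in OUTCOMES}
        self.validate()

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be a positive integer")
        if self.adversity_sd <= 0:
            raise ValueError("adversity_sd must be > 0")
        if not self.scale_min < self.scale_max:
            raise ValueError("scale_min must be below scale_max")
        for name, sd in self.resid_sd.items():
            if sd < 0:
                raise ValueError(f"resid_sd[{name!r}] must be >= 0")
        for label, r in (
            ("resid_corr_mediators", self.resid_corr_mediators),
            ("resid_corr_outcomes", self.resid_corr_outcomes),
        ):
            if not -1.0 < r < 1.0:
                raise ValueError(
                    f"residual correlation matrix for {label} is not "
                    f"positive definite (r = {r})"
                )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenerativeConfig":
        d = dict(d)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown GenerativeConfig fields: {sorted(unknown)}")
        defaults = cls()
        for key in ("a_lin", "a_quad", "m_to_y", "cov_effects", "resid_sd",
                    "baseline_loading", "baseline_sd"):
            if key in d:
                merged = copy.deepcopy(getattr(defaults, key))
                for k, v in d[key].items():
                    if isinstance(v, Mapping):
                        merged[k] = {**merged.get(k, {}), **v}
                    else:
                        merged[k] = v
                d[key] = merged
        return cls(**d)

    def to_dict(self) -> dict:
        return {f: copy.deepcopy(getattr(self, f)) for f in self.__dataclass_fields__}


@dataclass
class LongitudinalDataset:
    """A case-by-variable table with an explicit observed-value mask.

    ``values`` holds NaN where a cell is missing; ``mask`` is True where
    the value is present.  On disk the table is an RFC-4180 CSV with a
    header row and empty cells for missing values.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.mask.columns):
            raise ValueError("values and mask must share columns")
        observed = self.values.notna()
        if not observed.equals(self.mask.astype(bool)):
            raise ValueError("mask must be True exactly where a value is present")

    @property
    def n_cases(self) -> int:
        return len(self.values)

    @property
    def columns(self) -> list:
        return list(self.values.columns)

    def copy(self) -> "LongitudinalDataset":
        return LongitudinalDataset(
            self.values.copy(), self.mask.copy(), copy.deepcopy(self.meta)
        )

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path) -> "LongitudinalDataset":
        values = pd.read_csv(path)
        return cls(values=values, mask=values.notna(), meta={"source": str(path)})

    @classmethod
    def from_frame(cls, values: pd.DataFrame, meta: dict | None = None):
        return cls(values=values, mask=values.notna(), meta=meta or {})

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _correlated_noise(rng, sds: Sequence[float], corr: float, n: int) -> np.ndarray:
    """Two correlated noise columns; degenerates cleanly when either SD is 0."""
    z = rng.standard_normal((n, 2))
    z[:, 1] = corr * z[:, 0] + np.sqrt(1.0 - corr**2) * z[:, 1]
    return z * np.asarray(sds)


def generate(config: GenerativeConfig) -> LongitudinalDataset:
    """Draw a full three-wave dataset from the generative cascade.

    Adversity is truncated-normal on its bounded scale; the quadratic
    term is built from the *sample*-centered adversity, mirroring the
    analysis pipeline.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases

    adversity = _truncnorm(
        rng, config.adversity_mean, config.adversity_sd,
        config.scale_min, config.scale_max, n,
    )
    c = adversity - adversity.mean()  # sample-centered, as the analysis does
    c2 = c**2

    sex = rng.integers(0, 2, size=n).astype(float)
    age = rng.normal(4.38, 0.32, size=n)
    income = np.clip(rng.normal(72.0, 40.0, size=n), 0.5, None)
    covs = {"sex": sex, "age": age, "income": income}

    data = {"adversity_w1": adversity, "sex": sex, "age": age, "income": income}
    for base, loading in config.baseline_loading.items():
        data[base] = loading * c + config.baseline_sd[base] * rng.standard_normal(n)

    med_noise = _correlated_noise(
        rng,
        [config.resid_sd["ec_w2"], config.resid_sd["ek_w2"]],
        config.resid_corr_mediators,
        n,
    )
    for j, (med, base) in enumerate(MEDIATORS.items()):
        data[med] = (
            config.ar_mediator[med] * data[base]
            + config.a_lin[med] * c
            + config.a_quad[med] * c2
            + sum(config.cov_effects[med][v] * covs[v] for v in COVARIATES)
            + med_noise[:, j]
        )

    out_noise = _correlated_noise(
        rng,
        [config.resid_sd["int_w3"], config.resid_sd["ext_w3"]],
        config.resid_corr_outcomes,
        n,
    )
    for j, (out, base) in enumerate(OUTCOMES.items()):
        data[out] = (
            config.ar_outcome[out] * data[base]
            + sum(config.m_to_y[out][m] * data[m] for m in MEDIATORS)
            + sum(config.cov_effects[out][v] * covs[v] for v in COVARIATES)
            + out_noise[:, j]
        )

    values = pd.DataFrame({col: data[col] for col in _COLUMNS})
    meta = {
        "config": config.to_dict(),
        "seed": config.seed,
        "realized_adversity_mean": float(adversity.mean()),
        "realized_adversity_sd": float(adversity.std(ddof=1)),
    }
    dataset = LongitudinalDataset(values=values, mask=values.notna(), meta=meta)
    if config.missing_rate > 0:
        # child seed so the masking stream is independent of the draws above
        dataset = apply_mcar(
            dataset, config.missing_rate,
            seed=np.random.SeedSequence([config.seed, 1]),
        )
        dataset.meta = meta
    return dataset


def apply_mcar(
    data: LongitudinalDataset,
    rate: float,
    seed,
    exempt: Sequence[str] = COVARIATES,
) -> LongitudinalDataset:
    """Mask eligible cells independently with probability ``rate``.

    Covariates are exempt by default (demographics in panel studies are
    near-complete); pass ``exempt=()`` to mask everything.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return data
    rng = np.random.default_rng(seed)
    eligible = [c for c in data.columns if c not in set(exempt)]
    values = data.values.copy()
    drop = rng.random((data.n_cases, len(eligible))) < rate
    for j, col in enumerate(eligible):
        values.loc[drop[:, j], col] = np.nan
    meta = dict(data.meta)
    meta["mcar"] = {"rate": rate, "exempt": list(exempt)}
    return LongitudinalDataset(values=values, mask=values.notna(), meta=meta)
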