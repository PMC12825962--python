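"""Config-driven orchestration: simulate -> fit -> mediate -> zones -> RoS -> report.

The pipeline consumes a YAML/JSON config (or the built-in demo config),
runs every analysis stage in order, persists stage artifacts under an
output directory, and assembles a single JSON-serializable report.  A
single global seed is expanded into per-stage child seeds through
``numpy.random.SeedSequence([seed, stage_code])`` with fixed stage
codes, so adding a stage never perturbs earlier stages' randomness.
"""

from __future__ import annotations

import copy
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mediation import compare_paths_z, indirect_effect_ci
from .path_fiml import (
    PathModelSpec,
    add_centered_quadratic,
    fit_indices,
    fit_path_model,
    little_mcar_test,
)
from .ros import RoSConfig, residualize, ros
from .synthetic import GenerativeConfig, LongitudinalDataset, generate
from .zones import (
    QuadraticFit,
    classify_zones,
    curve_profile,
    plot_zones,
    zone_boundaries,
)

__all__ = ["default_config", "load_config", "run", "describe", "cascade_model_spec"]

logger = logging.getLogger("quadmed")

# fixed stage codes for child-seed derivation (documented contract)
_STAGE_SEEDS = {"simulate": 0, "mediation": 2, "ros": 3}


def _stage_seed(seed: int, stage: str, k: int = 0) -> int:
    code = _STAGE_SEEDS[stage]
    return int(np.random.SeedSequence([seed, code, k]).generate_state(1)[0])


def cascade_model_spec() -> PathModelSpec:
    """The canonical two-mediator, two-outcome autoregressive path model."""
    quad = ["adversity_w1_c", "adversity_w1_c2"]
    covs = ["sex", "age", "income"]
    return PathModelSpec.from_strings(
        equations=[
            "ec_w2 ~ ec_w1 + " + " + ".join(quad + ["int_w1", "ext_w1"] + covs),
            "ek_w2 ~ ek_w1 + " + " + ".join(quad + ["int_w1", "ext_w1"] + covs),
            "int_w3 ~ int_w1 + ec_w2 + ek_w2 + " + " + ".join(quad + covs),
            "ext_w3 ~ ext_w1 + ec_w2 + ek_w2 + " + " + ".join(quad + covs),
        ],
        covariances=["ec_w2 ~~ ek_w2", "int_w3 ~~ ext_w3"],
    )


def default_config(n_cases: int = 238, seed: int = 0) -> dict:
    """Demo configuration mirroring the canonical cascade analysis."""
    return {
        "input": "simulate",
        "generative": {"n_cases": n_cases, "seed": seed},
        "quadratic": {"variable": "adversity_w1"},
        "model": {
            "equations": [
                "ec_w2 ~ ec_w1 + adversity_w1_c + adversity_w1_c2 + int_w1 + ext_w1"
                " + sex + age + income",
                "ek_w2 ~ ek_w1 + adversity_w1_c + adversity_w1_c2 + int_w1 + ext_w1"
                " + sex + age + income",
                "int_w3 ~ int_w1 + ec_w2 + ek_w2 + adversity_w1_c + adversity_w1_c2"
                " + sex + age + income",
                "ext_w3 ~ ext_w1 + ec_w2 + ek_w2 + adversity_w1_c + adversity_w1_c2"
                " + sex + age + income",
            ],
            "covariances": ["ec_w2 ~~ ek_w2", "int_w3 ~~ ext_w3"],
        },
        "mediation": [
            {"a": "ec_w2~adversity_w1_c2", "b": "ext_w3~ec_w2"},
            {"a": "ek_w2~adversity_w1_c2", "b": "int_w3~ek_w2"},
        ],
        "comparisons": [
            {"path1": "ext_w3~ec_w2", "path2": "int_w3~ec_w2"},
            {"path1": "int_w3~ek_w2", "path2": "ext_w3~ek_w2"},
        ],
        "zones": [
            {"outcome": "ec_w2", "predictor": "adversity_w1"},
            {"outcome": "ek_w2", "predictor": "adversity_w1"},
        ],
        "ros": [
            {
                "outcome": "ec_w2",
                "predictor": "adversity_w1",
                "covariates": ["ec_w1", "int_w1", "ext_w1", "sex", "age", "income"],
                "n_boot": 1000,
                "grid_n": 100,
                "level": 0.95,
            },
            {
                "outcome": "ek_w2",
                "predictor": "adversity_w1",
                "covariates": ["ek_w1", "int_w1", "ext_w1", "sex", "age", "income"],
                "n_boot": 1000,
                "grid_n": 100,
                "level": 0.95,
            },
        ],
        "seed": seed,
        "mediation_draws": 100_000,
    }


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def describe(data: LongitudinalDataset) -> dict:
    """Per-variable n/mean/SD/missing%, plus pairwise-complete correlations."""
    frame = data.values
    if frame.shape[1] < 1:
        raise ValueError("dataset has no variables")
    variables = {}
    for col in frame.columns:
        series = frame[col]
        n_obs = int(series.notna().sum())
        variables[col] = {
            "n": n_obs,
            "mean": float(series.mean()) if n_obs else math.nan,
            "sd": float(series.std(ddof=1)) if n_obs > 1 else math.nan,
            "missing_pct": 100.0 * (1.0 - n_obs / len(frame)),
        }
    corr = frame.corr(method="pearson", min_periods=2)
    return {
        "n_cases": int(len(frame)),
        "variables": variables,
        "correlations": {
            a: {b: (None if pd.isna(corr.loc[a, b]) else float(corr.loc[a, b]))
                for b in corr.columns}
            for a in corr.index
        },
    }


def _sanitize(obj):
    """Make a nested structure strictly JSON-serializable (NaN -> null)."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return None if not math.isfinite(obj) else float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_sanitize(v) for v in obj.tolist()]
    return obj


def _load_stage(config, seed):
    source = config.get("input", "simulate")
    if source == "simulate":
        gen = dict(config.get("generative", {}))
        gen.setdefault("seed", _stage_seed(seed, "simulate"))
        gcfg = GenerativeConfig.from_dict(gen)
        return generate(gcfg)
    return LongitudinalDataset.from_csv(source)


def _fit_stage(data, config):
    model_cfg = config["model"]
    spec = PathModelSpec.from_strings(
        model_cfg["equations"], model_cfg.get("covariances", ())
    )
    fitted = fit_path_model(data, spec)
    indices = fit_indices(fitted, data, spec)
    return spec, fitted, indices


def _mediation_stage(fitted, config, seed):
    n_draws = int(config.get("mediation_draws", 100_000))
    results = []
    for k, pair in enumerate(config.get("mediation", [])):
        a_name, b_name = pair["a"], pair["b"]
        res = indirect_effect_ci(
            a=fitted.get(a_name),
            se_a=fitted.get_se(a_name),
            b=fitted.get(b_name),
            se_b=fitted.get_se(b_name),
            cov_ab=fitted.get_cov(a_name, b_name),
            level=float(pair.get("level", 0.95)),
            n_draws=n_draws,
            seed=_stage_seed(seed, "mediation", k),
        )
        results.append({"a_path": a_name, "b_path": b_name, **vars(res)})
    comparisons = []
    for pair in config.get("comparisons", []):
        p1, p2 = pair["path1"], pair["path2"]
        cmp = compare_paths_z(
            fitted.get(p1), fitted.get_se(p1), fitted.get(p2), fitted.get_se(p2),
            fitted.get_cov(p1, p2),
        )
        comparisons.append({"path1": p1, "path2": p2, **vars(cmp)})
    return results, comparisons


def _zones_stage(data, fitted, config, quad_var, x_mean, x_sd, outdir):
    results = []
    want_plots = bool(config.get("plots", False)) and outdir is not None
    for request in config.get("zones", []):
        outcome = request["outcome"]
        predictor = request["predictor"]
        b1 = fitted.get(f"{outcome}~{quad_var}_c")
        b2 = fitted.get(f"{outcome}~{quad_var}_c2")
        # intercept adjusted to implied means of the remaining predictors
        b0 = fitted.get(f"{outcome}~1")
        for name in fitted.params.index:
            if "~~" in name or name.endswith("~1") or not name.startswith(f"{outcome}~"):
                continue
            pred = name.split("~", 1)[1]
            if pred in (f"{quad_var}_c", f"{quad_var}_c2"):
                continue
            b0 += fitted.get(name) * float(fitted.implied_mean[pred])
        fit = QuadraticFit(b0=b0, b1=b1, b2=b2, x_mean=x_mean, x_sd=x_sd)
        x_raw = data.values[predictor]
        entry = {"outcome": outcome, "predictor": predictor,
                 "b0": b0, "b1": b1, "b2": b2,
                 "x_mean": x_mean, "x_sd": x_sd,
                 "orientation": fit.orientation}
        if fit.b2 < 0:
            zones = zone_boundaries(
                fit, x_range=(float(x_raw.min()), float(x_raw.max()))
            )
            zones = classify_zones(x_raw, zones)
            entry.update(
                vertex_centered=zones.vertex_centered,
                vertex_raw=zones.vertex_raw,
                inflection_centered=zones.inflection_centered,
                inflection_raw=zones.inflection_raw,
                reference_low_raw=zones.reference_low_raw,
                extrapolated=zones.extrapolated,
                zone_percentages=zones.zone_percentages,
            )
            profile = curve_profile(fit)
            if outdir is not None:
                profile.to_csv(outdir / f"profile_{outcome}.csv", index=False)
            if want_plots:
                plot_zones(fit, zones, outdir / f"zones_{outcome}.png",
                           title=outcome)
        results.append(entry)
    return results


def _ros_stage(data, config, quad_var, x_mean, seed, outdir):
    results = []
    for k, request in enumerate(config.get("ros", [])):
        outcome = request["outcome"]
        predictor = request["predictor"]
        resid = residualize(data, outcome, list(request.get("covariates", [])))
        ros_cfg = RoSConfig(
            n_boot=int(request.get("n_boot", 1000)),
            grid_n=int(request.get("grid_n", 100)),
            level=float(request.get("level", 0.95)),
            seed=_stage_seed(seed, "ros", k),
            refit_method=request.get("refit_method", "complete_case_ls"),
        )
        x_centered = data.values[predictor] - x_mean
        result = ros(x_centered, resid, ros_cfg)
        if outdir is not None:
            result.to_frame().to_csv(outdir / f"ros_{outcome}.csv", index=False)
        results.append(
            {
                "outcome": outcome,
                "predictor": predictor,
                "x_mean": x_mean,
                "n_cases": result.n_cases,
                "n_failed_boot": result.n_failed_boot,
                "regions": result.regions,
                "sample_proportions": result.sample_proportions,
                "n_significant_points": int(result.significant.sum()),
                "grid_n": ros_cfg.grid_n,
            }
        )
    return results


def run(config: dict, output_dir=None) -> dict:
    """Execute the full pipeline and return the assembled report.

    Stage artifacts (dataset CSV, coefficient table, RoS and profile
    grids, the report itself) are persisted under ``output_dir`` when it
    is given.  Any stage failure raises with the stage name attached;
    artifacts from completed stages are retained.
    """
    config = copy.deepcopy(config)
    seed = int(config.get("seed", 0))
    outdir = None
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {"config": _sanitize(config), "seed": seed, "version": __version__}

    def stage(name, fn, *args, **kw):
        logger.info("stage %s", name)
        try:
            return fn(*args, **kw)
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err

    data = stage("load", _load_stage, config, seed)
    if outdir is not None:
        data.to_csv(outdir / "dataset.csv")

    report["dataset"] = stage("describe", describe, data)
    report["mcar_test"] = stage(
        "mcar", lambda: vars(little_mcar_test(data))
    )

    quad_var = config.get("quadratic", {}).get("variable", "adversity_w1")
    data, x_mean, x_sd = stage("quadratic", add_centered_quadratic, data, quad_var)

    spec, fitted, indices = stage("fit", _fit_stage, data, config)
    report["model"] = {
        "estimates": {k: float(v) for k, v in fitted.params.items()},
        "se": {k: float(v) for k, v in fitted.se.items()},
        "standardized": {k: float(v) for k, v in fitted.standardized.items()},
        "loglik": fitted.loglik,
        "converged": fitted.converged,
        "n_cases": fitted.n_cases,
        "n_params": fitted.n_params,
        "fit_indices": vars(indices),
    }
    if outdir is not None:
        fitted.coefficient_table().to_csv(outdir / "coefficients.csv", index=False)

    med, cmps = stage("mediation", _mediation_stage, fitted, config, seed)
    report["mediation"] = med
    report["path_comparisons"] = cmps
    report["zones"] = stage(
        "zones", _zones_stage, data, fitted, config, quad_var, x_mean, x_sd, outdir
    )
    report["ros"] = stage(
        "ros", _ros_stage, data, config, quad_var, x_mean, seed, outdir
    )

    report = _sanitize(report)
    if outdir is not None:
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, allow_nan=False) + "\n"
        )
    return report
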