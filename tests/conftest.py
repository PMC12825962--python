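import numpy as np
import pytest

from quadmed import GenerativeConfig, add_centered_quadratic, fit_path_model, generate
from quadmed.pipeline import cascade_model_spec


@pytest.fixture(scope="session")
def cascade_spec():
    return cascade_model_spec()


@pytest.fixture(scope="session")
def paper_like_dataset():
    """n=238 three-wave dataset with 13.7% MCAR and quadratic columns."""
    cfg = GenerativeConfig.from_dict({"n_cases": 238, "seed": 3})
    data, x_mean, x_sd = add_centered_quadratic(generate(cfg), "adversity_w1")
    return data, x_mean, x_sd


@pytest.fixture(scope="session")
def fitted_cascade(paper_like_dataset, cascade_spec):
    data, _, _ = paper_like_dataset
    return fit_path_model(data, cascade_spec)


@pytest.fixture(scope="session")
def complete_dataset():
    """Complete-data (no missingness) counterpart at n=500."""
    cfg = GenerativeConfig.from_dict({"n_cases": 500, "seed": 11, "missing_rate": 0.0})
    data, _, _ = add_centered_quadratic(generate(cfg), "adversity_w1")
    return data


def ols_coefs(frame, outcome, predictors):
    """Plain least-squares oracle: intercept + slopes on complete cases."""
    sub = frame[[outcome, *predictors]].dropna()
    X = np.column_stack([np.ones(len(sub)), sub[predictors].to_numpy(float)])
    beta, *_ = np.linalg.lstsq(X, sub[outcome].to_numpy(float), rcond=None)
    return beta
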