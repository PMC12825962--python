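"""Recursive path models by casewise full-information maximum likelihood.

Estimation maximizes the sum over cases of the multivariate-normal
log-density of each case's observed subvector under the model-implied
mean vector and covariance matrix, so incomplete cases contribute
through their observed margins.  Residual covariance blocks are
parameterized by log-Cholesky factors, which keeps them positive
definite throughout optimization.  Standard errors come from the
observed information matrix (central finite differences of the analytic
gradient) with a delta-method map onto the natural parameters.

Also provides likelihood-based fit indices (chi-square against the
saturated model, CFI against an independence null, RMSEA) and Little's
chi-square test of the MCAR hypothesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .synthetic import LongitudinalDataset

__all__ = [
    "PathModelSpec",
    "FittedPathModel",
    "FitIndices",
    "McarTestResult",
    "fit_path_model",
    "fit_indices",
    "fit_indices_from_stats",
    "little_mcar_test",
    "em_mvn",
    "add_centered_quadratic",
]

_LOG2PI = np.log(2.0 * np.pi)


def _solve_tri_lower(L: np.ndarray) -> np.ndarray:
    """Inverse of a lower-triangular matrix via LAPACK ``trtri``."""
    from scipy.linalg.lapack import dtrtri

    inv, info = dtrtri(L, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("singular triangular factor")
    return inv


# ---------------------------------------------------------------------------
# model specification


def _parse_equation(text: str) -> tuple[str, list[str]]:
    lhs, _, rhs = text.partition("~")
    y = lhs.strip()
    preds = [t.strip() for t in rhs.split("+") if t.strip()]
    if not y or not preds:
        raise ValueError(f"cannot parse equation {text!r}")
    return y, preds


def _parse_covariance(text: str) -> tuple[str, str]:
    a, sep, b = text.partition("~~")
    if not sep or not a.strip() or not b.strip():
        raise ValueError(f"cannot parse covariance {text!r}")
    return a.strip(), b.strip()


@dataclass
class PathModelSpec:
    """A recursive system of regression equations.

    ``equations`` maps each endogenous variable to its ordered predictor
    list.  ``residual_covariances`` lists endogenous pairs whose
    residuals covary freely; pairs linked by a directed path are
    rejected.  ``exogenous_covariances`` is True for an all-pairs free
    block, False for independent exogenous variables, or an explicit
    pair list.
    """

    equations: list
    residual_covariances: list = field(default_factory=list)
    exogenous_covariances: object = True
    mean_structure: bool = True

    @classmethod
    def from_strings(cls, equations, covariances=(), **kw) -> "PathModelSpec":
        eqs = [_parse_equation(e) for e in equations]
        rcov = [_parse_covariance(c) for c in covariances]
        return cls(equations=eqs, residual_covariances=rcov, **kw)

    @property
    def endogenous(self) -> list:
        return [y for y, _ in self.equations]

    @property
    def exogenous(self) -> list:
        endo = set(self.endogenous)
        seen: list[str] = []
        for _, preds in self.equations:
            for x in preds:
                if x not in endo and x not in seen:
                    seen.append(x)
        return seen

    @property
    def variables(self) -> list:
        return self.exogenous + self._topo_order()

    def _topo_order(self) -> list:
        """Endogenous variables ordered so predictors precede outcomes."""
        endo = self.endogenous
        if len(set(endo)) != len(endo):
            raise ValueError("duplicate endogenous variable in equations")
        preds = {y: [x for x in p if x in set(endo)] for y, p in self.equations}
        order, placed = [], set()
        remaining = list(endo)
        while remaining:
            progress = [y for y in remaining if all(x in placed for x in preds[y])]
            if not progress:
                raise ValueError(f"equations are cyclic among {remaining}")
            for y in progress:
                order.append(y)
                placed.add(y)
            remaining = [y for y in remaining if y not in placed]
        return order

    def _has_directed_path(self, src: str, dst: str) -> bool:
        eqs = dict(self.equations)
        stack, seen = [dst], set()
        while stack:
            node = stack.pop()
            if node == src:
                return True
            if node in seen or node not in eqs:
                continue
            seen.add(node)
            stack.extend(eqs[node])
        return False

    def validate(self) -> None:
        self._topo_order()
        endo = set(self.endogenous)
        for a, b in self.residual_covariances:
            if a not in endo or b not in endo:
                raise ValueError(
                    f"residual covariance {a}~~{b} must link endogenous variables"
                )
            if self._has_directed_path(a, b) or self._has_directed_path(b, a):
                raise ValueError(
                    f"residual covariance {a}~~{b} links variables on a directed path"
                )
        if not self.mean_structure:
            raise ValueError("FIML estimation requires mean_structure=True")


# ---------------------------------------------------------------------------
# internal structure: parameter layout


class _Structure:
    def __init__(self, spec: PathModelSpec):
        spec.validate()
        self.spec = spec
        self.variables = spec.variables
        self.index = {v: i for i, v in enumerate(self.variables)}
        self.p = len(self.variables)

        self.b_entries = []  # (row, col) into B, row = endogenous eq
        for y, preds in spec.equations:
            for x in preds:
                self.b_entries.append((self.index[y], self.index[x]))

        exo_idx = [self.index[v] for v in spec.exogenous]
        self.psi_blocks = self._exo_blocks(exo_idx) + self._endo_blocks()
        self.n_theta = self.p + len(self.b_entries) + sum(
            k * (k + 1) // 2 for k in map(len, self.psi_blocks)
        )
        self.n_params = self.n_theta

    def theta_bounds(self):
        """Loose box bounds; log-Cholesky diagonals are kept finite so a
        vanishing residual variance cannot drive the optimizer to -inf."""
        bounds = [(None, None)] * (self.p + len(self.b_entries))
        for block in self.psi_blocks:
            for r in range(len(block)):
                for c in range(r + 1):
                    bounds.append((-8.0, 15.0) if r == c else (None, None))
        return bounds

    def _exo_blocks(self, exo_idx):
        spec = self.spec
        if spec.exogenous_covariances is True:
            return [exo_idx] if exo_idx else []
        if spec.exogenous_covariances is False:
            return [[i] for i in exo_idx]
        # explicit pair list -> connected components
        pairs = [(self.index[a], self.index[b]) for a, b in spec.exogenous_covariances]
        return _components(exo_idx, pairs)

    def _endo_blocks(self):
        endo_idx = [self.index[y] for y in self.spec.endogenous]
        pairs = [
            (self.index[a], self.index[b]) for a, b in self.spec.residual_covariances
        ]
        return _components(endo_idx, pairs)

    # --- theta <-> (alpha, B, Psi) -----------------------------------

    def unpack(self, theta):
        p = self.p
        alpha = theta[:p]
        B = np.zeros((p, p))
        k = p
        for (i, j) in self.b_entries:
            B[i, j] = theta[k]
            k += 1
        Psi = np.zeros((p, p))
        Ls = []
        for block in self.psi_blocks:
            m = len(block)
            L = np.zeros((m, m))
            for r in range(m):
                for c in range(r + 1):
                    val = theta[k]
                    L[r, c] = np.exp(val) if r == c else val
                    k += 1
            Ls.append(L)
            Psi[np.ix_(block, block)] = L @ L.T
        return alpha, B, Psi, Ls

    def pack(self, alpha, B, Psi):
        theta = list(alpha)
        for (i, j) in self.b_entries:
            theta.append(B[i, j])
        for block in self.psi_blocks:
            sub = Psi[np.ix_(block, block)]
            sub = _nearest_pd(sub)
            L = np.linalg.cholesky(sub)
            for r in range(len(block)):
                for c in range(r + 1):
                    theta.append(
                        float(np.clip(np.log(L[r, r]), -7.5, 14.0))
                        if r == c
                        else L[r, c]
                    )
        return np.asarray(theta, dtype=float)

    def natural_names(self):
        names = [f"{v}~1" for v in self.variables]
        for (i, j) in self.b_entries:
            names.append(f"{self.variables[i]}~{self.variables[j]}")
        for block in self.psi_blocks:
            for r in range(len(block)):
                for c in range(r + 1):
                    a, b = self.variables[block[r]], self.variables[block[c]]
                    names.append(f"{a}~~{b}" if a != b else f"{a}~~{a}")
        return names

    def natural_values(self, theta, s):
        """Map working parameters to natural parameters on the raw scale.

        ``s`` are the per-variable scale factors used to standardize the
        data internally.
        """
        alpha, B, Psi, _ = self.unpack(theta)
        out = list(alpha * s)
        for (i, j) in self.b_entries:
            out.append(B[i, j] * s[i] / s[j])
        for block in self.psi_blocks:
            for r in range(len(block)):
                for c in range(r + 1):
                    i, j = block[r], block[c]
                    out.append(Psi[i, j] * s[i] * s[j])
        return np.asarray(out)


def _components(nodes, pairs):
    parent = {i: i for i in nodes}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        parent[find(a)] = find(b)
    groups: dict[int, list] = {}
    for i in nodes:
        groups.setdefault(find(i), []).append(i)
    return [sorted(g) for g in groups.values()]


def _nearest_pd(mat, floor_frac=1e-8):
    mat = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(mat)
    floor = max(floor_frac * max(np.mean(np.diag(mat)), 1e-12), 1e-12)
    if w.min() >= floor:
        return mat
    w = np.clip(w, floor, None)
    return v @ np.diag(w) @ v.T


# ---------------------------------------------------------------------------
# likelihood machinery


def _pattern_groups(X: np.ndarray):
    """Group case rows by missingness pattern; rows with no observed data drop.

    Each group carries its observed-column indices, a cached ``np.ix_``
    pair for scatter/gather into p x p matrices, and the observed data
    block, so per-iteration likelihood sweeps do no index bookkeeping.
    """
    obs = ~np.isnan(X)
    keep = obs.any(axis=1)
    X, obs = X[keep], obs[keep]
    groups = []
    _, inverse = np.unique(obs, axis=0, return_inverse=True)
    for g in np.unique(inverse):
        rows = np.flatnonzero(inverse == g)
        o = np.flatnonzero(obs[rows[0]])
        groups.append((o, np.ix_(o, o), X[np.ix_(rows, o)]))
    return groups, int(keep.sum())


def _negloglik_grad(theta, struct: _Structure, patterns):
    p = struct.p
    alpha, B, Psi, Ls = struct.unpack(theta)
    A = np.linalg.solve(np.eye(p) - B, np.eye(p))
    mu = A @ alpha
    Sigma = A @ Psi @ A.T

    ll = 0.0
    g_mu = np.zeros(p)
    G_S = np.zeros((p, p))
    for o, oo, Xo in patterns:
        n_k, p_k = Xo.shape
        So = Sigma[oo]
        try:
            L = np.linalg.cholesky(So)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros_like(theta)
        logdet = 2.0 * np.log(np.diagonal(L)).sum()
        Linv = _solve_tri_lower(L)
        W = Linv.T @ Linv
        D = Xo - mu[o]
        DW = D @ W
        ll += -0.5 * n_k * (p_k * _LOG2PI + logdet) - 0.5 * np.einsum(
            "ij,ij->", DW, D
        )
        g_mu[o] += DW.sum(axis=0)
        G_S[oo] += -0.5 * n_k * W + 0.5 * (DW.T @ DW)

    At_g = A.T @ g_mu
    grad = np.empty_like(theta)
    grad[:p] = At_g
    M = Sigma @ G_S @ A
    k = p
    for (i, j) in struct.b_entries:
        grad[k] = 2.0 * M[j, i] + mu[j] * At_g[i]
        k += 1
    H = A.T @ G_S @ A
    for block, L in zip(struct.psi_blocks, Ls):
        Hb = H[np.ix_(block, block)]
        GL = 2.0 * Hb @ L
        for r in range(len(block)):
            for c in range(r + 1):
                grad[k] = GL[r, r] * L[r, r] if r == c else GL[r, c]
                k += 1
    if not np.isfinite(ll):
        return np.inf, np.zeros_like(theta)
    return -ll, -grad


# ---------------------------------------------------------------------------
# saturated model via EM


def em_mvn(X: np.ndarray, tol: float = 1e-10, max_iter: int = 2000):
    """ML mean and covariance of an incomplete MVN sample, by EM.

    Returns ``(mu, Sigma, loglik, converged)``.  Rows without any
    observed value are ignored.
    """
    X = np.asarray(X, dtype=float)
    patterns, n = _pattern_groups(X)
    if n == 0:
        raise ValueError("no observed data")
    p = X.shape[1]

    col_mean = np.nanmean(X, axis=0)
    if np.isnan(col_mean).any():
        bad = np.flatnonzero(np.isnan(col_mean))
        raise ValueError(f"variables with no observed values at columns {bad}")
    Xc = X - col_mean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pairwise = np.ma.cov(np.ma.masked_invalid(Xc), rowvar=False, ddof=0)
    Sigma = np.asarray(pairwise.filled(0.0), dtype=float).reshape(p, p)
    diag_floor = np.nanvar(X, axis=0)
    diag_floor[diag_floor <= 0] = 1e-6
    np.fill_diagonal(Sigma, np.maximum(np.diag(Sigma), diag_floor))
    Sigma = _nearest_pd(Sigma, floor_frac=1e-6)
    mu = col_mean.copy()

    last_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        ll = 0.0
        for o, oo, Xo in patterns:
            n_k, p_k = Xo.shape
            m = np.setdiff1d(np.arange(p), o, assume_unique=True)
            So = Sigma[oo]
            cf = cho_factor(So, lower=True)
            logdet = 2.0 * np.log(np.diag(cf[0])).sum()
            D = Xo - mu[o]
            WD = cho_solve(cf, D.T).T
            ll += -0.5 * n_k * (p_k * _LOG2PI + logdet) - 0.5 * np.einsum(
                "ij,ij->", WD, D
            )
            full = np.empty((n_k, p))
            full[:, o] = Xo
            V = np.zeros((p, p))
            if m.size:
                C = cho_solve(cf, Sigma[np.ix_(o, m)])  # p_k x p_m
                full[:, m] = mu[m] + D @ C
                V[np.ix_(m, m)] = Sigma[np.ix_(m, m)] - Sigma[np.ix_(m, o)] @ C
            T1 += full.sum(axis=0)
            T2 += full.T @ full + n_k * V
        mu = T1 / n
        Sigma = _nearest_pd(T2 / n - np.outer(mu, mu), floor_frac=1e-10)
        if abs(ll - last_ll) < tol * (1.0 + abs(ll)):
            converged = True
            last_ll = ll
            break
        last_ll = ll
    return mu, Sigma, last_ll, converged


def _independence_loglik(X: np.ndarray):
    """FIML log-likelihood and parameter count of the independence model."""
    ll = 0.0
    for j in range(X.shape[1]):
        col = X[:, j]
        col = col[~np.isnan(col)]
        var = col.var()  # ML (denominator n)
        if var <= 0:
            raise ValueError(f"variable {j} has zero variance")
        ll += -0.5 * col.size * (_LOG2PI + np.log(var) + 1.0)
    return ll, 2 * X.shape[1]


# ---------------------------------------------------------------------------
# results


@dataclass
class FittedPathModel:
    """Estimates and inference for one fitted recursive path model."""

    params: pd.Series
    se: pd.Series
    est_cov: pd.DataFrame
    standardized: pd.Series
    loglik: float
    n_cases: int
    converged: bool
    n_params: int
    implied_mean: pd.Series
    implied_cov: pd.DataFrame
    spec: PathModelSpec
    diagnostics: dict = field(default_factory=dict)

    def get(self, name: str) -> float:
        return float(self.params[name])

    def get_se(self, name: str) -> float:
        return float(self.se[name])

    def get_cov(self, name1: str, name2: str) -> float:
        return float(self.est_cov.loc[name1, name2])

    def coefficient_table(self) -> pd.DataFrame:
        rows = []
        for name in self.params.index:
            if "~~" in name or name.endswith("~1"):
                continue
            b = self.params[name]
            se = self.se[name]
            z = b / se if se > 0 else np.nan
            rows.append(
                {
                    "path": name,
                    "estimate": b,
                    "se": se,
                    "z": z,
                    "p_value": 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                    "beta": self.standardized.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class FitIndices:
    chi2: float
    df: int
    p_value: float
    cfi: float
    rmsea: float
    chi2_null: float = float("nan")
    df_null: int = 0


@dataclass
class McarTestResult:
    chi2: float
    df: int
    p_value: float
    n_patterns: int
    applicable: bool = True


# ---------------------------------------------------------------------------
# fitting


def _design_matrix(data, spec: PathModelSpec):
    frame = data.values if isinstance(data, LongitudinalDataset) else pd.DataFrame(data)
    missing = [v for v in spec.variables if v not in frame.columns]
    if missing:
        raise ValueError(f"variables not present in data: {missing}")
    X = frame[spec.variables].to_numpy(dtype=float)
    keep = ~np.isnan(X).all(axis=1)
    return X[keep]


def fit_path_model(
    data,
    spec: PathModelSpec,
    *,
    compute_se: bool = True,
    std_method: str = "implied",
    max_restarts: int = 5,
    gtol: float = 1e-8,
) -> FittedPathModel:
    """Fit a recursive path model by casewise FIML.

    Parameters
    ----------
    data
        :class:`LongitudinalDataset` or DataFrame; NaN marks missing.
    spec
        Model specification; every variable must be a column of ``data``.
    compute_se
        Whether to compute the observed-information standard errors and
        estimate covariance (skipping them roughly halves the runtime).
    std_method
        ``"implied"`` standardizes with FIML-implied SDs, ``"listwise"``
        with complete-case sample SDs.
    """
    struct = _Structure(spec)
    X = _design_matrix(data, spec)
    n = X.shape[0]
    if n == 0:
        raise ValueError("no cases with observed data")

    # internal standardization for optimizer conditioning
    s = np.array([np.nanstd(X[:, j], ddof=1) for j in range(struct.p)])
    if np.any(~np.isfinite(s) | (s <= 0)):
        bad = [struct.variables[j] for j in np.flatnonzero(~np.isfinite(s) | (s <= 0))]
        raise ValueError(f"variables with zero or undefined variance: {bad}")
    Xs = X / s

    patterns, n_used = _pattern_groups(Xs)
    mu0, Sig0, _, _ = em_mvn(Xs, tol=1e-11)
    theta0 = _start_values(struct, mu0, Sig0)

    rng = np.random.default_rng(0)
    best = None
    theta_try = theta0
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(
            _negloglik_grad,
            theta_try,
            args=(struct, patterns),
            jac=True,
            method="L-BFGS-B",
            bounds=struct.theta_bounds(),
            options={
                "maxiter": 5000,
                "maxfun": 20000,
                "ftol": 1e-13,
                "gtol": gtol,
                "maxcor": min(60, struct.n_theta),
            },
        )
        if best is None or res.fun < best.fun:
            best = res
        grad_ok = np.max(np.abs(res.jac)) < 1e-5 * (1.0 + abs(res.fun))
        if res.success or grad_ok:
            best = res if res.fun <= best.fun else best
            break
        theta_try = theta0 + rng.normal(scale=0.05, size=theta0.size) * (
            1.0 + np.abs(theta0)
        )
    res = best
    converged = bool(
        res.success or np.max(np.abs(res.jac)) < 1e-5 * (1.0 + abs(res.fun))
    )
    theta_hat = res.x

    # natural-scale results
    names = struct.natural_names()
    natural = struct.natural_values(theta_hat, s)
    params = pd.Series(natural, index=names)

    alpha, B, Psi, _ = struct.unpack(theta_hat)
    p = struct.p
    A = np.linalg.solve(np.eye(p) - B, np.eye(p))
    mu_s = A @ alpha
    Sig_s = A @ Psi @ A.T
    implied_mean = pd.Series(mu_s * s, index=struct.variables)
    implied_cov = pd.DataFrame(
        Sig_s * np.outer(s, s), index=struct.variables, columns=struct.variables
    )

    # log-likelihood on the raw scale (Jacobian of the standardization)
    n_obs_per_var = (~np.isnan(X)).sum(axis=0)
    loglik = -res.fun - float(n_obs_per_var @ np.log(s))

    if std_method == "implied":
        sds = np.sqrt(np.diag(implied_cov.to_numpy()))
        sd_map = dict(zip(struct.variables, sds))
    elif std_method == "listwise":
        complete = X[~np.isnan(X).any(axis=1)]
        if complete.shape[0] < 2:
            raise ValueError("listwise standardization needs >= 2 complete cases")
        sd_map = dict(zip(struct.variables, complete.std(axis=0, ddof=1)))
    else:
        raise ValueError(f"unknown std_method {std_method!r}")
    standardized = {}
    for (i, j) in struct.b_entries:
        y, x = struct.variables[i], struct.variables[j]
        b = params[f"{y}~{x}"]
        standardized[f"{y}~{x}"] = b * sd_map[x] / sd_map[y]
    standardized = pd.Series(standardized)

    if compute_se:
        H = _fd_hessian(theta_hat, struct, patterns)
        cov_w = _psd_inverse(H)
        J = _fd_jacobian(lambda t: struct.natural_values(t, s), theta_hat)
        cov_nat = J @ cov_w @ J.T
        cov_nat = 0.5 * (cov_nat + cov_nat.T)
        w, v = np.linalg.eigh(cov_nat)
        cov_nat = v @ np.diag(np.clip(w, 0.0, None)) @ v.T
        est_cov = pd.DataFrame(cov_nat, index=names, columns=names)
        se = pd.Series(np.sqrt(np.clip(np.diag(cov_nat), 0.0, None)), index=names)
    else:
        est_cov = pd.DataFrame(np.full((len(names),) * 2, np.nan), index=names,
                               columns=names)
        se = pd.Series(np.full(len(names), np.nan), index=names)

    return FittedPathModel(
        params=params,
        se=se,
        est_cov=est_cov,
        standardized=standardized,
        loglik=float(loglik),
        n_cases=n_used,
        converged=converged,
        n_params=struct.n_params,
        implied_mean=implied_mean,
        implied_cov=implied_cov,
        spec=spec,
        diagnostics={
            "optimizer_message": str(res.message),
            "grad_max": float(np.max(np.abs(res.jac))),
            "n_iter": int(res.nit),
            "scale_factors": dict(zip(struct.variables, s)),
        },
    )


def _start_values(struct: _Structure, mu0, Sig0):
    p = struct.p
    alpha = mu0.copy()
    B = np.zeros((p, p))
    eq_coefs = {}
    for y, preds in struct.spec.equations:
        yi = struct.index[y]
        P = np.array([struct.index[x] for x in preds])
        b = np.linalg.solve(Sig0[np.ix_(P, P)], Sig0[P, yi])
        B[yi, P] = b
        alpha[yi] = mu0[yi] - b @ mu0[P]
        eq_coefs[yi] = (P, b)
    Psi = np.zeros((p, p))
    exo_idx = [struct.index[v] for v in struct.spec.exogenous]
    Psi[np.ix_(exo_idx, exo_idx)] = Sig0[np.ix_(exo_idx, exo_idx)]
    endo_idx = [struct.index[y] for y in struct.spec.endogenous]
    for yi in endo_idx:
        P, b = eq_coefs[yi]
        Psi[yi, yi] = max(Sig0[yi, yi] - b @ Sig0[P, yi], 1e-4)
    for a, bvar in struct.spec.residual_covariances:
        i, j = struct.index[a], struct.index[bvar]
        Pi, bi = eq_coefs[i]
        Pj, bj = eq_coefs[j]
        rcov = (
            Sig0[i, j]
            - bi @ Sig0[Pi, j]
            - bj @ Sig0[Pj, i]
            + bi @ Sig0[np.ix_(Pi, Pj)] @ bj
        )
        cap = 0.95 * np.sqrt(Psi[i, i] * Psi[j, j])
        Psi[i, j] = Psi[j, i] = np.clip(rcov, -cap, cap)
    return struct.pack(alpha, B, Psi)


def _fd_hessian(theta, struct, patterns):
    n = theta.size
    H = np.empty((n, n))
    for k in range(n):
        eps = 1e-5 * (1.0 + abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += eps
        tm[k] -= eps
        _, gp = _negloglik_grad(tp, struct, patterns)
        _, gm = _negloglik_grad(tm, struct, patterns)
        H[:, k] = (gp - gm) / (2.0 * eps)
    return 0.5 * (H + H.T)


def _fd_jacobian(fn, theta):
    f0 = fn(theta)
    J = np.empty((f0.size, theta.size))
    for k in range(theta.size):
        eps = 1e-6 * (1.0 + abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += eps
        tm[k] -= eps
        J[:, k] = (fn(tp) - fn(tm)) / (2.0 * eps)
    return J


def _psd_inverse(H):
    H = 0.5 * (H + H.T)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


# ---------------------------------------------------------------------------
# fit indices


def fit_indices_from_stats(chi2, df, chi2_null, df_null, n) -> FitIndices:
    """CFI/RMSEA from likelihood-ratio statistics.

    ``cfi = 1 - max(chi2 - df, 0) / max(chi2_null - df_null, chi2 - df, 0)``
    and ``rmsea = sqrt(max(chi2 - df, 0) / (df * (n - 1)))`` (0 when
    ``df`` is 0), truncations included, so a model with ``chi2 < df``
    reports CFI = 1 and RMSEA = 0.
    """
    excess = max(chi2 - df, 0.0)
    if excess < 1e-8:  # numerical-noise guard: saturated fits report exactly 1/0
        excess = 0.0
    denom = max(chi2_null - df_null, excess, 0.0)
    cfi = 1.0 if denom == 0.0 else 1.0 - excess / denom
    rmsea = 0.0 if df == 0 else float(np.sqrt(excess / (df * (n - 1))))
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    return FitIndices(
        chi2=float(chi2),
        df=int(df),
        p_value=p_value,
        cfi=float(cfi),
        rmsea=rmsea,
        chi2_null=float(chi2_null),
        df_null=int(df_null),
    )


def fit_indices(model: FittedPathModel, data, spec: PathModelSpec) -> FitIndices:
    """Chi-square against the saturated model, CFI, and RMSEA.

    The saturated log-likelihood is the EM maximum of the unrestricted
    MVN model on the same cases; the CFI null is the independence model
    (free means and variances, zero covariances) estimated by FIML.
    """
    X = _design_matrix(data, spec)
    p = len(spec.variables)
    n_moments = p * (p + 3) // 2
    df = n_moments - model.n_params
    if df < 0:
        raise ValueError(
            f"model has more parameters ({model.n_params}) than moments ({n_moments})"
        )
    _, _, ll_sat, _ = em_mvn(X, tol=1e-11)
    chi2 = max(2.0 * (ll_sat - model.loglik), 0.0)
    ll_null, null_params = _independence_loglik(X)
    chi2_null = max(2.0 * (ll_sat - ll_null), 0.0)
    df_null = n_moments - null_params
    return fit_indices_from_stats(chi2, df, chi2_null, df_null, model.n_cases)


# ---------------------------------------------------------------------------
# Little's MCAR test


def little_mcar_test(data, variables=None) -> McarTestResult:
    """Little's chi-square test of the MCAR hypothesis.

    ``chi2 = sum_k n_k (xbar_k - mu_k)' Sigma_k^{-1} (xbar_k - mu_k)``
    over missingness patterns, with FIML (EM) grand estimates restricted
    to each pattern's observed variables; ``df = sum_k p_k - p``.
    """
    frame = data.values if isinstance(data, LongitudinalDataset) else pd.DataFrame(data)
    if variables is not None:
        frame = frame[list(variables)]
    X = frame.to_numpy(dtype=float)
    keep = ~np.isnan(X).all(axis=1)
    X = X[keep]
    p = X.shape[1]
    patterns, _ = _pattern_groups(X)
    if len(patterns) < 2:
        return McarTestResult(
            chi2=0.0, df=0, p_value=float("nan"), n_patterns=len(patterns),
            applicable=False,
        )
    mu, Sigma, _, _ = em_mvn(X, tol=1e-10)
    chi2 = 0.0
    df = 0
    for o, oo, Xo in patterns:
        n_k, p_k = Xo.shape
        d = Xo.mean(axis=0) - mu[o]
        So = Sigma[oo]
        try:
            sol = np.linalg.solve(So, d)
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular pattern covariance in Little's test; using pseudo-inverse",
                RuntimeWarning,
                stacklevel=2,
            )
            sol = np.linalg.pinv(So) @ d
        chi2 += n_k * float(d @ sol)
        df += p_k
    df -= p
    return McarTestResult(
        chi2=float(chi2),
        df=int(df),
        p_value=float(stats.chi2.sf(chi2, df)),
        n_patterns=len(patterns),
    )


# ---------------------------------------------------------------------------
# quadratic-term construction


def add_centered_quadratic(data: LongitudinalDataset, var: str):
    """Append sample-centered linear and squared columns for ``var``.

    The linear term is centered at the observed mean; the squared column
    is the square of the centered term and is *not* re-centered.
    Returns ``(dataset, x_mean, x_sd)`` with new columns ``{var}_c`` and
    ``{var}_c2``.
    """
    values = data.values.copy()
    if var not in values.columns:
        raise ValueError(f"variable {var!r} not in data")
    x = values[var]
    x_mean = float(x.mean())
    x_sd = float(x.std(ddof=1))
    c = x - x_mean
    values[f"{var}_c"] = c
    values[f"{var}_c2"] = c**2
    out = LongitudinalDataset(values=values, mask=values.notna(), meta=dict(data.meta))
    return out, x_mean, x_sd
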