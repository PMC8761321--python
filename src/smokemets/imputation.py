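"""Multiple imputation by chained equations and Rubin pooling.

``chained_impute`` runs m independent chains.  Each chain initialises
missing entries with random draws from the observed marginal of the same
variable, then sweeps the incomplete variables in turn: the variable's
conditional model (linear, logistic or multinomial on all other columns)
is fitted to the currently-completed data and the missing entries are
redrawn from the *predictive* distribution, including parameter
uncertainty via an approximate normal posterior draw of the coefficients
(and, for linear models, a scaled inverse-chi-square draw of the residual
variance).  Observed values are never altered and the whole procedure is
reproducible from the seed.

``pool_rubin`` combines per-imputation estimates with Rubin's rules:
total variance = within + (1 + 1/m) x between, and the CI uses a t
reference with Barnard-Rubin degrees of freedom.

``median_replace`` implements the simpler single-value rule used for the
handful of former smokers with unknown daily intensity: missing values
inside the eligible mask are set to the observed median of that mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "ImputationSpec",
    "PooledEstimate",
    "chained_impute",
    "pool_rubin",
    "median_replace",
]


@dataclass(frozen=True)
class ImputationSpec:
    """Settings for chained-equation imputation.

    ``variable_models`` maps each incomplete variable to its conditional
    family: ``"linear"`` (Gaussian), ``"logistic"`` (binary) or
    ``"multinomial"`` (categorical).  Defaults: m = 5 imputed datasets,
    10 sweeps per chain.
    """

    m: int = 5
    n_iterations: int = 10
    variable_models: Dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n_iterations < 1:
            raise ValueError("m and n_iterations must be >= 1")
        bad = {f for f in self.variable_models.values()} - {"linear", "logistic", "multinomial"}
        if bad:
            raise ValueError(f"unknown model families: {sorted(bad)}")


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    total_variance: float
    within_variance: float
    between_variance: float
    df: float
    ci: tuple


def _predictor_matrix(df: pd.DataFrame, target: str) -> np.ndarray:
    """Numeric design from all columns except the target (dummy-coding
    string/categorical predictors against their most frequent level)."""
    cols = [np.ones(len(df))]
    for c in df.columns:
        if c == target:
            continue
        s = df[c]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(s.dtype, pd.CategoricalDtype):
            cols.append(s.to_numpy(dtype=float))
        else:
            levels = sorted(s.astype(str).unique())
            ref = s.astype(str).value_counts().idxmax()
            for level in levels:
                if level != ref:
                    cols.append((s.astype(str) == level).to_numpy(dtype=float))
    return np.column_stack(cols)


def _draw_linear(y_obs, X_obs, X_mis, rng):
    n, p = X_obs.shape
    beta, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta
    dof = max(n - p, 1)
    s2 = float(resid @ resid) / dof
    sigma2 = s2 * dof / rng.chisquare(dof)
    xtx_inv = np.linalg.pinv(X_obs.T @ X_obs)
    cov = sigma2 * xtx_inv
    beta_draw = rng.multivariate_normal(beta, cov, method="cholesky" if _is_pd(cov) else "svd")
    return X_mis @ beta_draw + rng.standard_normal(X_mis.shape[0]) * np.sqrt(sigma2)


def _is_pd(a: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(a + 1e-12 * np.eye(a.shape[0]))
        return True
    except np.linalg.LinAlgError:
        return False


def _draw_logistic(y_obs, X_obs, X_mis, rng, name):
    try:
        res = sm.Logit(y_obs, X_obs).fit(disp=0, maxiter=100)
    except Exception as exc:  # separation etc.
        raise RuntimeError(f"conditional logistic model for {name!r} failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(f"conditional logistic model for {name!r} did not converge")
    cov = np.asarray(res.cov_params())
    beta_draw = rng.multivariate_normal(
        res.params, cov, method="cholesky" if _is_pd(cov) else "svd"
    )
    p = 1.0 / (1.0 + np.exp(-X_mis @ beta_draw))
    return (rng.random(X_mis.shape[0]) < p).astype(float)


def _draw_multinomial(y_obs, X_obs, X_mis, rng, name):
    levels, codes = np.unique(y_obs.astype(str), return_inverse=True)
    if len(levels) < 2:
        return np.repeat(levels[0], X_mis.shape[0])
    try:
        res = sm.MNLogit(codes, X_obs).fit(disp=0, maxiter=200, method="bfgs")
    except Exception as exc:
        raise RuntimeError(f"conditional multinomial model for {name!r} failed: {exc}") from exc
    flat = np.asarray(res.params).ravel(order="F")
    cov = np.asarray(res.cov_params())
    draw = rng.multivariate_normal(flat, cov, method="cholesky" if _is_pd(cov) else "svd")
    B = draw.reshape(res.params.shape, order="F")
    eta = np.column_stack([np.zeros(X_mis.shape[0]), X_mis @ B])
    eta -= eta.max(axis=1, keepdims=True)
    probs = np.exp(eta)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(X_mis.shape[0])[:, None]
    idx = (probs.cumsum(axis=1) < u).sum(axis=1)
    return levels[np.clip(idx, 0, len(levels) - 1)]


def chained_impute(df: pd.DataFrame, spec: ImputationSpec) -> list:
    """Return ``spec.m`` completed copies of ``df``.

    Every variable named in ``spec.variable_models`` that has missing
    entries is imputed; all other columns act as predictors and must be
    complete.  A variable with no observed values is an error.
    """
    incomplete = [c for c in spec.variable_models if df[c].isna().any()]
    for c in incomplete:
        if df[c].notna().sum() == 0:
            raise ValueError(f"variable {c!r} has no observed values")
        frac = df[c].isna().mean()
        if frac >= 0.5:
            raise ValueError(f"variable {c!r} is {frac:.0%} missing (>= 50%)")
    other = [c for c in df.columns if c not in spec.variable_models]
    if df[other].isna().any().any():
        bad = [c for c in other if df[c].isna().any()]
        raise ValueError(f"predictor columns contain missing values: {bad}")
    if not incomplete:
        return [df.copy() for _ in range(spec.m)]

    masks = {c: df[c].isna().to_numpy() for c in incomplete}
    completed = []
    for chain in range(spec.m):
        rng = np.random.default_rng([int(spec.seed), chain])
        work = df.copy()
        # initialise from observed marginals
        for c in incomplete:
            obs = work[c].dropna().to_numpy()
            work.loc[masks[c], c] = rng.choice(obs, size=int(masks[c].sum()), replace=True)
        for _ in range(spec.n_iterations):
            for c in incomplete:
                family = spec.variable_models[c]
                X = _predictor_matrix(work, c)
                miss = masks[c]
                y_obs = df.loc[~miss, c].to_numpy()
                X_obs, X_mis = X[~miss], X[miss]
                if family == "linear":
                    vals = _draw_linear(y_obs.astype(float), X_obs, X_mis, rng)
                elif family == "logistic":
                    vals = _draw_logistic(y_obs.astype(float), X_obs, X_mis, rng, c)
                else:
                    vals = _draw_multinomial(y_obs, X_obs, X_mis, rng, c)
                work.loc[miss, c] = vals
        completed.append(work)
    return completed


def pool_rubin(estimates: Sequence[float], variances: Sequence[float], df_com: float = np.inf) -> PooledEstimate:
    """Rubin's rules with a Barnard-Rubin t reference.

    ``df_com`` is the complete-data degrees of freedom (infinite for the
    large-sample normal reference).
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape:
        raise ValueError("estimates and variances must have the same length")
    if np.any(u < 0):
        raise ValueError("variances must be >= 0")
    m = q.shape[0]
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1)) if m > 1 else 0.0
    t = w + (1 + 1 / m) * b
    if b > 0 and m > 1:
        r = (1 + 1 / m) * b / w if w > 0 else np.inf
        nu_old = (m - 1) * (1 + 1 / r) ** 2
        if np.isfinite(df_com):
            lam = (1 + 1 / m) * b / t
            nu_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
            nu = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
        else:
            nu = nu_old
    else:
        nu = df_com
    crit = scipy.stats.t.ppf(0.975, nu) if np.isfinite(nu) else scipy.stats.norm.ppf(0.975)
    half = crit * np.sqrt(t)
    return PooledEstimate(
        estimate=qbar,
        total_variance=float(t),
        within_variance=w,
        between_variance=b,
        df=float(nu),
        ci=(qbar - half, qbar + half),
    )


def median_replace(values: Sequence[float], mask: Sequence[bool]) -> np.ndarray:
    """Fill missing entries within ``mask`` with the observed mask median.

    Values outside the mask are returned unchanged (including missing
    ones); at least one observed value inside the mask is required.
    """
    v = np.asarray(values, dtype=float).copy()
    m = np.asarray(mask, dtype=bool)
    obs = v[m & ~np.isnan(v)]
    fill = m & np.isnan(v)
    if fill.any():
        if obs.size == 0:
            raise ValueError("no observed values inside the mask to take a median from")
        v[fill] = np.median(obs)
    return v
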