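"""Multiple imputation by chained equations and Rubin's-rules pooling.

Variable-by-variable conditional imputation cycled for a fixed number of
sweeps and repeated m times.  Continuous (and count) targets use Bayesian
linear regression with predictive mean matching — each missing cell takes
the observed value of a donor drawn from the k observed cases whose
regression predictions are closest — so imputed values always lie in the
observed support (utilities stay in the index range, counts stay
non-negative).  Binary targets use a logistic draw with parameter
uncertainty, falling back to PMM when the fit is degenerate (separation,
too few cases).

Downstream estimates computed once per completed dataset are combined by
Rubin's rules: pooled estimate = mean, total variance = within +
(1 + 1/m) x between, with Barnard-Rubin small-sample degrees of freedom
when the complete-data degrees of freedom are supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = ["ImputationSpec", "PooledEstimate", "impute", "pool"]


@dataclass
class ImputationSpec:
    """Controls one chained-equations run.

    ``methods`` maps variable -> 'pmm' | 'logistic'; unlisted variables
    default to 'logistic' when their observed values are all 0/1 and
    'pmm' otherwise.  ``predictors`` maps variable -> predictor list;
    unlisted variables use every other column.
    """

    m: int = 20
    n_iterations: int = 10
    k_pmm: int = 5
    methods: dict = field(default_factory=dict)
    predictors: dict = field(default_factory=dict)
    seed: int = 0
    by_arm: bool = False

    def validate(self) -> None:
        if self.m < 2:
            raise ValueError(f"m: need >= 2 imputations, got {self.m}")
        if self.n_iterations < 1:
            raise ValueError(f"n_iterations: need >= 1, got {self.n_iterations}")
        if self.k_pmm < 1:
            raise ValueError(f"k_pmm: need >= 1, got {self.k_pmm}")


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m estimates."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))

    def conf_int(self, alpha: float = 0.05):
        from scipy import stats
        if not np.isfinite(self.df):
            t = stats.norm.ppf(1 - alpha / 2)
        else:
            t = stats.t.ppf(1 - alpha / 2, self.df)
        return (self.estimate - t * self.se, self.estimate + t * self.se)


def _bayes_linear_draw(rng, X_obs, y_obs, X_mis):
    """Posterior-draw predictions for PMM.

    Returns (yhat_obs under the ML fit, yhat_mis under a parameter draw).
    """
    n, p = X_obs.shape
    beta, _, rank, _ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta
    dof = max(n - rank, 1)
    sigma2 = (resid @ resid) / rng.chisquare(dof)
    XtX = X_obs.T @ X_obs
    # ridge jitter keeps the draw defined under collinearity
    cov = np.linalg.pinv(XtX + 1e-10 * np.eye(p)) * sigma2
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    beta_star = beta + L @ rng.standard_normal(p)
    return X_obs @ beta, X_mis @ beta_star


def _pmm_impute(rng, X_obs, y_obs, X_mis, k):
    if len(np.unique(y_obs)) == 1 or len(y_obs) <= X_obs.shape[1] + 1:
        # too little information for a regression: random observed donors
        return rng.choice(y_obs, size=len(X_mis))
    yhat_obs, yhat_mis = _bayes_linear_draw(rng, X_obs, y_obs, X_mis)
    k = min(k, len(y_obs))
    out = np.empty(len(X_mis))
    for i, ym in enumerate(yhat_mis):
        donors = np.argpartition(np.abs(yhat_obs - ym), k - 1)[:k]
        out[i] = y_obs[donors[rng.integers(k)]]
    return out


def _logistic_impute(rng, X_obs, y_obs, X_mis, k):
    if len(np.unique(y_obs)) == 1:
        return np.full(len(X_mis), y_obs[0])
    try:
        with np.errstate(all="ignore"):
            fit = sm.GLM(y_obs, X_obs, family=sm.families.Binomial()).fit(maxiter=50)
            beta = fit.params
            cov = fit.cov_params()
            L = np.linalg.cholesky(cov + 1e-10 * np.eye(len(beta)))
        beta_star = beta + L @ rng.standard_normal(len(beta))
        eta = np.clip(X_mis @ beta_star, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        return (rng.random(len(X_mis)) < p).astype(float)
    except Exception as exc:  # separation / singular fit
        logger.info("logistic imputation fell back to PMM: %s", exc)
        return _pmm_impute(rng, X_obs, y_obs, X_mis, k)


def _impute_once(rng, df, targets, spec, pool_cols):
    work = df.copy()
    masks = {v: df[v].isna().to_numpy() for v in targets}
    # start from random observed draws per variable
    for v in targets:
        obs = df[v].dropna().to_numpy(float)
        work.loc[masks[v], v] = rng.choice(obs, size=int(masks[v].sum()))
    order = sorted(targets, key=lambda v: int(masks[v].sum()))
    for _ in range(spec.n_iterations):
        for v in order:
            mis = masks[v]
            preds = spec.predictors.get(v, pool_cols)
            preds = [p for p in preds if p in pool_cols and p != v]
            X = work[preds].to_numpy(float)
            X = np.column_stack([np.ones(len(X)), X])
            y_obs = df.loc[~mis, v].to_numpy(float)
            method = spec.methods.get(v)
            if method is None:
                method = "logistic" if set(np.unique(y_obs)) <= {0.0, 1.0} else "pmm"
            fn = _logistic_impute if method == "logistic" else _pmm_impute
            work.loc[mis, v] = fn(rng, X[~mis], y_obs, X[mis], spec.k_pmm)
    return work


def impute(df: pd.DataFrame, spec: ImputationSpec,
           variables=None) -> list:
    """Run chained equations; returns m completed copies of ``df``.

    Only numeric columns are imputed; ``variables`` restricts the target
    set (default: every numeric column with at least one missing value).
    Observed cells are never modified.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    numeric = df.select_dtypes(include=[np.number]).columns
    targets = [v for v in (variables if variables is not None else numeric)
               if df[v].isna().any()]
    for v in targets:
        if df[v].notna().sum() == 0:
            raise ValueError(f"variable {v!r} has no observed values")
    if not targets:
        return [df.copy() for _ in range(spec.m)]
    non_target_numeric = [c for c in numeric if c not in targets]
    # predictor pool: targets (kept filled along the chain) plus complete
    # numeric columns; incomplete non-targets (e.g. death day, NaN = alive)
    # never enter a design matrix
    pool_cols = [c for c in numeric
                 if c in targets or not df[c].isna().any()]

    def _run(frame, substream):
        out = []
        for i in range(spec.m):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=spec.seed,
                                       spawn_key=(substream, i)))
            out.append(_impute_once(rng, frame, targets, spec, pool_cols))
        return out

    if spec.by_arm and "arm" in df.columns:
        by_label = {lab: _run(g, j) for j, (lab, g)
                    in enumerate(df.groupby("arm", sort=False))}
        completed = []
        for i in range(spec.m):
            parts = [by_label[lab][i] for lab in pd.unique(df["arm"])]
            completed.append(pd.concat(parts).loc[df.index])
    else:
        completed = _run(df, 0)
    # numeric columns without missingness must come back bit-identical
    for c in non_target_numeric:
        for comp in completed:
            comp[c] = df[c]
    return completed


def pool(estimates, variances, dfcom: float | None = None) -> PooledEstimate:
    """Rubin's rules for m (estimate, within-variance) pairs.

    ``dfcom`` is the complete-data residual degrees of freedom; when given
    the Barnard-Rubin adjusted df is reported, otherwise the classical
    large-sample df.
    """
    q = np.asarray(estimates, float)
    u = np.asarray(variances, float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be matching 1-d sequences")
    m = len(q)
    if m < 2:
        raise ValueError(f"pooling needs m >= 2 estimates, got {m}")
    qbar = float(q.mean())
    within = float(u.mean())
    between = float(q.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    if between == 0.0:
        df_t = float("inf")
    else:
        r = (1.0 + 1.0 / m) * between / within if within > 0 else float("inf")
        df_old = (m - 1) * (1.0 + 1.0 / r) ** 2 if np.isfinite(r) else float(m - 1)
        if dfcom is None:
            df_t = df_old
        else:
            lam = (1.0 + 1.0 / m) * between / total
            df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
            df_t = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    return PooledEstimate(estimate=qbar, within_var=within, between_var=between,
                          total_var=total, df=df_t, m=m)
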