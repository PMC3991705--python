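"""Regression-adjusted increments via identity-link GLMs.

Total cost is modelled with a gamma family and QALYs with a normal
family, both with an identity link, against the pre-specified covariate
set (arm, baseline utility for the QALY model only, stoma plan, viscus
plan, emergency surgery, age, BMI, diabetes, smoking, SSI).  Continuous
covariates are mean-centred so the arm coefficient is an at-the-means
adjusted increment.  The identity-link gamma fit can propose negative
means mid-iteration; estimation starts from the OLS coefficients and
falls back to log-link coefficients as starting values before giving up.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import DomainWarning

# identity-link gamma is deliberate (the adjusted increment must be
# additive in £); validity of the fitted means is checked after the fit
warnings.filterwarnings("ignore", category=DomainWarning)

from .imputation import pool, PooledEstimate

logger = logging.getLogger(__name__)

__all__ = ["AdjustmentSpec", "AdjustedResult", "fit_adjusted", "fit_adjusted_pooled",
           "COST_COVARIATES", "QALY_COVARIATES"]

COST_COVARIATES = ["stoma_planned", "viscus_planned", "emergency_surgery",
                   "age", "bmi", "diabetes", "smoker", "ssi"]
QALY_COVARIATES = ["baseline_utility"] + COST_COVARIATES

_CONTINUOUS = {"age", "bmi", "baseline_utility"}


@dataclass
class AdjustmentSpec:
    """One adjusted model: outcome, family, covariates, zero policy."""

    outcome: str = "cost"          # 'cost' | 'qaly'
    family: str = "gamma"          # 'gamma' | 'normal'
    covariates: list = field(default_factory=lambda: list(COST_COVARIATES))
    zero_handling: str = "shift"   # 'shift' | 'drop' (gamma family only)
    shift: float = 0.01

    def validate(self) -> None:
        if self.outcome not in ("cost", "qaly"):
            raise ValueError(f"outcome: unknown {self.outcome!r}")
        if self.family not in ("gamma", "normal"):
            raise ValueError(f"family: unknown {self.family!r}")
        if self.family == "gamma" and self.outcome != "cost":
            raise ValueError("family: gamma is reserved for the cost outcome")
        if self.family == "normal" and self.outcome != "qaly":
            raise ValueError("family: normal is reserved for the QALY outcome")
        if self.outcome == "cost" and "baseline_utility" in self.covariates:
            raise ValueError("covariates: baseline_utility enters the QALY "
                             "model only")
        if self.zero_handling not in ("shift", "drop"):
            raise ValueError(f"zero_handling: unknown {self.zero_handling!r}")

    @classmethod
    def cost_default(cls) -> "AdjustmentSpec":
        return cls(outcome="cost", family="gamma",
                   covariates=list(COST_COVARIATES))

    @classmethod
    def qaly_default(cls) -> "AdjustmentSpec":
        return cls(outcome="qaly", family="normal",
                   covariates=list(QALY_COVARIATES))


@dataclass
class AdjustedResult:
    adjusted_increment: float
    se: float
    ci_low: float
    ci_high: float
    coefficients: pd.DataFrame  # term, estimate, se, ci_low, ci_high
    converged: bool
    n: int


def _design(df, spec, outcome_col, intervention_label):
    cols = ["arm", outcome_col] + spec.covariates
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    use = df[cols].dropna()
    n, p = len(use), len(spec.covariates) + 2
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} complete records, have {n}")
    y = use[outcome_col].to_numpy(float)
    X = pd.DataFrame(index=use.index)
    X["const"] = 1.0
    X["arm"] = (use["arm"] == intervention_label).astype(float)
    for c in spec.covariates:
        v = use[c].to_numpy(float)
        X[c] = v - v.mean() if c in _CONTINUOUS else v
        uniq = np.unique(X[c])
        if len(uniq) == 1:
            raise ValueError(f"covariate {c!r} is constant in the "
                             "estimation sample")
        if c not in _CONTINUOUS and set(np.unique(v)) - {0.0, 1.0}:
            raise ValueError(f"covariate {c!r} is not binary")
    return y, X


def _gamma_deviance(y, mu):
    return 2.0 * float(np.sum(-np.log(y / mu) + (y - mu) / mu))


def _irls_gamma_identity(y, X, max_iter=500, tol=1e-10):
    """Fisher scoring for the identity-link gamma mean, with step-halving
    whenever a proposal leaves the positive-mean region or increases the
    deviance (plain IRLS oscillates on this model).  Returns the
    coefficient vector or None."""
    beta = np.zeros(X.shape[1])
    beta[0] = y.mean()
    mu = X @ beta
    dev = _gamma_deviance(y, mu)
    for _ in range(max_iter):
        w = 1.0 / mu**2
        wx = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ wx, wx.T @ y)
        except np.linalg.LinAlgError:
            return None
        step = beta_new - beta
        for h in range(60):
            cand = beta + step * 0.5**h
            mu_c = X @ cand
            if np.all(mu_c > 0):
                dev_c = _gamma_deviance(y, mu_c)
                if dev_c <= dev + 1e-12:
                    break
        else:
            return beta  # no improving direction: at (numerical) optimum
        beta, mu = cand, mu_c
        if abs(dev - dev_c) < tol * (abs(dev) + 1.0):
            return beta
        dev = dev_c
    return beta


class _GammaIdentityFit:
    """Wald summary for the step-halving IRLS solution.

    Covariance is φ̂ (XᵀWX)⁻¹ with W = 1/μ² and φ̂ the Pearson-based scale,
    matching the library's gamma-GLM convention; CIs are normal-based."""

    def __init__(self, beta, X, y):
        from scipy import stats as _st
        self.params = np.asarray(beta, float)
        self.mu = X @ self.params
        n, p = X.shape
        scale = float((((y - self.mu) / self.mu) ** 2).sum() / (n - p))
        w = 1.0 / self.mu**2
        cov = np.linalg.pinv(X.T @ (X * w[:, None])) * scale
        self.bse = np.sqrt(np.diag(cov))
        self.converged = True
        self._z = _st.norm.ppf(0.975)
        self.deviance = _gamma_deviance(y, self.mu)

    def conf_int(self, alpha: float = 0.05):
        return np.column_stack([self.params - self._z * self.bse,
                                self.params + self._z * self.bse])


def _fit_gamma_identity(y, X, spec):
    if spec.zero_handling == "drop":
        keep = y > 0
        if (~keep).any():
            logger.warning("dropping %d non-positive-cost records",
                           int((~keep).sum()))
        y, X = y[keep], X.loc[X.index[keep]]
    else:
        nonpos = y <= 0
        if nonpos.any():
            logger.warning("shifting %d non-positive costs by £%.2f",
                           int(nonpos.sum()), spec.shift)
            y = y.copy()
            y[nonpos] = spec.shift
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DomainWarning)
        model = sm.GLM(y, X, family=sm.families.Gamma(
            link=sm.families.links.Identity()))
    Xm = X.to_numpy(float)
    own = _irls_gamma_identity(y, Xm)
    if own is None:
        raise RuntimeError("gamma-identity GLM failed: singular Fisher "
                           "scoring step")
    own_dev = _gamma_deviance(y, Xm @ own)
    # library polish from the converged solution; its plain IRLS (no step
    # halving) can wander off, so accept it only if it keeps the deviance
    try:
        with np.errstate(all="ignore"):
            fit = model.fit(start_params=own, maxiter=500)
        if (fit.converged and np.all(fit.mu > 0)
                and fit.deviance <= own_dev + 1e-6 * (abs(own_dev) + 1.0)):
            return fit
    except Exception as exc:
        logger.info("library polish of gamma-identity fit failed: %s", exc)
    logger.info("using step-halving IRLS estimate with analytic Wald "
                "covariance (library IRLS did not hold the optimum)")
    return _GammaIdentityFit(own, Xm, y)


def _check_separation(X, y):
    for c in X.columns:
        if c == "const" or c in _CONTINUOUS:
            continue
        vals = X[c].to_numpy()
        if set(np.unique(vals)) == {0.0, 1.0}:
            g1, g0 = y[vals == 1.0], y[vals == 0.0]
            if len(g1) and len(g0) and (g1.max() < g0.min() or g0.max() < g1.min()):
                logger.warning("covariate %r perfectly separates the outcome", c)


def fit_adjusted(df: pd.DataFrame, spec: AdjustmentSpec,
                 *, outcome_col: str | None = None,
                 intervention_label="intervention") -> AdjustedResult:
    """Fit the specified GLM; the arm coefficient is the adjusted increment.

    ``outcome_col`` defaults to 'total_cost' for the cost model and
    'qaly' for the QALY model.  Wald 95% CIs are reported; pooling across
    multiply-imputed datasets uses :func:`fit_adjusted_pooled`.
    """
    spec.validate()
    outcome_col = outcome_col or ("total_cost" if spec.outcome == "cost" else "qaly")
    y, X = _design(df, spec, outcome_col, intervention_label)
    _check_separation(X, y)
    if spec.family == "normal":
        fit = sm.GLM(y, X, family=sm.families.Gaussian(
            link=sm.families.links.Identity())).fit()
        converged = True
    else:
        fit = _fit_gamma_identity(y, X, spec)
        converged = bool(fit.converged)
    ci = fit.conf_int()
    coef = pd.DataFrame({
        "term": X.columns,
        "estimate": np.asarray(fit.params),
        "se": np.asarray(fit.bse),
        "ci_low": np.asarray(ci)[:, 0],
        "ci_high": np.asarray(ci)[:, 1],
    })
    arm_row = coef[coef["term"] == "arm"].iloc[0]
    return AdjustedResult(
        adjusted_increment=float(arm_row["estimate"]),
        se=float(arm_row["se"]),
        ci_low=float(arm_row["ci_low"]),
        ci_high=float(arm_row["ci_high"]),
        coefficients=coef,
        converged=converged,
        n=len(y),
    )


def fit_adjusted_pooled(dfs, spec: AdjustmentSpec,
                        **kwargs) -> tuple[PooledEstimate, list]:
    """Fit one GLM per completed dataset and pool the arm coefficient
    by Rubin's rules (Barnard-Rubin df from the complete-data residual
    df).  Returns (pooled arm estimate, per-dataset results)."""
    results = [fit_adjusted(df, spec, **kwargs) for df in dfs]
    dfcom = results[0].n - len(results[0].coefficients)
    pooled = pool([r.adjusted_increment for r in results],
                  [r.se**2 for r in results], dfcom=dfcom)
    return pooled, results
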