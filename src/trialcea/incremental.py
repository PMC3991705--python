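"""Incremental cost-effectiveness: point estimates, dominance, BCa bootstrap.

The incremental cost ΔC and incremental effect ΔE are intervention-minus-
comparator arm means.  The ICER ΔC/ΔE is reported only in the trade-off
quadrants of the cost-effectiveness plane; elsewhere a dominance label is
emitted (a sign-ambiguous ratio carries no information).  Uncertainty is
quantified by a non-parametric bootstrap resampling patients with
replacement within arm (so arm sizes are preserved), with bias-corrected
and accelerated (BCa) 95% intervals: the bias constant z0 comes from the
fraction of replicates below the point estimate (midpoint tie convention)
and the acceleration from the jackknife skewness formula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "IncrementalResult",
    "increment",
    "classify",
    "bca_interval",
    "bca_bootstrap",
    "bootstrap_increments",
    "ce_plane_export",
]


def increment(intervention, comparator):
    """(ΔC, ΔE): intervention-minus-comparator (cost, effect) arm means."""
    (ci, ei), (cc, ec) = intervention, comparator
    return (float(ci) - float(cc), float(ei) - float(ec))


def classify(delta_cost: float, delta_effect: float):
    """ICER in the trade-off quadrants, a dominance label elsewhere.

    Returns a float (£/QALY) when both increments share a sign and the
    effect is nonzero; otherwise one of the dominance labels.
    """
    dc, de = float(delta_cost), float(delta_effect)
    if dc == 0.0 and de == 0.0:
        return "equivalent"
    if de == 0.0:
        return ("dominated (equal effect, higher cost)" if dc > 0
                else "dominant (equal effect, lower cost)")
    if dc == 0.0:
        return ("dominant (equal cost, greater effect)" if de > 0
                else "dominated (equal cost, lower effect)")
    if dc > 0 and de < 0:
        return "dominated"
    if dc < 0 and de > 0:
        return "dominant"
    return dc / de


def _jackknife_acceleration(jack: np.ndarray) -> float:
    d = jack.mean() - jack
    denom = (d**2).sum() ** 1.5
    if denom == 0:
        return 0.0
    return float((d**3).sum() / (6.0 * denom))


def bca_interval(replicates, point, jackknife_values=None,
                 alpha: float = 0.05, *, acceleration: float | None = None):
    """BCa (1-alpha) interval from bootstrap replicates of a scalar statistic.

    The acceleration is computed from leave-one-out ``jackknife_values``
    unless given directly via ``acceleration`` (used when pooling
    replicate clouds across imputed datasets).  With z0 = 0 and a = 0
    this reduces exactly to the percentile interval computed with the
    same quantile rule.
    """
    rep = np.asarray(replicates, float)
    if rep.size == 0:
        raise ValueError("no replicates")
    if np.ptp(rep) == 0.0:
        return (float(rep[0]), float(rep[0]))
    below = np.count_nonzero(rep < point) + 0.5 * np.count_nonzero(rep == point)
    frac = below / len(rep)
    frac = min(max(frac, 0.5 / len(rep)), 1.0 - 0.5 / len(rep))
    z0 = stats.norm.ppf(frac)
    if acceleration is not None:
        a = float(acceleration)
    elif jackknife_values is not None:
        a = _jackknife_acceleration(np.asarray(jackknife_values, float))
    else:
        raise ValueError("provide jackknife_values or acceleration")
    zlo, zhi = stats.norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])

    def adj(z):
        num = z0 + z
        return stats.norm.cdf(z0 + num / (1.0 - a * num))

    lo, hi = np.quantile(rep, [adj(zlo), adj(zhi)], method="linear")
    return (float(lo), float(hi))


def _stratified_indices(rng, groups):
    """Within-group resample with replacement; preserves group sizes."""
    idx = np.empty(sum(len(g) for g in groups), dtype=int)
    pos = 0
    for g in groups:
        idx[pos:pos + len(g)] = rng.choice(g, size=len(g), replace=True)
        pos += len(g)
    return idx


def bca_bootstrap(data: pd.DataFrame, statistic, B: int = 1000,
                  seed: int = 0, *, stratify_by: str | None = "arm",
                  alpha: float = 0.05, max_redraws: int = 100):
    """Generic patient-level BCa bootstrap of a scalar statistic.

    ``statistic`` maps a DataFrame to a float and must be computable on
    the full sample.  Resampling is within-``stratify_by`` groups by
    default (set None for plain resampling).  Replicates on which the
    statistic is undefined (NaN) are redrawn, with a logged count.
    Returns (point, replicates, (lo, hi)); deterministic given seed.
    """
    if B < 100:
        raise ValueError(f"B: need >= 100 replicates, got {B}")
    point = float(statistic(data))
    if np.isnan(point):
        raise ValueError("statistic undefined on the full sample")
    rng = np.random.default_rng(seed)
    n = len(data)
    if stratify_by is not None:
        groups = [np.flatnonzero(data[stratify_by].to_numpy() == lab)
                  for lab in pd.unique(data[stratify_by])]
    else:
        groups = [np.arange(n)]
    rep = np.empty(B)
    redraws = 0
    for b in range(B):
        val = np.nan
        for _ in range(max_redraws):
            val = statistic(data.iloc[_stratified_indices(rng, groups)])
            if not np.isnan(val):
                break
            redraws += 1
        if np.isnan(val):
            raise RuntimeError("statistic undefined after repeated redraws")
        rep[b] = val
    if redraws:
        logger.info("redrew %d degenerate bootstrap replicates", redraws)
    jack = np.array([statistic(data.drop(data.index[j])) for j in range(n)])
    return point, rep, bca_interval(rep, point, jack, alpha)


@dataclass
class IncrementalResult:
    """Point estimates and bootstrap uncertainty for (ΔC, ΔE)."""

    delta_cost: float
    delta_effect: float
    icer_or_label: object
    ci_cost: tuple
    ci_effect: tuple
    replicates: pd.DataFrame  # columns delta_cost, delta_effect
    B: int
    seed: int
    accel_cost: float = 0.0    # jackknife accelerations, reused when pooling
    accel_effect: float = 0.0  # replicate clouds across imputed datasets


def _arm_arrays(df, cost_col, effect_col, arm_col, intervention_label):
    labels = pd.unique(df[arm_col])
    if len(labels) != 2:
        raise ValueError(f"exactly two arms required, got {list(labels)}")
    if intervention_label not in set(labels):
        raise ValueError(f"arm {intervention_label!r} not present")
    comparator = [l for l in labels if l != intervention_label][0]
    out = {}
    for lab in (intervention_label, comparator):
        sub = df[df[arm_col] == lab]
        out[lab] = (sub[cost_col].to_numpy(float), sub[effect_col].to_numpy(float))
    return out, comparator


def bootstrap_increments(df: pd.DataFrame, B: int = 1000, seed: int = 0,
                         *, cost_col: str = "total_cost",
                         effect_col: str = "qaly", arm_col: str = "arm",
                         intervention_label="intervention",
                         alpha: float = 0.05) -> IncrementalResult:
    """Within-arm bootstrap of the (ΔC, ΔE) mean differences with BCa CIs.

    The mean-difference statistic is vectorised (resampled index matrices
    per arm) and its jackknife is closed-form, so B=1,000 on a
    735-patient trial runs in well under a second.  Rows with missing
    cost or effect are excluded up front (impute or restrict upstream).
    """
    if B < 100:
        raise ValueError(f"B: need >= 100 replicates, got {B}")
    use = df[[arm_col, cost_col, effect_col]].dropna()
    dropped = len(df) - len(use)
    if dropped:
        logger.info("bootstrap_increments: %d incomplete rows excluded", dropped)
    arms, comparator = _arm_arrays(use, cost_col, effect_col, arm_col,
                                   intervention_label)
    (ci, ei) = arms[intervention_label]
    (cc, ec) = arms[comparator]
    dc = float(ci.mean() - cc.mean())
    de = float(ei.mean() - ec.mean())

    rng = np.random.default_rng(seed)
    idx_i = rng.integers(0, len(ci), size=(B, len(ci)))
    idx_c = rng.integers(0, len(cc), size=(B, len(cc)))
    rep_c = ci[idx_i].mean(axis=1) - cc[idx_c].mean(axis=1)
    rep_e = ei[idx_i].mean(axis=1) - ec[idx_c].mean(axis=1)

    def loo(x):  # leave-one-out means
        return (x.sum() - x) / (len(x) - 1)

    jack_c = np.concatenate([loo(ci) - cc.mean(), ci.mean() - loo(cc)])
    jack_e = np.concatenate([loo(ei) - ec.mean(), ei.mean() - loo(ec)])

    return IncrementalResult(
        delta_cost=dc,
        delta_effect=de,
        icer_or_label=classify(dc, de),
        ci_cost=bca_interval(rep_c, dc, jack_c, alpha),
        ci_effect=bca_interval(rep_e, de, jack_e, alpha),
        replicates=pd.DataFrame({"delta_cost": rep_c, "delta_effect": rep_e}),
        B=B,
        seed=seed,
        accel_cost=_jackknife_acceleration(jack_c),
        accel_effect=_jackknife_acceleration(jack_e),
    )


def ce_plane_export(replicates: pd.DataFrame) -> pd.DataFrame:
    """Cost-effectiveness-plane table: one row per replicate with quadrant.

    Quadrants: I (ΔE>0, ΔC>0), II (ΔE<0, ΔC>0), III (ΔE<0, ΔC<0),
    IV (ΔE>0, ΔC<0); points on an axis are 'axis', the origin 'origin'.
    """
    de = replicates["delta_effect"].to_numpy(float)
    dc = replicates["delta_cost"].to_numpy(float)
    lab = np.full(len(de), "axis", dtype=object)
    lab[(de > 0) & (dc > 0)] = "I"
    lab[(de < 0) & (dc > 0)] = "II"
    lab[(de < 0) & (dc < 0)] = "III"
    lab[(de > 0) & (dc < 0)] = "IV"
    lab[(de == 0) & (dc == 0)] = "origin"
    return pd.DataFrame({"delta_effect": de, "delta_cost": dc, "quadrant": lab})
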