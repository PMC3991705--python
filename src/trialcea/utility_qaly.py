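"""EQ-5D-3L utility scoring and 30-day QALY construction.

Profiles on the five EQ-5D dimensions (mobility, self-care, usual
activities, pain/discomfort, anxiety/depression), each at level 1-3, are
scored with the UK time-trade-off value set: the index is 1 minus a
constant decrement applied once for any dysfunction, per-dimension
level-2/level-3 decrements, and a further constant when any dimension is
at level 3.  The index range is [-0.594, 1.0].

QALYs over the 30-day horizon are the area under the utility line between
the baseline and 30-day assessments (trapezoid), in years.  Deaths before
day 30 accrue utility declining linearly from baseline to zero at the day
of death and zero thereafter (switchable to last-value-carried-forward).
The interim 5-7 day assessment is never used here; it serves only as an
imputation predictor upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DIMENSIONS",
    "UK_MIN_INDEX",
    "load_tariff",
    "score_eq5d",
    "score_profile_string",
    "qaly_30d",
    "adjust_qaly_baseline",
    "BaselineAdjustment",
]

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

#: Floor of the UK TTO value set (profile 33333).
UK_MIN_INDEX = -0.594

DAYS_PER_YEAR = 365.25
HORIZON_DAYS = 30


def load_tariff(path=None) -> dict:
    """Load a tariff table into {'constant', 'n3', (dimension, level): decrement}.

    The bundled CSV is the UK TTO value set; a CSV with the same columns
    (term, level, decrement) substitutes any other additive 3L value set.
    """
    if path is None:
        src = resources.files("trialcea.data").joinpath("uk_tto_tariff.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    tariff: dict = {}
    for _, row in df.iterrows():
        term = row["term"]
        if term == "any_dysfunction":
            tariff["constant"] = float(row["decrement"])
        elif term == "any_level3":
            tariff["n3"] = float(row["decrement"])
        else:
            tariff[(term, int(row["level"]))] = float(row["decrement"])
    missing = [d for d in DIMENSIONS for l in (2, 3) if (d, l) not in tariff]
    if missing or "constant" not in tariff or "n3" not in tariff:
        raise ValueError(f"tariff table incomplete; missing terms: {missing}")
    return tariff


_TARIFF: dict | None = None


def _default_tariff() -> dict:
    global _TARIFF
    if _TARIFF is None:
        _TARIFF = load_tariff()
    return _TARIFF


def score_eq5d(profile, tariff: dict | None = None) -> float:
    """Score a five-level EQ-5D-3L profile to a utility index.

    Parameters
    ----------
    profile : sequence of five ints in {1, 2, 3}
        Levels for (mobility, self-care, usual activities, pain/discomfort,
        anxiety/depression).
    tariff : dict, optional
        As returned by :func:`load_tariff`; defaults to the UK TTO set.
    """
    levels = tuple(int(l) for l in profile)
    if len(levels) != 5 or any(l not in (1, 2, 3) for l in levels):
        raise ValueError(f"invalid EQ-5D-3L profile: {profile!r}")
    t = tariff if tariff is not None else _default_tariff()
    if levels == (1, 1, 1, 1, 1):
        return 1.0
    u = 1.0 - t["constant"]
    for dim, lev in zip(DIMENSIONS, levels):
        if lev > 1:
            u -= t[(dim, lev)]
    if 3 in levels:
        u -= t["n3"]
    return u


def score_profile_string(s, tariff: dict | None = None) -> float:
    """Score a profile written as a 5-digit string such as ``"11121"``."""
    s = str(s).strip()
    if len(s) != 5 or not s.isdigit():
        raise ValueError(f"expected a 5-digit profile string, got {s!r}")
    return score_eq5d([int(c) for c in s], tariff)


def qaly_30d(
    baseline_u,
    day30_u=None,
    death_day=None,
    *,
    days_per_year: float = DAYS_PER_YEAR,
    death_rule: str = "linear_to_zero",
) -> float | None:
    """QALYs accrued over the 30-day post-operative horizon.

    Utility is interpolated linearly between the baseline and 30-day
    assessments and the area under the line converted to years.  If the
    patient died on day ``d`` (0..30), utility runs from baseline to zero
    at day ``d`` and is zero thereafter (``death_rule='linear_to_zero'``),
    or is held at baseline until death (``'lvcf'``).

    Returns ``None`` when the 30-day utility is missing and there is no
    death — the case that flows to imputation or complete-case handling.
    """
    if baseline_u is None or (isinstance(baseline_u, float) and np.isnan(baseline_u)):
        return None
    baseline_u = float(baseline_u)
    if death_day is not None and not (
        isinstance(death_day, float) and np.isnan(death_day)
    ):
        d = int(death_day)
        if not 0 <= d <= HORIZON_DAYS:
            raise ValueError(f"death_day must be in [0, {HORIZON_DAYS}], got {d}")
        if death_rule == "linear_to_zero":
            area_days = baseline_u * d / 2.0
        elif death_rule == "lvcf":
            area_days = baseline_u * d
        else:
            raise ValueError(f"unknown death_rule {death_rule!r}")
        return area_days / days_per_year
    if day30_u is None or (isinstance(day30_u, float) and np.isnan(day30_u)):
        return None
    return (baseline_u + float(day30_u)) / 2.0 * HORIZON_DAYS / days_per_year


@dataclass
class BaselineAdjustment:
    """Result of regressing QALYs on arm with centred baseline utility."""

    incremental_qaly: float
    se: float
    ci_low: float
    ci_high: float
    adjusted_means: dict  # arm label -> model prediction at grand-mean baseline
    n: int
    params: pd.Series


def adjust_qaly_baseline(
    qaly,
    baseline_u,
    arm,
    *,
    intervention_label="intervention",
) -> BaselineAdjustment:
    """Baseline-utility-adjusted incremental QALY (regression adjustment).

    Ordinary least squares of QALY on an arm indicator and mean-centred
    baseline utility; the arm coefficient is the adjusted incremental QALY
    and the per-arm adjusted means are predictions at the grand-mean
    baseline utility.  Rows with any missing input are dropped.
    """
    df = pd.DataFrame(
        {"qaly": np.asarray(qaly, float), "u0": np.asarray(baseline_u, float),
         "arm": np.asarray(arm, object)}
    ).dropna()
    arms = pd.unique(df["arm"])
    if len(arms) != 2:
        raise ValueError(f"exactly two arms required, got {list(arms)}")
    if intervention_label not in set(arms):
        raise ValueError(f"arm label {intervention_label!r} not present")
    per_arm = df.groupby("arm").size()
    if (per_arm < 2).any():
        raise ValueError("need at least 2 complete records per arm")
    z = (df["arm"] == intervention_label).astype(float)
    u0c = df["u0"] - df["u0"].mean()
    X = sm.add_constant(pd.DataFrame({"arm": z, "baseline_u": u0c}))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("degenerate design: arm indicator and baseline utility collinear")
    fit = sm.OLS(df["qaly"], X).fit()
    beta = float(fit.params["arm"])
    ci = fit.conf_int().loc["arm"]
    control_label = [a for a in arms if a != intervention_label][0]
    means = {
        control_label: float(fit.params["const"]),
        intervention_label: float(fit.params["const"] + beta),
    }
    return BaselineAdjustment(
        incremental_qaly=beta,
        se=float(fit.bse["arm"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        adjusted_means=means,
        n=int(len(df)),
        params=fit.params,
    )
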