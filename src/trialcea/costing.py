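"""Patient-level costing under a unit-cost table.

Resource quantities (inpatient/ITU/HDU days, primary-care visits,
medication spend) are multiplied by unit costs and aggregated into an
inpatient block, a primary-care block and a grand total, mirroring the
standard cost-table layout of a within-trial evaluation.  Ward days are
the inpatient days not spent in ITU or HDU, floored at zero.  Missing
quantities propagate null components and null affected totals; imputation
(base case) or record dropping (complete case) happens upstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields as dc_fields
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "UnitCostTable",
    "CostBreakdown",
    "inflate_unit_cost",
    "load_hchs_index",
    "cost_patient",
    "cost_table",
    "summarise_costs",
    "round_pounds",
]

#: Resource items every cost model references.
REQUIRED_ITEMS = (
    "device",
    "ward_day",
    "itu_day",
    "hdu_day",
    "gp_visit",
    "practice_nurse_visit",
    "district_nurse_visit",
    "outpatient_visit",
)


@dataclass(frozen=True)
class UnitCostTable:
    """Map from resource item to unit cost in £ at a given price year."""

    entries: dict
    price_year: int = 2011
    inflation_index: dict | None = None

    def __post_init__(self):
        missing = [it for it in REQUIRED_ITEMS if it not in self.entries]
        if missing:
            raise ValueError(f"unit-cost table missing items: {missing}")
        bad = {k: v for k, v in self.entries.items() if v < 0}
        if bad:
            raise ValueError(f"negative unit costs: {bad}")

    def __getitem__(self, item: str) -> float:
        return float(self.entries[item])

    @classmethod
    def from_csv(cls, path=None) -> "UnitCostTable":
        """Read an (item, unit_cost, price_year, source) CSV.

        With no path, loads the bundled 2011-value table (device £15,
        general-ward day £311, ITU day £1,515, HDU day £856, GP visit £36,
        practice-nurse visit £13, district-nurse visit £73, outpatient
        visit £101).
        """
        if path is None:
            src = resources.files("trialcea.data").joinpath("table1_2011.csv")
            with resources.as_file(src) as p:
                df = pd.read_csv(p)
        else:
            df = pd.read_csv(path)
        entries = dict(zip(df["item"], df["unit_cost"].astype(float)))
        year = int(df["price_year"].max())
        return cls(entries=entries, price_year=year)


def load_hchs_index(path=None) -> dict:
    """Hospital & community health services pay-and-price index, year -> value.

    The bundled series is a synthetic stand-in with representative values;
    substitute the published series for production costing.
    """
    if path is None:
        src = resources.files("trialcea.data").joinpath("hchs_index_synthetic.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return dict(zip(df["year"].astype(int), df["index"].astype(float)))


def inflate_unit_cost(cost: float, from_year: int, to_year: int, index: dict) -> float:
    """Restate a unit cost across price years: cost × index(to)/index(from)."""
    if from_year == to_year:
        return float(cost)
    for y in (from_year, to_year):
        if y not in index:
            raise KeyError(f"year {y} not in inflation index")
    return float(cost) * index[to_year] / index[from_year]


@dataclass
class CostBreakdown:
    """Per-patient cost components in £; None marks a missing input."""

    intervention_cost: float | None
    ward_cost: float | None
    itu_cost: float | None
    hdu_cost: float | None
    gp_cost: float | None
    practice_nurse_cost: float | None
    district_nurse_cost: float | None
    outpatient_cost: float | None
    medication_cost: float | None
    inpatient_total: float | None
    primary_care_total: float | None
    total: float | None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def _sum_or_none(parts) -> float | None:
    if any(_is_missing(p) for p in parts):
        return None
    return float(sum(parts))


def cost_patient(
    record,
    costs: UnitCostTable,
    device_arm="intervention",
    *,
    missing_medication_as_zero: bool = True,
) -> CostBreakdown:
    """Cost one patient: each component is quantity × unit cost.

    ``record`` is any mapping (a dict, a pandas row) with the resource-use
    fields of the patient table.  The device cost applies to ``device_arm``
    patients only.  Ward days are inpatient_days − itu_days − hdu_days,
    floored at 0 (flooring is logged).  Medication spend arrives already
    priced in £; an absent field counts as £0 by default since it is not
    subject to missingness in the source data.
    """
    get = record.get if hasattr(record, "get") else lambda k, d=None: getattr(record, k, d)

    for f in ("inpatient_days", "itu_days", "hdu_days", "gp_visits",
              "practice_nurse_visits", "district_nurse_visits", "outpatient_visits"):
        v = get(f)
        if not _is_missing(v) and float(v) < 0:
            raise ValueError(f"negative resource quantity {f}={v}")

    arm = get("arm")
    intervention_cost = costs["device"] if arm == device_arm else 0.0

    inpat, itu, hdu = get("inpatient_days"), get("itu_days"), get("hdu_days")
    if _is_missing(inpat) or _is_missing(itu) or _is_missing(hdu):
        # any missing stay component blanks the ward decomposition
        ward_cost = None
        itu_cost = None if _is_missing(itu) else float(itu) * costs["itu_day"]
        hdu_cost = None if _is_missing(hdu) else float(hdu) * costs["hdu_day"]
    else:
        ward_days = float(inpat) - float(itu) - float(hdu)
        if ward_days < 0:
            logger.warning(
                "patient %s: ITU+HDU days exceed inpatient days (%s+%s > %s); "
                "ward days floored at 0",
                get("patient_id", "?"), itu, hdu, inpat,
            )
            ward_days = 0.0
        ward_cost = ward_days * costs["ward_day"]
        itu_cost = float(itu) * costs["itu_day"]
        hdu_cost = float(hdu) * costs["hdu_day"]

    def visit_cost(field, item):
        q = get(field)
        return None if _is_missing(q) else float(q) * costs[item]

    gp_cost = visit_cost("gp_visits", "gp_visit")
    pn_cost = visit_cost("practice_nurse_visits", "practice_nurse_visit")
    dn_cost = visit_cost("district_nurse_visits", "district_nurse_visit")
    op_cost = visit_cost("outpatient_visits", "outpatient_visit")

    med = get("medication_cost")
    if _is_missing(med):
        med_cost = 0.0 if missing_medication_as_zero else None
    else:
        med_cost = float(med)

    inpatient_total = _sum_or_none([ward_cost, itu_cost, hdu_cost])
    primary_total = _sum_or_none([gp_cost, pn_cost, dn_cost, op_cost, med_cost])
    total = _sum_or_none([intervention_cost, inpatient_total, primary_total])

    return CostBreakdown(
        intervention_cost=intervention_cost,
        ward_cost=ward_cost,
        itu_cost=itu_cost,
        hdu_cost=hdu_cost,
        gp_cost=gp_cost,
        practice_nurse_cost=pn_cost,
        district_nurse_cost=dn_cost,
        outpatient_cost=op_cost,
        medication_cost=med_cost,
        inpatient_total=inpatient_total,
        primary_care_total=primary_total,
        total=total,
    )


def cost_table(
    df: pd.DataFrame,
    costs: UnitCostTable,
    device_arm="intervention",
    **kwargs,
) -> pd.DataFrame:
    """Cost every patient in a trial table; returns one breakdown row per patient."""
    rows = [
        cost_patient(rec, costs, device_arm, **kwargs).as_dict()
        for rec in df.to_dict("records")
    ]
    out = pd.DataFrame(rows, index=df.index, dtype=float)
    out.insert(0, "arm", df["arm"].to_numpy())
    if "patient_id" in df:
        out.insert(0, "patient_id", df["patient_id"].to_numpy())
    return out


def _gamma_se(x: np.ndarray) -> float:
    """SE of the mean under a gamma MLE: mean / sqrt(n·α̂).

    Requires strictly positive values; callers fall back to SD/√n
    otherwise.
    """
    alpha, _, _ = stats.gamma.fit(x, floc=0)
    return float(np.mean(x) / math.sqrt(len(x) * alpha))


def summarise_costs(
    breakdowns: pd.DataFrame,
    by: str = "arm",
    *,
    se_method: str = "normal",
) -> pd.DataFrame:
    """Arm-level mean and SE per cost component.

    ``se_method='normal'`` is the distribution-free SD/√n; ``'gamma'``
    assumes gamma-distributed costs and uses the MLE-based SE (used only
    for components that are strictly positive in that arm; otherwise the
    distribution-free SE is reported and the fallback logged).
    """
    if se_method not in ("normal", "gamma"):
        raise ValueError(f"unknown se_method {se_method!r}")
    components = [
        c for c in breakdowns.columns if c not in ("patient_id", by)
    ]
    records = []
    for arm, grp in breakdowns.groupby(by, sort=False):
        if grp["total"].notna().sum() < 2:
            raise ValueError(f"arm {arm!r}: need >= 2 patients with non-null totals")
        for comp in components:
            x = grp[comp].dropna().to_numpy(float)
            if len(x) == 0:
                logger.warning("arm %r: component %s all-null", arm, comp)
                records.append({by: arm, "component": comp, "n": 0,
                                "mean": np.nan, "se": np.nan})
                continue
            mean = float(np.mean(x))
            se = float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0
            if se_method == "gamma" and len(x) > 1 and np.std(x) > 0:
                if np.all(x > 0):
                    se = _gamma_se(x)
                else:
                    logger.info(
                        "arm %r component %s has non-positive values; "
                        "gamma SE falls back to SD/sqrt(n)", arm, comp)
            records.append({by: arm, "component": comp, "n": int(len(x)),
                            "mean": mean, "se": se})
    return pd.DataFrame.from_records(records)


def round_pounds(x) -> float:
    """Report-time whole-£ rounding, half away from zero."""
    if _is_missing(x):
        return x
    return float(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))
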