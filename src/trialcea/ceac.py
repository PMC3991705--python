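"""Cost-effectiveness acceptability curves from bootstrap replicates.

At each willingness-to-pay threshold λ the intervention's acceptability is
the fraction of bootstrap replicates with positive incremental net
monetary benefit λ·ΔE_b − ΔC_b (exact ties count half toward each
alternative); the comparator's curve is the exact complement.  The default
grid spans £0-£50,000/QALY in £100 steps, covering the conventional NHS
decision range of £20,000-£30,000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CEACCurve", "default_wtp_grid", "ceac_from_replicates", "ceac_export"]


def default_wtp_grid(lo: float = 0.0, hi: float = 50_000.0,
                     step: float = 100.0) -> np.ndarray:
    return np.arange(lo, hi + step / 2, step)


@dataclass
class CEACCurve:
    wtp_grid: np.ndarray
    p_intervention: np.ndarray
    p_comparator: np.ndarray
    B: int

    def max_over(self, lo: float, hi: float) -> float:
        """Max intervention acceptability over grid points in [lo, hi]."""
        sel = (self.wtp_grid >= lo) & (self.wtp_grid <= hi)
        if not sel.any():
            raise ValueError(f"no grid points in [{lo}, {hi}]")
        return float(self.p_intervention[sel].max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid,
                             "p_intervention": self.p_intervention,
                             "p_comparator": self.p_comparator})


def ceac_from_replicates(replicates: pd.DataFrame, wtp_grid=None) -> CEACCurve:
    """Acceptability curve from (ΔC_b, ΔE_b) bootstrap replicates.

    ``replicates`` needs columns delta_cost and delta_effect; the grid
    must be strictly increasing and non-empty.
    """
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("wtp grid must be strictly increasing")
    dc = replicates["delta_cost"].to_numpy(float)
    de = replicates["delta_effect"].to_numpy(float)
    if len(dc) == 0:
        raise ValueError("no replicates")
    nmb = grid[:, None] * de[None, :] - dc[None, :]
    p_int = ((nmb > 0).sum(axis=1) + 0.5 * (nmb == 0).sum(axis=1)) / len(dc)
    return CEACCurve(wtp_grid=grid, p_intervention=p_int,
                     p_comparator=1.0 - p_int, B=len(dc))


def ceac_export(curve: CEACCurve, path) -> None:
    """Write a (wtp, p_intervention, p_comparator) CSV; round-trip stable."""
    curve.to_frame().to_csv(path, index=False, float_format="%.10f")
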