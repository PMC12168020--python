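"""Screen statistics: normalized betanin absorbance and growth rates.

nAb(betanin) = A535 / OD600 is the plate-reader proxy for per-cell pigment
production; percent change is reported against a control strain.  The
maximum specific growth rate µmax (per hour) is estimated as the largest
least-squares slope of ln(OD) versus time over a sliding window of
consecutive points above an OD floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PromoswapError


@dataclass
class PlateMeasurement:
    well_id: str
    strain_id: str
    od600: float
    a535: float
    blank_corrected: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.od600) and np.isfinite(self.a535)):
            raise PromoswapError(f"well {self.well_id}: non-finite measurement")


@dataclass
class GrowthCurve:
    strain_id: str
    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise PromoswapError(f"{self.strain_id}: times and od differ in length")
        if not np.all(np.diff(self.times) > 0):
            raise PromoswapError(f"{self.strain_id}: times must be strictly increasing")
        if np.any(self.od < 0):
            raise PromoswapError(f"{self.strain_id}: negative OD values")


def normalized_betanin(m: PlateMeasurement) -> float:
    """nAb = A535 / OD600."""
    if m.od600 <= 0:
        raise PromoswapError(f"well {m.well_id}: OD600 must be positive for normalization")
    if m.a535 < 0:
        warnings.warn(f"well {m.well_id}: negative A535 ({m.a535}); value returned")
    return m.a535 / m.od600


def percent_change(sample_nab: float, control_nab: float) -> float:
    """100 * (sample - control) / control."""
    if control_nab <= 0:
        raise PromoswapError("control nAb must be positive")
    return 100.0 * (sample_nab - control_nab) / control_nab


def max_growth_rate(curve: GrowthCurve, window: int = 5, od_floor: float = 0.0) -> float:
    """µmax (per hour): maximum sliding-window OLS slope of ln(OD) vs time.

    Only points with OD strictly above ``od_floor`` (and above zero) enter;
    windows run over consecutive retained points.  A sensible floor for
    real plates is ~3x the blank standard deviation.
    """
    if window < 2:
        raise PromoswapError("window must span at least 2 points")
    keep = curve.od > max(od_floor, 0.0)
    t = curve.times[keep]
    y = np.log(curve.od[keep])
    if t.size < window:
        raise PromoswapError(
            f"{curve.strain_id}: only {t.size} points above the OD floor; "
            f"need at least {window}"
        )
    best = -np.inf
    for i in range(t.size - window + 1):
        tw, yw = t[i:i + window], y[i:i + window]
        slope = np.polyfit(tw, yw, 1)[0]
        best = max(best, float(slope))
    return best


def rank_hits(table: pd.DataFrame) -> pd.DataFrame:
    """Rank strains by percent change of nAb, descending.

    Expects columns ``strain_id`` and ``percent_change`` (other columns,
    e.g. ``nab``, pass through).  Ties break lexicographically on
    strain_id.  Adds ``rank`` (1-based) and ``improved``; strains with no
    improvement anywhere are still ranked, flagged ``improved == False``.
    """
    if table.empty:
        raise PromoswapError("cannot rank an empty strain table")
    out = table.sort_values(
        ["percent_change", "strain_id"], ascending=[False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["improved"] = out["percent_change"] > 0
    return out
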