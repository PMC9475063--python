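"""Acoustic distance cues: dB-per-doubling fits and critical distance.

Sound pressure level and the direct-to-reverberant energy ratio (DRR) both
fall roughly linearly in dB per doubling of source distance in ordinary
rooms. This module fits cue-vs-distance tables with OLS on a log2 distance
axis and solves the DRR fit for the critical distance — the distance at
which direct and reverberant energies are equal (DRR = 0 dB).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .psychometrics import DataError

__all__ = ["CueFit", "CriticalDistance", "validate_cue_table",
           "fit_db_per_doubling", "critical_distance", "synthetic_cue_table"]

CUE_COLUMNS = ["distance_m", "level_db", "drr_db"]


class NoCrossingError(ValueError):
    """Raised when a cue fit never crosses 0 dB (zero slope)."""


@dataclass(frozen=True)
class CueFit:
    """OLS fit of a cue in dB against log2(distance)."""

    slope_db_per_doubling: float
    intercept_db: float
    r_squared: float
    distance_range_m: tuple[float, float]


@dataclass(frozen=True)
class CriticalDistance:
    distance_m: float
    extrapolated: bool


def validate_cue_table(table: pd.DataFrame) -> None:
    missing = [c for c in CUE_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"cue table missing columns {missing}")
    d = table["distance_m"].to_numpy(float)
    if len(d) < 2:
        raise DataError("cue table needs at least 2 rows")
    if np.any(d <= 0):
        raise DataError("distances must be > 0")
    if np.unique(d).size != d.size or not np.all(np.diff(d) > 0):
        raise DataError("distances must be unique and ascending")


def fit_db_per_doubling(distance_m, cue_db) -> CueFit:
    """Fit cue_db = intercept + slope * log2(distance); slope is the dB
    change per doubling of source distance."""
    x = np.asarray(distance_m, dtype=float)
    y = np.asarray(cue_db, dtype=float)
    if np.any(x <= 0):
        raise DataError("distances must be > 0")
    if np.unique(x).size < 2:
        raise DataError("at least 2 distinct distances are required")
    lx = np.log2(x)
    slope, intercept = np.polyfit(lx, y, 1)
    resid = y - (intercept + slope * lx)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return CueFit(
        slope_db_per_doubling=float(slope),
        intercept_db=float(intercept),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        distance_range_m=(float(x.min()), float(x.max())),
    )


def critical_distance(drr_fit: CueFit) -> CriticalDistance:
    """Distance where the fitted DRR crosses 0 dB: x = 2**(-b/m).

    Flagged as extrapolated when the crossing lies outside the fitted
    distance range.
    """
    if abs(drr_fit.slope_db_per_doubling) < 1e-9:
        raise NoCrossingError("flat DRR never crosses 0 dB")
    x = 2.0 ** (-drr_fit.intercept_db / drr_fit.slope_db_per_doubling)
    lo, hi = drr_fit.distance_range_m
    return CriticalDistance(distance_m=float(x), extrapolated=not (lo <= x <= hi))


def synthetic_cue_table(
    critical_distance_m: float = 2.38,
    distances_m=None,
    level_at_1m_db: float = 60.0,
    level_slope_db: float = -4.0,
) -> pd.DataFrame:
    """Physically motivated synthetic cue table for testing and examples.

    Direct energy follows the inverse-square law (proportional to 1/x**2)
    while reverberant energy is constant (diffuse field), so
    DRR(x) = 20*log10(critical/x) = slope -6.02 dB per doubling crossing
    0 dB exactly at the requested critical distance. Level falls linearly in
    dB per doubling of distance.
    """
    if distances_m is None:
        distances_m = np.arange(1.0, 5.01, 0.25)
    x = np.asarray(distances_m, dtype=float)
    drr = 10.0 * np.log10(critical_distance_m ** 2 / x ** 2)
    level = level_at_1m_db + level_slope_db * np.log2(x)
    return pd.DataFrame({"distance_m": x, "level_db": level, "drr_db": drr})
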