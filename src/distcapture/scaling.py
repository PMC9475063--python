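"""Power-law scaling of perceived distance.

Absolute distance judgments in both hearing and vision are classically
summarised by Stevens-type power functions y = k * x**a relating judged to
physical distance: a < 1 means compressive underestimation of far targets.
Fits are performed by ordinary least squares on ln(judged) vs ln(target) —
exact, unique, and consistent with geometric-mean averaging and a log-normal
error model — with an optional nonlinear fit in linear space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .psychometrics import DataError

__all__ = ["PowerFit", "geometric_mean", "fit_power", "perceived_mean", "fit_power_judgments"]


@dataclass(frozen=True)
class PowerFit:
    """Fitted mapping from physical to mean perceived distance: k * x**a."""

    k: float
    a: float
    r_squared: float
    modality: str = ""
    n: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise DataError("power-law constant k must be > 0")


def geometric_mean(values) -> float:
    """exp(mean(ln(values))); the natural average for log-normal judgments."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.any(v <= 0):
        raise DataError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(v))))


def fit_power(target_m, judged_m, space: str = "log", modality: str = "") -> PowerFit:
    """Fit y = k * x**a to judged vs physical distance.

    ``space="log"`` (default) regresses ln(y) on ln(x) by OLS; a is the
    slope, k the exponentiated intercept, and R**2 the proportion of
    log-judgment variance explained. ``space="linear"`` minimises squared
    error on the linear scale by nonlinear least squares instead.
    """
    x = np.asarray(target_m, dtype=float)
    y = np.asarray(judged_m, dtype=float)
    if x.shape != y.shape:
        raise DataError("target and judged vectors must have equal length")
    if np.any(x <= 0) or np.any(y <= 0):
        raise DataError("distances and judgments must be > 0")
    if np.unique(x).size < 2:
        raise DataError("at least 2 distinct target distances are required")

    if space == "log":
        lx, ly = np.log(x), np.log(y)
        a, logk = np.polyfit(lx, ly, 1)
        resid = ly - (logk + a * lx)
        ss_tot = float(np.sum((ly - ly.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
        return PowerFit(k=float(np.exp(logk)), a=float(a),
                        r_squared=float(np.clip(r2, 0.0, 1.0)),
                        modality=modality, n=x.size)
    if space == "linear":
        (k, a), _ = curve_fit(lambda xx, k, a: k * xx ** a, x, y,
                              p0=(1.0, 1.0), maxfev=10000)
        resid = y - k * x ** a
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
        return PowerFit(k=float(k), a=float(a),
                        r_squared=float(np.clip(r2, 0.0, 1.0)),
                        modality=modality, n=x.size)
    raise ValueError(f"unknown fitting space {space!r}")


def perceived_mean(fit: PowerFit, x) -> np.ndarray | float:
    """Mean perceived distance k * x**a at physical distance x (m)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DataError("distance must be > 0")
    out = fit.k * x ** fit.a
    return float(out) if out.ndim == 0 else out


def fit_power_judgments(
    judgments: pd.DataFrame, per_subject: bool = False, space: str = "log"
) -> pd.DataFrame:
    """Fit power functions to an absolute-judgment table per modality.

    Group fits (default) first take geometric means of judgments across
    subjects at each target distance; per-subject fits use each subject's raw
    single judgments. Returns a tidy table with columns
    ``[subject_id,] modality, k, a, r_squared, n``.
    """
    required = {"subject_id", "modality", "target_m", "judged_m"}
    if not required.issubset(judgments.columns):
        raise DataError(f"judgment table must have columns {sorted(required)}")
    rows = []
    if per_subject:
        for (s, mod), sub in judgments.groupby(["subject_id", "modality"]):
            fit = fit_power(sub["target_m"], sub["judged_m"], space=space, modality=mod)
            rows.append((s, mod, fit.k, fit.a, fit.r_squared, fit.n))
        return pd.DataFrame(rows, columns=["subject_id", "modality", "k", "a", "r_squared", "n"])
    for mod, sub in judgments.groupby("modality"):
        gm = sub.groupby("target_m")["judged_m"].apply(geometric_mean)
        fit = fit_power(gm.index.to_numpy(), gm.to_numpy(), space=space, modality=mod)
        rows.append((mod, fit.k, fit.a, fit.r_squared, fit.n))
    return pd.DataFrame(rows, columns=["modality", "k", "a", "r_squared", "n"])
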