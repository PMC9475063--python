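"""Constrained least-squares fitting of coincidence models to d' data.

Each model variant is fitted per visual-target block by bound-constrained
nonlinear least squares on the observed-minus-predicted d' residuals, with
1, 2 or 3 free parameters:

    1 -> {k_aud}
    2 -> {k_aud, r}
    3 -> {k_aud, r, sigma_factor_aud}

k_aud is free because visual percepts may anchor the auditory distance scale
under bimodal presentation; r in [0, 1] is the inter-modal percept
correlation; the third parameter is the auditory variability factor (whose
natural log is the auditory log-SD for M3). The objective is non-convex in
k_aud, so each fit runs from a small deterministic multi-start grid and
keeps the best optimum. Model comparison uses the RMS error of the fitted
curve in d' units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .models import (
    MODEL_VARIANTS,
    DegenerateModelError,
    ModelSpec,
    predict_dprime,
)
from .observer import ParameterError
from .psychometrics import DataError, DPrimeCurve

__all__ = ["FitResult", "rms_error", "fit_model", "fit_all_models", "compare_models", "rms_summary"]

K_AUD_BOUNDS = (0.05, 20.0)
R_BOUNDS = (0.0, 1.0)
FACTOR_BOUNDS = (1.0 + 1e-9, 10.0)

_STARTS_K = (0.5, 1.0, 2.0)
_STARTS_R = (0.0, 0.5, 0.9)
_STARTS_FACTOR = (1.3, 1.7, 2.5)

_BIG_RESIDUAL = 1e6


@dataclass(frozen=True)
class FitResult:
    variant: str
    n_params: int
    k_aud: float
    r: float
    sigma_factor_aud: float | None
    rms_error: float
    visual_m: float
    scope: str = "pooled"
    converged: bool = True


def rms_error(observed, predicted) -> float:
    """Root mean squared difference between two equal-length vectors."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.size == 0:
        raise DataError("observed and predicted must be equal-length, non-empty")
    return float(np.sqrt(np.mean((o - p) ** 2)))


def _free_parameters(n_params: int):
    if n_params == 1:
        return ("k_aud",)
    if n_params == 2:
        return ("k_aud", "r")
    if n_params == 3:
        return ("k_aud", "r", "sigma_factor_aud")
    raise ParameterError("n_params must be 1, 2 or 3")


def _apply(spec: ModelSpec, names, theta) -> ModelSpec:
    kw = {}
    for name, value in zip(names, theta):
        if name == "k_aud":
            kw["k_aud_override"] = float(value)
        elif name == "r":
            kw["r"] = float(value)
        else:
            kw["aud_factor"] = float(value)
    return spec.with_params(**kw)


def fit_model(curve: DPrimeCurve, spec: ModelSpec, n_params: int = 2,
              scope: str = "pooled") -> FitResult:
    """Fit one model variant to one block's observed d' curve.

    Minimises the unweighted sum of squared (observed - predicted) d' over
    the block's auditory distances, subject to k_aud in [0.05, 20],
    r in [0, 1] and sigma factor in (1, 10]. Fixed parameters stay at the
    values carried by ``spec``. Runs a deterministic multi-start grid and
    returns the best optimum; ``converged=False`` flags a fit where no start
    terminated cleanly (the best point found is still reported).
    """
    names = _free_parameters(n_params)
    if curve.auditory_m.size < n_params + 1:
        raise DataError("curve must have more points than free parameters")
    observed = np.asarray(curve.dprime, dtype=float)

    bounds_map = {"k_aud": K_AUD_BOUNDS, "r": R_BOUNDS, "sigma_factor_aud": FACTOR_BOUNDS}
    lo = np.array([bounds_map[n][0] for n in names])
    hi = np.array([bounds_map[n][1] for n in names])

    def residuals(theta):
        try:
            pred = predict_dprime(_apply(spec, names, theta), curve.visual_m,
                                  curve.auditory_m)
        except DegenerateModelError:
            return np.full(observed.shape, _BIG_RESIDUAL)
        return np.asarray(pred) - observed

    starts_map = {"k_aud": _STARTS_K, "r": _STARTS_R, "sigma_factor_aud": _STARTS_FACTOR}
    grids = np.meshgrid(*[starts_map[n] for n in names], indexing="ij")
    starts = np.stack([g.ravel() for g in grids], axis=-1)

    best = None
    any_converged = False
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        res = least_squares(residuals, x0, bounds=(lo, hi),
                            xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=500)
        if best is None or res.cost < best.cost:
            best = res
        any_converged = any_converged or (res.status > 0)

    fitted = dict(zip(names, best.x))
    final = _apply(spec, names, best.x)
    try:
        pred = predict_dprime(final, curve.visual_m, curve.auditory_m)
        rms = rms_error(observed, pred)
    except DegenerateModelError:
        rms = float("inf")
    return FitResult(
        variant=spec.variant,
        n_params=n_params,
        k_aud=float(fitted.get("k_aud", spec.k_aud)),
        r=float(fitted.get("r", spec.r)),
        sigma_factor_aud=(float(fitted["sigma_factor_aud"])
                          if "sigma_factor_aud" in fitted else None),
        rms_error=rms,
        visual_m=curve.visual_m,
        scope=scope,
        converged=bool(any_converged),
    )


def fit_all_models(curve: DPrimeCurve, base_spec: ModelSpec, n_params: int = 2,
                   variants: Iterable[str] = MODEL_VARIANTS,
                   scope: str = "pooled") -> list[FitResult]:
    """Fit every requested model variant to one block's d' curve."""
    return [
        fit_model(curve, base_spec.with_params(variant=v), n_params, scope=scope)
        for v in variants
    ]


def compare_models(
    curves: Mapping,
    base_spec: ModelSpec,
    n_params: int = 2,
    variants: Iterable[str] = MODEL_VARIANTS,
) -> pd.DataFrame:
    """Fit all variants to every block and tabulate RMS errors.

    ``curves`` maps either ``visual_m -> DPrimeCurve`` (pooled analysis) or
    ``(subject_id, visual_m) -> DPrimeCurve`` (per-subject analysis, which
    feeds the mean +/- SE summary of :func:`rms_summary`). Returns a tidy
    table with one row per (scope, visual_m, variant).
    """
    if not curves:
        raise DataError("no curves to fit")
    rows = []
    for key, curve in curves.items():
        scope = "pooled" if not isinstance(key, tuple) else f"subject:{key[0]}"
        for fit in fit_all_models(curve, base_spec, n_params, variants, scope=scope):
            rows.append(
                (fit.visual_m, fit.variant, fit.n_params, fit.scope, fit.k_aud,
                 fit.r, fit.sigma_factor_aud, fit.rms_error, fit.converged)
            )
    return pd.DataFrame(
        rows,
        columns=["visual_m", "model", "n_params", "scope", "k_aud", "r",
                 "sigma_factor_aud", "rms_error", "converged"],
    ).sort_values(["visual_m", "model", "scope"]).reset_index(drop=True)


def rms_summary(comparison: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- standard error of RMS error across subjects per
    (model, visual distance) — the headline model-comparison summary for
    per-subject fits."""
    required = {"visual_m", "model", "scope", "rms_error"}
    if not required.issubset(comparison.columns):
        raise DataError(f"comparison table must have columns {sorted(required)}")
    sub = comparison[comparison["scope"] != "pooled"]
    if len(sub) == 0:
        raise DataError("summary requires per-subject fits")
    g = sub.groupby(["model", "visual_m"])["rms_error"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "rms_mean", "sem": "rms_se", "count": "n_subjects"})
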