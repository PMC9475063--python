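"""Empirical analysis of yes/no coincidence responses.

Turns trial-level coincidence responses into proportion-coincident curves
and the d' mismatch statistic

    d' = z(pc_max) - z(pc)

where pc is the proportion of "coincident" responses at each auditory target
distance, pc_max its maximum within a visual-target block, and z the standard
normal quantile. d' = 0 at the distance of strongest capture and grows with
perceptual mismatch. Confidence intervals come from subject-level bootstrap
resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .observer import ParameterError

__all__ = [
    "DataError",
    "DPrimeCurve",
    "proportion_coincident",
    "empirical_dprime",
    "dprime_curves",
    "predict_pc",
    "bootstrap_ci",
]

RESPONSE_COLUMNS = ["subject_id", "visual_m", "auditory_m", "trial_idx", "response"]


class DataError(ValueError):
    """Raised for malformed or insufficient response data."""


@dataclass
class DPrimeCurve:
    """Empirical (or resampled) d' vs auditory distance for one visual block."""

    visual_m: float
    auditory_m: np.ndarray
    pc: np.ndarray
    pc_max: float
    ref_distance_m: float
    dprime: np.ndarray
    n_per_point: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None


def _validate_responses(table: pd.DataFrame) -> None:
    missing = [c for c in RESPONSE_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"response table missing columns {missing}")
    if len(table) == 0:
        raise DataError("response table is empty")
    if not table["response"].isin([0, 1]).all():
        raise DataError("responses must be 0 or 1")
    if (table[["visual_m", "auditory_m"]] <= 0).any().any():
        raise DataError("distances must be > 0")


def proportion_coincident(table: pd.DataFrame, pooled: bool = True) -> pd.DataFrame:
    """Proportion of coincident responses per (visual, auditory) cell.

    With ``pooled=True`` trials are aggregated across subjects; otherwise one
    row per subject x cell. Returns columns
    ``[subject_id,] visual_m, auditory_m, n_trials, n_coincident, pc``.
    """
    _validate_responses(table)
    keys = ["visual_m", "auditory_m"] if pooled else ["subject_id", "visual_m", "auditory_m"]
    grouped = table.groupby(keys, sort=True)["response"].agg(["count", "sum"])
    if (grouped["count"] == 0).any():
        raise DataError("empty response cell after grouping")
    out = grouped.rename(columns={"count": "n_trials", "sum": "n_coincident"}).reset_index()
    out["pc"] = out["n_coincident"] / out["n_trials"]
    return out


def _clamp_pc(pc: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Clamp proportions away from 0/1 so z-scores stay finite:
    pc in [1/(2n), 1 - 1/(2n)]."""
    lo = 1.0 / (2.0 * n)
    return np.clip(pc, lo, 1.0 - lo)


def _ref_index(auditory_m: np.ndarray, pc: np.ndarray, visual_m: float) -> int:
    """Index of pc_max; ties resolved toward the distance closest to the
    visual target, remaining ties toward the smaller distance."""
    best = pc.max()
    tied = np.flatnonzero(pc == best)
    order = sorted(tied, key=lambda i: (abs(auditory_m[i] - visual_m), auditory_m[i]))
    return int(order[0])


def empirical_dprime(
    auditory_m: np.ndarray,
    pc: np.ndarray,
    n_per_point: np.ndarray | int,
    visual_m: float,
) -> DPrimeCurve:
    """Compute d' = z(pc_max) - z(pc) for one visual-target block.

    Proportions are clamped to [1/(2n), 1 - 1/(2n)] before the z-transform so
    extreme cells stay finite; the reference (pc_max) distance has d' = 0 by
    construction.
    """
    auditory_m = np.asarray(auditory_m, dtype=float)
    pc = np.asarray(pc, dtype=float)
    n = np.broadcast_to(np.asarray(n_per_point, dtype=float), pc.shape)
    if auditory_m.size < 2:
        raise DataError("at least 2 auditory distances are required")
    if (n < 1).any():
        raise DataError("n_per_point must be >= 1")
    pc_cl = _clamp_pc(pc, n)
    ref = _ref_index(auditory_m, pc_cl, visual_m)
    z = norm.ppf(pc_cl)
    dprime = z[ref] - z
    return DPrimeCurve(
        visual_m=float(visual_m),
        auditory_m=auditory_m,
        pc=pc,
        pc_max=float(pc[ref]),
        ref_distance_m=float(auditory_m[ref]),
        dprime=dprime,
        n_per_point=n.astype(int),
    )


def dprime_curves(table: pd.DataFrame, pooled: bool = True) -> dict:
    """Empirical d' curves for every visual block in a response table.

    Returns ``{visual_m: DPrimeCurve}`` when pooled, else
    ``{(subject_id, visual_m): DPrimeCurve}``.
    """
    pc_table = proportion_coincident(table, pooled=pooled)
    curves: dict = {}
    if pooled:
        for v, sub in pc_table.groupby("visual_m"):
            curves[float(v)] = empirical_dprime(
                sub["auditory_m"].to_numpy(), sub["pc"].to_numpy(),
                sub["n_trials"].to_numpy(), float(v),
            )
    else:
        for (s, v), sub in pc_table.groupby(["subject_id", "visual_m"]):
            curves[(s, float(v))] = empirical_dprime(
                sub["auditory_m"].to_numpy(), sub["pc"].to_numpy(),
                sub["n_trials"].to_numpy(), float(v),
            )
    return curves


def predict_pc(mu_diff, sd_diff, c) -> np.ndarray | float:
    """Closed-form probability that |A - V| <= c for the differencing
    observer, with A - V ~ N(mu_diff, sd_diff**2):

        pc = Phi((c - mu)/sd) - Phi((-c - mu)/sd)
    """
    mu = np.asarray(mu_diff, dtype=float)
    sd = np.asarray(sd_diff, dtype=float)
    if np.any(sd <= 0):
        raise ParameterError("sd_diff must be > 0")
    if np.any(np.asarray(c) <= 0):
        raise ParameterError("criterion c must be > 0")
    out = norm.cdf((c - mu) / sd) - norm.cdf((-c - mu) / sd)
    return float(out) if out.ndim == 0 else out


def bootstrap_ci(
    table: pd.DataFrame,
    B: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> dict[float, DPrimeCurve]:
    """Pooled d' curves with subject-resampling bootstrap confidence bands.

    Subjects are resampled with replacement B times, keeping each subject's
    trials intact; pooled pc and d' are recomputed per resample and the
    percentile 2.5/97.5 bounds (for the default 95% level) are attached per
    auditory distance.
    """
    _validate_responses(table)
    if B < 1:
        raise DataError("B must be >= 1")
    subjects = np.sort(table["subject_id"].unique())
    if subjects.size < 2:
        raise DataError("subject-level bootstrap requires at least 2 subjects")
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci_level) / 2.0
    curves = dprime_curves(table, pooled=True)

    per_subj = proportion_coincident(table, pooled=False)
    out: dict[float, DPrimeCurve] = {}
    for v, curve in curves.items():
        sub = per_subj[per_subj["visual_m"] == v]
        # subject x distance matrices of coincident counts and trial counts
        coin = sub.pivot(index="subject_id", columns="auditory_m", values="n_coincident")
        ntr = sub.pivot(index="subject_id", columns="auditory_m", values="n_trials")
        coin = coin.reindex(index=subjects, columns=curve.auditory_m).to_numpy(float)
        ntr = ntr.reindex(index=subjects, columns=curve.auditory_m).to_numpy(float)
        if np.isnan(coin).any() or np.isnan(ntr).any():
            raise DataError("every subject must contribute to every cell")
        idx = rng.integers(0, subjects.size, size=(B, subjects.size))
        coin_b = coin[idx].sum(axis=1)            # (B, D)
        n_b = ntr[idx].sum(axis=1)
        pc_b = _clamp_pc(coin_b / n_b, n_b)
        # tie-break preference order: |d - v| then d; argmax takes the first max
        pref = np.lexsort((curve.auditory_m, np.abs(curve.auditory_m - v)))
        ref_pos = pref[np.argmax(pc_b[:, pref], axis=1)]
        z_b = norm.ppf(pc_b)
        d_b = z_b[np.arange(B), ref_pos][:, None] - z_b
        lo = np.quantile(d_b, alpha, axis=0)
        hi = np.quantile(d_b, 1.0 - alpha, axis=0)
        out[v] = DPrimeCurve(
            visual_m=curve.visual_m,
            auditory_m=curve.auditory_m,
            pc=curve.pc,
            pc_max=curve.pc_max,
            ref_distance_m=curve.ref_distance_m,
            dprime=curve.dprime,
            n_per_point=curve.n_per_point,
            ci_low=lo,
            ci_high=hi,
        )
    return out
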