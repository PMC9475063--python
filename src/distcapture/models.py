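"""Probabilistic coincidence models for audio-visual distance capture.

A coincidence judgment is modelled as a comparison of two internal percept
distributions — perceived auditory and perceived visual distance — whose
overlap is summarised by the signal-detection sensitivity index

    d' = |mu_aud - mu_vis| / sqrt(sigma_aud**2 + sigma_vis**2
                                  - 2 r sigma_aud sigma_vis)

with r the inter-modal percept correlation. Mean perceived distance follows
power laws k * x**a per modality; variability enters as multiplicative
factors of perceived distance (10**0.23 auditory, 10**0.15 visual).

Three variants differ in scale and variance handling:

* M1 — linear distance scale, variances frozen at a reference distance (3 m);
* M2 — linear distance scale, SDs scale with each target's perceived mean;
* M3 — logarithmic distance scale: percepts are normal in log-distance
  (log-normal in linear distance) with log-SDs ln(factor).

For M3 the sensitivity index is, by default, evaluated on the log scale,
where both percept distributions are exactly normal and the index is exact;
this produces the hallmark asymmetry of capture along the linear distance
axis (sources nearer than the visual target are easier to reject than
sources farther by the same linear offset). Re-expressing M3 in linear space
through log-normal moments is available via ``m3_space="linear"`` (with an
additional as-printed moment-formula variant) for comparison; that
approximation shifts the predicted minimum and weakens the near/far
asymmetry at small offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .observer import ParameterError
from .scaling import PowerFit, perceived_mean

__all__ = [
    "AUD_VARIABILITY_FACTOR",
    "VIS_VARIABILITY_FACTOR",
    "DegenerateModelError",
    "PerceptDistribution",
    "ModelSpec",
    "sensitivity_dprime",
    "lognormal_moments",
    "predict_dprime",
    "parameter_sweep",
]

# Multiplicative variability factors of perceived distance, from large-sample
# absolute-judgment data: 10**0.23 (auditory), 10**0.15 (visual).
AUD_VARIABILITY_FACTOR: float = 10.0 ** 0.23
VIS_VARIABILITY_FACTOR: float = 10.0 ** 0.15

MODEL_VARIANTS = ("M1", "M2", "M3")


class DegenerateModelError(ValueError):
    """Raised when the difference distribution has non-positive variance."""


@dataclass(frozen=True)
class PerceptDistribution:
    """Percept distribution in one modality, on a linear or log scale.

    For ``scale="log"``, (m_log, s_log) are the defining normal parameters in
    log-distance and (mu, sigma) the implied log-normal linear moments.
    """

    mu: float
    sigma: float
    scale: str = "linear"
    m_log: float | None = None
    s_log: float | None = None

    @classmethod
    def from_log(cls, m_log: float, s_log: float, printed: bool = False) -> "PerceptDistribution":
        mu, sigma = lognormal_moments(m_log, s_log, printed=printed)
        return cls(mu=mu, sigma=sigma, scale="log", m_log=m_log, s_log=s_log)


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one coincidence-model variant.

    ``aud_fit``/``vis_fit`` supply the power-law distance functions estimated
    from absolute judgments; ``k_aud_override`` replaces the auditory
    constant when the model treats it as a free parameter. ``m3_space``
    selects log-scale (default) or linear-moment evaluation for M3;
    ``printed_formula_mode`` switches the linear-moment conversion to the
    as-printed (non-standard) mean formula.
    """

    variant: str
    aud_fit: PowerFit
    vis_fit: PowerFit
    aud_factor: float = AUD_VARIABILITY_FACTOR
    vis_factor: float = VIS_VARIABILITY_FACTOR
    reference_distance_m: float = 3.0
    r: float = 0.0
    k_aud_override: float | None = None
    m3_space: str = "log"
    printed_formula_mode: bool = False

    def __post_init__(self) -> None:
        if self.variant not in MODEL_VARIANTS:
            raise ParameterError(f"variant must be one of {MODEL_VARIANTS}")
        if self.aud_factor < 1 or self.vis_factor < 1:
            raise ParameterError("variability factors must be >= 1")
        if not 0.0 <= self.r <= 1.0:
            raise ParameterError("correlation r must lie in [0, 1]")
        if self.reference_distance_m <= 0:
            raise ParameterError("reference_distance_m must be > 0")
        if self.k_aud_override is not None and self.k_aud_override <= 0:
            raise ParameterError("k_aud_override must be > 0")
        if self.m3_space not in ("log", "linear"):
            raise ParameterError("m3_space must be 'log' or 'linear'")

    @property
    def k_aud(self) -> float:
        return self.aud_fit.k if self.k_aud_override is None else self.k_aud_override

    def with_params(self, **kw) -> "ModelSpec":
        return replace(self, **kw)


def sensitivity_dprime(mu_a, mu_v, sigma_a, sigma_v, r) -> np.ndarray | float:
    """Sensitivity index between two (possibly correlated) percepts:

        |mu_a - mu_v| / sqrt(sigma_a**2 + sigma_v**2 - 2 r sigma_a sigma_v)
    """
    mu_a = np.asarray(mu_a, float)
    mu_v = np.asarray(mu_v, float)
    sigma_a = np.asarray(sigma_a, float)
    sigma_v = np.asarray(sigma_v, float)
    if np.any(sigma_a < 0) or np.any(sigma_v < 0):
        raise ParameterError("sigmas must be >= 0")
    if np.any((np.asarray(r) < 0) | (np.asarray(r) > 1)):
        raise ParameterError("correlation r must lie in [0, 1]")
    var_diff = sigma_a ** 2 + sigma_v ** 2 - 2.0 * r * sigma_a * sigma_v
    if np.any(var_diff <= 0):
        raise DegenerateModelError(
            "difference distribution has non-positive variance "
            "(e.g. r = 1 with equal sigmas)"
        )
    out = np.abs(mu_a - mu_v) / np.sqrt(var_diff)
    return float(out) if out.ndim == 0 else out


def lognormal_moments(m_log, s_log, printed: bool = False):
    """Linear-space moments (mu, sigma) of exp(N(m_log, s_log**2)).

    Standard form: mu = exp(m + s**2/2), sigma**2 = (exp(s**2) - 1) *
    exp(2m + s**2). ``printed=True`` uses the non-standard mean
    exp(m + s**2) instead (the SD expression is unchanged once its
    self-referential variance symbol is read as s**2).
    """
    m = np.asarray(m_log, float)
    s = np.asarray(s_log, float)
    if np.any(s < 0):
        raise ParameterError("s_log must be >= 0")
    mu = np.exp(m + s ** 2 if printed else m + s ** 2 / 2.0)
    var = (np.exp(s ** 2) - 1.0) * np.exp(2.0 * m + s ** 2)
    sigma = np.sqrt(var)
    if mu.ndim == 0:
        return float(mu), float(sigma)
    return mu, sigma


def _log_params(spec: ModelSpec, visual_m: float, auditory_m: np.ndarray):
    """Log-space means and SDs for both modalities under a ModelSpec."""
    m_a = np.log(spec.k_aud) + spec.aud_fit.a * np.log(auditory_m)
    m_v = np.log(spec.vis_fit.k) + spec.vis_fit.a * np.log(visual_m)
    return m_a, m_v, np.log(spec.aud_factor), np.log(spec.vis_factor)


def predict_dprime(spec: ModelSpec, visual_m: float, auditory_m) -> np.ndarray | float:
    """Predicted d' vs auditory target distance for one visual target.

    M1: linear means k*x**a, SDs factor * (perceived mean at the reference
    distance), fixed across the block. M2: SDs factor * perceived mean at
    each target's own distance. M3: normal percepts in log-distance with
    means ln(k*x**a) and SDs ln(factor); the index is evaluated on the log
    scale by default, or through log-normal linear moments when
    ``m3_space="linear"``.
    """
    aud = np.asarray(auditory_m, dtype=float)
    if visual_m <= 0 or np.any(aud <= 0):
        raise ParameterError("distances must be > 0")
    k_a = spec.k_aud
    aud_fit = replace(spec.aud_fit, k=k_a)

    if spec.variant == "M1":
        mu_a = perceived_mean(aud_fit, aud)
        mu_v = perceived_mean(spec.vis_fit, visual_m)
        sig_a = spec.aud_factor * perceived_mean(aud_fit, spec.reference_distance_m)
        sig_v = spec.vis_factor * perceived_mean(spec.vis_fit, spec.reference_distance_m)
        return sensitivity_dprime(mu_a, mu_v, sig_a, sig_v, spec.r)
    if spec.variant == "M2":
        mu_a = perceived_mean(aud_fit, aud)
        mu_v = perceived_mean(spec.vis_fit, visual_m)
        sig_a = spec.aud_factor * mu_a
        sig_v = spec.vis_factor * mu_v
        return sensitivity_dprime(mu_a, mu_v, sig_a, sig_v, spec.r)
    # M3
    m_a, m_v, s_a, s_v = _log_params(spec, visual_m, aud)
    if spec.m3_space == "log":
        return sensitivity_dprime(m_a, m_v, s_a, s_v, spec.r)
    mu_a, sig_a = lognormal_moments(m_a, s_a, printed=spec.printed_formula_mode)
    mu_v, sig_v = lognormal_moments(m_v, s_v, printed=spec.printed_formula_mode)
    return sensitivity_dprime(mu_a, mu_v, sig_a, sig_v, spec.r)


def parameter_sweep(
    spec: ModelSpec,
    visual_m: float,
    grid,
    sweep: str,
    values,
) -> dict[float, np.ndarray]:
    """Families of predicted d' curves while sweeping one free parameter.

    ``sweep="k_aud"`` holds r = 0; ``sweep="r"`` holds k_aud = 1 — the
    exploration showing that k_aud positions the curve minimum while r
    controls the sharpness of the function.
    """
    grid = np.asarray(grid, dtype=float)
    out: dict[float, np.ndarray] = {}
    if sweep == "k_aud":
        for k in values:
            if k <= 0:
                raise ParameterError("k_aud values must be > 0")
            s = spec.with_params(k_aud_override=float(k), r=0.0)
            out[float(k)] = np.atleast_1d(predict_dprime(s, visual_m, grid))
        return out
    if sweep == "r":
        for r in values:
            if not 0.0 <= r <= 1.0:
                raise ParameterError("r values must lie in [0, 1]")
            s = spec.with_params(r=float(r), k_aud_override=1.0)
            out[float(r)] = np.atleast_1d(predict_dprime(s, visual_m, grid))
        return out
    raise ParameterError("sweep must be 'k_aud' or 'r'")
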