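"""Synthetic observer for audio-visual distance-coincidence experiments.

Simulates the two data tables the analysis pipeline consumes:

* absolute distance judgments (one judgment per subject x modality x target
  distance), drawn from a log-normal percept model with power-law means, and
* yes/no coincidence responses, produced by a differencing observer that
  draws a correlated bivariate normal percept pair in log-distance space and
  reports "coincident" when the percepts differ by less than a fixed
  criterion.

The experiment layout mirrors a blocked coincidence paradigm: within a block
the visual target sits at a fixed distance while the auditory target roams an
11-point grid around it; absolute judgments are collected separately per
modality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "ParameterError",
    "ExperimentDesign",
    "ObserverParams",
    "default_design",
    "simulate_absolute_judgments",
    "simulate_coincidence_responses",
]


class DesignError(ValueError):
    """Raised when an experiment design violates its invariants."""


class ParameterError(ValueError):
    """Raised when observer parameters violate their invariants."""


# Stream tags keep the absolute-judgment and coincidence RNG substreams
# disjoint even though both derive from the same root seed.
_STREAM_ABSOLUTE = 1
_STREAM_COINCIDENCE = 2


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of the coincidence + absolute-judgment experiment.

    ``auditory_grids`` holds one ascending, duplicate-free grid of auditory
    target distances (m) per visual target, aligned with ``visual_targets``.
    """

    visual_targets: tuple[float, ...]
    auditory_grids: tuple[tuple[float, ...], ...]
    trials_per_stimulus: int
    n_subjects: int
    absolute_auditory_distances: tuple[float, ...]
    absolute_visual_distances: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.visual_targets) == 0:
            raise DesignError("at least one visual target is required")
        if len(self.auditory_grids) != len(self.visual_targets):
            raise DesignError("one auditory grid per visual target is required")
        all_d = (
            list(self.visual_targets)
            + [d for g in self.auditory_grids for d in g]
            + list(self.absolute_auditory_distances)
            + list(self.absolute_visual_distances)
        )
        if any(d <= 0 for d in all_d):
            raise DesignError("all distances must be > 0")
        for grid in self.auditory_grids:
            if len(grid) == 0:
                raise DesignError("auditory grid must be non-empty")
            if list(grid) != sorted(set(grid)):
                raise DesignError("auditory grids must be sorted ascending and unique")
        if self.trials_per_stimulus < 1:
            raise DesignError("trials_per_stimulus must be >= 1")
        if self.n_subjects < 1:
            raise DesignError("n_subjects must be >= 1")

    @property
    def measurement_grid(self) -> tuple[float, ...]:
        """Sorted union of all per-block auditory distances."""
        return tuple(sorted({d for g in self.auditory_grids for d in g}))

    def grid_for(self, visual_m: float) -> tuple[float, ...]:
        for v, g in zip(self.visual_targets, self.auditory_grids):
            if v == visual_m:
                return g
        raise DesignError(f"no block with visual target {visual_m} m")


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the correlated log-normal percept model.

    Perceived distance in each modality is log-normal around a power-law mean
    ``k * x**a`` with log-space SD ``s``; on coincidence trials the two log
    percepts are drawn jointly with correlation ``r`` and the observer
    accepts "coincident" when ``|A - V| <= criterion_c`` (natural-log units).

    Defaults describe a typical listener/viewer: compressive, underestimating
    auditory distance perception (k_aud=1.32, a_aud=0.54), near-veridical
    vision (k_vis=1.0, a_vis=0.98), log-space SDs equal to the natural logs of
    the multiplicative variability factors 10**0.23 (auditory) and 10**0.15
    (visual), substantial inter-modal correlation under concurrent
    presentation (r=0.8), and an acceptance half-width of 0.5 log-units
    (percept ratio within ~x1.65 counts as coincident).
    """

    k_aud: float = 1.32
    a_aud: float = 0.54
    k_vis: float = 1.0
    a_vis: float = 0.98
    s_aud: float = field(default_factory=lambda: float(np.log(10 ** 0.23)))
    s_vis: float = field(default_factory=lambda: float(np.log(10 ** 0.15)))
    r: float = 0.8
    criterion_c: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_aud <= 0 or self.k_vis <= 0:
            raise ParameterError("power-law constants k must be > 0")
        if self.s_aud < 0 or self.s_vis < 0:
            raise ParameterError("log-space SDs s must be >= 0")
        if not 0.0 <= self.r <= 1.0:
            raise ParameterError("correlation r must lie in [0, 1]")
        if self.criterion_c <= 0:
            raise ParameterError("criterion_c must be > 0")

    def log_mean(self, modality: str, x: np.ndarray | float) -> np.ndarray:
        """Log-space percept mean ln(k * x**a) for ``modality`` at distance x."""
        x = np.asarray(x, dtype=float)
        if modality == "aud":
            return np.log(self.k_aud) + self.a_aud * np.log(x)
        if modality == "vis":
            return np.log(self.k_vis) + self.a_vis * np.log(x)
        raise ParameterError(f"unknown modality {modality!r}")


def default_design(
    *,
    step_m: float = 0.25,
    grid_points: int = 11,
    distance_limits_m: tuple[float, float] = (1.0, 5.0),
) -> ExperimentDesign:
    """Standard design: visual blocks at 1.5/3.0/4.5 m, 11-point auditory
    grids in 0.25 m steps, 30 trials per stimulus, 11 subjects.

    Each block's auditory grid is centered on its visual target and shifted
    inward where it would leave the measured distance range (1-5 m), so the
    union of block grids is the 17-point measurement grid.
    """
    lo, hi = distance_limits_m
    visual_targets = (1.5, 3.0, 4.5)
    grids = []
    half = (grid_points - 1) // 2
    for v in visual_targets:
        start = v - half * step_m
        # shift inward to stay within the measured range
        start = min(max(start, lo), hi - (grid_points - 1) * step_m)
        grid = tuple(round(start + i * step_m, 10) for i in range(grid_points))
        grids.append(grid)
    return ExperimentDesign(
        visual_targets=visual_targets,
        auditory_grids=tuple(grids),
        trials_per_stimulus=30,
        n_subjects=11,
        absolute_auditory_distances=tuple(np.arange(1.0, 5.01, 0.5)),
        absolute_visual_distances=(1.0, 2.0, 3.0),
    )


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *stream]))


def simulate_absolute_judgments(
    design: ExperimentDesign, params: ObserverParams
) -> pd.DataFrame:
    """Simulate single absolute distance judgments per subject x modality x
    target distance.

    Judgments are ``exp(N(ln(k x**a), s))`` drawn independently per cell,
    matching a single-judgment protocol. Returns a tidy table with columns
    ``subject_id, modality, target_m, judged_m``.
    """
    rows = []
    cells = [("aud", d) for d in design.absolute_auditory_distances] + [
        ("vis", d) for d in design.absolute_visual_distances
    ]
    for subject in range(design.n_subjects):
        rng = _rng(params.seed, _STREAM_ABSOLUTE, subject)
        for modality, target in cells:
            m = params.log_mean(modality, target)
            s = params.s_aud if modality == "aud" else params.s_vis
            judged = float(np.exp(rng.normal(m, s)))
            rows.append((subject, modality, target, judged))
    return pd.DataFrame(
        rows, columns=["subject_id", "modality", "target_m", "judged_m"]
    )


def simulate_coincidence_responses(
    design: ExperimentDesign, params: ObserverParams
) -> pd.DataFrame:
    """Simulate yes/no coincidence responses for every block of the design.

    Per trial a correlated bivariate normal (A, V) is drawn in log-distance
    space — means ``ln(k x**a)`` at the auditory/visual target distances, SDs
    ``s_aud``/``s_vis``, correlation ``r`` — and the response is 1 when
    ``|A - V| <= criterion_c``. One independent RNG substream per
    (subject, block), so subject subsets reproduce exactly.

    Returns a tidy table with columns
    ``subject_id, visual_m, auditory_m, trial_idx, response``.
    """
    frames = []
    n_trials = design.trials_per_stimulus
    for subject in range(design.n_subjects):
        for block, (v, grid) in enumerate(
            zip(design.visual_targets, design.auditory_grids)
        ):
            rng = _rng(params.seed, _STREAM_COINCIDENCE, subject, block)
            aud = np.repeat(np.asarray(grid, dtype=float), n_trials)
            m_a = params.log_mean("aud", aud)
            m_v = params.log_mean("vis", v)
            # correlated pair via shared + independent standard normals
            z1 = rng.standard_normal(aud.size)
            z2 = rng.standard_normal(aud.size)
            a_log = m_a + params.s_aud * z1
            v_log = m_v + params.s_vis * (
                params.r * z1 + np.sqrt(1.0 - params.r ** 2) * z2
            )
            response = (np.abs(a_log - v_log) <= params.criterion_c).astype(int)
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": subject,
                        "visual_m": v,
                        "auditory_m": aud,
                        "trial_idx": np.tile(np.arange(n_trials), len(grid)),
                        "response": response,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def observer_for_seed(params: ObserverParams, seed: int) -> ObserverParams:
    """Copy ``params`` with a different root seed."""
    return replace(params, seed=int(seed))
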