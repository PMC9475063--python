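"""Reproducible end-to-end pipeline and file interchange.

Stages: simulate (or ingest) responses -> power-law distance fits ->
empirical d' (+ subject bootstrap) -> model fits (M1/M2/M3 at the requested
parameter counts) -> RMS comparison table. All interchange is plain CSV with
fixed column names; each run writes a manifest with the config hash, seed
and library versions so identical configurations reproduce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import compare_models, rms_summary
from .models import AUD_VARIABILITY_FACTOR, VIS_VARIABILITY_FACTOR, ModelSpec
from .observer import (
    ExperimentDesign,
    ObserverParams,
    default_design,
    simulate_absolute_judgments,
    simulate_coincidence_responses,
)
from .psychometrics import RESPONSE_COLUMNS, DataError, bootstrap_ci, dprime_curves
from .scaling import PowerFit, fit_power_judgments

__all__ = ["RunConfig", "StageError", "run_pipeline", "validate_tables",
           "write_responses", "read_responses", "write_judgments", "read_judgments"]

logger = logging.getLogger("distcapture")

JUDGMENT_COLUMNS = ["subject_id", "modality", "target_m", "judged_m"]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative configuration of a full analysis run."""

    design: ExperimentDesign = field(default_factory=default_design)
    observer: ObserverParams = field(default_factory=ObserverParams)
    aud_factor: float = AUD_VARIABILITY_FACTOR
    vis_factor: float = VIS_VARIABILITY_FACTOR
    reference_distance_m: float = 3.0
    m3_space: str = "log"
    printed_formula_mode: bool = False
    n_params: tuple[int, ...] = (2,)
    bootstrap_B: int = 1000
    per_subject: bool = False
    seed: int = 0
    out_dir: str = "run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        design = raw.pop("design", None)
        observer = raw.pop("observer", None)
        cfg = cls(**raw)
        if design is not None:
            design["visual_targets"] = tuple(design["visual_targets"])
            design["auditory_grids"] = tuple(tuple(g) for g in design["auditory_grids"])
            for k in ("absolute_auditory_distances", "absolute_visual_distances"):
                design[k] = tuple(design[k])
            cfg.design = ExperimentDesign(**design)
        if observer is not None:
            cfg.observer = ObserverParams(**observer)
        if isinstance(cfg.n_params, list):
            cfg.n_params = tuple(cfg.n_params)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))

    def config_hash(self) -> str:
        # out_dir is deployment detail, not part of the scientific configuration
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------- CSV I/O

def write_responses(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, columns=RESPONSE_COLUMNS)


def read_responses(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_judgments(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, columns=JUDGMENT_COLUMNS)


def read_judgments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ------------------------------------------------------------- validation

def _check_responses(df: pd.DataFrame) -> list[str]:
    issues = []
    for col in RESPONSE_COLUMNS:
        if col not in df.columns:
            issues.append(f"missing column '{col}'")
    if issues:
        return issues
    bad = df.index[~df["response"].isin([0, 1])]
    issues += [f"row {i}: response {df.loc[i, 'response']!r} not in {{0,1}}" for i in bad[:20]]
    for col in ("visual_m", "auditory_m"):
        bad = df.index[df[col] <= 0]
        issues += [f"row {i}: {col} {df.loc[i, col]!r} not > 0" for i in bad[:20]]
    dup = df.duplicated(["subject_id", "visual_m", "auditory_m", "trial_idx"])
    issues += [f"row {i}: duplicate (subject, visual, auditory, trial) key"
               for i in df.index[dup][:20]]
    return issues


def _check_judgments(df: pd.DataFrame) -> list[str]:
    issues = []
    for col in JUDGMENT_COLUMNS:
        if col not in df.columns:
            issues.append(f"missing column '{col}'")
    if issues:
        return issues
    bad = df.index[~df["modality"].isin(["aud", "vis"])]
    issues += [f"row {i}: modality {df.loc[i, 'modality']!r} not in {{aud,vis}}" for i in bad[:20]]
    for col in ("target_m", "judged_m"):
        bad = df.index[df[col] <= 0]
        issues += [f"row {i}: {col} {df.loc[i, col]!r} not > 0" for i in bad[:20]]
    return issues


def validate_tables(paths: dict[str, str | Path]) -> dict[str, dict]:
    """Schema/range checks for interchange files.

    ``paths`` maps a kind ('responses' or 'absolute') to a CSV path. Returns
    ``{path: {"passed": bool, "issues": [...]}}``; unreadable files are
    reported, not raised.
    """
    checkers = {"responses": _check_responses, "absolute": _check_judgments}
    report: dict[str, dict] = {}
    for kind, path in paths.items():
        if kind not in checkers:
            report[str(path)] = {"passed": False, "issues": [f"unknown table kind '{kind}'"]}
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001 - reported, not raised
            report[str(path)] = {"passed": False, "issues": [f"unreadable: {exc}"]}
            continue
        issues = checkers[kind](df)
        report[str(path)] = {"passed": not issues, "issues": issues}
    return report


# --------------------------------------------------------------- pipeline

def _power_fit_from_row(row) -> PowerFit:
    return PowerFit(k=float(row["k"]), a=float(row["a"]),
                    r_squared=float(row["r_squared"]), modality=str(row["modality"]),
                    n=int(row["n"]))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full simulate -> fit -> compare pipeline into a run
    directory; returns its path.

    Outputs: responses.csv, absolute.csv, powerfits.csv, dprime.csv,
    fits.csv, comparison.csv, manifest.json, run.log. A stage failure leaves
    a FAILED marker naming the stage and re-raises :class:`StageError`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    stage = "simulate"
    try:
        logger.info("config hash %s, seed %d", config.config_hash(), config.seed)
        observer = dataclasses.replace(config.observer, seed=config.seed)
        responses = simulate_coincidence_responses(config.design, observer)
        judgments = simulate_absolute_judgments(config.design, observer)
        write_responses(responses, out / "responses.csv")
        write_judgments(judgments, out / "absolute.csv")

        stage = "fit-power"
        fits = fit_power_judgments(judgments, per_subject=False)
        fits.to_csv(out / "powerfits.csv", index=False)
        aud_fit = _power_fit_from_row(fits[fits["modality"] == "aud"].iloc[0])
        vis_fit = _power_fit_from_row(fits[fits["modality"] == "vis"].iloc[0])

        stage = "dprime"
        if config.bootstrap_B > 0:
            stage = "bootstrap"
            curves = bootstrap_ci(responses, B=config.bootstrap_B, seed=config.seed)
        else:
            curves = dprime_curves(responses, pooled=True)
        rows = []
        for v, c in curves.items():
            for j, d in enumerate(c.auditory_m):
                rows.append((v, d, c.pc[j], c.dprime[j],
                             c.ci_low[j] if c.ci_low is not None else "",
                             c.ci_high[j] if c.ci_high is not None else "",
                             c.n_per_point[j]))
        pd.DataFrame(rows, columns=["visual_m", "auditory_m", "pc", "dprime",
                                    "ci_low", "ci_high", "n"]).to_csv(
            out / "dprime.csv", index=False)

        stage = "fit-models"
        base_spec = ModelSpec(
            variant="M3", aud_fit=aud_fit, vis_fit=vis_fit,
            aud_factor=config.aud_factor, vis_factor=config.vis_factor,
            reference_distance_m=config.reference_distance_m,
            m3_space=config.m3_space,
            printed_formula_mode=config.printed_formula_mode,
        )
        tables = []
        fit_curves: dict = dict(curves)
        if config.per_subject:
            fit_curves.update(dprime_curves(responses, pooled=False))
        for n in config.n_params:
            tables.append(compare_models(fit_curves, base_spec, n_params=n))
        comparison = pd.concat(tables, ignore_index=True)
        comparison.to_csv(out / "fits.csv", index=False)

        stage = "compare"
        pooled = comparison[comparison["scope"] == "pooled"]
        summary = pooled[["visual_m", "model", "n_params", "rms_error"]].copy()
        if config.per_subject:
            by_subject = rms_summary(comparison)
            by_subject.to_csv(out / "rms_by_subject.csv", index=False)
        summary.to_csv(out / "comparison.csv", index=False)

        manifest = {
            "package": "distcapture",
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "versions": {"numpy": np.__version__, "pandas": pd.__version__},
            "outputs": sorted(p.name for p in out.glob("*.csv")),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
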