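"""End-to-end orchestration: simulate → preprocess → filter → screen → report.

:func:`run_pipeline` wires the library modules together over a run directory:
every stage's inputs and outputs are persisted as the module-standard
TSV/CSV/JSON artifacts, and a ``manifest.json`` records the package version,
seed, configuration, and per-stage probe counts, so the probe bookkeeping
(e.g. 1145 → 1008 → 522-style) is always reconstructible from disk. Any
stage failure aborts with the stage name while keeping the artifacts written
so far.

All computation lives in the library modules; this module only sequences
them and handles paths, logging, and serialization.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .io import (
    ExpressionMatrix,
    SampleSheet,
    read_expression_tsv,
    read_sample_sheet,
    write_expression_tsv,
    write_sample_sheet,
)
from .preprocess import detect_mask, quantile_normalize, subtract_background
from .filters import blood_cell_filter, low_abundance_filter, rescue_low_abundance
from .screening import ScreeningConfig, apply_cascade, de_screen
from .simulate import SimConfig, blood_list_from_truth, manifest_from_truth, simulate_dataset

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("mirscreen.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names it and partial outputs are on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Either simulate (default) or point ``expression_tsv``/``sample_sheet_csv``
    /``manifest_csv``/``blood_list_txt`` at existing artifacts. ``background``
    is the per-sample background level subtracted before detection calls; for
    simulated data it defaults to the simulator's additive background.
    """

    out_dir: str | Path = "mirscreen_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    undetectable_fraction: float = 0.10
    rescue_mean_floor: float = 100.0
    rescue_neg_fraction: float = 0.75
    background: float | None = None
    expression_tsv: str | None = None
    sample_sheet_csv: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.undetectable_fraction < 1:
            raise ValueError("undetectable_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" in raw:
            raw["sim"] = SimConfig(**raw["sim"])
        if "screening" in raw:
            raw["screening"] = ScreeningConfig(**raw["screening"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["out_dir"] = str(raw["out_dir"])
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class PipelineResult:
    """Handles to the artifacts of a completed run."""

    out_dir: Path
    manifest: dict
    cascade: "object"
    contrasts: "object"
    truth: "object | None" = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full screening pipeline into ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    def checkpoint() -> None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")

    stage = "simulate"
    try:
        truth = None
        if config.expression_tsv:
            matrix = read_expression_tsv(config.expression_tsv)
            sheet = read_sample_sheet(config.sample_sheet_csv)
            from .datasets import load_default_blood_list
            from .io import build_probe_manifest
            import pandas as pd

            probe_manifest = build_probe_manifest(
                pd.DataFrame(
                    {"probe_id": matrix.probe_ids, "mirna_name": matrix.probe_ids}
                )
            )
            blood_list = load_default_blood_list()
            background = config.background if config.background is not None else 0.0
        else:
            matrix, sheet, truth = simulate_dataset(config.sim, seed=config.seed)
            probe_manifest = manifest_from_truth(truth)
            blood_list = blood_list_from_truth(truth)
            background = (
                config.background
                if config.background is not None
                else config.sim.background_level
            )
            truth.to_csv(out / "truth.csv", index=False)
        write_expression_tsv(matrix, out / "expression_raw.tsv")
        write_sample_sheet(sheet, out / "sample_sheet.csv")
        probe_manifest.to_csv(out / "probe_manifest.csv", index=False)
        manifest["stages"][stage] = {
            "n_probes": matrix.n_probes,
            "n_samples": matrix.n_samples,
            "cohorts": sheet.cohort_sizes(),
        }
        logger.info("simulate: %d probes x %d samples", matrix.n_probes, matrix.n_samples)
        checkpoint()

        stage = "preprocess"
        bg_sub = subtract_background(matrix, background)
        mask = detect_mask(bg_sub)
        normalized = quantile_normalize(bg_sub)
        write_expression_tsv(normalized, out / "expression_normalized.tsv")
        manifest["stages"][stage] = {
            "background": background,
            "detected_fraction": float(mask.to_numpy().mean()),
        }
        logger.info("preprocess: detected fraction %.3f", mask.to_numpy().mean())
        checkpoint()

        stage = "blood_cell_filter"
        filtered1, report1 = blood_cell_filter(normalized, probe_manifest, blood_list)
        report1.to_json(out / "filter_blood_cell.json")
        manifest["stages"][stage] = {"in": report1.probes_in, "kept": report1.n_kept}
        logger.info("filter 1: %d -> %d probes", report1.probes_in, report1.n_kept)
        checkpoint()

        stage = "low_abundance_filter"
        max_undetectable = int(config.undetectable_fraction * filtered1.n_samples)
        filtered2, report2 = low_abundance_filter(filtered1, mask, max_undetectable)
        report2.to_json(out / "filter_low_abundance.json")
        manifest["stages"][stage] = {
            "in": report2.probes_in,
            "kept": report2.n_kept,
            "max_undetectable": max_undetectable,
        }
        logger.info("filter 2: %d -> %d probes", report2.probes_in, report2.n_kept)
        checkpoint()

        stage = "de_screen"
        contrasts = de_screen(filtered2, sheet, config.screening)
        contrasts.to_csv(out / "contrasts.csv", index=False)
        manifest["stages"][stage] = {"n_tested": int(len(contrasts))}
        checkpoint()

        stage = "cascade"
        cascade = apply_cascade(contrasts, config.screening)
        cascade.to_json(out / "cascade.json")
        manifest["stages"][stage] = {
            "n_de": cascade.n_de,
            "n_normalizing": cascade.n_normalizing,
            "n_final": len(cascade.final_candidates),
        }
        logger.info(
            "cascade: %d -> %d -> %d candidates",
            cascade.n_de, cascade.n_normalizing, len(cascade.final_candidates),
        )
        checkpoint()

        stage = "rescue"
        removed = normalized.subset_probes(report2.probes_removed)
        rescue = rescue_low_abundance(
            removed,
            sheet,
            mean_floor=config.rescue_mean_floor,
            neg_fraction=config.rescue_neg_fraction,
            alpha=config.screening.alpha_de,
        )
        rescue.to_json(out / "rescue.json")
        manifest["stages"][stage] = {
            "neg75": rescue.n_neg75,
            "low_mean": rescue.n_low_mean,
            "evaluable": rescue.n_evaluable,
            "significant": rescue.n_significant,
        }
        checkpoint()
    except PipelineError:
        raise
    except Exception as exc:
        checkpoint()
        raise PipelineError(stage, exc) from exc

    return PipelineResult(
        out_dir=out, manifest=manifest, cascade=cascade, contrasts=contrasts, truth=truth
    )
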