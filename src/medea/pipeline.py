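"""File-to-file pipeline orchestration: read, match, post-process, write."""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import yaml

from . import io as _io
from .clustering import AnnealingSchedule, default_schedule
from .model import MedeaPeakMatcher, PeakMatchingResults
from .tolerance import ToleranceModel

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("medea")


@dataclass
class PipelineConfig:
    """Everything a file-based run needs; mirrors the CLI flags."""

    input_path: str
    output_dir: str
    mz_ppm: float = 2.93
    rt_halfwidth: float = 0.3
    temperatures: tuple | None = None
    weight_floor: float = 0.1
    move_fraction: float = 0.001
    seed_order: str = "input"
    stage1: bool = True
    stage2: bool = True
    single_pass_fusion: bool = False
    dialect: str | None = None

    def tolerance(self) -> ToleranceModel:
        return ToleranceModel(self.mz_ppm, self.rt_halfwidth)

    def schedule(self) -> AnnealingSchedule:
        if self.temperatures is None:
            return AnnealingSchedule(
                weight_floor=self.weight_floor,
                move_fraction=self.move_fraction,
            )
        return AnnealingSchedule(tuple(self.temperatures),
                                 self.weight_floor, self.move_fraction)

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        """Load a key/value config file; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> PeakMatchingResults:
    """Run the full pipeline on files and write assignment + summary tables.

    Logs the headline counters (per-charge cluster counts, the annealing
    iteration histogram, stage-1 reassignments and stage-2 fusions) at INFO.
    """
    peaks = _io.read_peaks(config.input_path, config.dialect)
    logger.info("read %d peaks from %s", len(peaks), config.input_path)
    model = MedeaPeakMatcher(peaks, config.tolerance(), config.schedule(),
                             config.seed_order)
    results = model.fit(stage1=config.stage1, stage2=config.stage2,
                        single_pass_fusion=config.single_pass_fusion)
    per_charge: dict[int, int] = {}
    for c in results.clusters:
        per_charge[c.z] = per_charge.get(c.z, 0) + 1
    for z, n in sorted(per_charge.items()):
        logger.info("charge z=%d: %d clusters", z, n)
    logger.info("annealing iterations: %s", results.iteration_histogram())
    logger.info("stage 1 reassigned %d peaks; stage 2 fused %d clusters",
                results.n_reassigned, results.n_fused)
    paths = results.to_files(config.output_dir,
                             config.dialect if config.dialect else "tsv")
    logger.info("wrote %s and %s", paths["assignments"], paths["clusters"])
    return results
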