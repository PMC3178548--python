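"""Model/results interface to the full peak-matching pipeline.

``MedeaPeakMatcher`` holds a validated peak table and the matching
parameters (tolerances, annealing schedule, seed policy); ``fit`` runs the
annealed clustering and the enabled post-processing stages and returns a
``PeakMatchingResults`` with the clusters, per-peak labels, run diagnostics
and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as _io
from .clustering import (AnnealingSchedule, Cluster, cluster_peaks,
                         default_schedule)
from .postprocess import fuse_clusters, reassign
from .simulate import RecoveryReport, truth_metrics
from .tolerance import ToleranceModel
from .validation import (ClusteringSummary, clustering_summary,
                         clusters_per_peptide, peptide_dispersion)

__all__ = ["MedeaPeakMatcher", "PeakMatchingResults"]


class MedeaPeakMatcher:
    """Variance-constrained peak matching on an LC-MS peak table.

    Parameters
    ----------
    peaks : pandas.DataFrame
        Peak table with columns ``mz``, ``rt``, ``z`` (plus optional
        ``sample``, ``intensity``, ``peptide``); validated on construction.
    tolerance : ToleranceModel
        Box half-widths: relative m/z (ppm) and absolute RT (minutes).
    schedule : AnnealingSchedule, optional
        Temperature schedule; defaults to 8, 6, 4, 3, 2, 1.5, 1 (x5), 0.25.
    seed_order : {"input", "intensity"}
        Which unused peak seeds the next cluster.
    """

    def __init__(self, peaks: pd.DataFrame, tolerance: ToleranceModel,
                 schedule: AnnealingSchedule | None = None,
                 seed_order: str = "input"):
        self.peaks = _io.validate_peaks(peaks)
        self.tolerance = tolerance
        self.schedule = schedule or default_schedule()
        self.seed_order = seed_order

    @classmethod
    def from_dataframe(cls, peaks: pd.DataFrame, mz_ppm: float,
                       rt_halfwidth: float, **kwargs) -> "MedeaPeakMatcher":
        return cls(peaks, ToleranceModel(mz_ppm, rt_halfwidth), **kwargs)

    @classmethod
    def from_file(cls, path: str, mz_ppm: float, rt_halfwidth: float,
                  dialect: str | None = None, **kwargs) -> "MedeaPeakMatcher":
        return cls(_io.read_peaks(path, dialect),
                   ToleranceModel(mz_ppm, rt_halfwidth), **kwargs)

    def fit(self, stage1: bool = True, stage2: bool = True,
            single_pass_fusion: bool = False) -> "PeakMatchingResults":
        """Run clustering and the enabled post-processing stages."""
        clusters, iterations = cluster_peaks(
            self.peaks, self.tolerance, self.schedule, self.seed_order
        )
        n_reassigned = 0
        n_fused = 0
        if stage1:
            clusters, n_reassigned = reassign(clusters, self.peaks,
                                              self.tolerance)
        if stage2:
            clusters, n_fused = fuse_clusters(clusters, self.peaks,
                                              self.tolerance,
                                              single_pass=single_pass_fusion)
        return PeakMatchingResults(
            model=self, clusters=clusters, iteration_counts=iterations,
            n_reassigned=n_reassigned, n_fused=n_fused,
            stages=(bool(stage1), bool(stage2)),
        )


@dataclass
class PeakMatchingResults:
    """Fitted peak-matching result.

    Attributes
    ----------
    clusters : list of Cluster
        Final clusters, ordered by id.
    iteration_counts : numpy.ndarray
        Annealing iterations per grown cluster (before post-processing).
    n_reassigned, n_fused : int
        Stage-1 peak moves and stage-2 fusions performed.
    """

    model: MedeaPeakMatcher
    clusters: list
    iteration_counts: np.ndarray
    n_reassigned: int
    n_fused: int
    stages: tuple = (True, True)
    _labels: pd.Series | None = field(default=None, repr=False)

    @property
    def peaks(self) -> pd.DataFrame:
        return self.model.peaks

    @property
    def labels(self) -> pd.Series:
        """Cluster id per peak row (every peak belongs to exactly one)."""
        if self._labels is None:
            labels = pd.Series(-1, index=self.peaks.index, dtype=int)
            for c in self.clusters:
                labels.loc[c.members] = c.id
            self._labels = labels
        return self._labels

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def iteration_histogram(self) -> dict[int, int]:
        """{iterations: number of grown clusters} over the annealing run."""
        values, counts = np.unique(self.iteration_counts, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    def cluster_summary(self) -> ClusteringSummary:
        return clustering_summary(self.clusters, self.peaks,
                                  self.model.tolerance)

    def assignments(self) -> pd.DataFrame:
        return _io.assignment_table(self.clusters, self.peaks)

    def cluster_table(self) -> pd.DataFrame:
        return _io.cluster_table(self.clusters, self.peaks)

    def peptide_dispersion(self, **kwargs) -> pd.DataFrame:
        return peptide_dispersion(self.clusters, self.peaks, **kwargs)

    def clusters_per_peptide(self, **kwargs):
        return clusters_per_peptide(self.clusters, self.peaks, **kwargs)

    def recovery(self, truth: pd.Series | None = None) -> RecoveryReport:
        """Truth-label comparison (defaults to the ``peptide`` column)."""
        if truth is None:
            if "peptide" not in self.peaks.columns:
                raise ValueError("no truth labels: peak table has no "
                                 "'peptide' column")
            truth = self.peaks["peptide"]
        return truth_metrics(self.clusters, truth)

    def to_files(self, outdir: str, dialect: str | None = "tsv"):
        return _io.write_clusters(self.clusters, self.peaks, outdir, dialect)

    def summary(self) -> str:
        """Readable run report: parameters, headline counters, diagnostics."""
        tol = self.model.tolerance
        s = self.cluster_summary()
        per_charge = {}
        for c in self.clusters:
            per_charge[c.z] = per_charge.get(c.z, 0) + 1
        lines = [
            "MEDEA peak matching results",
            "=" * 46,
            f"Peaks                         {len(self.peaks)}",
            f"Tolerance half-widths         {tol.mz_ppm} ppm (m/z), "
            f"{tol.rt_halfwidth} min (RT)",
            f"Annealing schedule            {len(self.model.schedule)} steps, "
            f"T1={self.model.schedule.temperatures[0]}, "
            f"Tfinal={self.model.schedule.temperatures[-1]}",
            f"Stages run                    stage1={self.stages[0]}, "
            f"stage2={self.stages[1]}",
            "-" * 46,
            str(s),
            f"Clusters per charge           "
            + ", ".join(f"z={z}: {n}" for z, n in sorted(per_charge.items())),
            f"Annealing iterations          "
            + ", ".join(f"{k}: {v}" for k, v in
                        sorted(self.iteration_histogram().items())),
            f"Stage-1 peaks reassigned      {self.n_reassigned}",
            f"Stage-2 clusters fused        {self.n_fused}",
        ]
        return "\n".join(lines)
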