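"""Evaluation statistics for peak-matching results.

Per-peptide dispersion: each annotated peak is represented by the mean
location of the cluster it was assigned to; the standard deviation of
those locations across a peptide's peaks (per coordinate, population
convention) measures how much the algorithm scattered that peptide.  A
perfectly matched peptide has dispersion 0.  Dispersion ratios between two
algorithms, with zero-zero and near-unity ties removed, summarize which
algorithm keeps peptides more coherent.  Cluster-level summaries (count,
mean size, mean per-coordinate diameter) and the clusters-per-peptide
histogram complete the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import NOISE_LABEL
from .tolerance import ToleranceModel

__all__ = [
    "peptide_dispersion", "dispersion_ratios", "DispersionRatios",
    "clusters_per_peptide", "clustering_summary", "ClusteringSummary",
]

#: Relative half-width of the tie band around ratio 1.
TIE_EPSILON = 0.05

#: Ratios above this are reported as-is but capped here for plotting.
RATIO_CAP = 2.0


def _cluster_assignment(clusters, peaks: pd.DataFrame) -> pd.Series:
    assigned = pd.Series(-1, index=peaks.index, dtype=int)
    for c in clusters:
        assigned.loc[c.members] = c.id
    return assigned


def _cluster_means(clusters, peaks: pd.DataFrame) -> pd.DataFrame:
    rows = {
        c.id: (
            float(peaks.loc[c.members, "mz"].mean()),
            float(peaks.loc[c.members, "rt"].mean()),
        )
        for c in clusters
    }
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["mean_mz", "mean_rt"])


def peptide_dispersion(clusters, peaks: pd.DataFrame,
                       peptide_col: str = "peptide",
                       noise_label: str = NOISE_LABEL) -> pd.DataFrame:
    """Per-peptide location dispersion under a clustering.

    Each annotated peak maps to its cluster's arithmetic-mean (m/z, RT);
    the population standard deviation of those locations per peptide is
    returned as a DataFrame indexed by peptide with columns ``sigma_mz``,
    ``sigma_rt`` and ``n_peaks``.  Single-peak peptides get dispersion 0.
    Annotated peaks outside every cluster are an error.
    """
    if peptide_col not in peaks.columns:
        raise ValueError(f"peak table has no {peptide_col!r} column")
    annotated = peaks[peaks[peptide_col].notna()
                      & (peaks[peptide_col] != noise_label)]
    if annotated.empty:
        raise ValueError("no annotated peaks to evaluate")
    assigned = _cluster_assignment(clusters, peaks).loc[annotated.index]
    if (assigned < 0).any():
        missing = assigned.index[assigned < 0][:5].tolist()
        raise ValueError(f"annotated peaks not in any cluster: {missing}")
    means = _cluster_means(clusters, peaks)
    loc = means.loc[assigned].set_index(annotated.index)
    loc[peptide_col] = annotated[peptide_col]
    grouped = loc.groupby(peptide_col)
    out = pd.DataFrame({
        "sigma_mz": grouped["mean_mz"].std(ddof=0),
        "sigma_rt": grouped["mean_rt"].std(ddof=0),
        "n_peaks": grouped.size(),
    })
    out.index.name = "peptide"
    return out


@dataclass(frozen=True)
class DispersionRatios:
    """Dispersion ratios a/b per dimension, ties removed.

    ``mz``/``rt`` hold DataFrames with columns ``ratio`` (as computed) and
    ``capped`` (clipped at 2 for plotting).  One-zero pairs (one algorithm
    at zero dispersion, the other not) are excluded from the ratio lists
    and tallied in ``zero_numerator`` / ``zero_denominator`` per dimension.
    """

    mz: pd.DataFrame
    rt: pd.DataFrame
    zero_numerator: dict
    zero_denominator: dict
    epsilon: float = TIE_EPSILON


def _ratio_one_dim(a: pd.Series, b: pd.Series, epsilon: float):
    both_zero = (a == 0) & (b == 0)
    a_zero = (a == 0) & (b > 0)
    b_zero = (b == 0) & (a > 0)
    valid = ~(both_zero | a_zero | b_zero)
    ratio = a[valid] / b[valid]
    keep = (ratio < 1.0 - epsilon) | (ratio > 1.0 + epsilon)
    ratio = ratio[keep]
    frame = pd.DataFrame({"ratio": ratio,
                          "capped": ratio.clip(upper=RATIO_CAP)})
    return frame, int(a_zero.sum()), int(b_zero.sum())


def dispersion_ratios(a: pd.DataFrame, b: pd.DataFrame,
                      epsilon: float = TIE_EPSILON) -> DispersionRatios:
    """Ratios ``sigma_a / sigma_b`` per peptide and dimension.

    ``a`` and ``b`` are ``peptide_dispersion`` outputs over the same
    peptide universe.  Pairs with both dispersions zero are dropped, as are
    ratios inside ``1 +/- epsilon``; ratios above 2 are kept with a
    capped-at-2 companion column for plotting.
    """
    if set(a.index) != set(b.index):
        raise ValueError("dispersion tables cover different peptide sets")
    b = b.loc[a.index]
    mz, a0_mz, b0_mz = _ratio_one_dim(a["sigma_mz"], b["sigma_mz"], epsilon)
    rt, a0_rt, b0_rt = _ratio_one_dim(a["sigma_rt"], b["sigma_rt"], epsilon)
    return DispersionRatios(
        mz=mz, rt=rt,
        zero_numerator={"mz": a0_mz, "rt": a0_rt},
        zero_denominator={"mz": b0_mz, "rt": b0_rt},
        epsilon=epsilon,
    )


def clusters_per_peptide(clusters, peaks: pd.DataFrame,
                         peptide_col: str = "peptide",
                         noise_label: str = NOISE_LABEL):
    """Histogram {k: number of peptides found in k clusters} and its mean."""
    annotated = peaks[peaks[peptide_col].notna()
                      & (peaks[peptide_col] != noise_label)]
    assigned = _cluster_assignment(clusters, peaks).loc[annotated.index]
    spread = (
        pd.DataFrame({peptide_col: annotated[peptide_col],
                      "cluster": assigned})
        .groupby(peptide_col)["cluster"].nunique()
    )
    hist = {int(k): int(v) for k, v in spread.value_counts().sort_index().items()}
    mean = float(spread.mean()) if len(spread) else float("nan")
    return hist, mean


@dataclass(frozen=True)
class ClusteringSummary:
    """Headline statistics of a clustering run."""

    n_clusters: int
    mean_size: float
    mean_diameter_mz: float
    mean_diameter_rt: float
    n_box_violations: int | None = None

    def __str__(self) -> str:
        lines = [
            f"Number of clusters            {self.n_clusters}",
            f"Average cluster size          {self.mean_size:.4g}",
            f"Average cluster diameter m/z  {self.mean_diameter_mz:.4g}",
            f"Average cluster diameter RT   {self.mean_diameter_rt:.4g}",
        ]
        if self.n_box_violations is not None:
            lines.append(f"Box-constraint violations     {self.n_box_violations}")
        return "\n".join(lines)


def clustering_summary(clusters, peaks: pd.DataFrame,
                       tol: ToleranceModel | None = None) -> ClusteringSummary:
    """Cluster count, mean size and mean per-coordinate diameters.

    The diameter of a cluster is the per-coordinate range (max - min) of
    its members; singletons contribute 0.  With ``tol`` given, clusters
    whose members fall outside the closed box around the center are
    counted as violations (0 for any constraint-satisfying result).
    """
    clusters = list(clusters)
    if not clusters:
        return ClusteringSummary(0, float("nan"), float("nan"), float("nan"),
                                 0 if tol is not None else None)
    sizes, d_mz, d_rt = [], [], []
    violations = 0
    for c in clusters:
        mz = peaks.loc[c.members, "mz"].to_numpy()
        rt = peaks.loc[c.members, "rt"].to_numpy()
        sizes.append(mz.size)
        d_mz.append(mz.max() - mz.min())
        d_rt.append(rt.max() - rt.min())
        if tol is not None:
            d1 = float(tol.delta_mz(c.center_mz))
            ok = (np.abs(mz - c.center_mz) <= d1).all() and \
                 (np.abs(rt - c.center_rt) <= tol.rt_halfwidth).all()
            violations += int(not ok)
    return ClusteringSummary(
        n_clusters=len(clusters),
        mean_size=float(np.mean(sizes)),
        mean_diameter_mz=float(np.mean(d_mz)),
        mean_diameter_rt=float(np.mean(d_rt)),
        n_box_violations=violations if tol is not None else None,
    )
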