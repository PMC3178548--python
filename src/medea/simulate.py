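"""Synthetic multi-sample LC-MS peak tables with known ground truth.

The generator emulates the statistical structure of a concatenated
multi-run peak list after feature detection and run-to-run correction:
each true peptide species has a fixed (m/z, RT, z) location and produces
one peak per sample (minus dropout), with m/z scatter proportional to the
location (ppm-scaled, as mass accuracy is relative) and constant-scale RT
scatter; uniform background peaks model spurious detections.  Deliberately
adjacent cluster pairs (``overlap_pairs``) stress the annealing and the
post-processing stages.

Within-cluster scatter is a truncated Gaussian (+/- 3 sd) by default so
that "every cluster respects the tolerance box" scenarios can be built
exactly; pass ``truncate_scatter=False`` for heavy-tail stress tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .tolerance import ToleranceModel

__all__ = ["SyntheticConfig", "generate", "truth_metrics", "RecoveryReport",
           "NOISE_LABEL"]

NOISE_LABEL = "noise"

#: Default charge-state distribution, roughly that of tryptic peptides.
DEFAULT_CHARGES = {1: 0.15, 2: 0.55, 3: 0.30}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a 12-replicate experiment with tolerances
    ``delta1 = 2.93 ppm`` (m/z) and ``delta2 = 0.3 min`` (RT) and
    within-cluster scatter of one sixth of the half-width per coordinate,
    so each peptide's peaks span at most one half-width around the true
    location and always fit a tolerance box.  ``min_separation`` (in units
    of the box half-width, required in at least one coordinate) keeps
    independent peptides out of each other's search frames; overlap pairs
    are exempt and are placed 1-2 full box widths from their partner.
    """

    n_peptides: int = 50
    n_samples: int = 12
    mz_range: tuple = (400.0, 1600.0)
    rt_range: tuple = (10.0, 80.0)
    charges: dict = field(default_factory=lambda: dict(DEFAULT_CHARGES))
    mz_scatter_ppm: float = 0.5
    rt_scatter: float = 0.05
    dropout_rate: float = 0.1
    n_noise: int = 100
    overlap_pairs: int = 0
    rng_seed: int = 0
    # tolerance box the scenario is built against (scales separations)
    mz_tol_ppm: float = 2.93
    rt_tol: float = 0.3
    min_separation: float = 8.0
    truncate_scatter: bool = True
    long_elution: bool = False

    def __post_init__(self) -> None:
        if self.n_peptides < 0 or self.n_noise < 0 or self.n_samples < 0:
            raise ValueError("counts must be non-negative")
        if self.mz_scatter_ppm < 0 or self.rt_scatter < 0:
            raise ValueError("scatter must be non-negative")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.overlap_pairs > self.n_peptides:
            raise ValueError("overlap_pairs cannot exceed n_peptides")
        for name in ("mz_range", "rt_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be a non-degenerate (min, max)")
        if not self.charges or any(p < 0 for p in self.charges.values()):
            raise ValueError("charges must map states to non-negative weights")
        if self.mz_tol_ppm <= 0 or self.rt_tol <= 0:
            raise ValueError("tolerances must be positive")

    @property
    def tolerance(self) -> ToleranceModel:
        return ToleranceModel(self.mz_tol_ppm, self.rt_tol)

    def with_seed(self, rng_seed: int) -> "SyntheticConfig":
        return replace(self, rng_seed=rng_seed)


def _draw_locations(config: SyntheticConfig, rng: np.random.Generator):
    """Peptide locations with pairwise separation in at least one coordinate."""
    tol = config.tolerance
    n = config.n_peptides
    mz = rng.uniform(*config.mz_range, size=n)
    rt = rng.uniform(*config.rt_range, size=n)
    if config.min_separation <= 0 or n < 2:
        return mz, rt
    sep = config.min_separation
    for _ in range(200):
        order = np.argsort(mz)
        smz, srt = mz[order], rt[order]
        bad: set[int] = set()
        for i in range(n):
            j = i + 1
            while j < n and smz[j] - smz[i] <= sep * float(tol.delta_mz(smz[j])):
                if abs(srt[j] - srt[i]) <= sep * tol.rt_halfwidth:
                    bad.add(int(order[j]))
                j += 1
        if not bad:
            return mz, rt
        idx = np.array(sorted(bad))
        mz[idx] = rng.uniform(*config.mz_range, size=len(idx))
        rt[idx] = rng.uniform(*config.rt_range, size=len(idx))
    raise RuntimeError(
        "could not place peptides with the requested min_separation; "
        "the m/z-RT plane is too crowded"
    )


def _scatter(rng: np.random.Generator, size: int, sd: float,
             truncate: bool) -> np.ndarray:
    if sd == 0:
        return np.zeros(size)
    draw = rng.normal(0.0, sd, size=size)
    if truncate:
        # redraw outside +/- 3 sd: truncation, not clipping, keeps the shape
        out = np.abs(draw) > 3.0 * sd
        while out.any():
            draw[out] = rng.normal(0.0, sd, size=int(out.sum()))
            out = np.abs(draw) > 3.0 * sd
    return draw


def generate(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a labelled peak table; the truth label is the ``peptide`` column.

    Background peaks carry the label ``"noise"``.  Fully reproducible from
    ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    tol = config.tolerance
    loc_mz, loc_rt = _draw_locations(config, rng)
    charge_states = np.array(sorted(config.charges))
    probs = np.array([config.charges[z] for z in charge_states], dtype=float)
    probs = probs / probs.sum()
    loc_z = rng.choice(charge_states, size=config.n_peptides, p=probs)
    labels = [f"pep{i:04d}" for i in range(config.n_peptides)]

    # companions for deliberately overlapping pairs: offset by 1-2 full box
    # widths (2*delta) per coordinate from the partner, random sign
    extra_mz, extra_rt, extra_z, extra_labels = [], [], [], []
    for k in range(config.overlap_pairs):
        base_mz, base_rt = loc_mz[k], loc_rt[k]
        sign = rng.choice([-1.0, 1.0], size=2)
        off1 = rng.uniform(1.0, 2.0) * 2.0 * float(tol.delta_mz(base_mz))
        off2 = rng.uniform(1.0, 2.0) * 2.0 * tol.rt_halfwidth
        extra_mz.append(base_mz + sign[0] * off1)
        extra_rt.append(np.clip(base_rt + sign[1] * off2, *config.rt_range))
        extra_z.append(loc_z[k])
        extra_labels.append(f"pep{k:04d}x")
    loc_mz = np.concatenate([loc_mz, np.array(extra_mz)])
    loc_rt = np.concatenate([loc_rt, np.array(extra_rt)])
    loc_z = np.concatenate([loc_z, np.array(extra_z, dtype=loc_z.dtype)])
    labels = labels + extra_labels

    frames = []
    for i, label in enumerate(labels):
        keep = rng.uniform(size=config.n_samples) >= config.dropout_rate
        n_kept = int(keep.sum())
        if n_kept == 0:
            continue
        sd_mz = config.mz_scatter_ppm * 1e-6 * loc_mz[i]
        if config.long_elution and i == 0:
            # one peptide eluting over a long RT window (> one box width)
            rt_off = rng.uniform(-3.0 * tol.rt_halfwidth,
                                 3.0 * tol.rt_halfwidth, size=n_kept)
        else:
            rt_off = _scatter(rng, n_kept, config.rt_scatter,
                              config.truncate_scatter)
        frames.append(pd.DataFrame({
            "mz": loc_mz[i] + _scatter(rng, n_kept, sd_mz,
                                       config.truncate_scatter),
            "rt": loc_rt[i] + rt_off,
            "z": int(loc_z[i]),
            "sample": [f"S{s + 1:02d}" for s in np.flatnonzero(keep)],
            "intensity": np.exp(rng.normal(12.0, 1.0, size=n_kept)),
            "peptide": label,
        }))
    if config.n_noise:
        frames.append(pd.DataFrame({
            "mz": rng.uniform(*config.mz_range, size=config.n_noise),
            "rt": rng.uniform(*config.rt_range, size=config.n_noise),
            "z": rng.choice(charge_states, size=config.n_noise, p=probs),
            "sample": [
                f"S{s + 1:02d}"
                for s in rng.integers(0, max(config.n_samples, 1),
                                      size=config.n_noise)
            ],
            "intensity": np.exp(rng.normal(10.0, 1.0, size=config.n_noise)),
            "peptide": NOISE_LABEL,
        }))
    if not frames:
        return pd.DataFrame(
            columns=["mz", "rt", "z", "sample", "intensity", "peptide"]
        )
    out = pd.concat(frames, ignore_index=True)
    out["z"] = out["z"].astype(int)
    return out


@dataclass(frozen=True)
class RecoveryReport:
    """Truth-based recovery summary of a clustering."""

    ari: float
    clusters_per_peptide: dict
    mean_clusters_per_peptide: float
    n_peptides: int
    n_noise_peaks: int

    def __str__(self) -> str:
        hist = ", ".join(f"{k}:{v}" for k, v in
                         sorted(self.clusters_per_peptide.items()))
        return (f"ARI {self.ari:.4f} over {self.n_peptides} peptides "
                f"({self.n_noise_peaks} noise peaks excluded); "
                f"clusters/peptide mean {self.mean_clusters_per_peptide:.3f} "
                f"[{hist}]")


def truth_metrics(clusters, truth: pd.Series) -> RecoveryReport:
    """Compare a clustering with truth labels aligned on peak row index.

    Computes the adjusted Rand index over non-noise peaks and the number of
    distinct clusters each true peptide is spread over.
    """
    assigned = pd.Series(-1, index=truth.index, dtype=int)
    for c in clusters:
        extra = set(np.asarray(c.members).tolist()) - set(truth.index)
        if extra:
            raise ValueError(f"cluster {c.id} references unknown peaks {sorted(extra)[:5]}")
        assigned.loc[c.members] = c.id
    real = truth != NOISE_LABEL
    if (assigned[real] < 0).any():
        missing = assigned.index[real & (assigned < 0)][:5].tolist()
        raise ValueError(f"labelled peaks not covered by any cluster: {missing}")
    ari = float(adjusted_rand_score(truth[real], assigned[real]))
    spread = (
        pd.DataFrame({"peptide": truth[real], "cluster": assigned[real]})
        .groupby("peptide")["cluster"].nunique()
    )
    hist = spread.value_counts().sort_index()
    return RecoveryReport(
        ari=ari,
        clusters_per_peptide={int(k): int(v) for k, v in hist.items()},
        mean_clusters_per_peptide=float(spread.mean()) if len(spread) else float("nan"),
        n_peptides=int(len(spread)),
        n_noise_peaks=int((~real).sum()),
    )
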