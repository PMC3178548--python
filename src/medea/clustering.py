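"""MEDEA main loop: seeded cluster growth under deterministic annealing.

Peaks of each charge state are clustered independently.  An unused peak
seeds a cluster center; all unused peaks of that charge within a search
frame of +/- 3 half-widths are weighted against the center with the
annealed redescending weights, the center moves to the weighted mean, and
the frame follows the center.  The temperature starts high (the center is
drawn toward the local center of mass) and is lowered along a fixed
schedule until the weights approximate a hard cut at the tolerance-box
boundary.  Two early-termination rules make isolated, tolerance-respecting
clusters resolve in a single iteration:

(a) if every peak with weight above ``weight_floor`` already lies inside
    the box around the current center, jump straight to the final
    temperature; and
(b) if the center moves by no more than ``move_fraction`` of the half-width
    in both coordinates, likewise.

At the final temperature the weight function is effectively the indicator
of the box, so the closing pass is implemented exactly: the center becomes
the arithmetic mean of the in-box frame peaks (the skipped mean) and the
cluster's members are the frame peaks inside the box around that final
center (closed intervals).  Each grown cluster's members are marked used;
clustering continues until every peak is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import validate_peaks
from .mestimator import weight
from .tolerance import CUTOFF, ToleranceModel

__all__ = [
    "AnnealingSchedule", "Cluster", "default_schedule",
    "search_frame", "grow_cluster", "cluster_peaks",
]

#: Search frames extend this many half-widths from the center.
FRAME_FACTOR = 3.0

DEFAULT_TEMPERATURES = (8.0, 6.0, 4.0, 3.0, 2.0, 1.5, 1.0, 1.0, 1.0, 1.0, 1.0, 0.25)

SEED_ORDERS = ("input", "intensity")


@dataclass(frozen=True)
class AnnealingSchedule:
    """Temperature sequence plus the two early-stop thresholds.

    ``temperatures`` must be positive and non-increasing; the last entry is
    the final temperature at which membership is decided.  ``weight_floor``
    is the weight above which a peak counts as "attracted" for stop rule
    (a); ``move_fraction`` is the relative center-movement threshold of
    stop rule (b).
    """

    temperatures: tuple = DEFAULT_TEMPERATURES
    weight_floor: float = 0.1
    move_fraction: float = 0.001

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.temperatures)
        if len(t) == 0 or any(x <= 0 for x in t):
            raise ValueError("temperatures must be a non-empty positive sequence")
        if any(b > a for a, b in zip(t, t[1:])):
            raise ValueError("temperatures must be non-increasing")
        object.__setattr__(self, "temperatures", t)
        if not 0 < self.weight_floor < 1:
            raise ValueError("weight_floor must be in (0, 1)")
        if not 0 < self.move_fraction < 1:
            raise ValueError("move_fraction must be in (0, 1)")

    def __len__(self) -> int:
        return len(self.temperatures)


def default_schedule() -> AnnealingSchedule:
    """The standard 12-step schedule 8, 6, 4, 3, 2, 1.5, 1 (x5), 0.25."""
    return AnnealingSchedule()


@dataclass
class Cluster:
    """A matched peak group: center, charge and member row indices."""

    id: int
    center_mz: float
    center_rt: float
    z: int
    members: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=np.int64)
        if self.members.size == 0:
            raise ValueError("a cluster must have at least one member")

    @property
    def center(self) -> tuple[float, float]:
        return (self.center_mz, self.center_rt)

    @property
    def size(self) -> int:
        return int(self.members.size)


def search_frame(center: tuple[float, float], peaks: pd.DataFrame,
                 tol: ToleranceModel) -> np.ndarray:
    """Row indices of ``peaks`` inside the closed +/-3-half-width frame.

    ``peaks`` is expected to be pre-filtered to the unused peaks of one
    charge; this function only applies the double inequality.
    """
    cmz, crt = center
    d1 = float(tol.delta_mz(cmz))
    keep = (
        (np.abs(peaks["mz"].to_numpy() - cmz) <= FRAME_FACTOR * d1)
        & (np.abs(peaks["rt"].to_numpy() - crt) <= FRAME_FACTOR * tol.rt_halfwidth)
    )
    return peaks.index.to_numpy()[keep]


class _ChargeGroup:
    """m/z-sorted arrays of one charge's peaks with a used mask."""

    def __init__(self, rows: np.ndarray, mz: np.ndarray, rt: np.ndarray):
        order = np.argsort(mz, kind="stable")
        self.mz = mz[order]
        self.rt = rt[order]
        self.rows = rows[order]
        self.used = np.zeros(len(order), dtype=bool)
        # position of each original entry in the sorted arrays
        self.pos_by_entry = np.empty(len(order), dtype=np.int64)
        self.pos_by_entry[order] = np.arange(len(order))

    def frame(self, cmz: float, crt: float, tol: ToleranceModel) -> np.ndarray:
        d1 = FRAME_FACTOR * float(tol.delta_mz(cmz))
        a = np.searchsorted(self.mz, cmz - d1, side="left")
        b = np.searchsorted(self.mz, cmz + d1, side="right")
        keep = ~self.used[a:b] & (
            np.abs(self.rt[a:b] - crt) <= FRAME_FACTOR * tol.rt_halfwidth
        )
        return np.arange(a, b, dtype=np.int64)[keep]


def _coord_weights(dmz, drt, d1, d2, temperature):
    r1 = dmz * (CUTOFF / d1)
    r2 = drt * (CUTOFF / d2)
    return weight(r1, CUTOFF, temperature) * weight(r2, CUTOFF, temperature)


def _final_pass(group: _ChargeGroup, cmz: float, crt: float,
                frame: np.ndarray, tol: ToleranceModel,
                seed_pos: int, iteration: int):
    """Closing membership pass at the final temperature (skipped mean).

    The center becomes the arithmetic mean of the frame peaks inside the
    box around the incoming center; membership is the closed box around
    that final center.  Degenerate cases fall back to a seed singleton.
    """
    d2 = tol.rt_halfwidth
    if frame.size:
        fmz, frt = group.mz[frame], group.rt[frame]
        d1 = float(tol.delta_mz(cmz))
        inbox = (np.abs(fmz - cmz) <= d1) & (np.abs(frt - crt) <= d2)
        if inbox.any():
            new_mz = float(fmz[inbox].mean())
            new_rt = float(frt[inbox].mean())
            d1 = float(tol.delta_mz(new_mz))
            members = frame[(np.abs(fmz - new_mz) <= d1)
                            & (np.abs(frt - new_rt) <= d2)]
            if members.size:
                return new_mz, new_rt, members, iteration
    return (float(group.mz[seed_pos]), float(group.rt[seed_pos]),
            np.array([seed_pos], dtype=np.int64), iteration)


def _grow(group: _ChargeGroup, seed_pos: int, tol: ToleranceModel,
          sched: AnnealingSchedule):
    cmz = float(group.mz[seed_pos])
    crt = float(group.rt[seed_pos])
    d2 = tol.rt_halfwidth
    frame = group.frame(cmz, crt, tol)
    n_anneal = len(sched.temperatures) - 1
    for k in range(1, n_anneal + 1):
        if frame.size == 0:   # cannot happen from a seed-containing start
            return _final_pass(group, cmz, crt, frame, tol, seed_pos, k)
        temperature = sched.temperatures[k - 1]
        fmz, frt = group.mz[frame], group.rt[frame]
        d1 = float(tol.delta_mz(cmz))
        w = _coord_weights(fmz - cmz, frt - crt, d1, d2, temperature)
        inbox = (np.abs(fmz - cmz) <= d1) & (np.abs(frt - crt) <= d2)
        if np.all(inbox[w > sched.weight_floor]):          # stop rule (a)
            return _final_pass(group, cmz, crt, frame, tol, seed_pos, k)
        total = float(w.sum())
        if total <= 0.0:
            return _final_pass(group, cmz, crt, frame, tol, seed_pos, k)
        new_mz = float(w @ fmz / total)
        new_rt = float(w @ frt / total)
        small_move = (
            abs(new_mz - cmz) <= sched.move_fraction * float(tol.delta_mz(new_mz))
            and abs(new_rt - crt) <= sched.move_fraction * d2
        )
        cmz, crt = new_mz, new_rt
        frame = group.frame(cmz, crt, tol)
        if small_move:                                     # stop rule (b)
            return _final_pass(group, cmz, crt, frame, tol, seed_pos, k)
    return _final_pass(group, cmz, crt, frame, tol, seed_pos, len(sched))


def _make_group(peaks: pd.DataFrame) -> _ChargeGroup:
    return _ChargeGroup(
        peaks.index.to_numpy(dtype=np.int64),
        peaks["mz"].to_numpy(dtype=float),
        peaks["rt"].to_numpy(dtype=float),
    )


def grow_cluster(seed: int, peaks: pd.DataFrame, tol: ToleranceModel,
                 sched: AnnealingSchedule | None = None,
                 used: np.ndarray | None = None,
                 cluster_id: int = 0) -> tuple[Cluster, int]:
    """Grow a single cluster from the seed row index.

    ``peaks`` is the full table; only unused peaks sharing the seed's charge
    participate.  Returns the cluster and the number of annealing
    iterations it took.  The seed itself may legitimately end up outside
    the returned cluster when the center migrates to a denser region.
    """
    sched = sched or default_schedule()
    if used is not None and seed in set(np.asarray(used).tolist()):
        raise ValueError(f"seed {seed} is already used")
    if seed not in peaks.index:
        raise KeyError(f"seed row {seed} not in peak table")
    z = int(peaks.loc[seed, "z"])
    eligible = peaks[peaks["z"] == z]
    if used is not None:
        eligible = eligible.drop(index=np.asarray(used), errors="ignore")
    group = _make_group(eligible)
    seed_pos = int(group.pos_by_entry[eligible.index.get_indexer([seed])[0]])
    cmz, crt, members, n_iter = _grow(group, seed_pos, tol, sched)
    cluster = Cluster(cluster_id, cmz, crt, z, np.sort(group.rows[members]))
    return cluster, n_iter


def _seed_sequence(group: _ChargeGroup, peaks: pd.DataFrame, policy: str):
    if policy == "input":
        return np.argsort(group.rows, kind="stable")
    if policy == "intensity":
        if "intensity" not in peaks.columns:
            raise ValueError("seed_order='intensity' requires an intensity column")
        intensity = peaks["intensity"].reindex(group.rows).to_numpy(dtype=float)
        return np.lexsort((group.rows, -intensity))
    raise ValueError(f"unknown seed_order {policy!r}; expected one of {SEED_ORDERS}")


def cluster_peaks(peaks: pd.DataFrame, tol: ToleranceModel,
                  sched: AnnealingSchedule | None = None,
                  seed_order: str = "input"):
    """Partition a peak table into tolerance-box clusters, per charge state.

    Charges are processed in ascending order; within a charge, seeds are
    taken in input-row order (or descending intensity with
    ``seed_order='intensity'``).  Every peak ends up in exactly one cluster.

    Returns ``(clusters, iteration_counts)`` where ``iteration_counts`` has
    one entry per grown cluster (the annealing-iteration histogram of a run
    is ``numpy.bincount`` of it).
    """
    sched = sched or default_schedule()
    peaks = validate_peaks(peaks)
    clusters: list[Cluster] = []
    iterations: list[int] = []
    next_id = 0
    for z in sorted(pd.unique(peaks["z"])):
        sub = peaks[peaks["z"] == z]
        group = _make_group(sub)
        order = _seed_sequence(group, sub, seed_order)
        ptr = 0
        while ptr < len(order):
            pos = int(order[ptr])
            if group.used[pos]:
                ptr += 1
                continue
            cmz, crt, members, n_iter = _grow(group, pos, tol, sched)
            group.used[members] = True
            clusters.append(
                Cluster(next_id, cmz, crt, int(z), np.sort(group.rows[members]))
            )
            iterations.append(n_iter)
            next_id += 1
            # the seed may sit outside the grown cluster (center migrated to
            # a denser region); it then seeds again with the members gone
            if group.used[pos]:
                ptr += 1
    return clusters, np.asarray(iterations, dtype=np.int64)
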