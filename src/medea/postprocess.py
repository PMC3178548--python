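"""Post-processing of grown clusters: global reassignment and fusion.

The sequential main loop consumes peaks greedily, so two corrections are
applied afterwards.

Stage 1 (globally optimal assignment): clusters whose tolerance boxes
intersect are grouped into overlap components (the transitive closure of
the pairwise box-intersection relation).  Within each component, every peak
is re-associated with the cluster giving it the largest combined weight at
T = 1, centers are recomputed as per-coordinate mid-ranges, and the two
steps alternate until the association is stable.  Mid-range centering
keeps all members inside the box whenever the per-coordinate spread fits
one box width; any peak that still violates the box after convergence is
split off into its own singleton cluster so the tolerance contract always
holds.

Stage 2 (cluster fusion): for each cluster in ascending id order, the
overlapping neighbour whose center has the largest weight is fused in
whenever the union still fits one tolerance box; the fused center is again
the mid-range.  Passes repeat until none fuses.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import count

import numpy as np
import pandas as pd

from .clustering import Cluster
from .mestimator import combined_weight
from .tolerance import ToleranceModel

__all__ = [
    "OverlapComponent", "boxes_overlap", "overlap_components",
    "midrange_center", "reassign_component", "reassign", "fuse_clusters",
]

STAGE1_MAX_ITER = 100
POSTPROCESS_TEMPERATURE = 1.0


@dataclass(frozen=True)
class OverlapComponent:
    """An equivalence class of clusters under transitive box overlap."""

    cluster_ids: tuple
    peak_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.cluster_ids)


def boxes_overlap(a: Cluster, b: Cluster, tol: ToleranceModel) -> bool:
    """True iff the closed tolerance boxes of two same-charge clusters intersect.

    Each box's m/z half-width is evaluated at its own center m/z; clusters
    of different charge never overlap.
    """
    if a.z != b.z:
        return False
    return bool(
        abs(a.center_mz - b.center_mz)
        <= float(tol.delta_mz(a.center_mz)) + float(tol.delta_mz(b.center_mz))
        and abs(a.center_rt - b.center_rt) <= 2.0 * tol.rt_halfwidth
    )


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def overlap_components(clusters, tol: ToleranceModel):
    """Connected components of the box-overlap graph, ordered by min id.

    Uses a per-charge sweep over m/z box intervals so only candidate pairs
    whose m/z extents intersect are tested.
    """
    clusters = list(clusters)
    uf = _UnionFind([c.id for c in clusters])
    by_charge: dict[int, list[Cluster]] = {}
    for c in clusters:
        by_charge.setdefault(c.z, []).append(c)
    for group in by_charge.values():
        lo = np.array([c.center_mz - float(tol.delta_mz(c.center_mz)) for c in group])
        hi = np.array([c.center_mz + float(tol.delta_mz(c.center_mz)) for c in group])
        rt = np.array([c.center_rt for c in group])
        order = np.argsort(lo, kind="stable")
        lo, hi, rt = lo[order], hi[order], rt[order]
        ids = np.array([group[i].id for i in order])
        for i in range(len(order)):
            j = i + 1
            while j < len(order) and lo[j] <= hi[i]:
                if abs(rt[j] - rt[i]) <= 2.0 * tol.rt_halfwidth:
                    uf.union(int(ids[i]), int(ids[j]))
                j += 1
    groups: dict[int, list[Cluster]] = {}
    for c in clusters:
        groups.setdefault(uf.find(c.id), []).append(c)
    components = []
    for root in sorted(groups):
        members = sorted(groups[root], key=lambda c: c.id)
        peak_ids = np.sort(np.concatenate([c.members for c in members]))
        components.append(
            OverlapComponent(tuple(c.id for c in members), peak_ids)
        )
    return components


def midrange_center(mz: np.ndarray, rt: np.ndarray) -> tuple[float, float]:
    """Per-coordinate (min + max) / 2 of a non-empty peak set."""
    mz = np.asarray(mz, dtype=float)
    rt = np.asarray(rt, dtype=float)
    if mz.size == 0:
        raise ValueError("midrange_center of an empty peak set")
    return (float((mz.min() + mz.max()) / 2.0),
            float((rt.min() + rt.max()) / 2.0))


def _in_box(mz, rt, cmz, crt, tol):
    d1 = float(tol.delta_mz(cmz))
    return (np.abs(mz - cmz) <= d1) & (np.abs(rt - crt) <= tol.rt_halfwidth)


def reassign_component(component_clusters, peaks: pd.DataFrame,
                       tol: ToleranceModel,
                       temperature: float = POSTPROCESS_TEMPERATURE,
                       max_iter: int = STAGE1_MAX_ITER,
                       idgen=None):
    """Stage-1 reassignment of the peaks of one overlap component.

    Returns ``(clusters, n_changed, n_iterations)`` where ``n_changed``
    counts peaks whose cluster id changed.  Ties in the largest weight go
    to the lowest cluster id; empty clusters are dropped; final centers are
    always mid-ranges of the final membership; box violations are split off
    as fresh singleton clusters (ids from ``idgen``).
    """
    comp = sorted(component_clusters, key=lambda c: c.id)
    if idgen is None:
        idgen = count(max(c.id for c in comp) + 1)
    z = comp[0].z
    if any(c.z != z for c in comp):
        raise ValueError("an overlap component must be charge-pure")

    rows = np.sort(np.concatenate([c.members for c in comp]))
    mz = peaks.loc[rows, "mz"].to_numpy(dtype=float)
    rt = peaks.loc[rows, "rt"].to_numpy(dtype=float)
    ids = [c.id for c in comp]                       # ascending
    centers = [(c.center_mz, c.center_rt) for c in comp]
    incoming = {}
    for c in comp:
        for r in c.members:
            incoming[int(r)] = c.id
    prev = np.array([ids.index(incoming[int(r)]) for r in rows])

    n_iter = 0
    assign = prev
    for n_iter in range(1, max_iter + 1):
        w = np.column_stack([
            combined_weight(mz, rt, cmz, crt, tol, temperature)
            for cmz, crt in centers
        ])
        assign = w.argmax(axis=1)        # first max -> lowest id (ids ascending)
        if np.array_equal(assign, prev):
            break
        prev = assign
        # recompute centers as mid-ranges; drop emptied clusters
        keep = [k for k in range(len(ids)) if np.any(assign == k)]
        if len(keep) < len(ids):
            remap = {k: i for i, k in enumerate(keep)}
            ids = [ids[k] for k in keep]
            assign = np.array([remap[k] for k in assign])
            prev = assign
        centers = [
            midrange_center(mz[assign == k], rt[assign == k])
            for k in range(len(ids))
        ]

    out: list[Cluster] = []
    singles: list[Cluster] = []
    for k in range(len(ids)):
        sel = assign == k
        if not sel.any():
            continue
        krows = rows[sel]
        kmz, krt = mz[sel], rt[sel]
        # enforce the hard box constraint around the mid-range center
        while True:
            cmz, crt = midrange_center(kmz, krt)
            ok = _in_box(kmz, krt, cmz, crt, tol)
            if ok.all():
                break
            for r, pmz, prt in zip(krows[~ok], kmz[~ok], krt[~ok]):
                singles.append(Cluster(next(idgen), float(pmz), float(prt),
                                       z, np.array([r])))
            krows, kmz, krt = krows[ok], kmz[ok], krt[ok]
            if krows.size == 0:
                break
        if krows.size:
            out.append(Cluster(ids[k], cmz, crt, z, np.sort(krows)))
    out.extend(singles)
    final = {}
    for c in out:
        for r in c.members:
            final[int(r)] = c.id
    n_changed = sum(1 for r in rows if final[int(r)] != incoming[int(r)])
    return out, n_changed, n_iter


def reassign(clusters, peaks: pd.DataFrame, tol: ToleranceModel,
             temperature: float = POSTPROCESS_TEMPERATURE,
             max_iter: int = STAGE1_MAX_ITER):
    """Stage 1 over all overlap components.

    Singleton components pass through unchanged (no competition).  Returns
    ``(clusters, n_changed)`` with clusters ordered by id.
    """
    clusters = list(clusters)
    if not clusters:
        return [], 0
    by_id = {c.id: c for c in clusters}
    idgen = count(max(by_id) + 1)
    out: list[Cluster] = []
    n_changed = 0
    for comp in overlap_components(clusters, tol):
        members = [by_id[i] for i in comp.cluster_ids]
        if len(members) == 1:
            out.append(members[0])
            continue
        new, changed, _ = reassign_component(members, peaks, tol,
                                             temperature, max_iter, idgen)
        out.extend(new)
        n_changed += changed
    return sorted(out, key=lambda c: c.id), n_changed


def fuse_clusters(clusters, peaks: pd.DataFrame, tol: ToleranceModel,
                  temperature: float = POSTPROCESS_TEMPERATURE,
                  single_pass: bool = False):
    """Stage-2 fusion of clusters whose union fits one tolerance box.

    Within a pass, clusters are visited in ascending id; the best
    overlapping neighbour (largest center-to-center weight at T = 1, ties
    to the lowest id) is fused in if the union's per-coordinate spread fits
    a box whose m/z half-width is evaluated at the fused mid-range m/z.
    Passes repeat to a fixpoint unless ``single_pass``.  Returns
    ``(clusters, n_fused)``.
    """
    alive: dict[int, Cluster] = {c.id: c for c in clusters}
    mz_all = peaks["mz"]
    rt_all = peaks["rt"]
    total_fused = 0
    while True:
        fused_in_pass = 0
        used: set[int] = set()
        # positional state arrays, kept current as fusions happen in-pass
        ids = np.array(sorted(alive), dtype=np.int64)
        pos_of = {int(cid): k for k, cid in enumerate(ids)}
        cmz_arr = np.array([alive[int(i)].center_mz for i in ids])
        crt_arr = np.array([alive[int(i)].center_rt for i in ids])
        z_arr = np.array([alive[int(i)].z for i in ids])
        delta_arr = np.asarray(tol.delta_mz(cmz_arr), dtype=float)
        alive_mask = np.ones(len(ids), dtype=bool)
        for i in ids.tolist():
            if i not in alive or i in used:
                continue
            ci = alive[i]
            k = pos_of[i]
            cand = (
                alive_mask
                & (z_arr == ci.z)
                & (np.abs(cmz_arr - cmz_arr[k]) <= delta_arr + delta_arr[k])
                & (np.abs(crt_arr - crt_arr[k]) <= 2.0 * tol.rt_halfwidth)
            )
            cand[k] = False
            cand_pos = np.flatnonzero(cand)
            if cand_pos.size:
                weights = combined_weight(
                    cmz_arr[cand_pos], crt_arr[cand_pos],
                    ci.center_mz, ci.center_rt, tol, temperature,
                )
                best = cand_pos[int(np.argmax(weights))]  # first max -> lowest id
                cj = alive[int(ids[best])]
                rows = np.sort(np.concatenate([ci.members, cj.members]))
                mz = mz_all.loc[rows].to_numpy()
                rt = rt_all.loc[rows].to_numpy()
                cmz, crt = midrange_center(mz, rt)
                fits = (
                    mz.max() - mz.min() <= 2.0 * float(tol.delta_mz(cmz))
                    and rt.max() - rt.min() <= 2.0 * tol.rt_halfwidth
                )
                if fits:
                    alive[i] = Cluster(i, cmz, crt, ci.z, rows)
                    del alive[cj.id]
                    alive_mask[best] = False
                    cmz_arr[k], crt_arr[k] = cmz, crt
                    delta_arr[k] = float(tol.delta_mz(cmz))
                    fused_in_pass += 1
            used.add(i)
        total_fused += fused_in_pass
        if single_pass or fused_in_pass == 0:
            break
    return [alive[i] for i in sorted(alive)], total_fused
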