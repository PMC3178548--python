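import itertools

import numpy as np
import pandas as pd
import pytest

from medea import (Cluster, ToleranceModel, boxes_overlap, combined_weight,
                   fuse_clusters, midrange_center, overlap_components,
                   reassign, reassign_component)

from conftest import make_peaks


def cluster_of(cid, peaks, rows, z=2):
    """Cluster over the given rows, centered at their mid-range."""
    mz = peaks.loc[rows, "mz"].to_numpy()
    rt = peaks.loc[rows, "rt"].to_numpy()
    cmz, crt = midrange_center(mz, rt)
    return Cluster(cid, cmz, crt, z, np.array(rows))


def brute_force_components(clusters, tol):
    """Transitive closure by repeated pairwise sweeps (independent oracle)."""
    groups = [{c.id} for c in clusters]
    by_id = {c.id: c for c in clusters}
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(range(len(groups)), 2):
            if groups[a] and groups[b] and any(
                boxes_overlap(by_id[i], by_id[j], tol)
                for i in groups[a] for j in groups[b]
            ):
                groups[a] |= groups[b]
                groups[b] = set()
                changed = True
    return sorted(frozenset(g) for g in groups if g)


def random_clusters(rng, tol, n=30, spread=40.0):
    """Random small clusters over a crowded m/z-RT patch."""
    peaks_frames = []
    clusters = []
    row = 0
    for cid in range(n):
        cmz = rng.uniform(800.0, 800.0 + spread * 800.0 * 2.93e-6)
        crt = rng.uniform(40.0, 40.0 + spread * 0.03)
        d1 = 2.93e-6 * cmz
        k = int(rng.integers(1, 5))
        mz = cmz + rng.uniform(-0.9 * d1, 0.9 * d1, k)
        rt = crt + rng.uniform(-0.27, 0.27, k)
        peaks_frames.append(make_peaks(mz, rt))
        rows = list(range(row, row + k))
        row += k
        clusters.append((cid, rows))
    peaks = pd.concat(peaks_frames, ignore_index=True)
    return peaks, [cluster_of(cid, peaks, rows) for cid, rows in clusters]


def check_box_invariant(clusters, peaks, tol):
    for c in clusters:
        d1 = float(tol.delta_mz(c.center_mz))
        sub = peaks.loc[c.members]
        assert ((sub["mz"] - c.center_mz).abs() <= d1).all()
        assert ((sub["rt"] - c.center_rt).abs() <= tol.rt_halfwidth).all()


def peak_multiset(clusters):
    return sorted(np.concatenate([c.members for c in clusters]).tolist())


class TestBoxesOverlap:
    def test_identical_centers(self, tol):
        peaks = make_peaks([800.0], [40.0])
        a = cluster_of(0, peaks, [0])
        b = cluster_of(1, peaks, [0])
        assert boxes_overlap(a, b, tol)

    def test_distant_in_mz(self, tol):
        peaks = make_peaks([800.0, 801.0], [40.0, 40.0])
        assert not boxes_overlap(cluster_of(0, peaks, [0]),
                                 cluster_of(1, peaks, [1]), tol)

    def test_shared_edge_counts(self):
        # boxes touching exactly at one RT edge overlap (closed intervals);
        # 0.375 and 40.75 are exact in binary so the edge test is exact
        tol = ToleranceModel(2.93, 0.375)
        peaks = make_peaks([800.0, 800.0], [40.0, 40.75])
        assert boxes_overlap(cluster_of(0, peaks, [0]),
                             cluster_of(1, peaks, [1]), tol)

    def test_cross_charge_never_overlaps(self, tol):
        peaks = make_peaks([800.0], [40.0])
        assert not boxes_overlap(cluster_of(0, peaks, [0], z=2),
                                 cluster_of(1, peaks, [0], z=3), tol)


class TestOverlapComponents:
    def test_chain_closes_transitively(self, tol):
        # A-B overlap, B-C overlap, A-C do not: one component of three
        peaks = make_peaks([800.0, 800.0, 800.0], [40.0, 40.5, 41.0])
        clusters = [cluster_of(i, peaks, [i]) for i in range(3)]
        comps = overlap_components(clusters, tol)
        assert len(comps) == 1
        assert comps[0].cluster_ids == (0, 1, 2)
        assert not boxes_overlap(clusters[0], clusters[2], tol)

    def test_disjoint_boxes_all_singletons(self, tol):
        peaks = make_peaks([700.0, 800.0, 900.0], [10.0, 40.0, 70.0])
        comps = overlap_components(
            [cluster_of(i, peaks, [i]) for i in range(3)], tol)
        assert [c.cluster_ids for c in comps] == [(0,), (1,), (2,)]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_closure(self, tol, seed):
        rng = np.random.default_rng(seed)
        peaks, clusters = random_clusters(rng, tol, n=30)
        comps = overlap_components(clusters, tol)
        got = sorted(frozenset(c.cluster_ids) for c in comps)
        assert got == brute_force_components(clusters, tol)
        # every cluster in exactly one component
        all_ids = sorted(i for c in comps for i in c.cluster_ids)
        assert all_ids == list(range(len(clusters)))


class TestMidrange:
    def test_single_peak(self):
        assert midrange_center([800.0], [40.0]) == (800.0, 40.0)

    def test_two_point_rt(self):
        assert midrange_center([800.0, 800.0], [1.0, 3.0])[1] == 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            midrange_center([], [])

    def test_containment_within_half_spread(self, rng):
        mz = rng.uniform(700, 701, 25)
        rt = rng.uniform(10, 12, 25)
        cmz, crt = midrange_center(mz, rt)
        assert np.abs(mz - cmz).max() <= (mz.max() - mz.min()) / 2 + 1e-12
        assert np.abs(rt - crt).max() <= (rt.max() - rt.min()) / 2 + 1e-12


class TestReassign:
    def test_singleton_component_untouched(self, tol):
        peaks = make_peaks([800.0, 800.0001], [40.0, 40.01])
        c = cluster_of(0, peaks, [0, 1])
        out, n_changed = reassign([c], peaks, tol)
        assert n_changed == 0
        assert out[0] is c

    def test_peak_migrates_to_nearer_cluster(self, tol):
        """Two overlapping clusters; a peak sitting on the neighbour's
        center must migrate, and the final assignment must be the per-peak
        weight argmax over the final mid-range centers (the optimum an
        exhaustive enumeration would pick)."""
        d1 = 2.93e-6 * 800.0
        # cluster 0 owns a stray peak located inside cluster 1's core
        mz0 = [800.0 - 0.3 * d1, 800.0 + 0.3 * d1, 800.0 + 1.6 * d1]
        mz1 = [800.0 + 1.5 * d1, 800.0 + 1.7 * d1]
        peaks = make_peaks(mz0 + mz1, [40.0] * 5)
        c0 = cluster_of(0, peaks, [0, 1, 2])
        c1 = cluster_of(1, peaks, [3, 4])
        out, n_changed = reassign([c0, c1], peaks, tol)
        members = {c.id: sorted(c.members) for c in out}
        assert members[0] == [0, 1]
        assert members[1] == [2, 3, 4]
        assert n_changed == 1
        check_box_invariant(out, peaks, tol)
        # optimality: every peak sits with its largest-weight cluster
        for c in out:
            for r in c.members:
                w_own = combined_weight(peaks.loc[r, "mz"], peaks.loc[r, "rt"],
                                        c.center_mz, c.center_rt, tol, 1.0)
                for other in out:
                    w_other = combined_weight(
                        peaks.loc[r, "mz"], peaks.loc[r, "rt"],
                        other.center_mz, other.center_rt, tol, 1.0)
                    assert w_own >= w_other - 1e-12

    def test_fixed_point_recenters_to_midrange(self, tol):
        d1 = 2.93e-6 * 800.0
        peaks = make_peaks(
            [800.0, 800.0 + 0.4 * d1, 800.0 + 1.8 * d1, 800.0 + 2.2 * d1],
            [40.0, 40.0, 40.0, 40.0])
        c0 = Cluster(0, 800.0 + 0.1 * d1, 40.0, 2, np.array([0, 1]))
        c1 = Cluster(1, 800.0 + 2.0 * d1, 40.0, 2, np.array([2, 3]))
        out, n_changed = reassign([c0, c1], peaks, tol)
        assert n_changed == 0
        for c in out:
            mz = peaks.loc[c.members, "mz"].to_numpy()
            rt = peaks.loc[c.members, "rt"].to_numpy()
            assert (c.center_mz, c.center_rt) == midrange_center(mz, rt)

    def test_conservation_and_idempotence(self, tol):
        rng = np.random.default_rng(5)
        peaks, clusters = random_clusters(rng, tol, n=25, spread=10.0)
        out, _ = reassign(clusters, peaks, tol)
        assert peak_multiset(out) == peak_multiset(clusters)
        check_box_invariant(out, peaks, tol)
        again, n_changed = reassign(out, peaks, tol)
        assert n_changed == 0
        assert peak_multiset(again) == peak_multiset(out)

    def test_mixed_charge_component_rejected(self, tol):
        peaks = make_peaks([800.0, 800.0], [40.0, 40.0])
        a = cluster_of(0, peaks, [0], z=2)
        b = cluster_of(1, peaks, [1], z=3)
        with pytest.raises(ValueError):
            reassign_component([a, b], peaks, tol)


class TestFuse:
    def test_split_cloud_fuses_to_one(self, tol):
        """Two clusters carved out of one tight cloud whose union fits a
        single box become one cluster with the mid-range center."""
        d1 = 2.93e-6 * 900.0
        mz = 900.0 + np.array([-0.8, -0.5, 0.2, 0.5, 0.8]) * d1
        rt = 50.0 + np.array([-0.1, 0.05, 0.0, -0.05, 0.1])
        peaks = make_peaks(mz, rt)
        a = cluster_of(0, peaks, [0, 1])
        b = cluster_of(1, peaks, [2, 3, 4])
        out, n_fused = fuse_clusters([a, b], peaks, tol)
        assert n_fused == 1 and len(out) == 1
        assert sorted(out[0].members) == [0, 1, 2, 3, 4]
        assert (out[0].center_mz, out[0].center_rt) == midrange_center(mz, rt)
        check_box_invariant(out, peaks, tol)

    def test_wide_rt_union_not_fused(self, tol):
        peaks = make_peaks([900.0] * 4, [49.8, 50.2, 50.4, 50.56])
        a = cluster_of(0, peaks, [0, 1])
        b = cluster_of(1, peaks, [2, 3])
        assert boxes_overlap(a, b, tol)  # boxes intersect ...
        out, n_fused = fuse_clusters([a, b], peaks, tol)
        assert n_fused == 0 and len(out) == 2  # ... but the union is too wide

    def test_chain_matches_greedy_replay(self, tol):
        """Three adjacent tiny clusters whose pairwise unions all fit: the
        ascending-id greedy absorbs the best neighbour first, then the
        next pass continues to the fixpoint."""
        d1 = 2.93e-6 * 900.0
        mz = 900.0 + np.array([-0.6, 0.0, 0.6]) * d1
        peaks = make_peaks(mz, [50.0, 50.0, 50.0])
        clusters = [cluster_of(i, peaks, [i]) for i in range(3)]
        out, n_fused = fuse_clusters(clusters, peaks, tol)
        # greedy replay: i=0 absorbs its nearest neighbour 1; then i=2
        # (the only remaining unused cluster) absorbs the fused cluster 0,
        # which is still a legal fusion partner despite being marked used
        assert n_fused == 2
        assert len(out) == 1 and out[0].id == 2
        assert sorted(out[0].members) == [0, 1, 2]

    def test_single_pass_mode_stops_early(self, tol):
        d1 = 2.93e-6 * 900.0
        mz = 900.0 + np.array([-0.9, -0.3, 0.3, 0.9]) * d1
        peaks = make_peaks(mz, [50.0] * 4)
        clusters = [cluster_of(i, peaks, [i]) for i in range(4)]
        full, fused_full = fuse_clusters(clusters, peaks, tol)
        single, fused_single = fuse_clusters(clusters, peaks, tol,
                                             single_pass=True)
        assert fused_single <= fused_full
        assert peak_multiset(single) == peak_multiset(full)

    def test_conservation_and_idempotence(self, tol):
        rng = np.random.default_rng(9)
        peaks, clusters = random_clusters(rng, tol, n=25, spread=8.0)
        # fusion expects box-satisfying input; stage 1 provides it
        staged, _ = reassign(clusters, peaks, tol)
        out, _ = fuse_clusters(staged, peaks, tol)
        assert peak_multiset(out) == peak_multiset(staged)
        check_box_invariant(out, peaks, tol)
        again, n_fused = fuse_clusters(out, peaks, tol)
        assert n_fused == 0
        assert peak_multiset(again) == peak_multiset(out)
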