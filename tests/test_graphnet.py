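"""Voxel graph construction, reduction, cleaning, smoothing, assembly."""

import numpy as np
import pytest

from nettrace3d import (Segment, VoxelSkeleton, assemble_network,
                        build_voxel_graph, clean_graph, reduce_graph,
                        smooth_paths)


def skeleton_from_voxels(voxels, shape=(40, 40, 120), radius=2.0):
    voxels = np.asarray(voxels, dtype=int)
    return VoxelSkeleton(voxels, np.full(len(voxels), radius), shape, 1.0,
                         "thinning")


def line_voxels(n, start=(5, 5, 5), step=(0, 0, 1)):
    s, d = np.array(start), np.array(step)
    return [tuple(s + i * d) for i in range(n)]


class TestVoxelGraph:
    def test_collinear_path(self):
        g = build_voxel_graph(skeleton_from_voxels(line_voxels(3)))
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2

    def test_diagonal_offset_is_adjacent(self):
        g = build_voxel_graph(skeleton_from_voxels([(5, 5, 5), (6, 6, 6)]))
        assert g.number_of_edges() == 1

    def test_gap_of_two_not_adjacent(self):
        g = build_voxel_graph(skeleton_from_voxels([(5, 5, 5), (5, 5, 7)]))
        assert g.number_of_edges() == 0

    def test_staircase_shortcut_edges_pruned(self):
        # corner a-b-c with the diagonal a-c: the shortcut must go
        voxels = [(5, 5, 5), (5, 5, 6), (5, 6, 6), (5, 6, 7)]
        g = build_voxel_graph(skeleton_from_voxels(voxels))
        assert g.number_of_edges() == 3
        assert all(g.degree(v) <= 2 for v in g)

    def test_empty_skeleton_rejected(self):
        with pytest.raises(ValueError):
            build_voxel_graph(skeleton_from_voxels(
                np.empty((0, 3), dtype=int)))


class TestReduce:
    def test_straight_path(self):
        g = build_voxel_graph(skeleton_from_voxels(line_voxels(50)))
        r = reduce_graph(g)
        assert r.number_of_nodes() == 2
        assert r.number_of_edges() == 1
        (_, _, d), = r.edges(data=True)
        assert len(d["path"]) == 50

    def test_y_shape(self):
        arms = (line_voxels(20, (20, 20, 20), (0, 0, 1))
                + line_voxels(20, (20, 20, 20), (0, 1, 0))[1:]
                + line_voxels(20, (20, 20, 20), (1, 0, 0))[1:])
        r = reduce_graph(build_voxel_graph(skeleton_from_voxels(arms)))
        assert r.number_of_nodes() == 4      # 3 ends + 1 branch point
        assert r.number_of_edges() == 3

    def test_pure_cycle_anchored_deterministically(self):
        ring = (line_voxels(6, (5, 5, 5), (0, 0, 1))
                + line_voxels(6, (5, 5, 10), (0, 1, 0))[1:]
                + line_voxels(6, (5, 10, 10), (0, 0, -1))[1:]
                + line_voxels(5, (5, 10, 5), (0, -1, 0))[1:])
        r = reduce_graph(build_voxel_graph(skeleton_from_voxels(ring)))
        assert r.number_of_nodes() == 1
        (u, v, d), = r.edges(data=True)
        assert u == v == (5, 5, 5)           # lexicographically smallest
        assert d["path"][0] == d["path"][-1] == (5, 5, 5)

    def test_voxel_coverage_preserved(self):
        arms = (line_voxels(15, (20, 20, 20), (0, 0, 1))
                + line_voxels(15, (20, 20, 20), (0, 1, 0))[1:])
        g = build_voxel_graph(skeleton_from_voxels(arms))
        r = reduce_graph(g)
        covered = set()
        for *_, d in r.edges(data=True):
            covered.update(d["path"])
        assert covered == set(g.nodes)


def _y_with_spur(spur_len):
    """50-voxel path with a short side spur in the middle."""
    main = line_voxels(50, (20, 20, 20), (0, 0, 1))
    spur = line_voxels(spur_len + 1, (20, 20, 44), (0, 1, 0))[1:]
    return build_voxel_graph(skeleton_from_voxels(main + spur))


class TestClean:
    def test_short_spur_removed_and_edges_fused(self):
        r = reduce_graph(_y_with_spur(4))
        assert r.number_of_edges() == 3
        c = clean_graph(r)
        assert c.number_of_edges() == 1
        (_, _, d), = c.edges(data=True)
        assert len(d["path"]) == 50
        assert all(c.degree(v) < 3 for v in c)

    def test_long_spur_kept(self):
        c = clean_graph(reduce_graph(_y_with_spur(10)))
        assert c.number_of_edges() == 3

    def test_isolated_short_component_removed(self):
        g = build_voxel_graph(skeleton_from_voxels(
            line_voxels(50) + line_voxels(3, (30, 30, 30))))
        c = clean_graph(reduce_graph(g))
        assert c.number_of_edges() == 1

    def test_fixpoint(self):
        c1 = clean_graph(reduce_graph(_y_with_spur(4)))
        c2 = clean_graph(c1)
        assert c1.number_of_edges() == c2.number_of_edges()
        paths1 = sorted(tuple(d["path"]) for *_, d in c1.edges(data=True))
        paths2 = sorted(tuple(d["path"]) for *_, d in c2.edges(data=True))
        assert paths1 == paths2

    def test_short_bridge_contracted_to_middle(self):
        # H-shape: two crosses connected by a 4-voxel bridge
        left = (line_voxels(10, (20, 10, 20), (0, 1, 0))
                + line_voxels(10, (20, 19, 11), (0, 0, 1)))
        bridge = line_voxels(4, (20, 19, 21), (0, 0, 1))
        right = (line_voxels(10, (20, 15, 25), (0, 1, 0))
                 + line_voxels(10, (20, 24, 25), (0, 0, 1)))
        g = build_voxel_graph(skeleton_from_voxels(left + bridge + right))
        r = reduce_graph(g)
        c = clean_graph(r)
        branch_nodes = [v for v in c if c.degree(v) >= 3]
        assert len(branch_nodes) == 1        # the two junctions merged


class TestSmooth:
    def test_resampling_rates(self):
        for n, expected in ((100, 10), (20, 5), (7, 5)):
            g = build_voxel_graph(skeleton_from_voxels(line_voxels(n)))
            segs = smooth_paths(clean_graph(reduce_graph(g)))
            assert len(segs) == 1
            assert segs[0].n_points == expected

    def test_staircase_shortened_but_not_below_chord(self):
        # 26-connected zig-zag between two fixed endpoints
        voxels = []
        y = 10
        for i in range(60):
            y = 10 + (i % 2)
            voxels.append((10, y, 10 + i))
        g = build_voxel_graph(skeleton_from_voxels(voxels))
        segs = smooth_paths(clean_graph(reduce_graph(g)))
        (seg,) = segs
        smoothed_len = np.linalg.norm(np.diff(seg.points, axis=0),
                                      axis=1).sum()
        raw = np.asarray(voxels, float)
        raw_len = np.linalg.norm(np.diff(raw, axis=0), axis=1).sum()
        chord = np.linalg.norm(raw[-1] - raw[0])
        assert smoothed_len < raw_len
        assert smoothed_len >= chord * 0.999

    def test_junction_endpoints_pinned_to_terminal_voxels(self):
        arms = (line_voxels(20, (20, 20, 20), (0, 0, 1))
                + line_voxels(20, (20, 20, 20), (0, 1, 0))[1:]
                + line_voxels(20, (20, 20, 20), (1, 0, 0))[1:])
        g = build_voxel_graph(skeleton_from_voxels(arms))
        segs = smooth_paths(clean_graph(reduce_graph(g)))
        hub = (np.array([20, 20, 20])[::-1] + 0.5) * 1.0   # x, y, z μm
        hub_hits = sum(
            np.allclose(seg.points[0], hub) or np.allclose(seg.points[-1],
                                                           hub)
            for seg in segs)
        assert hub_hits == 3

    def test_radii_converted_to_um(self):
        g = build_voxel_graph(skeleton_from_voxels(line_voxels(30),
                                                   radius=3.0))
        g.graph["voxel_size"] = 0.5
        segs = smooth_paths(clean_graph(reduce_graph(g)))
        assert np.all(segs[0].radii >= 1.4)   # ≈ 3 voxels × 0.5 μm

    def test_too_short_path_rejected(self):
        import networkx as nx
        r = nx.MultiGraph(voxel_size=1.0, radius_of={})
        r.add_edge((0, 0, 0), (0, 0, 0), path=[(0, 0, 0)])
        with pytest.raises(ValueError):
            smooth_paths(r)


class TestAssemble:
    def _seg(self, sid, a, b, k0, k1):
        pts = np.linspace(a, b, 5)
        return Segment(sid, pts, np.ones(5), end_keys=(k0, k1))

    def test_three_segments_one_hub(self):
        hub = np.array([0.0, 0.0, 0.0])
        segs = [self._seg(i, hub, np.array(tip), "hub", f"t{i}")
                for i, tip in enumerate([(10, 0, 0), (0, 10, 0),
                                         (0, 0, 10)])]
        net = assemble_network(segs)
        assert net.n_fibers == 1
        assert net.n_branch_points == 1
        np.testing.assert_allclose(net.branch_points[0], hub)

    def test_disjoint_segments_are_separate_fibers(self):
        s1 = self._seg(0, np.zeros(3), np.array([5.0, 0, 0]), "a", "b")
        s2 = self._seg(1, np.array([20.0, 0, 0]), np.array([25.0, 0, 0]),
                       "c", "d")
        net = assemble_network([s1, s2])
        assert net.n_fibers == 2
        assert net.n_branch_points == 0

    def test_empty_input(self):
        net = assemble_network([])
        assert net.n_fibers == 0
        assert net.n_segments == 0

    def test_duplicate_ids_rejected(self):
        s = self._seg(0, np.zeros(3), np.ones(3), "a", "b")
        with pytest.raises(ValueError):
            assemble_network([s, s])

    def test_segments_never_internally_branched(self):
        # interior points of each segment touch no other segment
        hub = np.array([0.0, 0.0, 0.0])
        segs = [self._seg(i, hub, np.array(tip), "hub", f"t{i}")
                for i, tip in enumerate([(10, 0, 0), (0, 10, 0)])]
        net = assemble_network(segs)
        for sid, seg in net.segments.items():
            interior = seg.points[1:-1]
            for other_id, other in net.segments.items():
                if other_id == sid:
                    continue
                d = np.linalg.norm(interior[:, None, :]
                                   - other.points[None, :, :], axis=2)
                assert d.min() > 1e-6
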