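"""Measures of the Network/Fiber/Segment hierarchy and orientation stats."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from nettrace3d import (Network, Segment, assemble_network, fiber_direction,
                        measure_element, network_summary, radius_histogram,
                        rasterized_volume, spherical_histogram)
from tests.conftest import straight_tube_network, y_network


def seg(points, radii, sid=0, k0="a", k1="b"):
    return Segment(sid, np.asarray(points, float), np.asarray(radii, float),
                   end_keys=(k0, k1))


def frustum_by_quadrature(p0, p1, r0, r1):
    """∫ π r(z)² dz along the axis, by adaptive numeric integration."""
    h = np.linalg.norm(np.asarray(p1) - np.asarray(p0))
    val, _ = integrate.quad(
        lambda t: math.pi * (r0 + t * (r1 - r0)) ** 2 * h, 0.0, 1.0,
        epsabs=1e-13, epsrel=1e-13)
    return val


class TestMeasureElement:
    def test_constant_radius_cylinder_exact(self):
        m = measure_element(seg([(0, 0, 0), (0, 0, 10)], [2, 2]))
        assert m["length"] == 10
        assert m["volume"] == pytest.approx(40 * math.pi, rel=1e-12)
        assert m["mean_radius"] == 2
        assert m["cylinder_radius"] == pytest.approx(2.0, rel=1e-12)

    def test_frustum_matches_numeric_integration(self):
        m = measure_element(seg([(0, 0, 0), (0, 0, 3)], [1, 2]))
        assert m["volume"] == pytest.approx(7 * math.pi, rel=1e-12)
        assert m["volume"] == pytest.approx(
            frustum_by_quadrature((0, 0, 0), (0, 0, 3), 1, 2), rel=1e-9)
        assert m["cylinder_radius"] == pytest.approx(math.sqrt(7 / 3),
                                                     rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.1, 5), st.floats(0.1, 5), st.floats(0.1, 50))
    def test_random_frusta_match_quadrature(self, r0, r1, h):
        m = measure_element(seg([(0, 0, 0), (h, 0, 0)], [r0, r1]))
        assert m["volume"] == pytest.approx(
            frustum_by_quadrature((0, 0, 0), (h, 0, 0), r0, r1), rel=1e-9)

    def test_coincident_points(self):
        m = measure_element(seg([(1, 1, 1), (1, 1, 1)], [2, 2]))
        assert m["length"] == 0
        assert m["volume"] == 0
        assert math.isnan(m["cylinder_radius"])

    def test_fiber_and_network_are_sums(self):
        net = y_network()
        per_seg = [measure_element(s) for s in net.segments.values()]
        fiber = measure_element(net.fibers[0], net)
        whole = measure_element(net)
        for m in (fiber, whole):
            assert m["length"] == pytest.approx(
                sum(p["length"] for p in per_seg))
            assert m["volume"] == pytest.approx(
                sum(p["volume"] for p in per_seg))


class TestNetworkSummary:
    def test_y_counts(self):
        s = network_summary(y_network())
        assert s["number_of_fibers"] == 1
        assert s["number_of_segments"] == 3
        assert s["number_of_branch_points"] == 1

    def test_totals_conserved(self):
        net = y_network()
        s = network_summary(net)
        assert s["total_length"] == pytest.approx(
            sum(measure_element(x)["length"] for x in
                net.segments.values()))

    def test_additive_over_disjoint_union(self):
        a = straight_tube_network(axis="x")
        b = straight_tube_network(axis="y")
        merged = Network()
        next_id = 0
        for src in (a, b):
            for s in src.segments.values():
                merged.segments[next_id] = Segment(
                    next_id, s.points + next_id * 100, s.radii,
                    end_keys=(f"{next_id}a", f"{next_id}b"))
                next_id += 1
        sa, sb, sm = (network_summary(x) for x in (a, b, merged))
        assert sm["total_length"] == pytest.approx(
            sa["total_length"] + sb["total_length"])
        assert sm["total_volume"] == pytest.approx(
            sa["total_volume"] + sb["total_volume"])

    def test_bounding_box(self):
        s = network_summary(straight_tube_network(length=30.0, axis="z"))
        assert s["bounding_box_volume"] == pytest.approx(0.0)


class TestDirections:
    def test_straight_up(self):
        net = straight_tube_network(axis="z")
        d = fiber_direction(net.fibers[0], net)
        assert d.altitude == pytest.approx(90.0)

    def test_downward_flipped_up(self):
        s = seg([(0, 0, 5), (0, 0, 0)], [1, 1])
        net = assemble_network([s])
        d = fiber_direction(net.fibers[0], net)
        assert d.altitude == pytest.approx(90.0)

    def test_x_axis_convention(self):
        s = seg([(0, 0, 0), (5, 0, 0)], [1, 1])
        net = assemble_network([s])
        d = fiber_direction(net.fibers[0], net)
        assert d.altitude == pytest.approx(0.0)
        assert d.azimuth == pytest.approx(0.0)

    def test_zero_net_vector_flagged(self):
        s1 = seg([(0, 0, 0), (5, 0, 0)], [1, 1], sid=0, k0="a", k1="b")
        s2 = seg([(5, 0, 0), (0, 0, 0)], [1, 1], sid=1, k0="b", k1="c")
        net = assemble_network([s1, s2])
        d = fiber_direction(net.fibers[0], net)
        assert not d.defined


class TestSphericalHistogram:
    def _net_with_directions(self, vectors):
        segs = []
        for i, v in enumerate(vectors):
            segs.append(seg([(0, 0, 0), tuple(v)], [1, 1], sid=i,
                            k0=f"a{i}", k1=f"b{i}"))
        return assemble_network(segs)

    def test_all_vertical_in_top_cap(self):
        net = self._net_with_directions([(0, 0, 5)] * 7)
        h = spherical_histogram(net)
        top = h.counts[:, -1]
        assert h.counts.sum() == 7
        assert top.sum() == 7

    def test_area_sums_to_half_sphere(self):
        h = spherical_histogram(self._net_with_directions([(1, 0, 0)]))
        assert h.area.sum() == pytest.approx(2 * math.pi, rel=1e-12)

    def test_density_times_area_conserves_count(self):
        rng = np.random.default_rng(8)
        vecs = rng.normal(size=(40, 3))
        net = self._net_with_directions(vecs)
        h = spherical_histogram(net)
        assert (h.density * h.area).sum() == pytest.approx(h.n_vectors)

    def test_uniform_directions_give_unit_scaled_density(self):
        # area-correct sampler: azimuth uniform, sin(altitude) uniform
        rng = np.random.default_rng(12345)
        n = 10_000
        az = rng.uniform(0, 2 * math.pi, n)
        sin_alt = rng.uniform(0, 1, n)
        cos_alt = np.sqrt(1 - sin_alt ** 2)
        vecs = np.column_stack([cos_alt * np.cos(az), cos_alt * np.sin(az),
                                sin_alt])
        net = self._net_with_directions(vecs * 5)
        h = spherical_histogram(net)
        assert h.n_vectors == n
        # bins with enough expected mass sit near unit scaled density; the
        # near-polar bins hold only a handful of expected counts each, so
        # their Poisson scatter is intrinsically far wider
        expected = h.area * n / (2 * math.pi)
        sigma = np.sqrt(expected)
        assert np.all(np.abs(h.counts - expected) <= 4 * sigma + 1)
        # weighted mean of the scaled density is exactly 1
        assert (h.scaled_density * h.area).sum() / h.area.sum() == \
            pytest.approx(1.0)


class TestRadiusHistogram:
    def test_single_fiber_single_bin(self):
        counts, edges = radius_histogram(straight_tube_network(radius=2.0),
                                         bin_width=0.5)
        assert counts.sum() == 1
        occupied = np.nonzero(counts)[0]
        assert edges[occupied[0]] <= 2.0 <= edges[occupied[0] + 1]

    def test_two_distant_radii_two_bins(self):
        a = straight_tube_network(radius=1.0, axis="x")
        s2 = seg([(0, 50, 0), (30, 50, 0)], [9, 9], sid=10, k0="p", k1="q")
        merged = assemble_network(
            [list(a.segments.values())[0], s2])
        counts, _ = radius_histogram(merged, bin_width=1.0)
        assert (counts > 0).sum() == 2

    def test_counts_conserved_across_bin_widths(self):
        net = y_network()
        for w in (0.25, 0.5, 2.0):
            counts, _ = radius_histogram(net, bin_width=w)
            assert counts.sum() == net.n_fibers


class TestRasterizedVolume:
    def test_cylinder_within_5_percent(self):
        net = straight_tube_network(radius=3.0, length=30.0)
        vol = rasterized_volume(net, voxel_edge=0.5)
        assert vol == pytest.approx(math.pi * 9 * 30, rel=0.05)

    def test_empty_network_zero(self):
        assert rasterized_volume(Network(), 0.5) == 0.0

    def test_junction_overlap_not_double_counted(self):
        net = y_network()
        cone_sum = network_summary(net)["total_volume"]
        vol = rasterized_volume(net, voxel_edge=0.2)
        assert vol <= cone_sum * 1.02
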