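"""Ground-truth generator, rasterizer and degradation model."""

import math

import numpy as np
import pytest

from nettrace3d import (PipelineConfig, SyntheticSpec, Degradation, degrade,
                        fit_attenuation, generate_network, network_summary,
                        rasterize, run_pipeline)


class TestGenerator:
    def test_fiber_count_and_determinism(self):
        spec = SyntheticSpec(n_fibers=4, seed=11)
        net1 = generate_network(spec)
        net2 = generate_network(SyntheticSpec(n_fibers=4, seed=11))
        assert net1.n_fibers == 4
        for sid in net1.segments:
            np.testing.assert_array_equal(net1.segments[sid].points,
                                          net2.segments[sid].points)
            np.testing.assert_array_equal(net1.segments[sid].radii,
                                          net2.segments[sid].radii)

    def test_different_seeds_differ(self):
        a = generate_network(SyntheticSpec(seed=1))
        b = generate_network(SyntheticSpec(seed=2))
        assert not np.array_equal(a.all_points(), b.all_points())

    def test_radii_within_spec_range(self):
        spec = SyntheticSpec(seed=3, radius_range=(0.7, 1.2))
        net = generate_network(spec)
        radii = net.all_radii()
        assert radii.min() >= 0.7 - 1e-9
        assert radii.max() <= 1.2 + 1e-9

    def test_points_stay_inside_extent(self):
        spec = SyntheticSpec(seed=5)
        pts = generate_network(spec).all_points()
        assert np.all(pts >= 0)
        assert np.all(pts <= np.array(spec.extent))

    def test_branching_produces_branch_points(self):
        spec = SyntheticSpec(seed=3, branch_probability=1.0)
        net = generate_network(spec)
        assert net.n_branch_points == spec.n_fibers
        assert net.n_fibers == spec.n_fibers

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(extent=(0, 50, 50))
        with pytest.raises(ValueError):
            SyntheticSpec(radius_range=(1.5, 0.5))
        with pytest.raises(ValueError):
            SyntheticSpec(n_fibers=0)


class TestRasterize:
    def test_cylinder_volume_analytic(self):
        from tests.conftest import straight_tube_network
        net = straight_tube_network(radius=3.0, length=30.0)
        stack = rasterize(net, voxel_edge=0.5)
        volume = (stack.data > 0).sum() * 0.5 ** 3
        assert volume == pytest.approx(math.pi * 9 * 30, rel=0.05)

    def test_padding_shell_is_background(self):
        net = generate_network(SyntheticSpec(seed=2))
        stack = rasterize(net, voxel_edge=0.5, pad=3)
        data = stack.data
        assert not data[0].any() and not data[-1].any()
        assert not data[:, 0].any() and not data[:, -1].any()
        assert not data[:, :, 0].any() and not data[:, :, -1].any()

    def test_coarse_voxel_warns(self):
        from tests.conftest import straight_tube_network
        net = straight_tube_network(radius=0.4)
        with pytest.warns(UserWarning, match="coarse"):
            rasterize(net, voxel_edge=0.3)

    def test_binary_values_only(self):
        net = generate_network(SyntheticSpec(seed=1))
        stack = rasterize(net, voxel_edge=0.5)
        assert set(np.unique(stack.data)) <= {0, 255}


class TestDegrade:
    def test_zero_degradation_identity(self):
        spec = SyntheticSpec(seed=4, degradation=Degradation(0.0, 0.0, 0))
        net = generate_network(spec)
        stack = rasterize(net, voxel_edge=0.5)
        out = degrade(stack, spec)
        np.testing.assert_allclose(out.data, stack.data.astype(np.float32))

    def test_attenuation_recoverable_by_fit(self):
        # constant-content stack isolates the attenuation model itself
        from nettrace3d import ImageStack
        spec = SyntheticSpec(seed=4, degradation=Degradation(0.0, -0.02, 0))
        stack = ImageStack(np.full((40, 8, 8), 200.0), (0.5, 0.5, 0.5))
        out = degrade(stack, spec)
        fit = fit_attenuation(out)
        assert fit.b == pytest.approx(-0.02, rel=1e-6)
        assert fit.a == pytest.approx(200.0, rel=1e-6)

    def test_seeded_reproducibility(self):
        spec = SyntheticSpec(seed=9)
        net = generate_network(spec)
        stack = rasterize(net, voxel_edge=0.5)
        a, b = degrade(stack, spec), degrade(stack, spec)
        np.testing.assert_array_equal(a.data, b.data)


class TestEndToEnd:
    """Render → degrade → condition → segment → reconstruct → measure."""

    def test_degraded_recovery(self):
        # z-drop correction undoes the attenuation and island removal kills
        # the speckles; surface-modifying filters (median, blur) are left
        # off because they bias the radius of thin digitized tubes
        spec = SyntheticSpec(seed=5)
        net = generate_network(spec)
        truth = network_summary(net)
        stack = degrade(rasterize(net, voxel_edge=spec.voxel_edge), spec)
        cfg = PipelineConfig(zdrop_enabled=True,
                             close_iterations=1, min_island_um3=100.0)
        _, s = run_pipeline(cfg, stack=stack, export=False)
        assert s["number_of_fibers"] == truth["number_of_fibers"]
        assert s["total_length"] == pytest.approx(truth["total_length"],
                                                  rel=0.02)
        assert s["total_volume"] == pytest.approx(truth["total_volume"],
                                                  rel=0.01)

    def test_blurred_pipeline_keeps_topology_and_length(self):
        # Gaussian blur + histogram thresholding dilates thin tubes, so the
        # volume is biased high; the topology and centerline length survive
        spec = SyntheticSpec(seed=6)
        net = generate_network(spec)
        truth = network_summary(net)
        stack = degrade(rasterize(net, voxel_edge=spec.voxel_edge), spec)
        cfg = PipelineConfig(median_enabled=True, zdrop_enabled=True,
                             gaussian_enabled=True, close_iterations=1,
                             min_island_um3=100.0)
        _, s = run_pipeline(cfg, stack=stack, export=False)
        assert s["number_of_fibers"] == truth["number_of_fibers"]
        assert s["total_length"] == pytest.approx(truth["total_length"],
                                                  rel=0.02)

    def test_branch_point_displacement_bounded(self):
        spec = SyntheticSpec(seed=3, branch_probability=1.0)
        net = generate_network(spec)
        stack = rasterize(net, voxel_edge=spec.voxel_edge)
        origin = np.array(stack.origin)
        rec, s = run_pipeline(PipelineConfig(), stack=stack, export=False)
        assert rec.n_branch_points >= net.n_branch_points
        max_r = net.all_radii().max()
        for bp in net.branch_points:
            d = np.linalg.norm(rec.branch_points + origin - bp, axis=1)
            assert d.min() <= max_r + 1e-9
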