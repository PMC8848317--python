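"""Shared fixtures: small ground-truth networks and rasterized masks."""

from __future__ import annotations

import numpy as np
import pytest

from nettrace3d import BinaryStack, Segment, assemble_network, rasterize


def straight_tube_network(radius: float = 1.0, length: float = 30.0,
                          axis: str = "z", n_points: int = 60):
    """Single straight constant-radius segment along the given axis."""
    t = np.linspace(0.0, length, n_points)
    base = np.full(n_points, 8.0)
    cols = {"x": (t + 4.0, base, base),
            "y": (base, t + 4.0, base),
            "z": (base, base, t + 4.0)}[axis]
    pts = np.column_stack(cols)
    seg = Segment(0, pts, np.full(n_points, radius), end_keys=("a", "b"))
    return assemble_network([seg])


def y_network(arm: float = 14.0, radius: float = 1.0, n_points: int = 40):
    """Three straight segments meeting at a single branch point."""
    center = np.array([20.0, 20.0, 8.0])
    dirs = [np.array([1.0, 0.0, 0.0]),
            np.array([-0.5, np.sqrt(3) / 2, 0.0]),
            np.array([-0.5, -np.sqrt(3) / 2, 0.0])]
    segments = []
    for i, d in enumerate(dirs):
        t = np.linspace(0.0, arm, n_points)
        pts = center[None, :] + np.outer(t, d)
        segments.append(Segment(i, pts, np.full(n_points, radius),
                                end_keys=("hub", f"tip{i}")))
    return assemble_network(segments)


@pytest.fixture(scope="session")
def cylinder_mask():
    """Rasterized straight cylinder (r = 1 μm, L = 30 μm, 0.25 μm voxels)."""
    net = straight_tube_network()
    stack = rasterize(net, voxel_edge=0.25)
    return BinaryStack(stack.data > 0, stack.voxel_size), net, stack


@pytest.fixture(scope="session")
def y_mask():
    net = y_network()
    stack = rasterize(net, voxel_edge=0.25)
    return BinaryStack(stack.data > 0, stack.voxel_size), net, stack
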