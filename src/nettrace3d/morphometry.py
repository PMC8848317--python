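"""Network data model and morphometric measures.

A reconstructed network is a three-level hierarchy: the :class:`Network` is a
collection of :class:`Fiber` objects, each fiber a connected set of
:class:`Segment` objects, and each segment an ordered run of points with radii.
Segments end at branch points or free ends and are never internally branched; a
branch point belongs to every segment it connects.

Volumes treat the span between consecutive points as a truncated cone
(frustum), so an element of length L and volume V has a *cylinder radius*
``sqrt(V / (pi * L))`` — the radius of the cylinder with the same volume and
length.  This length-robust measure is the headline radius; the unweighted
point-mean radius is also reported but can be skewed by non-uniform point
spacing.

Orientation statistics live on a half-sphere: fibers have no intrinsic
direction in an image stack, so every direction vector is flipped to
non-negative z before azimuth/altitude are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Point",
    "Segment",
    "Fiber",
    "Network",
    "DirectionVector",
    "SphericalHistogram",
    "measure_element",
    "network_summary",
    "fiber_direction",
    "spherical_histogram",
    "radius_histogram",
    "rasterized_volume",
]


# ---------------------------------------------------------------------------
# hierarchy types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Point:
    """A single sample: position in micrometres plus local radius."""

    x: float
    y: float
    z: float
    radius: float


@dataclass
class Segment:
    """Unbranched ordered chain of points with per-point radii (μm).

    ``end_keys`` are opaque hashables identifying the two endpoints; segments
    sharing an end key are connected there.  ``kind`` distinguishes ordinary
    fiber segments from an SWC soma.
    """

    id: int
    points: np.ndarray          # (n, 3) float, columns x, y, z in μm
    radii: np.ndarray           # (n,) float, μm
    end_keys: tuple = (None, None)
    kind: str = "fiber"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("segment points must be an (n, 3) array")
        if self.radii.shape[0] != self.points.shape[0]:
            raise ValueError("radii length must match number of points")
        if np.any(self.radii < 0):
            raise ValueError("radii must be non-negative")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class Fiber:
    """Connected component of segments."""

    id: int
    segment_ids: list[int] = field(default_factory=list)


@dataclass
class Network:
    """The full reconstructed structure plus its provenance metadata."""

    segments: dict[int, Segment] = field(default_factory=dict)
    fibers: dict[int, Fiber] = field(default_factory=dict)
    branch_points: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=float)
    )
    metadata: dict = field(default_factory=dict)

    @property
    def n_fibers(self) -> int:
        return len(self.fibers)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_branch_points(self) -> int:
        return int(self.branch_points.shape[0])

    def fiber_segments(self, fiber_id: int) -> list[Segment]:
        return [self.segments[sid] for sid in self.fibers[fiber_id].segment_ids]

    def all_points(self) -> np.ndarray:
        if not self.segments:
            return np.empty((0, 3), dtype=float)
        return np.concatenate([s.points for s in self.segments.values()])

    def all_radii(self) -> np.ndarray:
        if not self.segments:
            return np.empty((0,), dtype=float)
        return np.concatenate([s.radii for s in self.segments.values()])


@dataclass(frozen=True)
class DirectionVector:
    """Fiber direction on the upper half-sphere.

    azimuth: degrees in [0, 360), 0° along +x, counterclockwise in the
    x/y-plane; altitude: degrees in [0, 90] above the x/y-plane.
    """

    azimuth: float
    altitude: float
    defined: bool = True


@dataclass
class SphericalHistogram:
    """Counts of fiber directions over a regular azimuth × altitude grid.

    ``area`` is the solid angle of each bin in steradians; ``density`` is
    count/area and ``scaled_density`` is density relative to the mean density
    over the half-sphere, so an isotropic network scores 1 everywhere.
    """

    azimuth_edges: np.ndarray    # (n_az + 1,) degrees
    altitude_edges: np.ndarray   # (n_alt + 1,) degrees
    counts: np.ndarray           # (n_az, n_alt)
    area: np.ndarray             # (n_az, n_alt) steradians
    density: np.ndarray
    scaled_density: np.ndarray
    n_vectors: int


# ---------------------------------------------------------------------------
# element measures
# ---------------------------------------------------------------------------

def _segment_length(seg: Segment) -> float:
    if seg.n_points < 2:
        return 0.0
    diffs = np.diff(seg.points, axis=0)
    return float(np.sum(np.sqrt(np.sum(diffs * diffs, axis=1))))


def _segment_volume(seg: Segment) -> float:
    """Sum of frustum volumes π·h·(r0² + r0·r1 + r1²)/3 over point pairs."""
    if seg.n_points < 2:
        return 0.0
    diffs = np.diff(seg.points, axis=0)
    h = np.sqrt(np.sum(diffs * diffs, axis=1))
    r0 = seg.radii[:-1]
    r1 = seg.radii[1:]
    return float(np.sum(math.pi * h * (r0 * r0 + r0 * r1 + r1 * r1) / 3.0))


def measure_element(element: Segment | Fiber | Network,
                    network: Network | None = None) -> dict[str, float]:
    """Length, volume, mean radius and cylinder radius of an element.

    For a :class:`Fiber` the owning ``network`` must be supplied so its
    segments can be resolved.  Length and volume are sums over the constituent
    segments; ``mean_radius`` pools all points; ``cylinder_radius`` is
    ``sqrt(volume / (pi * length))`` and is NaN for zero-length elements.
    """
    if isinstance(element, Segment):
        segments: list[Segment] = [element]
    elif isinstance(element, Fiber):
        if network is None:
            raise ValueError("measuring a Fiber requires the owning Network")
        segments = [network.segments[sid] for sid in element.segment_ids]
    elif isinstance(element, Network):
        segments = list(element.segments.values())
    else:
        raise TypeError(f"cannot measure {type(element).__name__}")

    length = sum(_segment_length(s) for s in segments)
    volume = sum(_segment_volume(s) for s in segments)
    radii = (np.concatenate([s.radii for s in segments])
             if segments else np.empty(0))
    mean_radius = float(np.mean(radii)) if radii.size else float("nan")
    if length > 0:
        cylinder_radius = math.sqrt(volume / (math.pi * length))
    else:
        cylinder_radius = float("nan")
    return {
        "length": length,
        "volume": volume,
        "mean_radius": mean_radius,
        "cylinder_radius": cylinder_radius,
    }


def network_summary(network: Network) -> dict:
    """Network-level record: counts, totals, bounding box and metadata.

    Total length excludes soma segments (SWC structure type 1); total volume
    includes them, since the soma occupies real volume but is not fiber
    length.  The bounding-box volume is axis-aligned over all points.
    """
    fiber_segments = [s for s in network.segments.values() if s.kind != "soma"]
    soma_segments = [s for s in network.segments.values() if s.kind == "soma"]

    total_length = sum(_segment_length(s) for s in fiber_segments)
    total_volume = sum(_segment_volume(s) for s in network.segments.values())
    radii = network.all_radii()
    mean_radius = float(np.mean(radii)) if radii.size else float("nan")
    if total_length > 0:
        cylinder_radius = math.sqrt(total_volume / (math.pi * total_length))
    else:
        cylinder_radius = float("nan")

    pts = network.all_points()
    if pts.size:
        extent = pts.max(axis=0) - pts.min(axis=0)
        bbox_volume = float(np.prod(extent))
    else:
        bbox_volume = 0.0

    return {
        "number_of_fibers": network.n_fibers,
        "number_of_segments": network.n_segments,
        "number_of_branch_points": network.n_branch_points,
        "total_length": float(total_length),
        "total_volume": float(total_volume),
        "mean_radius": mean_radius,
        "cylinder_radius": cylinder_radius,
        "bounding_box_volume": bbox_volume,
        "has_soma": bool(soma_segments),
        "metadata": dict(network.metadata),
    }


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def _direction_from_vector(v: np.ndarray) -> DirectionVector:
    norm = float(np.linalg.norm(v))
    if norm == 0.0 or not np.isfinite(norm):
        return DirectionVector(float("nan"), float("nan"), defined=False)
    if v[2] < 0:
        v = -v
    azimuth = math.degrees(math.atan2(v[1], v[0])) % 360.0
    altitude = math.degrees(math.atan2(v[2], math.hypot(v[0], v[1])))
    return DirectionVector(azimuth, altitude)


def fiber_direction(element: Fiber | Segment,
                    network: Network | None = None) -> DirectionVector:
    """Dominant direction of a fiber (or single segment) on the half-sphere.

    Each segment contributes its end-to-end displacement, flipped to
    non-negative z (start and end of a fiber are interchangeable in a stack);
    the displacements are summed and the sum flipped likewise.  The sum is
    length-weighted by construction: long straight segments dominate.
    """
    if isinstance(element, Segment):
        segments: list[Segment] = [element]
    else:
        if network is None:
            raise ValueError("fiber_direction on a Fiber requires the Network")
        segments = [network.segments[sid] for sid in element.segment_ids]
    total = np.zeros(3)
    for seg in segments:
        if seg.n_points < 2:
            continue
        disp = seg.points[-1] - seg.points[0]
        if disp[2] < 0:
            disp = -disp
        total += disp
    return _direction_from_vector(total)


def spherical_histogram(network: Network, n_azimuth: int = 18,
                        n_altitude: int = 9) -> SphericalHistogram:
    """Bin fiber directions on a regular azimuth × altitude half-sphere grid.

    Bin solid angle is Δazimuth·(sin(alt_hi) − sin(alt_lo)) sr, so areas sum
    to 2π and Σ(density·area) equals the number of binned vectors exactly.
    """
    directions = [
        fiber_direction(f, network) for f in network.fibers.values()
    ]
    directions = [d for d in directions if d.defined]

    az_edges = np.linspace(0.0, 360.0, n_azimuth + 1)
    alt_edges = np.linspace(0.0, 90.0, n_altitude + 1)
    d_az = math.radians(360.0 / n_azimuth)
    sin_alt = np.sin(np.radians(alt_edges))
    area = np.tile(d_az * np.diff(sin_alt), (n_azimuth, 1))

    counts = np.zeros((n_azimuth, n_altitude))
    for d in directions:
        i = min(int(d.azimuth / 360.0 * n_azimuth), n_azimuth - 1)
        j = min(int(d.altitude / 90.0 * n_altitude), n_altitude - 1)
        counts[i, j] += 1

    density = np.where(area > 0, counts / area, 0.0)
    n = len(directions)
    mean_density = n / (2.0 * math.pi)
    scaled = density / mean_density if n else np.zeros_like(density)
    return SphericalHistogram(az_edges, alt_edges, counts, area, density,
                              scaled, n)


def radius_histogram(network: Network,
                     bin_width: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-fiber cylinder radii; returns (counts, bin_edges)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    radii = []
    for fiber in network.fibers.values():
        r = measure_element(fiber, network)["cylinder_radius"]
        if np.isfinite(r):
            radii.append(r)
    if not radii:
        return np.zeros(0, dtype=int), np.zeros(1)
    lo = math.floor(min(radii) / bin_width) * bin_width
    hi = math.floor(max(radii) / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(radii, bins=edges)
    return counts, edges


def rasterized_volume(network: Network, voxel_edge: float) -> float:
    """Volume estimate from the rasterized network, in μm³.

    Renders the network on a grid of the given edge and counts foreground
    voxels, which removes the double counting of overlapping frusta at
    junctions that the summed truncated-cone volume suffers from.
    """
    from .synthetic import rasterize  # late import: synthetic builds Networks

    if not network.segments:
        return 0.0
    stack = rasterize(network, voxel_edge=voxel_edge)
    return float(np.count_nonzero(stack.data)) * voxel_edge ** 3
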