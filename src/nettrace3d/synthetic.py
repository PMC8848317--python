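"""Ground-truth network synthesis and rendering.

The generator produces smooth, branched tubular networks with exactly known
geometry (so length, volume and radii can be measured on the truth and
compared after reconstruction), and the rasterizer renders any network as a
layered 3D image: a voxel is foreground iff its center lies inside a
truncated cone spanned by a consecutive point pair of some segment.  A
degradation step emulates the main artifacts of optical slice microscopy —
exponential depth attenuation, additive Gaussian noise and single-voxel
speckles — so the pre-processing and segmentation stages can be exercised
without real data.

Fibers are laid out as serpentine curves in well-separated z-slabs, giving
long convoluted fibers (several times the stack extent) with guaranteed
clearance between them; optional side branches attach at an interior point
of a fiber, splitting it into segments joined at a ground-truth branch
point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate

from .io_formats import ImageStack
from .morphometry import Network, Segment
from .graphnet import assemble_network

__all__ = ["Degradation", "SyntheticSpec", "generate_network", "rasterize",
           "degrade"]


@dataclass
class Degradation:
    """Image degradation parameters for :func:`degrade`.

    noise_sigma is the Gaussian noise level as a fraction of the peak
    intensity; attenuation_b the exponential depth-decay rate per μm
    (negative dims deeper slices); speckle_count the number of random
    single-voxel bright speckles.
    """

    noise_sigma: float = 0.03
    attenuation_b: float = -0.01
    speckle_count: int = 150


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic ground-truth network.

    The defaults describe the reference fixture used throughout the test
    suite: 4 fibers with radii 0.7–1.2 μm winding through a 50³ μm volume,
    rendered at a 0.25 μm voxel edge.
    """

    n_fibers: int = 4
    points_per_fiber: int = 260
    extent: tuple[float, float, float] = (50.0, 50.0, 50.0)
    radius_range: tuple[float, float] = (0.7, 1.2)
    branch_probability: float = 0.5
    seed: int = 0
    voxel_edge: float = 0.25
    degradation: Degradation = field(default_factory=Degradation)

    def __post_init__(self) -> None:
        if min(self.extent) <= 0:
            raise ValueError("extents must be positive")
        if not (0 < self.radius_range[0] <= self.radius_range[1]):
            raise ValueError("radius range must be positive and ordered")
        if self.n_fibers < 1:
            raise ValueError("need at least one fiber")


def _smooth_radii(rng: np.random.Generator, n: int,
                  radius_range: tuple[float, float]) -> np.ndarray:
    """Slowly varying radii inside the requested range."""
    lo, hi = radius_range
    mid, amp = (lo + hi) / 2.0, (hi - lo) / 2.0
    phase = rng.uniform(0, 2 * math.pi)
    cycles = rng.uniform(1.0, 2.5)
    t = np.linspace(0, 1, n)
    return mid + amp * np.sin(2 * math.pi * cycles * t + phase)


def _resample_polyline(control: np.ndarray, n_out: int) -> np.ndarray:
    """Interpolating cubic spline through control points, n_out samples."""
    steps = np.linalg.norm(np.diff(control, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(steps)])
    u /= u[-1]
    tck, _ = interpolate.splprep(control.T, u=u, s=0,
                                 k=min(3, len(control) - 1))
    out = interpolate.splev(np.linspace(0, 1, n_out), tck)
    return np.array(out).T


def _serpentine_path(rng: np.random.Generator, ex: float, ey: float,
                     margin: float, turn_radius: float, z_center: float,
                     z_amp: float, n_points: int) -> np.ndarray:
    """Smooth serpentine curve: straight passes joined by semicircular turns.

    The turn radius bounds the curvature everywhere, so the rendered tube
    never overlaps itself; adjacent passes sit 2·turn_radius apart, keeping
    the clearance between them well above the fiber diameter.  z undulates
    gently around the slab center.  Densely sampled, then resampled to
    ``n_points`` uniformly in arc length.
    """
    rho = turn_radius
    y0, y1 = margin, ey - margin
    n_passes = max(2, int((y1 - y0) / (2 * rho)) + 1)
    # inset the pass endpoints so the turn arcs stay inside the extent
    xa = margin + rho + rng.uniform(0, 2.0)
    xb = ex - margin - rho - rng.uniform(0, 2.0)

    pieces: list[np.ndarray] = []
    ds = 0.25
    y = y0
    for p in range(n_passes):
        forward = p % 2 == 0
        x_from, x_to = (xa, xb) if forward else (xb, xa)
        n_s = max(2, int(abs(x_to - x_from) / ds))
        xs = np.linspace(x_from, x_to, n_s)
        pieces.append(np.column_stack([xs, np.full(n_s, y)]))
        if p == n_passes - 1:
            break
        # semicircular turn from (x_to, y) to (x_to, y + 2·rho)
        cx, cy = x_to, y + rho
        n_a = max(4, int(math.pi * rho / ds))
        theta = np.linspace(-math.pi / 2, math.pi / 2, n_a)
        sign = 1.0 if forward else -1.0
        arc_x = cx + sign * rho * np.cos(theta)
        arc_y = cy + rho * np.sin(theta)
        pieces.append(np.column_stack([arc_x[1:], arc_y[1:]]))
        y += 2 * rho
    xy = np.concatenate(pieces)

    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(steps)])
    s_new = np.linspace(0.0, arclen[-1], n_points)
    x = np.interp(s_new, arclen, xy[:, 0])
    y = np.interp(s_new, arclen, xy[:, 1])
    z = (z_center + z_amp
         * np.sin(2 * math.pi * rng.uniform(1.5, 2.5) * s_new / arclen[-1]
                  + rng.uniform(0, 2 * math.pi)))
    return np.column_stack([x, y, z])


def generate_network(spec: SyntheticSpec) -> Network:
    """Build a seeded random network of smooth serpentine fibers.

    Each fiber winds through its own z-slab (guaranteeing clearance of
    several fiber radii between fibers); with probability
    ``branch_probability`` a fiber gets a side branch attached at an
    interior point, which splits the fiber into three segments meeting at a
    known branch point.  All randomness derives from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    ex, ey, ez = spec.extent
    margin = max(2.0 * spec.radius_range[1], 0.04 * min(ex, ey))
    slab = ez / spec.n_fibers

    segments: list[Segment] = []
    seg_id = 0
    key_id = 0

    def new_key():
        nonlocal key_id
        key_id += 1
        return ("k", key_id)

    turn_radius = max(6.0, 5.0 * spec.radius_range[1])

    for f in range(spec.n_fibers):
        z_center = slab * (f + 0.5)
        z_amp = min(1.5, slab / 6.0)
        n = spec.points_per_fiber
        pts = _serpentine_path(rng, ex, ey, margin, turn_radius, z_center,
                               z_amp, n)
        radii = _smooth_radii(rng, n, spec.radius_range)

        if rng.uniform() < spec.branch_probability:
            # split the fiber at an interior anchor and hang a branch on it:
            # the branch rises out of the parent's plane, then runs parallel
            # to the local sweep direction with ~3.5 μm of z clearance
            i = int(rng.integers(n // 3, 2 * n // 3))
            k_start, k_anchor, k_end = new_key(), new_key(), new_key()
            segments.append(Segment(seg_id, pts[:i + 1], radii[:i + 1],
                                    end_keys=(k_start, k_anchor)))
            seg_id += 1
            segments.append(Segment(seg_id, pts[i:], radii[i:],
                                    end_keys=(k_anchor, k_end)))
            seg_id += 1

            anchor = pts[i]
            tangent = pts[min(i + 5, n - 1)] - pts[max(i - 5, 0)]
            tangent[2] = 0.0
            tnorm = np.linalg.norm(tangent)
            tangent = tangent / tnorm if tnorm > 1e-9 \
                else np.array([1.0, 0.0, 0.0])
            # lift to a fixed level clear of the parent's whole z band
            z_target = z_center + z_amp + 3.5
            rise = z_target - anchor[2]
            run = rng.uniform(10.0, 14.0)
            n_branch = 24
            bt = np.linspace(0.0, 1.0, n_branch)
            lift = rise * np.sin(np.clip(bt * 1.6, 0, 1) * math.pi / 2)
            along = run * bt ** 1.2 * rng.choice([-1.0, 1.0])
            bpts = (anchor[None, :] + np.outer(along, tangent))
            bpts[:, 2] += lift
            bpts = np.clip(bpts, 1.0, np.array([ex, ey, ez]) - 1.0)
            bpts[0] = anchor
            b_radii = np.linspace(radii[i], spec.radius_range[0], n_branch)
            segments.append(Segment(seg_id, bpts, b_radii,
                                    end_keys=(k_anchor, new_key())))
            seg_id += 1
        else:
            segments.append(Segment(seg_id, pts, radii,
                                    end_keys=(new_key(), new_key())))
            seg_id += 1

    return assemble_network(
        segments, voxel_size=spec.voxel_edge,
        metadata={"source": "synthetic", "seed": spec.seed})


def rasterize(network: Network, voxel_edge: float,
              pad: int = 3) -> ImageStack:
    """Render the network as a binary-valued image stack (0/255).

    A voxel is foreground iff its center lies inside the truncated cone of
    some consecutive point pair or inside a joint sphere.  Spheres are
    placed at bending interior polyline points and at shared (junction)
    endpoints to fill the wedge gap between consecutive frusta; collinear
    joints need none, and free fiber ends stay flat, so a straight
    constant-radius segment rasterizes to exactly a cylinder.  The stack is
    padded by ``pad`` voxels of background on every face; the physical
    position of voxel (0,0,0)'s center relative to the network frame is
    recorded on the returned stack as ``origin`` (x, y, z in μm of the stack
    frame's zero corner).
    """
    if voxel_edge <= 0:
        raise ValueError("voxel edge must be positive")
    if not network.segments:
        raise ValueError("cannot rasterize an empty network")
    pts = network.all_points()
    radii = network.all_radii()
    thinnest = radii[radii > 0].min() if np.any(radii > 0) else 0.0
    if thinnest and voxel_edge > thinnest / 2.0:
        import warnings
        warnings.warn(
            f"voxel edge {voxel_edge} μm is coarse for the thinnest fiber "
            f"radius {thinnest:.3g} μm; rendering may be unfaithful",
            stacklevel=2)

    lo = (pts - radii[:, None]).min(axis=0) - pad * voxel_edge
    hi = (pts + radii[:, None]).max(axis=0) + pad * voxel_edge
    shape_xyz = np.ceil((hi - lo) / voxel_edge).astype(int) + 1
    nz, ny, nx = int(shape_xyz[2]), int(shape_xyz[1]), int(shape_xyz[0])
    mask = np.zeros((nz, ny, nx), dtype=bool)

    def axis_coords(n, origin):
        return origin + (np.arange(n) + 0.5) * voxel_edge

    xs_all = axis_coords(nx, lo[0])
    ys_all = axis_coords(ny, lo[1])
    zs_all = axis_coords(nz, lo[2])

    end_count: dict = {}
    for seg in network.segments.values():
        for key in seg.end_keys:
            end_count[key] = end_count.get(key, 0) + 1

    def paint_sphere(center, radius):
        box_lo = center - radius - voxel_edge
        box_hi = center + radius + voxel_edge
        i0 = np.maximum(((box_lo - lo) / voxel_edge - 0.5), 0).astype(int)
        i1 = np.minimum(np.ceil((box_hi - lo) / voxel_edge + 0.5),
                        [nx, ny, nz]).astype(int)
        if np.any(i0 >= i1):
            return
        zz, yy, xx = np.meshgrid(zs_all[i0[2]:i1[2]], ys_all[i0[1]:i1[1]],
                                 xs_all[i0[0]:i1[0]], indexing="ij")
        inside = ((xx - center[0]) ** 2 + (yy - center[1]) ** 2
                  + (zz - center[2]) ** 2) <= radius ** 2
        mask[i0[2]:i1[2], i0[1]:i1[1], i0[0]:i1[0]] |= inside

    for seg in network.segments.values():
        for j in range(1, seg.n_points - 1):
            # a joint sphere is only needed where the polyline bends: the
            # wedge between consecutive frusta is empty at collinear joints
            a = seg.points[j] - seg.points[j - 1]
            b = seg.points[j + 1] - seg.points[j]
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if na > 0 and nb > 0 and a @ b >= 0.999999 * na * nb:
                continue
            paint_sphere(seg.points[j], seg.radii[j])
        if seg.n_points and end_count.get(seg.end_keys[0], 0) >= 2:
            paint_sphere(seg.points[0], seg.radii[0])
        if seg.n_points and end_count.get(seg.end_keys[1], 0) >= 2:
            paint_sphere(seg.points[-1], seg.radii[-1])
        for j in range(seg.n_points - 1):
            p0, p1 = seg.points[j], seg.points[j + 1]
            r0, r1 = seg.radii[j], seg.radii[j + 1]
            rmax = max(r0, r1)
            box_lo = np.minimum(p0, p1) - rmax - voxel_edge
            box_hi = np.maximum(p0, p1) + rmax + voxel_edge
            i0 = np.maximum(((box_lo - lo) / voxel_edge - 0.5), 0).astype(int)
            i1 = np.minimum(np.ceil((box_hi - lo) / voxel_edge + 0.5),
                            [nx, ny, nz]).astype(int)
            if np.any(i0 >= i1):
                continue
            zz, yy, xx = np.meshgrid(zs_all[i0[2]:i1[2]],
                                     ys_all[i0[1]:i1[1]],
                                     xs_all[i0[0]:i1[0]], indexing="ij")
            d = p1 - p0
            l2 = float(d @ d)
            if l2 == 0:
                dist2 = ((xx - p0[0]) ** 2 + (yy - p0[1]) ** 2
                         + (zz - p0[2]) ** 2)
                inside = dist2 <= rmax ** 2
            else:
                t = ((xx - p0[0]) * d[0] + (yy - p0[1]) * d[1]
                     + (zz - p0[2]) * d[2]) / l2
                inside_t = (t >= 0.0) & (t <= 1.0)
                tc = np.clip(t, 0.0, 1.0)
                cx = p0[0] + tc * d[0]
                cy = p0[1] + tc * d[1]
                cz = p0[2] + tc * d[2]
                dist2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
                r_at = r0 + tc * (r1 - r0)
                inside = inside_t & (dist2 <= r_at ** 2)
            mask[i0[2]:i1[2], i0[1]:i1[1], i0[0]:i1[0]] |= inside

    stack = ImageStack(np.where(mask, 255, 0).astype(np.uint8),
                       (voxel_edge, voxel_edge, voxel_edge),
                       source="rasterized network")
    stack.origin = tuple(float(v) for v in lo)  # stack frame offset in μm
    return stack


def degrade(stack: ImageStack, spec: SyntheticSpec) -> ImageStack:
    """Apply depth attenuation, Gaussian noise and speckles, in that order.

    Attenuation multiplies slice z by exp(b·z_μm); noise is additive
    Gaussian with sigma = noise_sigma × peak; speckles set random single
    voxels to the peak intensity.  All randomness is seeded from
    ``spec.seed``.  A zero-degradation spec is the identity.
    """
    deg = spec.degradation
    rng = np.random.default_rng(spec.seed + 104729)   # decorrelated stream
    data = np.asarray(stack.data, dtype=np.float32).copy()
    peak = float(data.max()) or 1.0

    if deg.attenuation_b:
        z = np.arange(data.shape[0], dtype=np.float32) * stack.voxel_size[2]
        data *= np.exp(deg.attenuation_b * z)[:, None, None]
    if deg.noise_sigma:
        data += rng.normal(0.0, deg.noise_sigma * peak,
                           size=data.shape).astype(np.float32)
        np.clip(data, 0, None, out=data)
    if deg.speckle_count:
        idx = tuple(rng.integers(0, s, size=deg.speckle_count)
                    for s in data.shape)
        data[idx] = peak
    out = ImageStack(data, stack.voxel_size, stack.channel, stack.source)
    if hasattr(stack, "origin"):
        out.origin = stack.origin
    return out
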