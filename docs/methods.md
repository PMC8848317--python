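# Methods

This note records the models, algorithms and numerical choices behind
nettrace3d, and what the synthetic ground-truth tests do and do not show
about real data.

## Pipeline model

The input is a 3D scalar intensity stack (z, y, x) with a physical voxel
size in μm.  Reconstruction assumes the imaged objects are tubular: locally
circular cross-sections around a 1D centerline, which is what makes the
distance transform a radius estimator and a curve skeleton a faithful
summary.  Plate-like or blob-like structures are outside the model (a soma
is tolerated and bookkept separately when reading SWC files, but it is not
reconstructed from images).

### Conditioning (optional, off by default)

- **Median filter** (size 3 voxels, edge-replicated): removes single-voxel
  speckles and extrema.  Note that on thin tubes (radius ≲ 4 voxels) a
  median filter shaves the digitized surface and biases radii low by a few
  per cent — enable it when the data has shot noise worth removing, not as
  a default.
- **Depth attenuation (z-drop)**: optical slice microscopy loses signal
  with depth; the per-slice mean intensity is modeled as `a·exp(b·z)` with
  z the physical slice depth in μm, a the reference intensity at z = 0 and
  b the decay rate per μm (negative in absorbing samples).  The fit is
  non-linear least squares initialised by log-linear regression on the
  positive slice means; correction multiplies slice z by `exp(−b·z)`,
  normalising to the z = 0 level.  If the optimiser fails, the log-linear
  estimate is used and flagged.
- **Isotropic resampling** (always on; identity for already-cubic voxels):
  third-order spline interpolation to a cubic voxel, by default the
  smallest of the three edges, so the finer in-plane sampling is kept and z
  is upsampled.  Both skeletonization algorithms require an isotropic grid
  and reject anisotropic input.
- **Gaussian blur** (σ = 2 voxels when enabled): suppresses noise ahead of
  thresholding.  Blur-then-threshold systematically dilates thin tubes —
  the surface moves to where the blurred profile crosses the threshold,
  which for a histogram-derived threshold sits below the half-maximum
  level; on 3.8-voxel-radius tubes with σ = 2 the measured mean radius
  inflates by 16–19 %.  Length and topology are unaffected.  Use it for
  noisy data where segmentation integrity matters more than radii.

### Segmentation

Otsu's threshold is computed on a 256-bin histogram spanning the observed
intensity range, maximising the between-class variance with ties broken
toward the lower level; voxels **≥** the threshold are foreground.  A
percentage-of-maximum threshold is the manual alternative.  Optional
closing (n dilations then n erosions, 3³ structuring element,
26-connectivity; the original foreground is always retained) fills small
holes; island removal drops 26-connected components smaller than a physical
volume (strictly smaller — a 100 μm³ component survives a 100 μm³
threshold).

### Skeletonization

**Thinning (default).**  Iterative deletion of border voxels over the six
border directions until stable.  A voxel is deletable when it is
topologically simple — its foreground 26-neighbors form exactly one
26-connected component and the background of its 18-neighborhood forms
exactly one 6-connected component touching a face neighbor (topological
numbers T26 = T6 = 1) — and not a curve end point (≥ 2 foreground
neighbors required).  Candidates are collected per direction and deleted
sequentially with re-checking, which guarantees the object's topology;
within each sub-iteration candidates are processed checkerboard-first
(even z+y+x before odd).  The parity interleave matters: with plain scan
order a deletion wavefront can run monotonically along a symmetric
two-voxel-wide structure and consume it entirely — topologically legal,
geometrically catastrophic (a straight tube whose axis falls exactly on a
lattice plane reduces to two voxels; the widely used Fiji/skimage 3D
thinning exhibits exactly this failure, which is why the routine is
implemented here rather than delegated).  With the interleave such ladders
resolve into a stable one-voxel zigzag.  The implementation is
numba-compiled; a ~200³-voxel stack thins in a few seconds.

**TEASAR-style tracing (alternative).**  Per 26-connected component: the
root is the voxel geodesically farthest from a deterministic seed; a
penalty field `5000·(1 − d/(1.01·d_max))¹⁶` (d the distance transform)
pushes paths toward the centerline; repeatedly the minimal-penalty path
(edge cost = step length + target-voxel penalty, Dijkstra) from the root to
the farthest still-valid voxel is accepted, and all voxels within
`scale·r + const` (defaults 1.5 and 3 voxels) of the path are invalidated;
the union of paths is the skeleton.  Produces tree-shaped centerlines;
recommended for neuron-like objects with a bulky soma.

### Radii

Each skeleton voxel carries the Euclidean distance transform value — the
shortest distance to background — as its radius, in voxels.  Inside a tube
the distance field is a cone, `EDT(x) ≈ r − dist⊥(x, axis)`, so a
lattice-quantized skeleton voxel underestimates the radius by its off-axis
offset (~0.3 voxels on average, i.e. −8 % at r = 3.8 voxels).  The offset
is recovered from the field itself: the central difference
`eᵢ = (EDT(v+δᵢ) − EDT(v−δᵢ))/2` straddles the cone apex and equals the
per-axis offset, giving `r = EDT(v) + |e|`.  The estimator carries a
+0.13-voxel noise floor (the median overshoot measured on digitized
straight, sinusoid and helix tubes of 2–6 voxel radius at random sub-voxel
offsets — an oracle independent of the test fixtures), which is subtracted;
|e| is clamped to the voxel half-diagonal.  After this correction the mean
radius of reconstructed synthetic tubes is accurate to well under 1 %.

### Graph stage

Skeleton voxels become graph vertices, 26-adjacency becomes edges, and
diagonal edges that shortcut a staircase corner (a triangle whose longest
edge has a two-step detour of strictly shorter steps) are pruned so corners
do not masquerade as junctions.  The graph is reduced to end points
(degree 1) and branch points (degree ≥ 3) with the full voxel path stored
per reduced edge; a pure cycle is anchored at its lexicographically
smallest voxel.  Cleaning iterates to a fixpoint: spurs shorter than
6 voxels hanging off a junction are pruned (and a junction left with
degree 2 has its edges fused), bridges shorter than 6 voxels between two
junctions are contracted to the path's middle voxel (this is what displaces
reconstructed branch points by up to about one tube radius), and isolated
components shorter than the threshold are dropped.  Edge length for the
rule is the stored path's voxel count.

Each surviving path is fit with a cubic smoothing spline over (x, y, z)
parameterized by cumulative chord length and resampled at
`max(5, round(0.1·n_voxels))` points (~1 point per 10 voxels, ≥ 5 per
edge).  The spline smoothing factor is `n·s²` with s = 0.5 voxels of
tolerated RMS residual — the scale of the staircase quantization noise —
so voxel artifacts are removed without flattening real curvature.
Junction endpoints are pinned to their terminal voxels; free tips are
pushed outward along the local tangent by the terminal voxel's distance
value, because thinning retracts a tube's end point to where the end face
is as close as the side wall, i.e. by exactly that distance.  Radii are
linearly interpolated from the voxel radii along the spline parameter,
never re-measured.

### Assembly and measures

Segments sharing an end key form the segment-endpoint graph; fibers are its
connected components, and an end key with ≥ 3 incident segment ends is a
branch point (counted once per junction).  Length is the polyline length,
volume the frustum sum, mean radius the unweighted point mean (kept for
comparability, though it is skewed by uneven point spacing), and the
cylinder radius √(V/(πL)) the headline radius; fiber- and network-level
values sum the lengths and volumes and pool the points.  Network totals
exclude soma segments from the length but include them in the volume.  An
improved volume that does not double-count overlapping frusta at junctions
is available by rasterizing the network and counting voxels.

Fiber direction is the sum of per-segment end-to-end displacements, each
flipped to non-negative z first (start and end of a fiber in a stack are
interchangeable), the sum flipped likewise — a length-weighted dominant
direction.  The spherical histogram bins directions on a regular
18 × 9 azimuth × altitude grid; bin solid angle is
`Δaz·(sin alt_hi − sin alt_lo)` sr (areas sum to 2π exactly), density is
count/area and the scaled density divides by the mean density n/2π, so an
isotropic network scores 1.  With iid directions the per-bin scatter is
Poisson: the polar bins expect only ~n/1185 counts each (8.4 at n = 10⁴),
so per-bin flatness should be judged against √λ, not a fixed band.

## Synthetic ground truth

The generator lays each fiber as a rounded serpentine — straight passes
joined by semicircular turns of radius ≥ 6 μm — inside its own z-slab,
with smooth sinusoidal radii inside the requested range and optional side
branches that rise out of the parent's undulation band before running
parallel to it.  This guarantees bounded curvature (≥ 5 tube radii, so the
tube never overlaps itself) and inter-fiber clearance of several radii —
plain random walks at these densities produce turns sharper than the tube
radius, which no centerline method could recover.  All randomness derives
from a single seed.  The default fixture is 4 fibers, radii 0.7–1.2 μm, in
a 50³ μm volume rendered at 0.25 μm voxels (tube radii of ~3–5 voxels).

The rasterizer marks a voxel foreground iff its center lies inside a
truncated cone spanned by a consecutive point pair, with spheres at bending
interior joints (the wedge between consecutive frusta is empty at collinear
joints, so straight constant-radius segments rasterize to exact cylinders)
and flat free ends.  The voxel-center test makes foreground count × voxel
volume an unbiased volume estimate (measured within 0.1 % of the frustum
sum on the default fixture).  Degradation applies, in order, multiplicative
exponential depth attenuation (default b = −0.01/μm), additive Gaussian
noise (default 3 % of peak) and random single-voxel speckles (default 150),
all seeded.

What passing round trips show: on well-separated smooth tubes of ≥ 2 voxel
radius, the pipeline recovers fiber counts exactly and length/volume/mean
radius to ≲ 1 %.  What they do not show: performance on touching or
crossing vessels, intensity inhomogeneity along fibers, non-circular cross
sections, or point-spread-function anisotropy — real stacks are harder
than the fixture in all these ways.

## Degenerate inputs and edge behavior

Constant images are rejected by Otsu (degenerate histogram); empty masks
skeletonize to empty; zero-length elements report NaN cylinder radius
rather than raising; a fiber with zero net direction is flagged undefined
and excluded from orientation statistics; networks with loops export to
MV3D/CSV/JSON but are refused by SWC (a forest format) with a warning from
the batch pipeline.  All pre-processing runs in float32; intensities are
cast back only on export, with an explicit overflow error unless scaling
is requested.

## Known limitations

- Radii below ~2 voxels are at the resolution limit; rasterization warns
  when the voxel edge exceeds half the thinnest radius.
- The 6-voxel cleaning rule can swallow genuine side branches shorter than
  6 voxels and can leave a residual spurious junction where two tubes pass
  within a voxel of each other.
- Gaussian blur and median filtering bias radii on thin tubes (see above);
  they are off by default and should be enabled deliberately.
- TEASAR path endpoints land on end-cap planes but offset from the cap
  center by up to one tube radius (the farthest-point rule).
- The native container preserves everything bit-exactly but is not
  byte-compatible with any external tool's binary format.
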