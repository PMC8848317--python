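"""Reading and writing image stacks and network descriptions.

Image stacks are multi-page gray-scale TIFFs carried in memory as
:class:`ImageStack` with axis order (z, y, x) and a physical voxel size in
micrometres.  Networks travel as SWC (the neuronal reconstruction standard:
``id type x y z radius parent`` samples forming a forest), MicroVisu3D
``.mv3d`` (blocks of ``id x y z d`` points per vessel segment, d a diameter),
per-segment CSV tables, or a lossless native container.

Conventions: arrays are indexed (z, y, x); exported point coordinates are
(x, y, z) in μm; voxel index (0, 0, 0) maps to the physical point at that
voxel's center, i.e. 0.5·voxel_size per axis.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .morphometry import Network, Segment, measure_element, network_summary

__all__ = [
    "ImageStack",
    "read_stack",
    "write_stack",
    "read_network",
    "write_network",
    "export_summary",
    "NATIVE_FORMAT_VERSION",
]

NATIVE_FORMAT_VERSION = 1

_SWC_SOMA_TYPE = 1
_SWC_FIBER_TYPE = 3


@dataclass
class ImageStack:
    """3D scalar intensity volume with physical voxel size.

    data is indexed (z, y, x); voxel_size is (x, y, z) in μm.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("stack data must be a non-empty 3D array")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be three positive values (x, y, z)")
        self.voxel_size = vs
        if np.issubdtype(self.data.dtype, np.floating):
            if not np.all(np.isfinite(self.data)):
                raise ValueError("intensities must be finite")
            if np.any(self.data < 0):
                raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        vx, vy, vz = self.voxel_size
        return math_isclose(vx, vy) and math_isclose(vy, vz)


def math_isclose(a: float, b: float, rel: float = 1e-6) -> bool:
    return abs(a - b) <= rel * max(abs(a), abs(b), 1e-30)


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def _voxel_size_from_tiff(tf: tifffile.TiffFile) -> tuple | None:
    """Voxel size (x, y, z) in μm from resolution tags + ImageJ metadata."""
    page = tf.pages[0]
    tags = page.tags
    if "XResolution" not in tags or "YResolution" not in tags:
        return None
    xres = tags["XResolution"].value
    yres = tags["YResolution"].value
    if xres[0] == 0 or yres[0] == 0:
        return None
    unit_tag = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 1
    unit_um = {1: 1.0, 2: 25400.0, 3: 10000.0}.get(int(unit_tag), 1.0)
    meta = tf.imagej_metadata or {}
    if unit_tag == 1 and meta.get("unit") not in ("um", "µm", "micron"):
        # RESUNIT "none" is only meaningful when ImageJ metadata declares μm
        return None
    vx = xres[1] / xres[0] * unit_um
    vy = yres[1] / yres[0] * unit_um
    vz = float(meta.get("spacing", 0.0))
    if vz <= 0:
        return None
    return (vx, vy, vz)


def read_stack(path: str | Path, voxel_size_override: tuple | None = None,
               channel: int | None = None) -> ImageStack:
    """Load a single- or multi-page gray-scale TIFF as an ImageStack.

    The voxel size comes from the TIFF resolution tags plus ImageJ-style
    z-spacing metadata, or from ``voxel_size_override`` (x, y, z in μm), which
    wins when both are present.  Multi-channel files require ``channel``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes.upper()
        tag_voxel = _voxel_size_from_tiff(tf)

    # normalise to (z, y, x)
    if "C" in axes or "S" in axes:
        ch_axis = axes.index("C") if "C" in axes else axes.index("S")
        if channel is None:
            raise ValueError(
                "multi-channel image: a channel selection is required")
        data = np.take(data, channel, axis=ch_axis)
        axes = axes.replace("C", "", 1) if "C" in axes else axes.replace("S", "", 1)
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise ValueError(f"unsupported TIFF layout with axes {axes!r}")

    voxel_size = voxel_size_override or tag_voxel
    if voxel_size is None:
        raise ValueError(
            "voxel size metadata required: none found in file and no "
            "override given")
    return ImageStack(data, tuple(voxel_size), channel=channel,
                      source=str(path))


def write_stack(stack: ImageStack, path: str | Path, dtype: str = "uint16",
                scale: bool = False) -> Path:
    """Write the stack as a multi-page TIFF, page k = slice z=k.

    dtype is one of uint8/uint16/float32.  With ``scale`` the intensities are
    mapped linearly from [0, max] onto the full dtype range; without it the
    values must already fit the target dtype or a ValueError is raised.
    Voxel size is stored in the resolution tags (x/y) and ImageJ-style
    z-spacing metadata.
    """
    if dtype not in ("uint8", "uint16", "float32"):
        raise ValueError(f"unsupported dtype {dtype!r}")
    path = Path(path)
    data = np.asarray(stack.data, dtype=np.float64)
    if scale:
        peak = data.max()
        if peak > 0:
            if dtype == "float32":
                data = data / peak
            else:
                data = data / peak * np.iinfo(dtype).max
    elif dtype != "float32":
        if data.max() > np.iinfo(dtype).max:
            raise ValueError(
                f"intensity {data.max():g} overflows {dtype}; enable scaling")
    out = np.round(data).astype(dtype) if dtype != "float32" \
        else data.astype(np.float32)
    vx, vy, vz = stack.voxel_size
    tifffile.imwrite(
        path, out, imagej=True, resolution=(1.0 / vx, 1.0 / vy),
        metadata={"axes": "ZYX", "spacing": vz, "unit": "um"})
    return path


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def _parse_swc(path: Path):
    """Parse SWC samples -> dict id -> (type, x, y, z, radius, parent)."""
    nodes: dict[int, tuple] = {}
    order: list[int] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 7:
            raise ValueError(
                f"{path.name}:{lineno}: expected 7 columns, got {len(fields)}")
        try:
            nid = int(fields[0])
            ntype = int(fields[1])
            x, y, z, radius = (float(v) for v in fields[2:6])
            parent = int(fields[6])
        except ValueError as exc:
            raise ValueError(
                f"{path.name}:{lineno}: non-numeric field ({exc})") from None
        if nid in nodes:
            raise ValueError(f"{path.name}:{lineno}: duplicate id {nid}")
        if radius < 0:
            raise ValueError(f"{path.name}:{lineno}: negative radius")
        nodes[nid] = (ntype, x, y, z, radius, parent)
        order.append(nid)
    for nid in order:
        parent = nodes[nid][5]
        if parent != -1 and parent not in nodes:
            raise ValueError(
                f"{path.name}: node {nid} references missing parent {parent}")
    return nodes, order


def _swc_to_segments(nodes: dict[int, tuple]) -> list[Segment]:
    """Split the SWC forest into unbranched segments at branch/end nodes."""
    children: dict[int, list[int]] = {nid: [] for nid in nodes}
    for nid, rec in nodes.items():
        if rec[5] != -1:
            children[rec[5]].append(nid)

    def degree(nid: int) -> int:
        return len(children[nid]) + (0 if nodes[nid][5] == -1 else 1)

    def is_soma(nid: int) -> bool:
        return nodes[nid][0] == _SWC_SOMA_TYPE

    terminals = {nid for nid in nodes if degree(nid) != 2}
    # split chains where the soma flag flips; the soma-side sample anchors
    # the boundary so the soma segment stays type-pure
    for nid, rec in nodes.items():
        parent = rec[5]
        if parent != -1 and is_soma(nid) != is_soma(parent):
            terminals.add(nid if is_soma(nid) else parent)
    segments: list[Segment] = []
    seg_id = 0
    for start in sorted(terminals):
        for child in children[start]:
            chain = [start, child]
            while chain[-1] not in terminals:
                (nxt,) = children[chain[-1]]
                chain.append(nxt)
            pts = np.array([nodes[n][1:4] for n in chain], dtype=float)
            radii = np.array([nodes[n][4] for n in chain], dtype=float)
            kind = ("soma" if all(nodes[n][0] == _SWC_SOMA_TYPE for n in chain)
                    else "fiber")
            segments.append(Segment(seg_id, pts, radii,
                                    end_keys=(chain[0], chain[-1]), kind=kind))
            seg_id += 1
    # an isolated sample (root with no children) forms a degenerate segment
    for nid in sorted(nodes):
        if degree(nid) == 0:
            rec = nodes[nid]
            kind = "soma" if rec[0] == _SWC_SOMA_TYPE else "fiber"
            segments.append(Segment(
                seg_id, np.array([rec[1:4]], dtype=float),
                np.array([rec[4]], dtype=float), end_keys=(nid, nid),
                kind=kind))
            seg_id += 1
    return segments


def _write_swc(network: Network, path: Path) -> None:
    # SWC is a forest: walk each fiber from an arbitrary end, reusing sample
    # ids at shared endpoints; a cycle makes the network unrepresentable.
    from .graphnet import segment_adjacency

    adjacency = segment_adjacency(network)
    lines = ["# id type x y z radius parent"]
    sample_of_key: dict = {}
    next_id = 1
    visited_segments: set[int] = set()

    def emit(x, y, z, r, kind, parent):
        nonlocal next_id
        stype = _SWC_SOMA_TYPE if kind == "soma" else _SWC_FIBER_TYPE
        lines.append(f"{next_id} {stype} {x:.6f} {y:.6f} {z:.6f} {r:.6f} "
                     f"{parent}")
        next_id += 1
        return next_id - 1

    for start_key in sorted(adjacency, key=repr):
        if start_key in sample_of_key:
            continue
        stack = [start_key]
        while stack:
            key = stack.pop()
            for sid in adjacency.get(key, ()):
                if sid in visited_segments:
                    continue
                visited_segments.add(sid)
                seg = network.segments[sid]
                k0, k1 = seg.end_keys
                pts, radii = seg.points, seg.radii
                if key == k1 and key != k0:
                    pts, radii = pts[::-1], radii[::-1]
                    k0, k1 = k1, k0
                if k0 not in sample_of_key:
                    sample_of_key[k0] = emit(*pts[0], radii[0], seg.kind, -1)
                parent = sample_of_key[k0]
                for p, r in zip(pts[1:-1], radii[1:-1]):
                    parent = emit(*p, r, seg.kind, parent)
                if seg.n_points > 1:
                    if k1 in sample_of_key:
                        raise ValueError(
                            "unsupported topology for format: network "
                            "contains a cycle, SWC is a forest")
                    sample_of_key[k1] = emit(*pts[-1], radii[-1], seg.kind,
                                             parent)
                stack.append(k1)
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# MicroVisu3D
# ---------------------------------------------------------------------------

def _parse_mv3d(path: Path) -> list[Segment]:
    segments: list[Segment] = []
    block: list[tuple] = []
    seg_id = 0

    def flush():
        nonlocal seg_id, block
        if not block:
            return
        pts = np.array([(x, y, z) for _, x, y, z, _ in block], dtype=float)
        radii = np.array([d / 2.0 for *_, d in block], dtype=float)
        key0 = tuple(np.round(pts[0], 4))
        key1 = tuple(np.round(pts[-1], 4))
        segments.append(Segment(seg_id, pts, radii, end_keys=(key0, key1)))
        seg_id += 1
        block = []

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#"):
            continue
        if not line:
            flush()
            continue
        fields = line.split()
        if len(fields) != 5:
            raise ValueError(
                f"{path.name}:{lineno}: expected 5 columns, got {len(fields)}")
        try:
            rec = (int(fields[0]), *(float(v) for v in fields[1:]))
        except ValueError as exc:
            raise ValueError(
                f"{path.name}:{lineno}: non-numeric field ({exc})") from None
        block.append(rec)
    flush()
    return segments


def _write_mv3d(network: Network, path: Path) -> None:
    n_points = sum(s.n_points for s in network.segments.values())
    out = [
        "# MicroVisu3D file",
        f"# Number of lines   {len(network.segments)}",
        f"# Number of points  {n_points}",
        "#",
        "# No\tx\ty\tz\td",
    ]
    for i, sid in enumerate(sorted(network.segments)):
        seg = network.segments[sid]
        for p, r in zip(seg.points, seg.radii):
            out.append(f"{i}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\t"
                       f"{2.0 * r:.6f}")
        out.append("")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# native container
# ---------------------------------------------------------------------------

def _write_native(network: Network, path: Path) -> None:
    arrays: dict[str, np.ndarray] = {"branch_points": network.branch_points}
    seg_meta = []
    for sid in sorted(network.segments):
        seg = network.segments[sid]
        arrays[f"seg_{sid}_points"] = seg.points
        arrays[f"seg_{sid}_radii"] = seg.radii
        seg_meta.append({
            "id": sid, "kind": seg.kind,
            "end_keys": [_key_to_json(k) for k in seg.end_keys],
        })
    meta = {
        "format_version": NATIVE_FORMAT_VERSION,
        "metadata": network.metadata,
        "segments": seg_meta,
        "fibers": {str(fid): f.segment_ids
                   for fid, f in network.fibers.items()},
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta))
        from io import BytesIO
        buf = BytesIO()
        np.savez(buf, **arrays)
        zf.writestr("arrays.npz", buf.getvalue())


def _key_to_json(key):
    if isinstance(key, tuple):
        return {"t": list(key)}
    return key


def _key_from_json(obj):
    if isinstance(obj, dict) and "t" in obj:
        return tuple(obj["t"])
    return obj


def _read_native(path: Path) -> Network:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta.get("format_version") != NATIVE_FORMAT_VERSION:
            raise ValueError(
                f"unsupported native format version {meta.get('format_version')}")
        from io import BytesIO
        arrays = np.load(BytesIO(zf.read("arrays.npz")))
        network = Network(metadata=meta["metadata"])
        for rec in meta["segments"]:
            sid = rec["id"]
            network.segments[sid] = Segment(
                sid, arrays[f"seg_{sid}_points"], arrays[f"seg_{sid}_radii"],
                end_keys=tuple(_key_from_json(k) for k in rec["end_keys"]),
                kind=rec["kind"])
        from .morphometry import Fiber
        for fid, sids in meta["fibers"].items():
            network.fibers[int(fid)] = Fiber(int(fid), list(sids))
        network.branch_points = arrays["branch_points"]
    return network


# ---------------------------------------------------------------------------
# public network I/O
# ---------------------------------------------------------------------------

def read_network(path: str | Path, format: str | None = None) -> Network:
    """Read a network file (swc, mv3d or native) into a Network.

    SWC radii are used as-is; the MV3D diameter column is halved to a radius;
    SWC structure type 1 marks soma segments.  Fibers and branch points are
    assembled from the file's connectivity.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".swc": "swc", ".mv3d": "mv3d"}.get(
            path.suffix.lower(), "native")
    if format == "native":
        return _read_native(path)
    if format == "swc":
        nodes, _ = _parse_swc(path)
        segments = _swc_to_segments(nodes)
    elif format == "mv3d":
        segments = _parse_mv3d(path)
    else:
        raise ValueError(f"unsupported network format {format!r}")
    from .graphnet import assemble_network

    return assemble_network(segments, metadata={"source": str(path),
                                                "format": format})


def write_network(network: Network, path: str | Path,
                  format: str | None = None) -> Path:
    """Write a network as swc, mv3d, csv or the native container."""
    path = Path(path)
    if format is None:
        format = {".swc": "swc", ".mv3d": "mv3d", ".csv": "csv"}.get(
            path.suffix.lower(), "native")
    if format in ("swc", "mv3d") and not network.segments:
        raise ValueError(f"cannot write an empty network as {format}")
    if format == "swc":
        _write_swc(network, path)
    elif format == "mv3d":
        _write_mv3d(network, path)
    elif format == "csv":
        _segment_table(network).to_csv(path, index=False)
    elif format == "native":
        _write_native(network, path)
    else:
        raise ValueError(f"unsupported network format {format!r}")
    return path


def _segment_table(network: Network) -> pd.DataFrame:
    seg_fiber = {sid: fid for fid, f in network.fibers.items()
                 for sid in f.segment_ids}
    rows = []
    for sid in sorted(network.segments):
        seg = network.segments[sid]
        m = measure_element(seg)
        rows.append({
            "fiber_id": seg_fiber.get(sid, -1), "segment_id": sid,
            "kind": seg.kind, "n_points": seg.n_points,
            "length": m["length"], "volume": m["volume"],
            "mean_radius": m["mean_radius"],
            "cylinder_radius": m["cylinder_radius"],
        })
    return pd.DataFrame(rows, columns=[
        "fiber_id", "segment_id", "kind", "n_points", "length", "volume",
        "mean_radius", "cylinder_radius"])


def export_summary(network: Network, path: str | Path,
                   format: str = "json") -> Path:
    """Write the measured properties of the network.

    json: the network-level summary plus per-fiber and per-segment measures
    and input metadata.  csv: one row per segment (plus header).
    """
    path = Path(path)
    if format == "csv":
        _segment_table(network).to_csv(path, index=False)
        return path
    if format != "json":
        raise ValueError(f"unsupported summary format {format!r}")
    record = {
        "network": network_summary(network),
        "fibers": {
            str(fid): measure_element(f, network)
            for fid, f in network.fibers.items()
        },
        "segments": {
            str(sid): measure_element(s)
            for sid, s in network.segments.items()
        },
    }
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    return path
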