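"""From voxel skeleton to measured network hierarchy.

The skeleton voxels become a graph (voxel = vertex, 26-adjacency = edge),
which is reduced to its topology: end points (degree 1) and branch points
(degree ≥ 3), with the ordered voxel path between each pair of terminals
stored on the reduced edge.  Short artifact edges — spurs on the rim, stubs
between nearby junctions — are merged or removed, each surviving path is
smoothed with a cubic spline and resampled, and the resulting segments are
assembled into fibers (connected components) and a Network.

Edge length for the cleaning rule is the voxel count of the stored path;
edges shorter than 6 voxels (default) are merged with larger neighbors or
removed when isolated.
"""

from __future__ import annotations

import math

import numpy as np
import networkx as nx
from scipy import interpolate

from .morphometry import Fiber, Network, Segment
from .skeletonize import VoxelSkeleton

__all__ = [
    "build_voxel_graph",
    "reduce_graph",
    "clean_graph",
    "smooth_paths",
    "assemble_network",
    "segment_adjacency",
]

_OFFSETS = [(dz, dy, dx)
            for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dz, dy, dx) > (0, 0, 0)]


# ---------------------------------------------------------------------------
# voxel graph
# ---------------------------------------------------------------------------

def build_voxel_graph(skeleton: VoxelSkeleton) -> nx.Graph:
    """Graph with one vertex per skeleton voxel, edges between 26-neighbors.

    Vertex attribute ``radius`` carries the distance-transform radius in
    voxels; graph attributes record voxel size and source algorithm.
    """
    if skeleton.n_voxels == 0:
        raise ValueError("cannot build a graph from an empty skeleton")
    graph = nx.Graph(voxel_size=skeleton.voxel_size,
                     algorithm=skeleton.algorithm)
    lookup = skeleton.radius_lookup()
    for voxel, radius in lookup.items():
        graph.add_node(voxel, radius=radius)
    for voxel in lookup:
        for off in _OFFSETS:
            nb = (voxel[0] + off[0], voxel[1] + off[1], voxel[2] + off[2])
            if nb in lookup:
                graph.add_edge(voxel, nb)
    _prune_shortcut_edges(graph)
    return graph


def _step2(u, v) -> int:
    return ((u[0] - v[0]) ** 2 + (u[1] - v[1]) ** 2 + (u[2] - v[2]) ** 2)


def _prune_shortcut_edges(graph: nx.Graph) -> None:
    """Drop diagonal edges that shortcut a staircase corner.

    A 26-connected voxel curve turning a corner yields triangles (a, b, c)
    where the diagonal a–c skips the corner voxel b; such shortcut edges
    masquerade as junctions.  An edge is removed when a common neighbor
    connects its endpoints through two strictly shorter steps (witnesses are
    evaluated on the original adjacency, so connectivity and cycle topology
    are preserved).
    """
    adjacency = {v: set(graph.neighbors(v)) for v in graph.nodes}
    drop = []
    for u, v in graph.edges:
        d_uv = _step2(u, v)
        if d_uv <= 1:
            continue
        for w in adjacency[u] & adjacency[v]:
            if _step2(u, w) < d_uv and _step2(w, v) < d_uv:
                drop.append((u, v))
                break
    graph.remove_edges_from(drop)


# ---------------------------------------------------------------------------
# reduction to terminals
# ---------------------------------------------------------------------------

def reduce_graph(graph: nx.Graph) -> nx.MultiGraph:
    """Collapse degree-2 chains: keep only end and branch points.

    The reduced multigraph's nodes are terminal voxels (degree 1 or ≥ 3 in
    the voxel graph, plus isolated voxels); each edge stores the ordered
    voxel ``path`` between its two terminals, endpoints included.  A pure
    cycle has no terminal, so it is anchored at its lexicographically
    smallest voxel and stored as a self-loop.
    """
    reduced = nx.MultiGraph(**graph.graph)
    reduced.graph["radius_of"] = {
        v: graph.nodes[v]["radius"] for v in graph.nodes}

    terminals = {v for v in graph.nodes if graph.degree(v) != 2}
    visited_edges: set[frozenset] = set()

    def walk(start, first):
        path = [start, first]
        while path[-1] not in terminals:
            nxt = [n for n in graph.neighbors(path[-1]) if n != path[-2]]
            if not nxt:            # dead end inside a chain (cannot happen
                break              # for degree-2 interiors, kept defensive)
            path.append(nxt[0])
        return path

    for t in sorted(terminals):
        reduced.add_node(t)
        for nb in sorted(graph.neighbors(t)):
            path = walk(t, nb)
            step_edges = [frozenset((path[i], path[i + 1]))
                          for i in range(len(path) - 1)]
            if step_edges[0] in visited_edges:
                continue
            visited_edges.update(step_edges)
            reduced.add_edge(path[0], path[-1], path=path)

    # components without any terminal are pure cycles
    for component in nx.connected_components(graph):
        if component & terminals:
            continue
        anchor = min(component)
        path = [anchor]
        prev = None
        while True:
            nxt = [n for n in graph.neighbors(path[-1]) if n != prev]
            prev = path[-1]
            path.append(nxt[0])
            if path[-1] == anchor:
                break
        reduced.add_node(anchor)
        reduced.add_edge(anchor, anchor, path=path)
    return reduced


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def _fuse_pass_through(reduced: nx.MultiGraph) -> bool:
    """Merge the two edges of any degree-2 non-terminal node into one."""
    changed = False
    for node in list(reduced.nodes):
        if reduced.degree(node) != 2:
            continue
        edges = list(reduced.edges(node, keys=True, data=True))
        if len(edges) != 2:        # degree 2 via a self-loop: keep as cycle
            continue
        (u0, v0, k0, d0), (u1, v1, k1, d1) = edges
        p0 = d0["path"] if d0["path"][0] == node else d0["path"][::-1]
        p1 = d1["path"] if d1["path"][0] == node else d1["path"][::-1]
        merged = p0[::-1] + p1[1:]
        a, b = merged[0], merged[-1]
        reduced.remove_edge(u0, v0, k0)
        reduced.remove_edge(u1, v1, k1)
        reduced.remove_node(node)
        reduced.add_edge(a, b, path=merged)
        changed = True
    return changed


def clean_graph(reduced: nx.MultiGraph,
                min_edge_voxels: int = 6) -> nx.MultiGraph:
    """Remove or merge artifact edges shorter than ``min_edge_voxels``.

    Three rules, iterated to a fixpoint: (i) short spurs (one endpoint of
    degree 1 hanging off a branch point) are pruned, and a branch point left
    with degree 2 has its remaining edges fused; (ii) short bridges between
    two branch points are contracted, merging the junctions at the path's
    middle voxel; (iii) isolated components shorter than the threshold are
    deleted outright.  The operation is idempotent.
    """
    g = reduced.copy()
    g.graph.setdefault("radius_of", {})

    def edge_len(d) -> int:
        return len(d["path"])

    changed = True
    while changed:
        changed = False

        # (iii) short isolated components
        for component in list(nx.connected_components(g)):
            sub_edges = list(g.subgraph(component).edges(data=True))
            voxels = set()
            for *_, d in sub_edges:
                voxels.update(d["path"])
            if not sub_edges:
                g.remove_nodes_from(component)
                changed = True
            elif len(voxels) < min_edge_voxels and all(
                    g.degree(n) <= 2 for n in component):
                g.remove_nodes_from(component)
                changed = True

        # (i) spur pruning
        for u, v, k, d in sorted(g.edges(keys=True, data=True),
                                 key=lambda e: (e[3]["path"][0], e[2])):
            if not g.has_edge(u, v, k) or g[u][v][k] is not d:
                continue
            if edge_len(d) >= min_edge_voxels or u == v:
                continue
            du, dv = g.degree(u), g.degree(v)
            if (du == 1) == (dv == 1):
                continue           # not a spur: either isolated or a bridge
            leaf, anchor = (u, v) if du == 1 else (v, u)
            if g.degree(anchor) < 3:
                continue
            g.remove_edge(u, v, k)
            g.remove_node(leaf)
            changed = True
        if _fuse_pass_through(g):
            changed = True

        # (ii) short bridges between two branch points
        for u, v, k, d in sorted(g.edges(keys=True, data=True),
                                 key=lambda e: (e[3]["path"][0], e[2])):
            if not g.has_edge(u, v, k) or u == v:
                continue
            if g[u][v][k] is not d:
                continue
            if edge_len(d) >= min_edge_voxels:
                continue
            if g.degree(u) < 3 or g.degree(v) < 3:
                continue
            path = d["path"] if d["path"][0] == u else d["path"][::-1]
            mid_idx = (len(path) - 1) // 2
            mid = path[mid_idx]
            g.remove_edge(u, v, k)
            for old, stub in ((u, path[:mid_idx + 1][::-1]),
                              (v, path[mid_idx:])):
                # stub runs from mid out to the old junction voxel
                if old == mid:
                    continue
                for a, b, kk, dd in list(g.edges(old, keys=True, data=True)):
                    other = b if a == old else a
                    p = dd["path"] if dd["path"][0] == old \
                        else dd["path"][::-1]
                    # stub runs mid -> old; extend so paths start at mid
                    new_path = stub + p[1:]
                    g.remove_edge(a, b, kk)
                    if a == b:     # self-loop at the old junction: close it
                        new_path = new_path + stub[::-1][1:]
                        g.add_edge(mid, mid, path=new_path)
                    else:
                        g.add_edge(mid, other if other != old else mid,
                                   path=new_path)
                if old in g and g.degree(old) == 0:
                    g.remove_node(old)
            changed = True
    return g


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def smooth_paths(reduced: nx.MultiGraph, points_per_voxel: float = 0.1,
                 min_points: int = 5,
                 spline_smoothing: float = 0.5) -> list[Segment]:
    """Spline-smooth every reduced edge and resample it into a Segment.

    Each path is fit with a cubic smoothing spline over x, y, z,
    parameterized by cumulative chord length, and resampled at
    ``max(min_points, round(n_voxels · points_per_voxel))`` points — the
    defaults give ~1 point every 10 voxels with at least 5 points per edge.
    ``spline_smoothing`` is the tolerated RMS residual per voxel (in voxels);
    the spline smoothing factor is ``n_voxels · spline_smoothing²``, i.e.
    stiffness grows with path length.  Endpoints are pinned to the terminal
    voxel positions.

    Radii are linearly interpolated along the same parameter from the
    per-voxel radii carried by the skeleton (distance-transform values with
    sub-voxel off-axis correction); they are never re-measured here.

    Free tips (degree-1 terminals) are extended outward along the local
    tangent by the terminal voxel's distance-transform value: thinning
    retracts a tube's end point to where the end face is as close as the
    side wall, i.e. by exactly that distance, so the extension restores the
    tube's true extent.  Non-tip endpoints stay pinned to their terminal
    voxel positions.  Coordinates and radii are converted to μm (voxel
    center convention: index + 0.5 voxel).
    """
    edge = float(reduced.graph.get("voxel_size", 1.0))
    radius_of = reduced.graph.get("radius_of", {})
    segments: list[Segment] = []
    seg_id = 0
    for u, v, d in sorted(reduced.edges(data=True),
                          key=lambda e: (e[2]["path"][0], e[2]["path"][-1])):
        path = d["path"]
        # networkx may report (u, v) in either orientation; the stored path
        # is authoritative, and its terminal voxels are the end keys
        u, v = path[0], path[-1]
        n = len(path)
        if n < 2:
            raise ValueError("cannot smooth a path of fewer than 2 voxels")
        coords = np.asarray(path, dtype=float)           # (n, 3) z, y, x
        steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        chord = np.concatenate([[0.0], np.cumsum(steps)])
        if chord[-1] == 0:
            raise ValueError("degenerate path with zero extent")
        param = chord / chord[-1]

        n_out = max(min_points, int(round(n * points_per_voxel)))
        u_new = np.linspace(0.0, 1.0, n_out)
        k = min(3, n - 1)
        if n > k + 1:
            s = n * spline_smoothing ** 2
            tck, _ = interpolate.splprep(coords.T, u=param, s=s, k=k)
            smoothed = np.array(interpolate.splev(u_new, tck)).T
        else:
            smoothed = np.column_stack([
                np.interp(u_new, param, coords[:, i]) for i in range(3)])
        smoothed[0] = coords[0]
        smoothed[-1] = coords[-1]

        radii_vox = np.array([radius_of.get(p, 1.0) for p in path])
        radii_new = np.interp(u_new, param, radii_vox) * edge

        # tip restitution: push free ends out by the terminal EDT value
        if n_out >= 2:
            if reduced.degree(u) == 1 and u != v:
                d0 = smoothed[0] - smoothed[1]
                norm = np.linalg.norm(d0)
                if norm > 0:
                    smoothed[0] = (coords[0]
                                   + d0 / norm * radius_of.get(path[0], 0.0))
            if reduced.degree(v) == 1 and u != v:
                d1 = smoothed[-1] - smoothed[-2]
                norm = np.linalg.norm(d1)
                if norm > 0:
                    smoothed[-1] = (coords[-1]
                                    + d1 / norm
                                    * radius_of.get(path[-1], 0.0))

        # (z, y, x) voxel index -> physical (x, y, z) μm at voxel centers
        xyz = (smoothed[:, ::-1] + 0.5) * edge
        segments.append(Segment(seg_id, xyz, radii_new, end_keys=(u, v)))
        seg_id += 1
    return segments


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_network(segments: list[Segment], voxel_size: float | None = None,
                     metadata: dict | None = None) -> Network:
    """Group segments into fibers and collect branch points.

    Fibers are the connected components of the segment-endpoint graph (two
    segments connect when they share an end key).  A branch point is an end
    key where ≥ 3 segment ends meet (a self-looping segment contributes both
    of its ends); its coordinates are taken from the segment endpoints.
    """
    network = Network(metadata=dict(metadata or {}))
    if voxel_size is not None:
        network.metadata.setdefault("voxel_size", voxel_size)
    if not segments:
        return network

    ids = [s.id for s in segments]
    if len(set(ids)) != len(ids):
        raise ValueError("segment ids must be unique")
    for seg in segments:
        network.segments[seg.id] = seg

    key_graph = nx.MultiGraph()
    end_count: dict = {}
    key_position: dict = {}
    for seg in segments:
        k0, k1 = seg.end_keys
        key_graph.add_edge(k0, k1, segment=seg.id)
        end_count[k0] = end_count.get(k0, 0) + 1
        end_count[k1] = end_count.get(k1, 0) + 1
        key_position.setdefault(k0, seg.points[0])
        key_position.setdefault(k1, seg.points[-1])

    for fid, component in enumerate(
            sorted(nx.connected_components(key_graph), key=sorted)):
        sids = sorted({d["segment"] for *_, d
                       in key_graph.subgraph(component).edges(data=True)})
        network.fibers[fid] = Fiber(fid, sids)

    branch_keys = sorted((k for k, c in end_count.items() if c >= 3),
                         key=repr)
    if branch_keys:
        network.branch_points = np.array(
            [key_position[k] for k in branch_keys], dtype=float)
    return network


def segment_adjacency(network: Network) -> dict:
    """Map end key -> sorted ids of the segments ending there."""
    adjacency: dict = {}
    for sid in sorted(network.segments):
        seg = network.segments[sid]
        for key in seg.end_keys:
            adjacency.setdefault(key, [])
            if sid not in adjacency[key]:
                adjacency[key].append(sid)
    return adjacency
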