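"""Skeletonization of the vessel mask and extraction of the centerline graph.

The binary mask is thinned to a 1-px skeleton with the classic two-subiteration
Zhang-Suen algorithm (8-connectivity).  Skeleton pixels are then classified by
their 8-neighbour count n: n = 0 isolated, n = 1 endpoint, n >= 3 intersection,
n = 2 regular.  Segments are traced between nodes, and centerlines can be
downsampled at a fixed index interval so that later cross-section contours do
not intersect.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class Skeleton:
    """1-px-wide binary skeleton, 8-connectivity convention."""

    grid: np.ndarray  # (H, W) bool

    @property
    def pixels(self) -> np.ndarray:
        """(N, 2) array of (row, col) skeleton pixel coordinates."""
        return np.argwhere(self.grid)


@dataclass
class GraphNode:
    id: int
    pos: tuple[float, float]          # (row, col); centroid for merged clusters
    kind: str                          # endpoint | bifurcation | isolated | break
    pixels: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class GraphSegment:
    id: int
    node_a: int
    node_b: int
    points: np.ndarray                 # ordered (N, 2) int path node_a -> node_b


@dataclass
class VesselGraph:
    """Centerline graph: nodes (endpoints/bifurcations) + ordered pixel paths."""

    nodes: list[GraphNode]
    segments: list[GraphSegment]
    shape: tuple[int, int]

    def node_by_id(self, nid: int) -> GraphNode:
        return self.nodes[nid]

    def degree(self, nid: int) -> int:
        return sum((s.node_a == nid) + (s.node_b == nid) for s in self.segments)

    def to_json(self) -> str:
        payload = {
            "shape": list(self.shape),
            "nodes": [
                {"id": n.id, "pos": list(n.pos), "kind": n.kind,
                 "pixels": [list(p) for p in n.pixels]}
                for n in self.nodes
            ],
            "segments": [
                {"id": s.id, "node_a": s.node_a, "node_b": s.node_b,
                 "points": s.points.tolist()}
                for s in self.segments
            ],
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "VesselGraph":
        d = json.loads(text)
        nodes = [GraphNode(n["id"], tuple(n["pos"]), n["kind"],
                           [tuple(p) for p in n["pixels"]]) for n in d["nodes"]]
        segs = [GraphSegment(s["id"], s["node_a"], s["node_b"],
                             np.asarray(s["points"], dtype=int))
                for s in d["segments"]]
        return cls(nodes, segs, tuple(d["shape"]))


# ---------------------------------------------------------------------------
# Zhang-Suen thinning
# ---------------------------------------------------------------------------

def _neighbours(img: np.ndarray):
    """P2..P9 planes (N, NE, E, SE, S, SW, W, NW) for a 0-padded image."""
    p = np.pad(img, 1)
    H, W = img.shape
    P2 = p[0:H, 1:W + 1]
    P3 = p[0:H, 2:W + 2]
    P4 = p[1:H + 1, 2:W + 2]
    P5 = p[2:H + 2, 2:W + 2]
    P6 = p[2:H + 2, 1:W + 1]
    P7 = p[2:H + 2, 0:W]
    P8 = p[1:H + 1, 0:W]
    P9 = p[0:H, 0:W]
    return P2, P3, P4, P5, P6, P7, P8, P9


def zhang_suen_thin(mask: np.ndarray) -> Skeleton:
    """Classic two-subiteration Zhang-Suen thinning, run to a fixed point.

    Each subiteration deletes, in parallel, the foreground pixels whose
    8-neighbour count B is in [2, 6], whose circular 0->1 transition count A
    equals 1, and whose two directional products (P2*P4*P6, P4*P6*P8 in the
    first subiteration; P2*P4*P8, P2*P6*P8 in the second) are zero.  Iterates
    until no pixel is corroded.
    """
    img = np.asarray(mask).astype(bool).astype(np.uint8)
    while True:
        changed = False
        for sub in (0, 1):
            P = _neighbours(img)
            seq = np.stack(P, axis=0).astype(np.int8)
            B = seq.sum(axis=0)
            nxt = np.roll(seq, -1, axis=0)
            A = ((seq == 0) & (nxt == 1)).sum(axis=0)
            P2, P3, P4, P5, P6, P7, P8, P9 = P
            if sub == 0:
                c1 = P2 * P4 * P6 == 0
                c2 = P4 * P6 * P8 == 0
            else:
                c1 = P2 * P4 * P8 == 0
                c2 = P2 * P6 * P8 == 0
            kill = (img == 1) & (B >= 2) & (B <= 6) & (A == 1) & c1 & c2
            if kill.any():
                img[kill] = 0
                changed = True
        if not changed:
            break
    return Skeleton(grid=img.astype(bool))


_COUNT_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def neighbour_counts(grid: np.ndarray) -> np.ndarray:
    """8-neighbour count for every pixel (the 3x3 area minus the center)."""
    return ndimage.convolve(grid.astype(np.uint8), _COUNT_KERNEL,
                            mode="constant", cval=0)


def classify_skeleton_points(skel: Skeleton) -> list[GraphNode]:
    """Endpoints (n=1), intersections (n>=3) and isolated pixels (n=0).

    Adjacent intersection pixels are merged into a single node at the cluster
    centroid.  Warns if the input does not look thinned (contains a 2x2 solid
    block).
    """
    grid = skel.grid
    g = grid.astype(np.uint8)
    if ((g[:-1, :-1] & g[:-1, 1:] & g[1:, :-1] & g[1:, 1:]) == 1).any():
        warnings.warn("input skeleton contains a 2x2 solid block; "
                      "did you run zhang_suen_thin?", stacklevel=2)
    counts = neighbour_counts(grid)
    nodes: list[GraphNode] = []

    iso = grid & (counts == 0)
    ends = grid & (counts == 1)
    inter = grid & (counts >= 3)

    for r, c in np.argwhere(iso):
        nodes.append(GraphNode(len(nodes), (float(r), float(c)), "isolated",
                               [(int(r), int(c))]))
    for r, c in np.argwhere(ends):
        nodes.append(GraphNode(len(nodes), (float(r), float(c)), "endpoint",
                               [(int(r), int(c))]))
    # merge 8-connected clusters of intersection pixels into one node each
    lab, nlab = ndimage.label(inter, structure=np.ones((3, 3), dtype=int))
    for k in range(1, nlab + 1):
        pix = np.argwhere(lab == k)
        centroid = tuple(pix.mean(axis=0))
        nodes.append(GraphNode(len(nodes), centroid, "bifurcation",
                               [tuple(map(int, p)) for p in pix]))
    return nodes


_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def trace_segments(skel: Skeleton, nodes: list[GraphNode]) -> VesselGraph:
    """Walk from node pixels along unvisited skeleton pixels to the next node.

    Every segment is listed once, oriented from the lower node id to the
    higher.  A skeleton cycle containing no node gets one synthetic break
    node so it can be represented as a single closed segment.
    """
    grid = skel.grid
    H, W = grid.shape
    node_of_pixel: dict[tuple[int, int], int] = {}
    for n in nodes:
        for p in n.pixels:
            node_of_pixel[p] = n.id
    nodes = list(nodes)

    visited = np.zeros_like(grid, dtype=bool)
    for p in node_of_pixel:
        visited[p] = True

    def nbrs(p):
        r, c = p
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and grid[rr, cc]:
                yield (rr, cc)

    segments: list[GraphSegment] = []

    def walk(start_node: int, first: tuple[int, int]):
        """Trace from a node through `first` until another node pixel."""
        path = [first]
        visited[first] = True
        prev = None
        cur = first
        while True:
            nxt_node = None
            nxt_free = None
            for q in nbrs(cur):
                if q == prev:
                    continue
                if q in node_of_pixel:
                    # avoid immediately re-entering the starting node cluster
                    if len(path) == 1 and node_of_pixel[q] == start_node:
                        continue
                    nxt_node = q
                elif not visited[q]:
                    nxt_free = q
            if nxt_node is not None:
                end_node = node_of_pixel[nxt_node]
                _emit(start_node, end_node, path)
                return
            if nxt_free is None:
                # dead end without node pixel (shouldn't happen on clean input)
                end = path[-1]
                nid = len(nodes)
                nodes.append(GraphNode(nid, (float(end[0]), float(end[1])),
                                       "endpoint", [end]))
                node_of_pixel[end] = nid
                _emit(start_node, nid, path[:-1])
                return
            prev, cur = cur, nxt_free
            path.append(cur)
            visited[cur] = True

    def _emit(a: int, b: int, interior):
        pts = ([tuple(map(int, np.round(nodes[a].pos)))] + list(interior)
               + [tuple(map(int, np.round(nodes[b].pos)))])
        if a > b:
            a, b = b, a
            pts = pts[::-1]
        segments.append(GraphSegment(len(segments), a, b,
                                     np.asarray(pts, dtype=int)))

    for n in list(nodes):
        for p in n.pixels:
            for q in nbrs(p):
                if q not in node_of_pixel and not visited[q]:
                    walk(n.id, q)
            # direct node-to-node adjacency with no interior pixels
            for q in nbrs(p):
                if q in node_of_pixel and node_of_pixel[q] > n.id:
                    b = node_of_pixel[q]
                    if not any({s.node_a, s.node_b} == {n.id, b} and
                               len(s.points) <= 2 for s in segments):
                        _emit(n.id, b, [])

    # leftover pixels belong to node-free cycles: break each with a synthetic node
    leftover = grid & ~visited
    while leftover.any():
        start = tuple(np.argwhere(leftover)[0])
        nid = len(nodes)
        nodes.append(GraphNode(nid, (float(start[0]), float(start[1])),
                               "break", [start]))
        node_of_pixel[start] = nid
        visited[start] = True
        first = next((q for q in nbrs(start) if not visited[q]), None)
        if first is not None:
            walk(nid, first)
        leftover = grid & ~visited

    return VesselGraph(nodes=nodes, segments=segments, shape=grid.shape)


def skeleton_to_graph(mask: np.ndarray,
                      roi: tuple[int, int, int, int] | None = None,
                      prune: bool = True,
                      min_spur_len: float = 10.0,
                      merge_dist: float = 4.0) -> VesselGraph:
    """mask -> thin -> classify -> trace, optionally cropped to a (r0, c0, r1, c1) ROI.

    The ROI stands in for the manually outlined optic-disc region: pixels
    outside it are cleared before skeletonization, coordinates stay global.
    ``prune`` cleans junction-scale thinning artifacts (see :func:`prune_graph`).
    """
    mask = np.asarray(mask).astype(bool)
    if roi is not None:
        r0, c0, r1, c1 = roi
        m = np.zeros_like(mask)
        m[r0:r1, c0:c1] = mask[r0:r1, c0:c1]
        mask = m
    skel = zhang_suen_thin(mask)
    nodes = classify_skeleton_points(skel)
    graph = trace_segments(skel, nodes)
    if prune:
        graph = prune_graph(graph, min_spur_len=min_spur_len,
                            merge_dist=merge_dist)
    return graph


def _segment_length(seg: GraphSegment) -> float:
    pts = seg.points.astype(float)
    if len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def prune_graph(graph: VesselGraph, min_spur_len: float = 10.0,
                merge_dist: float = 4.0) -> VesselGraph:
    """Clean thinning artifacts: drop short spurs, contract short
    junction-junction links, and dissolve the degree-2 nodes left behind.

    Junction neighbourhoods of thick vessels skeletonize into clusters of
    spurious nodes and stub segments on the scale of the vessel radius; this
    pass recovers the intended branch topology.  Iterates to a fixed point.
    """
    nodes = {n.id: GraphNode(n.id, n.pos, n.kind, list(n.pixels))
             for n in graph.nodes}
    segs: dict[int, GraphSegment] = {
        s.id: GraphSegment(s.id, s.node_a, s.node_b, s.points.copy())
        for s in graph.segments}

    def degree(nid):
        return sum((s.node_a == nid) + (s.node_b == nid) for s in segs.values())

    changed = True
    while changed:
        changed = False
        # 1. spurs: a short segment whose one end is a leaf and whose other
        #    end is a junction (degree >= 3)
        for sid, s in list(segs.items()):
            da, db = degree(s.node_a), degree(s.node_b)
            if _segment_length(s) < min_spur_len and (
                    (da == 1 and db >= 3) or (db == 1 and da >= 3)):
                leaf = s.node_a if da == 1 else s.node_b
                del segs[sid]
                nodes.pop(leaf, None)
                changed = True
        # 2. contract short junction-junction segments into one node
        for sid, s in list(segs.items()):
            if s.node_a == s.node_b:
                continue
            if (_segment_length(s) < merge_dist
                    and degree(s.node_a) >= 3 and degree(s.node_b) >= 3):
                keep, drop = s.node_a, s.node_b
                pa = np.asarray(nodes[keep].pos)
                pb = np.asarray(nodes[drop].pos)
                nodes[keep] = GraphNode(keep, tuple((pa + pb) / 2.0),
                                        "bifurcation",
                                        nodes[keep].pixels + nodes[drop].pixels)
                del segs[sid]
                nodes.pop(drop, None)
                for t in segs.values():
                    if t.node_a == drop:
                        t.node_a = keep
                    if t.node_b == drop:
                        t.node_b = keep
                # drop degenerate self-loops created by chain contraction
                for tid, t in list(segs.items()):
                    if t.node_a == t.node_b and _segment_length(t) < merge_dist:
                        del segs[tid]
                changed = True
                break
        # 3. dissolve degree-2 nodes: join their two segments end to end
        for nid in list(nodes):
            incident = [s for s in segs.values()
                        if nid in (s.node_a, s.node_b)]
            if len(incident) != 2 or incident[0].id == incident[1].id:
                continue
            s1, s2 = incident
            if s1.node_a == s1.node_b or s2.node_a == s2.node_b:
                continue  # self-loop: keep the break node
            p1 = s1.points if s1.node_b == nid else s1.points[::-1]
            a = s1.node_a if s1.node_b == nid else s1.node_b
            p2 = s2.points if s2.node_a == nid else s2.points[::-1]
            b = s2.node_b if s2.node_a == nid else s2.node_a
            merged = np.concatenate([p1, p2[1:]], axis=0)
            if a > b:
                a, b = b, a
                merged = merged[::-1]
            new = GraphSegment(s1.id, a, b, merged)
            del segs[s2.id]
            segs[s1.id] = new
            del nodes[nid]
            changed = True
            break

    # compact ids
    id_map = {old: i for i, old in enumerate(sorted(nodes))}
    out_nodes = []
    for old in sorted(nodes):
        n = nodes[old]
        deg = sum((s.node_a == old) + (s.node_b == old) for s in segs.values())
        kind = ("endpoint" if deg == 1 else
                "bifurcation" if deg >= 3 else n.kind)
        out_nodes.append(GraphNode(id_map[old], n.pos, kind, n.pixels))
    out_segs = []
    for i, sid in enumerate(sorted(segs)):
        s = segs[sid]
        a, b = id_map[s.node_a], id_map[s.node_b]
        pts = s.points if a <= b or s.node_a == s.node_b else s.points[::-1]
        if a > b:
            a, b = b, a
        out_segs.append(GraphSegment(i, a, b, pts))
    return VesselGraph(out_nodes, out_segs, graph.shape)


def downsample_centerline(path: np.ndarray, interval: int) -> np.ndarray:
    """Keep indices 0, interval, 2*interval, ... and always the last point."""
    path = np.asarray(path)
    if len(path) == 0:
        raise ValueError("cannot downsample an empty path")
    if interval < 1:
        raise ValueError("interval must be >= 1")
    idx = list(range(0, len(path), interval))
    if idx[-1] != len(path) - 1:
        idx.append(len(path) - 1)
    return path[idx]
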