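"""Lofted 3D vessel surfaces from planar centerline profiles.

The centerline lives in the image plane (z = 0); the model gains its third
dimension from circular cross-sections drawn around each sampled point in the
plane normal to the local tangent.  Rings are oriented by parallel transport
(twist-minimizing), lofted into triangle strips, and the tubes meeting at a
junction are bridged by triangle fans converging on the shared junction
vertex, after the radius of any protruding contour has been pulled toward the
junction median.  Local Laplacian smoothing fairs the junction regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from fvs3d.profiling import CenterlineProfile, ProfiledSegment

WALL, CAP_INLET, CAP_OUTLET = 0, 1, 2


@dataclass
class Contour:
    """Circular cross-section: a ring of n_pts vertices around a 3D center."""

    center: np.ndarray   # (3,)
    radius: float
    tangent: np.ndarray  # (3,) unit
    ring: np.ndarray     # (n_pts, 3)


@dataclass
class VesselSurfaceMesh:
    vertices: np.ndarray       # (V, 3)
    triangles: np.ndarray      # (F, 3) int
    face_labels: np.ndarray    # (F,) int: WALL / CAP_INLET / CAP_OUTLET
    inlet_node: int | None = None
    outlet_nodes: list[int] = field(default_factory=list)

    def to_trimesh(self, process: bool = False) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices.copy(),
                               faces=self.triangles.copy(), process=process)

    def wall_triangles(self) -> np.ndarray:
        return self.triangles[self.face_labels == WALL]

    def boundary_edge_count(self) -> int:
        return count_boundary_edges(self.triangles)

    def euler_characteristic(self) -> int:
        V = len(np.unique(self.triangles))
        edges = np.sort(self.triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        E = len(np.unique(edges, axis=0))
        return V - E + len(self.triangles)


def count_boundary_edges(triangles: np.ndarray) -> int:
    """Edges referenced by exactly one triangle."""
    edges = np.sort(np.asarray(triangles)[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int((counts == 1).sum())


def _to_3d(points_rc: np.ndarray, px_size: float = 1.0) -> np.ndarray:
    """(row, col) image points -> (x, y, 0) with x = col, y = row."""
    pts = np.asarray(points_rc, dtype=float)
    return np.stack([pts[:, 1], pts[:, 0], np.zeros(len(pts))], axis=1) * px_size


def _transport_frame(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Parallel-transport an initial orthonormal (u, v) frame along tangents."""
    t0 = tangents[0]
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, t0)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(t0, ref)
    u /= np.linalg.norm(u)
    v = np.cross(t0, u)
    us, vs = [u], [v]
    for i in range(1, len(tangents)):
        a, b = tangents[i - 1], tangents[i]
        axis = np.cross(a, b)
        s = np.linalg.norm(axis)
        c = float(np.clip(np.dot(a, b), -1.0, 1.0))
        if s < 1e-12:
            us.append(us[-1])
            vs.append(vs[-1])
            continue
        axis = axis / s
        ang = np.arctan2(s, c)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        Rm = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        us.append(Rm @ us[-1])
        vs.append(Rm @ vs[-1])
    return np.asarray(us), np.asarray(vs)


def _rings_cross(c1: Contour, c2: Contour) -> bool:
    """True if ring 2 pokes behind ring 1's plane or vice versa (crossover)."""
    behind2 = ((c2.ring - c1.center) @ c1.tangent <= 1e-9).any()
    ahead1 = ((c1.ring - c2.center) @ c2.tangent >= -1e-9).any()
    return behind2 or ahead1


def build_contours(profile: CenterlineProfile, n_pts: int = 24
                   ) -> list[list[Contour]]:
    """One ring per sampled centerline point, per segment.

    Ring orientation is propagated by parallel transport of the first ring's
    frame to minimize twist.  If two consecutive rings intersect, the interior
    offender is dropped (local re-downsampling) until successive contours no
    longer cross; the first and last contours of a segment are always kept.
    """
    if n_pts < 8:
        raise ValueError("n_pts must be >= 8")
    theta = 2 * np.pi * np.arange(n_pts) / n_pts
    out: list[list[Contour]] = []
    for seg in profile.segments:
        if (seg.radii <= 0).any():
            bad = int(np.argmax(seg.radii <= 0))
            raise ValueError(
                f"segment {seg.seg_id} has non-positive radius at sample {bad}")
        centers = _to_3d(seg.points, profile.px_size)
        t2 = seg.tangents
        tangents = np.stack([t2[:, 1], t2[:, 0], np.zeros(len(t2))], axis=1)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        us, vs = _transport_frame(tangents)
        radii = seg.radii * profile.px_size
        rings = []
        for i in range(len(centers)):
            ring = (centers[i][None, :]
                    + radii[i] * (np.cos(theta)[:, None] * us[i][None, :]
                                  + np.sin(theta)[:, None] * vs[i][None, :]))
            rings.append(Contour(centers[i], float(radii[i]), tangents[i], ring))
        # local re-downsampling: greedily keep rings that do not cross the
        # previous kept ring; the final ring always survives
        kept = [rings[0]]
        for i in range(1, len(rings) - 1):
            if not _rings_cross(kept[-1], rings[i]):
                kept.append(rings[i])
        if len(rings) > 1:
            while len(kept) > 1 and _rings_cross(kept[-1], rings[-1]):
                kept.pop()
            kept.append(rings[-1])
        out.append(kept)
    return out


def loft_segment(contours: list[Contour]) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate between consecutive rings: 2*n_pts*(k-1) triangles.

    Ring i vertex j connects to ring i+1 vertices {j, j+1 mod n_pts}.
    Returns (vertices, triangles) of the open tube.
    """
    if len(contours) < 2:
        raise ValueError("need at least 2 contours to loft")
    n = len(contours[0].ring)
    if any(len(c.ring) != n for c in contours):
        raise ValueError("all contours must share the same n_pts")
    verts = np.concatenate([c.ring for c in contours], axis=0)
    faces = []
    for i in range(len(contours) - 1):
        a = i * n
        b = (i + 1) * n
        for j in range(n):
            jn = (j + 1) % n
            faces.append([a + j, b + j, b + jn])
            faces.append([a + j, b + jn, a + jn])
    return verts, np.asarray(faces, dtype=int)


def _fan(ring_idx: np.ndarray, apex_idx: int, flip: bool) -> np.ndarray:
    n = len(ring_idx)
    tris = []
    for j in range(n):
        jn = (j + 1) % n
        if flip:
            tris.append([ring_idx[jn], ring_idx[j], apex_idx])
        else:
            tris.append([ring_idx[j], ring_idx[jn], apex_idx])
    return np.asarray(tris, dtype=int)


def _signed_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def repair_junctions(contours_per_segment: list[list[Contour]],
                     profile: CenterlineProfile,
                     radius_ratio_threshold: float = 1.5,
                     inlet_node: int | None = None) -> VesselSurfaceMesh:
    """Adjust protruding junction contours, loft and merge into one mesh.

    At each junction the terminal contours of the incident segments are
    compared; while the max/min radius ratio exceeds the threshold, the
    contour deviating most from the junction median is pulled toward the
    median (this removes the protruding silhouette).  Tubes are then lofted
    and bridged at each junction by triangle fans meeting at the shared
    junction vertex, and capped at endpoints, so the merged wall has no
    boundary edges.  Endpoint caps are labelled inlet/outlet.
    """
    segs = profile.segments
    # junction node -> [(segment index, end)] with end 0 = first ring, -1 = last
    incident: dict[int, list[tuple[int, int]]] = {}
    for si, seg in enumerate(segs):
        for node, end in ((seg.node_a, 0), (seg.node_b, -1)):
            incident.setdefault(node, []).append((si, end))

    for node, ends in incident.items():
        if len(ends) < 2:
            continue
        radii = np.array([contours_per_segment[si][end].radius for si, end in ends])
        if radii.min() <= 0:
            continue
        med = float(np.median(radii))
        guard = 0
        while radii.max() / radii.min() > radius_ratio_threshold and guard < 64:
            k = int(np.argmax(np.abs(radii - med)))
            radii[k] = 0.5 * (radii[k] + med)
            guard += 1
        for (si, end), r_new in zip(ends, radii):
            c = contours_per_segment[si][end]
            if abs(r_new - c.radius) > 1e-12:
                ring = c.center + (c.ring - c.center) * (r_new / c.radius)
                contours_per_segment[si][end] = Contour(c.center, float(r_new),
                                                        c.tangent, ring)

    # choose inlet: endpoint node whose terminal contour radius is largest
    endpoint_nodes = [n for n, ends in incident.items() if len(ends) == 1]
    if inlet_node is None and endpoint_nodes:
        inlet_node = max(
            endpoint_nodes,
            key=lambda n: contours_per_segment[incident[n][0][0]][incident[n][0][1]].radius)

    all_verts: list[np.ndarray] = []
    all_faces: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    outlet_nodes: list[int] = []

    node_positions = {}
    for node, ends in incident.items():
        si, end = ends[0]
        node_positions[node] = contours_per_segment[si][end].center

    for si, contours in enumerate(contours_per_segment):
        base = sum(len(v) for v in all_verts)
        verts, faces = loft_segment(contours)
        n = len(contours[0].ring)
        labels = [np.full(len(faces), WALL)]
        faces = [faces]
        extra_verts = [verts]
        for node, end in ((segs[si].node_a, 0), (segs[si].node_b, -1)):
            ring_idx = (np.arange(n) if end == 0
                        else np.arange(len(verts) - n, len(verts)))
            apex_local = len(np.concatenate(extra_verts))
            is_junction = len(incident[node]) > 1
            apex = (node_positions[node] if is_junction
                    else contours[end].center)
            extra_verts.append(apex[None, :])
            flip = end == 0
            fan = _fan(ring_idx, apex_local, flip)
            faces.append(fan)
            if is_junction:
                labels.append(np.full(len(fan), WALL))
            elif node == inlet_node:
                labels.append(np.full(len(fan), CAP_INLET))
            else:
                labels.append(np.full(len(fan), CAP_OUTLET))
                if node not in outlet_nodes:
                    outlet_nodes.append(node)
        v = np.concatenate(extra_verts, axis=0)
        f = np.concatenate(faces, axis=0)
        lab = np.concatenate(labels)
        # enforce consistent outward winding on the closed component
        tm = trimesh.Trimesh(vertices=v, faces=f, process=False)
        trimesh.repair.fix_normals(tm)
        f = np.asarray(tm.faces)
        if _signed_volume(v, f) < 0:
            f = f[:, ::-1]
        all_verts.append(v)
        all_faces.append(f + base)
        all_labels.append(lab)

    mesh = VesselSurfaceMesh(
        vertices=np.concatenate(all_verts, axis=0),
        triangles=np.concatenate(all_faces, axis=0),
        face_labels=np.concatenate(all_labels),
        inlet_node=inlet_node,
        outlet_nodes=outlet_nodes,
    )
    if mesh.boundary_edge_count() > 0:
        raise RuntimeError("junction repair left boundary edges on the wall")
    return mesh


def _vertex_adjacency(triangles: np.ndarray, n_verts: int) -> list[set]:
    adj = [set() for _ in range(n_verts)]
    for a, b, c in triangles:
        adj[a].update((b, c))
        adj[b].update((a, c))
        adj[c].update((a, b))
    return adj


def laplacian_smooth(mesh: VesselSurfaceMesh, iterations: int = 5,
                     lam: float = 0.5, junction_only: bool = False,
                     junction_radius: float = 6.0) -> VesselSurfaceMesh:
    """v <- v + lam * (centroid(neighbours) - v), on all or junction vertices.

    Geometrically coincident vertices (the per-tube junction apexes that meet
    at the same point) are smoothed as one group with the union of their
    neighbourhoods, so the bridged tubes stay joined.  With ``junction_only``
    only vertices within ``junction_radius`` geodesic (edge-path) distance of
    a junction group are moved.  Vertex and triangle counts never change.
    """
    import heapq
    import warnings as _w

    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda step must be in [0, 1]")
    verts = mesh.vertices.copy()
    tris = mesh.triangles
    adj = _vertex_adjacency(tris, len(verts))
    isolated = [i for i, s in enumerate(adj) if not s]
    if isolated:
        _w.warn(f"{len(isolated)} isolated vertices skipped by smoothing")

    # group coincident vertices (junction apexes from different tubes)
    keys = {}
    group_of = np.empty(len(verts), dtype=int)
    for i, p in enumerate(np.round(verts, 6)):
        k = tuple(p)
        if k not in keys:
            keys[k] = len(keys)
        group_of[i] = keys[k]
    n_groups = len(keys)
    members: list[list[int]] = [[] for _ in range(n_groups)]
    for i, g in enumerate(group_of):
        members[g].append(i)
    gadj: list[set] = [set() for _ in range(n_groups)]
    for i, s in enumerate(adj):
        gi = group_of[i]
        for j in s:
            gj = group_of[j]
            if gi != gj:
                gadj[gi].add(gj)
    gpos = np.array([verts[m].mean(axis=0) for m in members])

    if junction_only:
        seeds = [g for g in range(n_groups) if len(members[g]) > 1]
        dist = np.full(n_groups, np.inf)
        pq = [(0.0, g) for g in seeds]
        for _, g in pq:
            dist[g] = 0.0
        heapq.heapify(pq)
        while pq:
            d, u = heapq.heappop(pq)
            if d > dist[u]:
                continue
            for w in gadj[u]:
                nd = d + float(np.linalg.norm(gpos[u] - gpos[w]))
                if nd < dist[w] and nd <= junction_radius:
                    dist[w] = nd
                    heapq.heappush(pq, (nd, w))
        move = dist <= junction_radius
    else:
        move = np.ones(n_groups, dtype=bool)
    move &= np.array([len(s) > 0 for s in gadj])

    idx = np.where(move)[0]
    for _ in range(iterations):
        new = gpos.copy()
        for g in idx:
            nb = np.fromiter(gadj[g], dtype=int)
            new[g] = gpos[g] + lam * (gpos[nb].mean(axis=0) - gpos[g])
        gpos = new
    for g, mem in enumerate(members):
        verts[mem] = gpos[g]
    return VesselSurfaceMesh(verts, tris.copy(), mesh.face_labels.copy(),
                             mesh.inlet_node, list(mesh.outlet_nodes))


def export_mesh(mesh: VesselSurfaceMesh, path: str, fmt: str | None = None,
                strict_watertight: bool = False) -> str:
    """Write STL (binary), OBJ or VTP.  Returns the path written."""
    fmt = (fmt or str(path).rsplit(".", 1)[-1]).lower()
    tm = mesh.to_trimesh()
    if strict_watertight and not tm.is_watertight:
        raise ValueError("mesh is not watertight; refusing strict export")
    if fmt in ("stl", "obj"):
        tm.export(path, file_type=fmt)
    elif fmt == "vtp":
        _write_vtp(mesh, path)
    else:
        raise ValueError(f"unknown mesh format: {fmt}")
    return str(path)


def _write_vtp(mesh: VesselSurfaceMesh, path: str) -> None:
    """Minimal ASCII VTK XML PolyData writer."""
    v = mesh.vertices
    f = mesh.triangles
    pts = " ".join(f"{x:.9g}" for x in v.ravel())
    conn = " ".join(str(i) for i in f.ravel())
    offs = " ".join(str(3 * (i + 1)) for i in range(len(f)))
    labs = " ".join(str(int(l)) for l in mesh.face_labels)
    with open(path, "w") as fh:
        fh.write(
            '<?xml version="1.0"?>\n'
            '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">\n'
            f'<PolyData><Piece NumberOfPoints="{len(v)}" NumberOfPolys="{len(f)}">\n'
            '<Points><DataArray type="Float64" NumberOfComponents="3" '
            f'format="ascii">{pts}</DataArray></Points>\n'
            '<CellData Scalars="face_label"><DataArray type="Int32" '
            f'Name="face_label" format="ascii">{labs}</DataArray></CellData>\n'
            '<Polys><DataArray type="Int64" Name="connectivity" '
            f'format="ascii">{conn}</DataArray>'
            '<DataArray type="Int64" Name="offsets" '
            f'format="ascii">{offs}</DataArray></Polys>\n'
            '</Piece></PolyData></VTKFile>\n')


def build_surface(profile: CenterlineProfile, n_pts: int = 24,
                  radius_ratio_threshold: float = 1.5,
                  smooth_iterations: int = 3, smooth_lambda: float = 0.5,
                  inlet_node: int | None = None) -> VesselSurfaceMesh:
    """Full surface stage: contours -> junction repair/merge -> local smoothing."""
    contours = build_contours(profile, n_pts=n_pts)
    mesh = repair_junctions(contours, profile, radius_ratio_threshold,
                            inlet_node=inlet_node)
    if smooth_iterations > 0:
        mesh = laplacian_smooth(mesh, iterations=smooth_iterations,
                                lam=smooth_lambda, junction_only=True)
    return mesh
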