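"""Contours, lofting, junction repair, smoothing and mesh export."""

import numpy as np
import pytest

from fvs3d import profiling as prof
from fvs3d import surface as surf
from fvs3d.profiling import CenterlineProfile, ProfiledSegment
from fvs3d.skeleton import skeleton_to_graph
from fvs3d.synthetic import rasterize_tree_mask
from tests.conftest import straight_tube_tree


def line_profile(radius=2.0, n=33, length=10.0, row=0.0):
    """Straight synthetic profile along +col (x axis), constant radius."""
    cols = np.linspace(0.0, length, n)
    pts = np.stack([np.full(n, row), cols], axis=1)
    tangents = np.tile([0.0, 1.0], (n, 1))
    normals = np.tile([1.0, 0.0], (n, 1))
    seg = ProfiledSegment(0, 0, 1, pts, tangents, normals,
                          np.full(n, radius), np.zeros(n, bool))
    return CenterlineProfile([seg], px_size=1.0, shape=(64, 64))


def y_profile(r_parent=4.0, r_daughter=3.2):
    """Symmetric Y: parent along +col, two daughters at +-45 degrees."""
    def seg(i, a, b, p0, direction, n, radius):
        d = np.asarray(direction) / np.linalg.norm(direction)
        pts = np.asarray(p0) + np.outer(np.arange(n, dtype=float) * 2.0, d)
        tangents = np.tile(d, (n, 1))
        normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
        normals = np.stack([tangents[:, 1], -tangents[:, 0]], axis=1)
        normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
        return ProfiledSegment(i, a, b, pts, tangents, normals,
                               np.full(n, radius), np.zeros(n, bool))

    parent = seg(0, 0, 1, (40.0, 5.0), (0.0, 1.0), 12, r_parent)
    tip = parent.points[-1]
    d1 = seg(1, 1, 2, tip, (1.0, 1.0), 10, r_daughter)
    d2 = seg(2, 1, 3, tip, (-1.0, 1.0), 10, r_daughter)
    return CenterlineProfile([parent, d1, d2], px_size=1.0, shape=(96, 96))


class TestBuildContours:
    def test_straight_segment_rings_in_normal_planes(self):
        contours = surf.build_contours(line_profile(radius=2.0), n_pts=16)[0]
        for c in contours:
            d = np.linalg.norm(c.ring - c.center, axis=1)
            assert np.allclose(d, 2.0, rtol=1e-9)
            # ring plane perpendicular to tangent (x axis here)
            assert np.allclose((c.ring - c.center) @ c.tangent, 0.0, atol=1e-9)

    def test_octagon_perimeter_closed_form(self):
        contours = surf.build_contours(line_profile(radius=1.0), n_pts=8)[0]
        ring = contours[0].ring
        per = np.linalg.norm(np.roll(ring, -1, axis=0) - ring, axis=1).sum()
        assert per == pytest.approx(8 * 2 * np.sin(np.pi / 8), rel=1e-12)

    def test_crossover_triggers_local_redownsampling(self):
        # dense samples with jagged tangent estimates (the situation a noisy
        # pixel centerline produces): adjacent tilted rings intersect unless
        # intermediate contours are dropped
        n = 40
        pts = np.stack([np.full(n, 20.0), 5.0 + 0.5 * np.arange(n)], axis=1)
        ang = np.where(np.arange(n) % 2 == 0, np.deg2rad(20), np.deg2rad(-20))
        tangents = np.stack([np.sin(ang), np.cos(ang)], axis=1)
        normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
        seg = ProfiledSegment(0, 0, 1, pts, tangents, normals,
                              np.full(n, 4.0), np.zeros(n, bool))
        p = CenterlineProfile([seg], px_size=1.0, shape=(64, 64))
        contours = surf.build_contours(p, n_pts=12)[0]
        for a, b in zip(contours[:-1], contours[1:]):
            assert not surf._rings_cross(a, b)
        assert len(contours) < n

    def test_nonpositive_radius_rejected(self):
        p = line_profile()
        p.segments[0].radii[3] = 0.0
        with pytest.raises(ValueError, match="segment 0"):
            surf.build_contours(p)

    def test_min_ring_points_enforced(self):
        with pytest.raises(ValueError):
            surf.build_contours(line_profile(), n_pts=4)


class TestLoftSegment:
    def test_triangle_count_formula(self):
        contours = surf.build_contours(line_profile(n=2), n_pts=8)[0]
        _, faces = surf.loft_segment(contours)
        assert len(faces) == 16  # 2 * n_pts * (k-1)

    def test_cylinder_lateral_area(self):
        p = line_profile(radius=1.0, n=33, length=10.0)
        contours = surf.build_contours(p, n_pts=32)[0]
        verts, faces = surf.loft_segment(contours)
        a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
        area = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum()
        assert area == pytest.approx(2 * np.pi * 1.0 * 10.0, rel=0.02)

    def test_lateral_area_converges_with_resolution(self):
        exact = 2 * np.pi * 10.0
        errs = []
        for n_pts, k in [(8, 5), (16, 9), (32, 33)]:
            p = line_profile(radius=1.0, n=k, length=10.0)
            contours = surf.build_contours(p, n_pts=n_pts)[0]
            verts, faces = surf.loft_segment(contours)
            a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
            area = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum()
            errs.append(abs(area - exact))
        assert errs[0] > errs[1] > errs[2]

    def test_mismatched_ring_sizes_rejected(self):
        c8 = surf.build_contours(line_profile(n=2), n_pts=8)[0]
        c16 = surf.build_contours(line_profile(n=2), n_pts=16)[0]
        with pytest.raises(ValueError):
            surf.loft_segment([c8[0], c16[1]])


def _capped_tube_mesh(radius=1.0, n=17, n_pts=16):
    p = line_profile(radius=radius, n=n)
    contours = surf.build_contours(p, n_pts=n_pts)
    return surf.repair_junctions(contours, p)


class TestMergedMesh:
    def test_capped_cylinder_is_watertight_sphere_topology(self):
        mesh = _capped_tube_mesh()
        assert mesh.boundary_edge_count() == 0
        assert mesh.euler_characteristic() == 2
        tm = mesh.to_trimesh()
        assert tm.is_watertight
        assert tm.volume > 0

    def test_symmetric_y_equal_radii_unadjusted(self):
        p = y_profile(r_parent=3.0, r_daughter=3.0)
        contours = surf.build_contours(p, n_pts=12)
        before = [[c.radius for c in seg] for seg in contours]
        mesh = surf.repair_junctions(contours, p, radius_ratio_threshold=1.5)
        after = [[c.radius for c in seg] for seg in contours]
        assert before == after
        assert mesh.boundary_edge_count() == 0

    def test_over_threshold_y_repaired_no_boundary_edges(self):
        p = y_profile(r_parent=5.0, r_daughter=2.0)
        contours = surf.build_contours(p, n_pts=12)
        mesh = surf.repair_junctions(contours, p, radius_ratio_threshold=1.5)
        # protruding parent contour pulled toward the junction median
        junction_radii = [contours[0][-1].radius, contours[1][0].radius,
                          contours[2][0].radius]
        assert max(junction_radii) / min(junction_radii) <= 1.5 + 1e-9
        assert mesh.boundary_edge_count() == 0
        assert mesh.to_trimesh().is_watertight

    def test_infinite_threshold_leaves_radii_untouched(self):
        p = y_profile(r_parent=5.0, r_daughter=2.0)
        contours = surf.build_contours(p, n_pts=12)
        before = [[c.radius for c in seg] for seg in contours]
        surf.repair_junctions(contours, p, radius_ratio_threshold=np.inf)
        after = [[c.radius for c in seg] for seg in contours]
        assert before == after

    def test_inlet_and_outlet_faces_labelled(self):
        p = y_profile()
        contours = surf.build_contours(p, n_pts=12)
        mesh = surf.repair_junctions(contours, p)
        labels = set(mesh.face_labels.tolist())
        assert {surf.WALL, surf.CAP_INLET, surf.CAP_OUTLET} <= labels
        assert mesh.inlet_node == 0  # widest terminal contour (parent root)
        assert sorted(mesh.outlet_nodes) == [2, 3]


class TestLaplacianSmooth:
    def test_lambda_zero_is_identity(self):
        mesh = _capped_tube_mesh()
        out = surf.laplacian_smooth(mesh, iterations=3, lam=0.0)
        assert np.allclose(out.vertices, mesh.vertices)

    def test_vertex_at_neighbour_centroid_is_fixed_point(self):
        # regular octahedron: every vertex sits at its neighbours' centroid
        # only after centering; use a single step on a symmetric mesh
        verts = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                          [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
        tris = np.array([[0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
                         [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5]])
        mesh = surf.VesselSurfaceMesh(verts, tris, np.zeros(len(tris), int))
        out = surf.laplacian_smooth(mesh, iterations=1, lam=1.0)
        # all neighbour centroids lie at the origin-symmetric positions:
        # every vertex moves straight toward the origin, none sideways
        assert np.allclose(np.cross(out.vertices, mesh.vertices), 0.0, atol=1e-12)

    def test_volume_strictly_decreases_each_iteration(self):
        mesh = _capped_tube_mesh(radius=2.0)
        vols = [mesh.to_trimesh().volume]
        cur = mesh
        for _ in range(5):
            cur = surf.laplacian_smooth(cur, iterations=1, lam=0.5)
            vols.append(cur.to_trimesh().volume)
        assert all(b < a for a, b in zip(vols[:-1], vols[1:]))

    def test_topology_unchanged(self):
        mesh = _capped_tube_mesh()
        out = surf.laplacian_smooth(mesh, iterations=4, lam=0.5,
                                    junction_only=False)
        assert out.vertices.shape == mesh.vertices.shape
        assert (out.triangles == mesh.triangles).all()

    def test_junction_only_moves_only_junction_neighbourhood(self):
        p = y_profile()
        contours = surf.build_contours(p, n_pts=12)
        mesh = surf.repair_junctions(contours, p)
        out = surf.laplacian_smooth(mesh, iterations=2, lam=0.5,
                                    junction_only=True, junction_radius=4.0)
        moved = np.linalg.norm(out.vertices - mesh.vertices, axis=1) > 1e-12
        assert moved.any() and not moved.all()


class TestExport:
    def test_stl_roundtrip_triangle_count(self, tmp_path):
        import trimesh

        mesh = _capped_tube_mesh()
        path = surf.export_mesh(mesh, tmp_path / "tube.stl")
        back = trimesh.load(path)
        assert len(back.faces) == len(mesh.triangles)

    def test_obj_roundtrip_vertex_coordinates(self, tmp_path):
        import trimesh

        mesh = _capped_tube_mesh()
        path = surf.export_mesh(mesh, tmp_path / "tube.obj")
        back = trimesh.load(path, process=False)
        assert np.allclose(np.asarray(back.vertices), mesh.vertices, atol=1e-6)

    def test_vtp_written_with_labels(self, tmp_path):
        mesh = _capped_tube_mesh()
        path = surf.export_mesh(mesh, tmp_path / "tube.vtp")
        text = (tmp_path / "tube.vtp").read_text()
        assert "PolyData" in text and "face_label" in text

    def test_strict_export_refuses_open_mesh(self, tmp_path):
        p = line_profile(n=5)
        contours = surf.build_contours(p, n_pts=8)[0]
        verts, faces = surf.loft_segment(contours)  # open tube
        open_mesh = surf.VesselSurfaceMesh(verts, faces,
                                           np.zeros(len(faces), int))
        with pytest.raises(ValueError, match="watertight"):
            surf.export_mesh(open_mesh, tmp_path / "open.stl",
                             strict_watertight=True)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            surf.export_mesh(_capped_tube_mesh(), tmp_path / "m.xyz")


class TestEndToEndSurface:
    def test_synthetic_tree_surface_watertight(self):
        from fvs3d.synthetic import generate_vessel_tree

        tree = generate_vessel_tree(seed=1)
        mask = rasterize_tree_mask(tree)
        graph = skeleton_to_graph(mask)
        profile = prof.profile_graph(graph, prof.edges_from_mask(mask))
        mesh = surf.build_surface(profile)
        assert mesh.boundary_edge_count() == 0
        assert mesh.to_trimesh().is_watertight
        assert mesh.to_trimesh().volume > 0
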