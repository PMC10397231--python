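"""Triangle mesh quality indicators.

Four standard simulation-suite indicators, each anchored so an equilateral
triangle scores the ideal value:

* element quality  = 4*sqrt(3) * area / sum(l_i^2)        (best 1, worst 0)
* aspect ratio     = R / (2 r), circumradius over twice inradius (best 1)
* maximum angle    = largest interior angle in degrees     (best 60)
* skewness         = max((th_max - 60)/120, (60 - th_min)/60)  (best 0)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_EQ_NORM = 4.0 * np.sqrt(3.0)  # makes element quality of an equilateral = 1


@dataclass(frozen=True)
class TriangleQuality:
    element_quality: float  # in [0, 1]
    aspect_ratio: float     # >= 1
    max_angle: float        # degrees, (0, 180)
    skewness: float         # in [0, 1]


def triangle_metrics(p1, p2, p3) -> TriangleQuality:
    """Quality indicators of one (possibly 3D) triangle.

    Raises on degenerate (collinear) input.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    e = np.array([p3 - p2, p1 - p3, p2 - p1])
    lengths = np.linalg.norm(e, axis=1)
    a, b, c = lengths
    area = 0.5 * np.linalg.norm(np.cross(p2 - p1, p3 - p1))
    if area <= 0 or lengths.min() == 0:
        raise ValueError("degenerate (collinear) triangle")

    eq = _EQ_NORM * area / float((lengths ** 2).sum())
    s = lengths.sum() / 2.0
    inradius = area / s
    circumradius = a * b * c / (4.0 * area)
    aspect = circumradius / (2.0 * inradius)

    # interior angles from the law of cosines
    cos_angles = np.array([
        (b * b + c * c - a * a) / (2 * b * c),
        (a * a + c * c - b * b) / (2 * a * c),
        (a * a + b * b - c * c) / (2 * a * b),
    ])
    angles = np.degrees(np.arccos(np.clip(cos_angles, -1.0, 1.0)))
    th_max, th_min = float(angles.max()), float(angles.min())
    skew = max((th_max - 60.0) / 120.0, (60.0 - th_min) / 60.0)
    return TriangleQuality(float(eq), float(aspect), th_max, float(skew))


def _batch_metrics(verts: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Metric rows per triangle; degenerate (zero-area) triangles are
    skipped — vertex-merging on import can collapse a fan triangle."""
    vals = []
    for a, b, c in tris:
        try:
            q = triangle_metrics(verts[a], verts[b], verts[c])
        except ValueError:
            continue
        vals.append((q.element_quality, q.aspect_ratio, q.max_angle, q.skewness))
    if not vals:
        raise ValueError("all triangles degenerate")
    return np.asarray(vals)


def mesh_quality_report(mesh, include_caps: bool = False) -> pd.DataFrame:
    """Per-metric mean and standard deviation over the wall triangles.

    ``mesh`` is a :class:`fvs3d.surface.VesselSurfaceMesh` or any object with
    ``vertices`` and ``triangles`` arrays.  Caps are excluded by default when
    face labels are available.
    """
    verts = np.asarray(mesh.vertices, dtype=float)
    # VesselSurfaceMesh stores index triples in .triangles; trimesh exposes
    # index triples as .faces (its .triangles are coordinate triples)
    if hasattr(mesh, "faces"):
        tris = np.asarray(mesh.faces, dtype=int)
    else:
        tris = np.asarray(mesh.triangles, dtype=int)
    if not include_caps and hasattr(mesh, "face_labels"):
        from fvs3d.surface import WALL
        tris = tris[np.asarray(mesh.face_labels) == WALL]
    if len(tris) == 0:
        raise ValueError("no triangles to evaluate")
    vals = _batch_metrics(verts, tris)
    names = ["element_quality", "aspect_ratio", "max_angle", "skewness"]
    return pd.DataFrame({
        "metric": names,
        "mean": vals.mean(axis=0),
        "std": vals.std(axis=0),
        "n_triangles": len(vals),
    })
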