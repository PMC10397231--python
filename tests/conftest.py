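"""Shared fixtures: analytic tubes, hand-built skeleton shapes, blob masks."""

from __future__ import annotations

import numpy as np
import pytest

from fvs3d.synthetic import GroundTruthTree, rasterize_tree_mask


def straight_tube_tree(radius: float, length: int = 120,
                       shape=(64, 160), row: float = 32.0,
                       col0: float = 20.0) -> GroundTruthTree:
    """Horizontal constant-radius tube with known centerline."""
    pts = np.stack([np.full(length, row),
                    np.arange(col0, col0 + length)], axis=1)
    return GroundTruthTree(
        segments=[(pts, np.full(length, float(radius)))],
        children={0: []}, root=(row, col0), image_size=shape)


def arc_tube_tree(radius: float, arc_radius: float = 60.0,
                  shape=(160, 160)) -> GroundTruthTree:
    """Circular-arc tube (curved fixture with analytic normals)."""
    t = np.linspace(0.0, np.pi / 1.5, 200)
    pts = np.stack([80.0 - arc_radius * np.cos(t) + 20.0,
                    30.0 + arc_radius * np.sin(t)], axis=1)
    return GroundTruthTree(
        segments=[(pts, np.full(len(pts), float(radius)))],
        children={0: []}, root=tuple(pts[0]), image_size=shape)


def tube_mask(radius: float, **kw) -> np.ndarray:
    return rasterize_tree_mask(straight_tube_tree(radius, **kw))


def random_blob_mask(rng: np.random.Generator, shape=(64, 64),
                     n_strokes: int = 3) -> np.ndarray:
    """Union of dilated random-walk strokes: elongated, vessel-like blobs."""
    m = np.zeros(shape, bool)
    for _ in range(n_strokes):
        r = rng.uniform(5, shape[0] - 5)
        c = rng.uniform(5, shape[1] - 5)
        ang = rng.uniform(0, 2 * np.pi)
        rad = int(rng.integers(1, 5))
        for _ in range(int(rng.integers(10, 40))):
            ang += rng.normal(0, 0.25)
            r += np.sin(ang)
            c += np.cos(ang)
            rr = int(round(min(max(r, 1), shape[0] - 2)))
            cc = int(round(min(max(c, 1), shape[1] - 2)))
            m[max(rr - rad, 0):rr + rad + 1, max(cc - rad, 0):cc + rad + 1] = True
    return m


@pytest.fixture
def y_skeleton() -> np.ndarray:
    """1-px Y: three arms meeting at (8, 8); center has exactly 3 neighbours."""
    g = np.zeros((16, 16), bool)
    for p in [(8, 8),
              (7, 7), (6, 6), (5, 5), (4, 4),
              (7, 9), (6, 10), (5, 11), (4, 12),
              (9, 8), (10, 8), (11, 8), (12, 8)]:
        g[p] = True
    return g


@pytest.fixture
def plus_skeleton() -> np.ndarray:
    g = np.zeros((11, 11), bool)
    g[5, 2:9] = True
    g[2:9, 5] = True
    return g


@pytest.fixture
def line_skeleton() -> np.ndarray:
    g = np.zeros((9, 20), bool)
    g[4, 3:17] = True
    return g


@pytest.fixture
def ring_skeleton() -> np.ndarray:
    """Closed 1-px diamond ring (every pixel has exactly 2 neighbours)."""
    g = np.zeros((13, 13), bool)
    c, k = 6, 5
    for r in range(13):
        for q in range(13):
            if abs(r - c) + abs(q - c) == k:
                g[r, q] = True
    return g
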