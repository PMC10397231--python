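"""Seeded synthetic fundus-like fixtures with known ground truth.

Every downstream stage of the pipeline is testable against these generators:
vascular trees with known centerlines and radii, rendered fundus-like images
with exact rasterized masks, and feature tables with planted group differences.

Conventions: pixel grid uses (row, col) with 0-based integer coordinates at
pixel centers.  Trees are planar; the 3D surface model later gains its third
dimension from circular cross-sections only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter


class TreeGenerationError(RuntimeError):
    """Raised when a tree cannot be placed inside the image bounds."""


@dataclass
class GroundTruthTree:
    """A planar vascular tree: ordered centerline points and radii per segment.

    ``segments[i]`` is ``(points, radii)`` with ``points`` an (N, 2) float
    array in (row, col) pixel coordinates and ``radii`` an (N,) positive
    array in pixels.  ``children[i]`` lists the indices of the segments that
    branch off the end of segment ``i``; segment 0 starts at ``root``.
    """

    segments: list[tuple[np.ndarray, np.ndarray]]
    children: dict[int, list[int]]
    root: tuple[float, float]
    class_label: int = 0
    image_size: tuple[int, int] = (256, 256)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def all_points(self) -> np.ndarray:
        return np.concatenate([p for p, _ in self.segments], axis=0)

    def all_radii(self) -> np.ndarray:
        return np.concatenate([r for _, r in self.segments], axis=0)

    def scaled_radii(self, factor: float) -> "GroundTruthTree":
        """Return a copy with every radius multiplied by ``factor``."""
        segs = [(p.copy(), r * factor) for p, r in self.segments]
        return GroundTruthTree(segs, dict(self.children), self.root,
                               self.class_label, self.image_size)

    def to_json(self) -> str:
        payload = {
            "root": list(self.root),
            "class_label": int(self.class_label),
            "image_size": list(self.image_size),
            "children": {str(k): v for k, v in self.children.items()},
            "segments": [
                {"points": p.tolist(), "radii": r.tolist()}
                for p, r in self.segments
            ],
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthTree":
        d = json.loads(text)
        segs = [
            (np.asarray(s["points"], dtype=float), np.asarray(s["radii"], dtype=float))
            for s in d["segments"]
        ]
        children = {int(k): list(v) for k, v in d["children"].items()}
        return cls(segs, children, tuple(d["root"]), d["class_label"],
                   tuple(d["image_size"]))


@dataclass
class SyntheticImageBundle:
    """Rendered image + exact mask + the tree that produced them."""

    image: np.ndarray          # (H, W, 3) uint8, RGB
    mask: np.ndarray           # (H, W) bool
    tree: GroundTruthTree
    seed: int = 0


def _grow_segment(rng, start, heading, length, radius, radius_end, wiggle=0.03):
    """Random-walk polyline of ~unit steps with a slowly drifting heading."""
    pts = [np.asarray(start, dtype=float)]
    ang = float(heading)
    drift = rng.normal(0.0, 0.01)
    n = max(int(round(length)), 2)
    for _ in range(n):
        ang += rng.normal(0.0, wiggle) + drift
        step = np.array([np.sin(ang), np.cos(ang)])  # (row, col)
        pts.append(pts[-1] + step)
    pts = np.asarray(pts)
    radii = np.linspace(radius, radius_end, len(pts))
    return pts, radii, ang


def generate_vessel_tree(
    image_size: tuple[int, int] = (256, 256),
    n_branch_levels: int = 3,
    root_radius: float = 8.0,
    radius_decay: float = 0.8,
    seed: int = 0,
    max_retries: int = 50,
) -> GroundTruthTree:
    """Grow a connected binary tree of smooth vessel segments.

    Daughter radius = parent radius x ``radius_decay`` at each bifurcation.
    Deterministic per seed.  Raises :class:`TreeGenerationError` if no
    placement inside the image succeeds within the retry budget.
    """
    if root_radius < 2:
        raise ValueError("root_radius must be >= 2 px")
    if n_branch_levels < 1:
        raise ValueError("n_branch_levels must be >= 1")
    if not (0.0 < radius_decay < 1.0):
        raise ValueError("radius_decay must be in (0, 1)")

    H, W = image_size
    margin = root_radius + 3.0

    def in_bounds(points, radii):
        lo = points - radii[:, None]
        hi = points + radii[:, None]
        return (lo[:, 0].min() >= 1 and lo[:, 1].min() >= 1
                and hi[:, 0].max() <= H - 2 and hi[:, 1].max() <= W - 2)

    base_len = 0.36 * min(H, W) / (1.0 + 0.35 * (n_branch_levels - 1))

    for attempt in range(max_retries):
        rng = np.random.default_rng((seed, attempt))
        root = (H / 2.0 + rng.uniform(-0.1, 0.1) * H, margin)
        segments: list[tuple[np.ndarray, np.ndarray]] = []
        children: dict[int, list[int]] = {}
        ok = True

        # (start point, heading, radius, level) queue, breadth-first
        queue = [(np.asarray(root), 0.0 + rng.normal(0, 0.1), float(root_radius), 1, None)]
        while queue:
            start, heading, radius, level, parent = queue.pop(0)
            length = base_len * rng.uniform(0.9, 1.2) * (0.9 ** (level - 1))
            pts, radii, end_ang = _grow_segment(rng, start, heading, length, radius, radius)
            if not in_bounds(pts, radii):
                ok = False
                break
            idx = len(segments)
            segments.append((pts, radii))
            children[idx] = []
            if parent is not None:
                children[parent].append(idx)
            if level < n_branch_levels:
                spread = rng.uniform(np.deg2rad(26), np.deg2rad(42))
                r_child = radius * radius_decay
                for sgn in (+1.0, -1.0):
                    queue.append((pts[-1], end_ang + sgn * spread, r_child,
                                  level + 1, idx))
        if ok:
            return GroundTruthTree(segments, children, tuple(root),
                                   image_size=tuple(image_size))
    raise TreeGenerationError(
        f"could not fit tree in image {image_size} after {max_retries} attempts")


def _tube_coverage(tree: GroundTruthTree, image_size):
    """Signed distance to the tube set per pixel: d(p) = min_s (|p - c(s)| - r(s)).

    Returns the array of min(|p - c| - r) over all dense centerline samples,
    evaluated only inside per-segment bounding boxes (np.inf elsewhere).
    """
    H, W = image_size
    sd = np.full((H, W), np.inf)
    for pts, radii in tree.segments:
        rmax = radii.max()
        r0 = max(int(np.floor(pts[:, 0].min() - rmax - 2)), 0)
        r1 = min(int(np.ceil(pts[:, 0].max() + rmax + 2)), H - 1)
        c0 = max(int(np.floor(pts[:, 1].min() - rmax - 2)), 0)
        c1 = min(int(np.ceil(pts[:, 1].max() + rmax + 2)), W - 1)
        rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
        grid = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
        # (M pixels, N samples) distance matrix, chunked over samples
        best = np.full(grid.shape[0], np.inf)
        for lo in range(0, len(pts), 512):
            hi = lo + 512
            d = np.linalg.norm(grid[:, None, :] - pts[None, lo:hi, :], axis=2)
            best = np.minimum(best, (d - radii[None, lo:hi]).min(axis=1))
        sd[r0:r1 + 1, c0:c1 + 1] = np.minimum(sd[r0:r1 + 1, c0:c1 + 1],
                                              best.reshape(rr.shape))
    return sd


def rasterize_tree_mask(tree: GroundTruthTree,
                        image_size: tuple[int, int] | None = None) -> np.ndarray:
    """Exact pixel-center rasterization of the tube set (union of capsules)."""
    size = image_size or tree.image_size
    return _tube_coverage(tree, size) <= 0.0


@dataclass
class BackgroundSpec:
    """Texture parameters for the rendered fundus background.

    The base colour is reddish (as in real fundus photographs); vessels are
    drawn darker than background predominantly in the G channel and partly in
    R, which is what makes the channel-proportion experiment meaningful.
    """

    base_rgb: tuple[float, float, float] = (185.0, 120.0, 60.0)
    noise_sigma: float = 6.0          # smoothing of the texture field, px
    noise_amplitude: float = 10.0     # peak-ish texture amplitude, intensity units
    contrast_g: float = 70.0          # centerline darkening in G
    contrast_r: float = 30.0          # centerline darkening in R
    contrast_b: float = 5.0


def render_fundus(
    tree: GroundTruthTree,
    background_spec: BackgroundSpec | None = None,
    seed: int = 0,
) -> SyntheticImageBundle:
    """Render the tree as dark tubes on a textured reddish background.

    The mask is the exact rasterization of the tube set; the image gets an
    anti-aliased soft tube profile so edges behave like real (blurred) vessel
    boundaries.
    """
    spec = background_spec or BackgroundSpec()
    H, W = tree.image_size
    rng = np.random.default_rng((seed, 0xF0))

    sd = _tube_coverage(tree, (H, W))
    mask = sd <= 0.0
    # soft coverage: 1 deep inside, linear ramp across the boundary pixel
    finite = np.isfinite(sd)
    cov = np.zeros((H, W))
    cov[finite] = np.clip(0.5 - sd[finite], 0.0, 1.0)

    texture = gaussian_filter(rng.normal(0.0, 1.0, (H, W)), spec.noise_sigma)
    if texture.std() > 0:
        texture = texture / texture.std() * spec.noise_amplitude
    image = np.zeros((H, W, 3))
    for ch, (base, contrast) in enumerate(
        zip(spec.base_rgb, (spec.contrast_r, spec.contrast_g, spec.contrast_b))
    ):
        image[:, :, ch] = base + texture - contrast * cov
    image = np.clip(image, 0, 255).astype(np.uint8)
    return SyntheticImageBundle(image=image, mask=mask, tree=tree, seed=seed)


def generate_feature_dataset(
    n_subjects: int = 20,
    n_features: int = 140,
    n_informative: int = 4,
    effect_size: float = 2.0,
    seed: int = 0,
) -> "pd.DataFrame | tuple":
    """Gaussian feature table with ``n_informative`` planted group differences.

    Returns a :class:`fvs3d.selection.FeatureTable`.  Informative features
    differ between the balanced binary classes by ``effect_size`` standard
    deviations; the rest are pure noise.
    """
    from fvs3d.selection import FeatureTable

    if n_subjects < 4:
        raise ValueError("n_subjects must be >= 4 for leave-one-out evaluation")
    if n_informative > n_features:
        raise ValueError("n_informative must be <= n_features")

    rng = np.random.default_rng(seed)
    labels = np.zeros(n_subjects, dtype=int)
    labels[n_subjects // 2:] = 1
    rng.shuffle(labels)
    X = rng.normal(0.0, 1.0, (n_subjects, n_features))
    X[labels == 1, :n_informative] += effect_size
    names = [f"f{i:04d}" for i in range(n_features)]
    df = pd.DataFrame(X, columns=names,
                      index=[f"s{i:03d}" for i in range(n_subjects)])
    return FeatureTable(features=df, labels=pd.Series(labels, index=df.index))


def make_cohort(
    n_subjects: int = 20,
    narrowed_fraction: float = 0.5,
    narrowing: float = 0.7,
    image_size: tuple[int, int] = (256, 256),
    n_branch_levels: int = 3,
    root_radius: float = 8.0,
    radius_decay: float = 0.8,
    seed: int = 0,
) -> list[SyntheticImageBundle]:
    """A two-class cohort: half the subjects have globally narrowed vessels.

    Narrowing multiplies every radius by ``narrowing`` (default 0.7),
    emulating a diffuse vasoconstrictive condition.  Class labels: 1 for
    narrowed subjects, 0 otherwise.
    """
    n_narrow = int(round(n_subjects * narrowed_fraction))
    bundles = []
    for i in range(n_subjects):
        tree = generate_vessel_tree(image_size, n_branch_levels, root_radius,
                                    radius_decay, seed=(seed * 1009 + i) & 0x7FFFFFFF)
        if i < n_narrow:
            tree = tree.scaled_radii(narrowing)
            tree.class_label = 1
        bundles.append(render_fundus(tree, seed=(seed * 2003 + i) & 0x7FFFFFFF))
    return bundles
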