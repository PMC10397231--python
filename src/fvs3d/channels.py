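"""Weighted G/R channel fusion and 1-D local search over the G weight.

Most vessel segmenters use the green channel alone; the red channel can carry
complementary contrast, so a fused grayscale g*G + r*R (g + r = 1) is formed
and the weight is tuned by hill-climbing on a 0.01 lattice around the best
coarse proportion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


@dataclass(frozen=True)
class ChannelProportion:
    """Weights for the G and R channels; must sum to 1."""

    g: float
    r: float

    def __post_init__(self):
        if not (0.0 <= self.g <= 1.0 and 0.0 <= self.r <= 1.0):
            raise ValueError("channel weights must lie in [0, 1]")
        if abs(self.g + self.r - 1.0) > 1e-9:
            raise ValueError(f"g + r must equal 1, got {self.g + self.r}")

    @classmethod
    def from_g(cls, g: float) -> "ChannelProportion":
        g = min(max(g, 0.0), 1.0)
        return cls(g=g, r=1.0 - g)


def fuse_channels(image: np.ndarray, prop: ChannelProportion) -> np.ndarray:
    """Per-pixel g*G + r*R as floating point (no requantization).

    ``image`` is (H, W, 3) RGB (channel order R, G, B) or (H, W, C>=2).
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 2:
        missing = "G" if (image.ndim != 3 or image.shape[-1] < 2) else "R"
        raise ValueError(
            f"fuse_channels needs R and G channels; input shape {image.shape} "
            f"is missing channel {missing}")
    R = image[:, :, 0].astype(float)
    G = image[:, :, 1].astype(float)
    return prop.g * G + prop.r * R


def local_search_proportion(
    evaluator: Callable[[ChannelProportion], float],
    start: ChannelProportion,
    step: float = 0.01,
    max_radius: int = 100,
) -> tuple[ChannelProportion, list[tuple[float, float]]]:
    """Hill-climb the G weight on the lattice g0 ± i*step, i = 1..max_radius.

    At each radius the two neighbours (g + i*step) and (g - i*step) are
    scored (clipped to [0, 1]); expansion continues while the better
    neighbour improves the incumbent and stops after one non-improving
    radius.  Ties keep the incumbent closest to the start.  Returns the
    incumbent and the (g, score) evaluation trace.
    """
    if step <= 0:
        raise ValueError("step must be positive")

    def run(g: float) -> float:
        try:
            return float(evaluator(ChannelProportion.from_g(g)))
        except Exception as exc:  # identify the failing proportion
            raise RuntimeError(f"evaluator failed at proportion g={g:.4f}") from exc

    trace: list[tuple[float, float]] = []
    g_best = start.g
    s_best = run(g_best)
    trace.append((g_best, s_best))
    seen = {round(g_best, 9)}

    for i in range(1, max_radius + 1):
        improved = False
        for g_cand in (start.g + i * step, start.g - i * step):
            g_cand = min(max(g_cand, 0.0), 1.0)
            key = round(g_cand, 9)
            if key in seen:
                continue
            seen.add(key)
            s = run(g_cand)
            trace.append((g_cand, s))
            if s > s_best:  # strict: ties keep the incumbent nearer start
                g_best, s_best = g_cand, s
                improved = True
        if not improved:
            break
    return ChannelProportion.from_g(g_best), trace


COARSE_PROPORTIONS: Sequence[ChannelProportion] = (
    ChannelProportion(0.5, 0.5),
    ChannelProportion(0.75, 0.25),
    ChannelProportion(1.0, 0.0),
)
"""The three coarse starting proportions scanned before the local search."""
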