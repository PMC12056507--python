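"""Spheroid shape characteristics derived from a segmentation mask.

The quantities practitioners actually track are the mean diameter
d = 2·sqrt(|T|/π) (diameter of the circle with the mask's area), the
spherical volume estimate π·d³/6 built on it, and the circularity
4π·|T|/L² as quality control for the sphericity assumption, with L the
polygonal-chain perimeter of the outer border.

Perimeters come from border following, which slightly overestimates
the circumference of digitized disks; values are reported as computed,
without a digitization correction, so circularity may exceed 1 for
small shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .masks import PolyChain, chain_length

__all__ = ["Morphometrics", "diameter", "volume", "circularity", "measure"]


@dataclass(frozen=True)
class Morphometrics:
    area_px: int
    diameter_px: float
    diameter_um: float
    volume_um3: float
    circularity: float
    perimeter_px: float
    degenerate: bool


def diameter(mask: np.ndarray) -> float:
    """Mean diameter 2·sqrt(area/π) in pixels; 0 for an empty mask."""
    area = int(np.count_nonzero(mask))
    return 2.0 * math.sqrt(area / math.pi)


def volume(diameter_um: float) -> float:
    """Spherical volume estimate π·d³/6 in µm³."""
    if diameter_um < 0:
        raise ValueError("diameter must be >= 0")
    return math.pi * diameter_um**3 / 6.0


def circularity(mask: np.ndarray, contour: PolyChain) -> tuple[float, bool]:
    """Circularity 4π·area/L² with the polygonal perimeter L.

    Components too small to carry a perimeter (< 3 chain points, L = 0)
    are assigned circularity 1.0 and flagged degenerate.
    Returns ``(circularity, degenerate)``.
    """
    L = chain_length(contour)
    if len(contour) < 3 or L == 0:
        return 1.0, True
    area = int(np.count_nonzero(mask))
    return 4.0 * math.pi * area / L**2, False


def measure(mask: np.ndarray, contour: PolyChain, pixel_size: float) -> Morphometrics:
    """Full per-image morphometrics row for one segmented spheroid."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    area = int(np.count_nonzero(mask))
    d_px = diameter(mask)
    d_um = d_px * pixel_size
    circ, degen = circularity(mask, contour)
    return Morphometrics(
        area_px=area,
        diameter_px=d_px,
        diameter_um=d_um,
        volume_um3=volume(d_um),
        circularity=circ,
        perimeter_px=chain_length(contour),
        degenerate=degen,
    )
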