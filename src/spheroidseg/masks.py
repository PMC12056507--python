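"""Pixel-set geometry for segmentation masks.

Binary masks are plain 2-D boolean :class:`numpy.ndarray` rasters in
(row, col) order with 0-based indices; images and masks share the same
grid with pixel-center coordinates.  This module provides the mask
algebra every downstream metric is built on: connected-component
labeling, largest-component selection, outer-border contour tracing
(Moore-neighbor border following) and the polygonal-chain perimeter.

Connectivity convention: foreground is 8-connected, background
4-connected — the standard pairing for border following on square
grids.  Only the outer border of a component is traced; interior holes
do not contribute to the perimeter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ComponentSet",
    "PolyChain",
    "label_components",
    "largest_component",
    "trace_contour",
    "chain_length",
    "mask_overlap",
]

# 8-connected structuring element for foreground labeling
_STRUCT8 = np.ones((3, 3), dtype=bool)

# Moore neighborhood in clockwise order starting East, as (drow, dcol).
# Traversed clockwise around the current pixel this yields a
# counterclockwise walk along the outer border in image coordinates
# (row axis pointing down).
_MOORE = np.array(
    [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)],
    dtype=np.intp,
)


@dataclass(frozen=True)
class ComponentSet:
    """Labeled 8-connected foreground components of a binary mask.

    Attributes
    ----------
    labels:
        Integer raster; 0 is background, components are numbered
        1..k in raster-scan order of their first (topmost-leftmost)
        pixel.
    areas:
        Pixel count per component, ``areas[i]`` belonging to label
        ``i + 1``.
    """

    labels: np.ndarray
    areas: tuple[int, ...] = field(default=())

    @property
    def k(self) -> int:
        """Number of components."""
        return len(self.areas)

    def component_mask(self, label: int) -> np.ndarray:
        """Boolean mask of a single component (labels are 1-based)."""
        if not 1 <= label <= self.k:
            raise ValueError(f"label {label} out of range 1..{self.k}")
        return self.labels == label


@dataclass(frozen=True)
class PolyChain:
    """Closed polygonal chain of a component's outer border.

    ``points`` is an ``(n, 2)`` integer array of (row, col) pixel
    coordinates; consecutive points are 8-neighbors.  For a closed
    chain the last point is 8-adjacent to the first (the closing
    segment is implicit, not repeated).
    """

    points: np.ndarray
    closed: bool = True

    def __len__(self) -> int:
        return len(self.points)


def _as_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    return mask.astype(bool, copy=False)


def label_components(mask: np.ndarray) -> ComponentSet:
    """Label 8-connected foreground components in raster-scan order.

    Labels are deterministic: component 1 is the one whose first pixel
    comes first in raster-scan (row-major) order, and so on.  An empty
    mask yields ``k = 0``.
    """
    mask = _as_bool(mask)
    if mask.size == 0:
        raise ValueError("mask shape must be non-empty")
    raw, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return ComponentSet(labels=raw, areas=())
    # scipy assigns labels in raster-scan order of first pixel already,
    # but that is an implementation detail; enforce it explicitly.
    flat = raw.ravel()
    first_idx = np.full(n + 1, flat.size, dtype=np.intp)
    nz = np.flatnonzero(flat)
    # reversed so the earliest index wins
    first_idx[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first_idx[1:], kind="stable")  # old labels, 0-based
    remap = np.zeros(n + 1, dtype=raw.dtype)
    remap[order + 1] = np.arange(1, n + 1)
    labels = remap[raw]
    areas = tuple(int(a) for a in np.bincount(labels.ravel(), minlength=n + 1)[1:])
    return ComponentSet(labels=labels, areas=areas)


def largest_component(components: ComponentSet) -> tuple[np.ndarray, bool]:
    """Select the largest-area component.

    Returns ``(mask, ambiguous)`` where ``ambiguous`` is true whenever
    more than one component is present.  Ties on area are broken by the
    lowest label (first in raster-scan order).  With no components the
    returned mask is empty and ``ambiguous`` is false.
    """
    if components.k == 0:
        return np.zeros_like(components.labels, dtype=bool), False
    areas = np.asarray(components.areas)
    best = int(np.argmax(areas)) + 1  # argmax takes the first maximum
    return components.labels == best, components.k > 1


def trace_contour(component: np.ndarray) -> PolyChain:
    """Trace the outer border of a single component into a closed chain.

    Moore-neighbor border following: starting from the topmost-leftmost
    foreground pixel, the Moore neighborhood of the current border
    pixel is scanned clockwise from the backtrack direction; the walk
    terminates on re-entering the start pixel.  The resulting chain
    runs counterclockwise along the outer border and visits every
    outer-border pixel of blob-like components (a one-pixel spur at the
    start pixel can close the walk early; thresholded probability maps
    do not produce such shapes at the start position in practice).

    Raises ``ValueError`` if the input holds more than one 8-connected
    component; isolate one first (see :func:`largest_component`).
    """
    component = _as_bool(component)
    _, n = ndimage.label(component, structure=_STRUCT8)
    if n == 0:
        raise ValueError("cannot trace contour of an empty mask")
    if n > 1:
        raise ValueError(
            f"trace_contour expects a single component, found {n}; "
            "isolate one with largest_component first"
        )
    rows, cols = np.nonzero(component)
    start = (int(rows[0]), int(cols[0]))  # raster-scan first pixel
    if len(rows) == 1:
        return PolyChain(points=np.array([start], dtype=np.intp), closed=True)

    h, w = component.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and component[r, c]

    points: list[tuple[int, int]] = [start]
    # Backtrack starts one pixel West of the start pixel, which is
    # guaranteed background because start is topmost-leftmost.
    cur = start
    back_dir = 4  # direction from cur toward its backtrack pixel (West)
    max_steps = 4 * component.size  # safety bound; the walk is a closed cycle
    for _ in range(max_steps):
        # scan the Moore neighborhood clockwise from just past backtrack
        found = -1
        for i in range(1, 9):
            d = (back_dir + i) % 8
            dr, dc = _MOORE[d]
            if fg(cur[0] + dr, cur[1] + dc):
                found = d
                break
        if found < 0:  # isolated pixel; guarded above but kept for safety
            break
        nxt = (cur[0] + int(_MOORE[found][0]), cur[1] + int(_MOORE[found][1]))
        if nxt == start:
            break  # border walk closed
        points.append(nxt)
        back_dir = (found + 4) % 8  # from nxt back toward cur
        cur = nxt
    return PolyChain(points=np.array(points, dtype=np.intp), closed=True)


def chain_length(chain: PolyChain) -> float:
    """Polygonal perimeter: summed Euclidean distances along the chain.

    Includes the closing segment for closed chains.  Chains with fewer
    than 2 points have length 0.
    """
    pts = np.asarray(chain.points, dtype=float)
    if len(pts) < 2:
        return 0.0
    diffs = np.diff(pts, axis=0)
    total = float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())
    if chain.closed:
        closing = pts[0] - pts[-1]
        total += float(np.hypot(closing[0], closing[1]))
    return total


def mask_overlap(p: np.ndarray, t: np.ndarray) -> tuple[int, int]:
    """Exact intersection and union pixel counts of two masks."""
    p = _as_bool(p)
    t = _as_bool(t)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    inter = int(np.count_nonzero(p & t))
    union = int(np.count_nonzero(p | t))
    return inter, union
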