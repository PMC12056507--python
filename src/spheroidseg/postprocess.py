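"""Probability map to final contour: the postprocessing chain.

The network emits a per-pixel spheroid probability (softmax of the
last layer).  The chain to a usable segmentation is: threshold at 0.5
(inclusive), label 8-connected components, keep the largest one —
mirroring the experimental convention that the largest regrowing body
is the one that matters for relapse detection — and trace its outer
border into a polygonal chain.  A classical Otsu-threshold baseline
runs the same component/contour chain on raw intensity, for
head-to-head comparison on debris-laden images where thresholding is
expected to fail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .io import GrayImage
from .masks import (
    ComponentSet,
    PolyChain,
    label_components,
    largest_component,
    trace_contour,
)

__all__ = ["SegmentationResult", "binarize", "extract_spheroid", "otsu_baseline"]

PROB_THRESHOLD = 0.5


@dataclass(frozen=True)
class SegmentationResult:
    full_mask: np.ndarray  # all thresholded foreground
    spheroid_mask: np.ndarray  # largest component only
    contour: PolyChain | None  # absent when empty
    n_components: int
    ambiguous: bool  # more than one component detected
    empty: bool  # nothing detected


def binarize(prob: np.ndarray) -> np.ndarray:
    """Threshold a probability map at 0.5; the threshold is inclusive
    (a pixel at exactly 0.5 counts as spheroid)."""
    prob = np.asarray(prob, dtype=np.float64)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability values must lie in [0, 1]")
    return prob >= PROB_THRESHOLD


def _from_mask(mask: np.ndarray, min_area: int = 0) -> SegmentationResult:
    comps = label_components(mask)
    if min_area > 0 and comps.k > 0:
        keep = np.array([0] + [1 if a >= min_area else 0 for a in comps.areas])
        mask = keep[comps.labels].astype(bool)
        comps = label_components(mask)
    spheroid, ambiguous = largest_component(comps)
    empty = comps.k == 0
    contour = None if empty else trace_contour(spheroid)
    return SegmentationResult(
        full_mask=mask,
        spheroid_mask=spheroid,
        contour=contour,
        n_components=comps.k,
        ambiguous=ambiguous,
        empty=empty,
    )


def extract_spheroid(prob: np.ndarray, min_area: int = 0) -> SegmentationResult:
    """Full chain: binarize → label → largest component → contour.

    ``min_area`` (px) optionally suppresses speckle components before
    the largest-component rule; the default 0 applies no filtering.
    """
    return _from_mask(binarize(prob), min_area=min_area)


def otsu_baseline(image: GrayImage, min_area: int = 0) -> SegmentationResult:
    """Classical comparator: Otsu threshold on inverted intensity.

    The spheroid is dark on a bright background, so foreground is the
    set of pixels *below* the Otsu threshold of the 8-bit image.  The
    rest of the chain (components, largest, contour) is identical to
    the model path.  A constant image yields an empty result.
    """
    if image.bit_depth != 8:
        raise ValueError("otsu_baseline expects an 8-bit image; convert first")
    v = image.values
    if v.min() == v.max():
        return _from_mask(np.zeros(image.shape, dtype=bool))
    thr = threshold_otsu(v)
    return _from_mask(v < thr, min_area=min_area)
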