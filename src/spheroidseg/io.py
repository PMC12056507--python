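"""Image, mask and manifest I/O plus the preprocessing pipeline.

Covers the steps between the raw 16-bit brightfield frame and the
tensors the segmentation model consumes: per-image min–max conversion
to 8 bit, resolution reduction, spheroid-exclusive dataset splitting
and the three-transform augmentation (vertical flip, horizontal flip,
180° rotation).

Masks travel as 8-bit PNG (0 background / 255 foreground), images as
TIFF (8- or 16-bit gray), manifests as CSV with columns
``image,mask,spheroid_id,split``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "GrayImage",
    "SplitEntry",
    "to_8bit",
    "resize_image",
    "resize_mask",
    "split_by_spheroid",
    "augment_pair",
    "apply_transform",
    "build_training_set",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_manifest",
    "write_manifest",
]

AUGMENT_TRANSFORMS = ("vflip", "hflip", "rot180")

#: native physical resolution of the brightfield frames, µm per pixel
NATIVE_PIXEL_SIZE_UM = 2.04


@dataclass(frozen=True)
class GrayImage:
    """Gray-scale intensity raster with bit depth and physical scale."""

    values: np.ndarray  # 2-D, integer dtype
    bit_depth: int  # 8 or 16
    pixel_size: float = NATIVE_PIXEL_SIZE_UM  # µm/px

    def __post_init__(self):
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("image must be 2-D gray-scale")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class SplitEntry:
    """One manifest row: an image/mask pair with its spheroid identity."""

    image: str
    mask: str
    spheroid_id: str
    split: str = ""


def to_8bit(image: GrayImage) -> GrayImage:
    """Per-image linear min–max rescale of a 16-bit frame to 8 bit.

    The smallest gray value of the frame maps to 0 and the largest to
    255; rounding is half-up.  Only a narrow band of the 16-bit range
    is populated by the microscope, so the contrast loss is negligible.
    A constant frame (max = min) maps to all zeros.  8-bit input passes
    through unchanged.
    """
    if image.bit_depth == 8:
        return image
    v = image.values.astype(np.float64)
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        out = np.zeros(image.shape, dtype=np.uint8)
    else:
        scaled = 255.0 * (v - lo) / (hi - lo)
        out = np.floor(scaled + 0.5).astype(np.uint8)  # round half up
    return GrayImage(values=out, bit_depth=8, pixel_size=image.pixel_size)


def _resized_dims(shape: tuple[int, int], factor: float) -> tuple[int, int]:
    if not 0 < factor <= 1:
        raise ValueError(f"resize factor must be in (0, 1], got {factor}")
    h = int(round(shape[0] * factor))
    w = int(round(shape[1] * factor))
    if min(h, w) < 8:
        raise ValueError(f"resized dims {h}x{w} below the 8 px minimum")
    return h, w


def resize_image(image: GrayImage, factor: float) -> GrayImage:
    """Bilinear downscale of an intensity image by ``factor`` ∈ (0, 1]."""
    if factor == 1:
        return image
    h, w = _resized_dims(image.shape, factor)
    out = _sk_resize(
        image.values.astype(np.float64),
        (h, w),
        order=1,
        anti_aliasing=False,
        preserve_range=True,
    )
    maxval = 2**image.bit_depth - 1
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    out = np.clip(np.floor(out + 0.5), 0, maxval).astype(dtype)
    return GrayImage(
        values=out, bit_depth=image.bit_depth, pixel_size=image.pixel_size / factor
    )


def resize_mask(mask: np.ndarray, factor: float) -> np.ndarray:
    """Nearest-neighbor resize of a binary mask (up or down).

    ``factor`` may exceed 1 here: metric evaluation happens on the
    native grid, so masks produced at reduced resolution are scaled
    back up before comparison.
    """
    mask = np.asarray(mask, dtype=bool)
    if factor == 1:
        return mask
    h = int(round(mask.shape[0] * factor))
    w = int(round(mask.shape[1] * factor))
    if min(h, w) < 1:
        raise ValueError("resized mask would be empty")
    out = _sk_resize(mask, (h, w), order=0, anti_aliasing=False, preserve_range=True)
    return out.astype(bool)


def upscale_probmap(values: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear upscale of a probability map to the native grid.

    Thresholding happens only after this step so all metrics live on
    one pixel grid.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape == tuple(target_shape):
        return values
    out = _sk_resize(
        values, target_shape, order=1, anti_aliasing=False, preserve_range=True
    )
    return np.clip(out, 0.0, 1.0)


def split_by_spheroid(
    entries: Sequence[SplitEntry],
    fractions: tuple[float, float, float],
    seed: int,
) -> list[SplitEntry]:
    """Randomized train/val/test split at the spheroid level.

    All images of one spheroid land in the same split, ruling out
    leakage between training, validation and testing through temporal
    correlation within an image series.  Proportions are honored as
    closely as integer spheroid counts allow (largest-remainder
    rounding); every non-empty fraction receives at least one id.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = sorted({e.spheroid_id for e in entries})
    n_ids = len(ids)
    n_nonempty = sum(1 for f in fractions if f > 0)
    if n_ids < max(3, n_nonempty):
        raise ValueError(
            f"need at least {max(3, n_nonempty)} spheroid ids, got {n_ids}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_ids)
    # largest-remainder apportionment over ids
    quotas = np.array(fractions) * n_ids
    counts = np.floor(quotas).astype(int)
    for i, f in enumerate(fractions):
        if f > 0 and counts[i] == 0:
            counts[i] = 1
    while counts.sum() > n_ids:
        counts[int(np.argmax(counts))] -= 1
    remainders = quotas - np.floor(quotas)
    while counts.sum() < n_ids:
        i = int(np.argmax(remainders))
        counts[i] += 1
        remainders[i] = -1
    assignment: dict[str, str] = {}
    names = ("train", "val", "test")
    pos = 0
    for name, c in zip(names, counts):
        for j in order[pos : pos + c]:
            assignment[ids[j]] = name
        pos += c
    return [replace(e, split=assignment[e.spheroid_id]) for e in entries]


def apply_transform(arr: np.ndarray, transform: str) -> np.ndarray:
    """Apply one of the three orientation transforms to a 2-D array."""
    if transform == "vflip":
        return arr[::-1, :].copy()
    if transform == "hflip":
        return arr[:, ::-1].copy()
    if transform == "rot180":
        return arr[::-1, ::-1].copy()
    raise ValueError(f"unknown transform {transform!r}")


def augment_pair(
    image: np.ndarray, mask: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, str]:
    """Apply one uniformly chosen orientation transform to both arrays.

    Spheroids have no preferred orientation, and all three transforms
    preserve the rectangular frame, so no border pixels need to be
    extrapolated.  Returns ``(image, mask, transform_name)``.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask must share shape")
    t = AUGMENT_TRANSFORMS[int(rng.integers(len(AUGMENT_TRANSFORMS)))]
    return apply_transform(image, t), apply_transform(mask, t), t


def build_training_set(entries: Sequence, rng: np.random.Generator | None = None):
    """Double a training list: originals plus one augmented copy each.

    Each original is transformed exactly once (the copy is fixed, not
    re-drawn per epoch).  Entries may be any objects; the returned list
    is ``originals + [(entry, transform_name), ...]`` so the caller
    decides how to materialize the augmented copy.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    augmented = [
        (e, AUGMENT_TRANSFORMS[int(rng.integers(len(AUGMENT_TRANSFORMS)))])
        for e in entries
    ]
    return list(entries) + augmented


# ---------------------------------------------------------------------------
# file I/O


def read_image(path: str | Path, pixel_size: float = NATIVE_PIXEL_SIZE_UM) -> GrayImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # collapse accidental RGB
        arr = arr[..., 0]
    depth = 16 if arr.dtype.itemsize > 1 else 8
    return GrayImage(values=arr, bit_depth=depth, pixel_size=pixel_size)


def write_image(path: str | Path, image: GrayImage) -> None:
    path = Path(path)
    dtype = np.uint16 if image.bit_depth == 16 else np.uint8
    arr = image.values.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def read_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(Path(path))


def read_manifest(path: str | Path) -> list[SplitEntry]:
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"image", "mask", "spheroid_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest missing columns {required - set(df.columns)}")
    if "split" not in df.columns:
        df["split"] = ""
    return [
        SplitEntry(r.image, r.mask, r.spheroid_id, r.split)
        for r in df.itertuples(index=False)
    ]


def write_manifest(path: str | Path, entries: Iterable[SplitEntry]) -> None:
    df = pd.DataFrame(
        [(e.image, e.mask, e.spheroid_id, e.split) for e in entries],
        columns=["image", "mask", "spheroid_id", "split"],
    )
    df.to_csv(path, index=False)
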