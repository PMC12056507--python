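"""Seeded generator of synthetic brightfield-like spheroid images.

Treated multicellular tumor spheroids appear in brightfield microscopy
as dark, compact, roughly circular bodies whose surroundings are
littered with shed dead-cell debris.  The debris cloud can extend far
beyond the spheroid and can be locally thicker — and therefore darker —
than the spheroid rim itself, which is what defeats plain intensity
thresholding.  This module renders that phenomenology: a radially
perturbed dark disk with center darkening, a textured annular debris
cloud, a narrow-band 16-bit background with noise and an illumination
ramp, occasional double spheroids, and multi-rater boundary jitter.

The ground-truth mask covers the spheroid only; debris is never part
of the target, mirroring the manual segmentation convention.

Everything is driven by a single integer seed through counter-based
per-sample streams, so any sample of any dataset is independently
reproducible from ``(seed, index)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import GrayImage, SplitEntry
from .masks import label_components, largest_component, mask_overlap

__all__ = [
    "SynthConfig",
    "SynthSample",
    "generate_sample",
    "generate_dataset",
    "perturb_as_rater",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic image model.

    Defaults emulate the native acquisition geometry (1,300 × 1,030 px
    at 2.04 µm/px) and intensity statistics (16-bit values centered
    near 1,300 with spread ~130, i.e. a narrow band of the dynamic
    range) of brightfield spheroid monitoring, with a debris cloud
    extending well beyond the spheroid.
    """

    image_size: tuple[int, int] = (1030, 1300)  # (rows, cols) px
    pixel_size: float = 2.04  # µm/px
    spheroid_diameter_range: tuple[float, float] = (200.0, 500.0)  # µm
    boundary_irregularity: float = 0.08  # RMS relative radial perturbation
    debris_extent_factor: float = 2.5  # debris radius / spheroid radius
    debris_opacity: float = 0.5  # peak attenuation of debris patches
    debris_graininess: float = 6.0  # texture correlation length, px
    double_spheroid_prob: float = 0.05
    background_level: float = 1300.0  # 16-bit mean
    background_sd: float = 130.0  # 16-bit units
    illumination_gradient: float = 0.05  # max relative slope across frame
    growth_per_step: tuple[float, float] = (1.0, 1.08)  # time-series growth
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.spheroid_diameter_range
        if not (0 < lo <= hi):
            raise ValueError("spheroid_diameter_range must be positive and ordered")
        if self.debris_extent_factor < 0:
            raise ValueError("debris_extent_factor must be >= 0")
        for p in (self.debris_opacity, self.double_spheroid_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities/opacities must lie in [0, 1]")


@dataclass
class SynthSample:
    """One rendered image with its ground truth and bookkeeping."""

    image: GrayImage
    target: np.ndarray  # boolean mask, spheroid only
    spheroid_id: str
    metadata: dict = field(default_factory=dict)
    rater_masks: list[np.ndarray] | None = None
    debris_mask: np.ndarray | None = None  # debris-only region (excludes target)


def desk_scale_config(seed: int = 0, image_size: tuple[int, int] = (128, 128), **overrides) -> SynthConfig:
    """Scaled-down study conditions for CPU-sized experiments.

    A 128×128 frame at 4 µm/px (512 µm field of view) holding a
    100–200 µm spheroid keeps the spheroid-to-frame proportions of the
    native acquisition while making training and evaluation tractable
    on one CPU core.  All other phenomenology parameters (debris
    extent and opacity, background statistics relative to contrast,
    irregularity) keep their full-scale defaults.
    """
    base = dict(
        image_size=image_size,
        pixel_size=4.0,
        spheroid_diameter_range=(100.0, 200.0),
        seed=seed,
    )
    base.update(overrides)
    return SynthConfig(**base)


# spheroid attenuation profile: transmittance at rim / at center
_RIM_ATTENUATION = 0.35
_CENTER_ATTENUATION = 0.70
# nominal diameters are drawn from the inner 90% of the configured range so
# the rendered equivalent diameter stays inside it after boundary perturbation
_DIAMETER_MARGIN = 0.05


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _radial_profile(rng: np.random.Generator, irregularity: float, n_modes: int = 4):
    """Random smooth periodic perturbation with the requested RMS."""
    ks = np.arange(2, 2 + n_modes)
    a = rng.standard_normal(n_modes)
    b = rng.standard_normal(n_modes)
    # RMS of sum a_k cos + b_k sin over θ is sqrt(Σ(a²+b²)/2)
    rms = math.sqrt(float(np.sum(a**2 + b**2)) / 2.0)
    if rms == 0:
        rms = 1.0
    scale = irregularity / rms

    def r_of_theta(theta: np.ndarray, r0: float) -> np.ndarray:
        pert = sum(
            a[i] * np.cos(ks[i] * theta) + b[i] * np.sin(ks[i] * theta)
            for i in range(n_modes)
        )
        return r0 * (1.0 + scale * pert)

    return r_of_theta


def _disk_mask(shape, center, r0, r_of_theta) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = rr - center[0]
    dx = cc - center[1]
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    return rho <= r_of_theta(theta, r0)


def _smooth_noise(rng, shape, corr_len: float) -> np.ndarray:
    """Blurred white noise rescaled to [0, 1]."""
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=max(corr_len, 0.5))
    lo, hi = g.min(), g.max()
    if hi == lo:
        return np.zeros(shape)
    return (g - lo) / (hi - lo)


def generate_sample(
    config: SynthConfig, index: int, spheroid_id: str | None = None
) -> SynthSample:
    """Render one synthetic frame; deterministic for fixed (seed, index)."""
    rng = _sample_rng(config.seed, index)
    h, w = config.image_size
    lo_um, hi_um = config.spheroid_diameter_range
    span = hi_um - lo_um
    d_um = rng.uniform(lo_um + _DIAMETER_MARGIN * span, hi_um - _DIAMETER_MARGIN * span)
    return _render(config, rng, d_um, spheroid_id or f"S{index:04d}", index)


def _render(
    config: SynthConfig,
    rng: np.random.Generator,
    d_um: float,
    spheroid_id: str,
    index: int,
    geometry: dict | None = None,
) -> SynthSample:
    h, w = config.image_size
    r_px = 0.5 * d_um / config.pixel_size
    if 2 * r_px >= min(h, w):
        raise ValueError(
            f"spheroid diameter {2 * r_px:.0f} px exceeds frame {min(h, w)} px"
        )

    if geometry is None:
        margin = r_px * 1.2 + 2
        center = (
            rng.uniform(margin, h - margin) if h > 2 * margin else h / 2,
            rng.uniform(margin, w - margin) if w > 2 * margin else w / 2,
        )
        r_of_theta = _radial_profile(rng, config.boundary_irregularity)
        double = rng.uniform() < config.double_spheroid_prob
        double_dir = rng.uniform(0, 2 * math.pi)
        double_ratio = rng.uniform(0.6, 0.9)
    else:
        center = geometry["center"]
        r_of_theta = geometry["r_of_theta"]
        double = geometry["double"]
        double_dir = geometry["double_dir"]
        double_ratio = geometry["double_ratio"]

    target = _disk_mask((h, w), center, r_px, r_of_theta)

    rr, cc = np.mgrid[0:h, 0:w]
    dy = rr - center[0]
    dx = cc - center[1]
    rho = np.hypot(dy, dx)

    # transmittance field: 1 = unobstructed background
    trans = np.ones((h, w))
    # spheroid body: darker toward the center (thickness proxy)
    rho_rel = np.clip(rho / max(r_px, 1e-9), 0, 1)
    atten = _RIM_ATTENUATION + (_CENTER_ATTENUATION - _RIM_ATTENUATION) * (
        1.0 - rho_rel**2
    )
    trans = np.where(target, 1.0 - atten, trans)

    if double:
        r2 = r_px * double_ratio
        c2 = (
            center[0] + math.sin(double_dir) * (r_px + r2) * 0.85,
            center[1] + math.cos(double_dir) * (r_px + r2) * 0.85,
        )
        second = _disk_mask((h, w), c2, r2, r_of_theta)
        second &= ~target  # primary body keeps its profile where they overlap
        rho2 = np.hypot(rr - c2[0], cc - c2[1])
        rho2_rel = np.clip(rho2 / max(r2, 1e-9), 0, 1)
        atten2 = _RIM_ATTENUATION + (_CENTER_ATTENUATION - _RIM_ATTENUATION) * (
            1.0 - rho2_rel**2
        )
        trans = np.where(second, 1.0 - atten2, trans)
        target = target | second

    # debris: textured annulus around the spheroid, excluded from the target
    debris_radius = config.debris_extent_factor * r_px
    debris_mask = None
    if config.debris_extent_factor > 0 and config.debris_opacity > 0:
        annulus = (~target) & (rho <= debris_radius)
        texture = _smooth_noise(rng, (h, w), config.debris_graininess)
        # radial falloff: full strength at the spheroid edge, 0 at cloud edge
        if debris_radius > r_px:
            falloff = np.clip((debris_radius - rho) / (debris_radius - r_px), 0, 1)
        else:
            falloff = np.zeros((h, w))
        a_debris = config.debris_opacity * texture * np.sqrt(falloff)
        trans = np.where(annulus, trans * (1.0 - a_debris), trans)
        debris_mask = annulus & (a_debris > 0.05)

    # illumination: level with a linear ramp along a random direction
    ramp_dir = rng.uniform(0, 2 * math.pi)
    u = (dy * math.sin(ramp_dir) + dx * math.cos(ramp_dir)) / max(h, w)
    illum = config.background_level * (1.0 + config.illumination_gradient * u)

    # noise rides on the illumination and is attenuated with it
    img = (illum + rng.standard_normal((h, w)) * config.background_sd) * trans
    img = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    sample = SynthSample(
        image=GrayImage(values=img, bit_depth=16, pixel_size=config.pixel_size),
        target=target,
        spheroid_id=spheroid_id,
        metadata={
            "index": index,
            "diameter_um": d_um,
            "radius_px": r_px,
            "debris_radius_px": float(debris_radius),
            "double": bool(double),
            "center": (float(center[0]), float(center[1])),
        },
        debris_mask=debris_mask,
    )
    return sample


def generate_dataset(
    config: SynthConfig, n: int, images_per_spheroid: int = 1
) -> tuple[list[SynthSample], list[SplitEntry]]:
    """Generate ``n`` spheroids with a short image series each.

    All images of one spheroid share the underlying geometry (boundary
    shape, position, double-spheroid status); across the series the
    diameter grows by a per-step factor drawn from
    ``config.growth_per_step``, emulating monitoring over time.
    Returns the samples plus manifest entries (paths follow the
    ``images/<id>_t<step>.tif`` / ``masks/<id>_t<step>.png`` layout the
    CLI writes).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    samples: list[SynthSample] = []
    entries: list[SplitEntry] = []
    lo_um, hi_um = config.spheroid_diameter_range
    span = hi_um - lo_um
    for i in range(n):
        rng = _sample_rng(config.seed, i)
        sid = f"S{i:04d}"
        # draw low enough that the whole series stays inside the range
        max_growth = config.growth_per_step[1] ** max(images_per_spheroid - 1, 0)
        d0_hi = min(
            hi_um - _DIAMETER_MARGIN * span,
            (hi_um - _DIAMETER_MARGIN * span) / max_growth,
        )
        d0 = rng.uniform(lo_um + _DIAMETER_MARGIN * span, max(d0_hi, lo_um + _DIAMETER_MARGIN * span))
        geometry = {
            "center": None,  # filled below, needs radius-dependent margin
            "r_of_theta": _radial_profile(rng, config.boundary_irregularity),
            "double": rng.uniform() < config.double_spheroid_prob,
            "double_dir": rng.uniform(0, 2 * math.pi),
            "double_ratio": rng.uniform(0.6, 0.9),
        }
        h, w = config.image_size
        r_max = 0.5 * d0 * max_growth / config.pixel_size
        margin = r_max * 1.2 + 2
        geometry["center"] = (
            rng.uniform(margin, h - margin) if h > 2 * margin else h / 2,
            rng.uniform(margin, w - margin) if w > 2 * margin else w / 2,
        )
        d = d0
        for t in range(images_per_spheroid):
            step_rng = _sample_rng(config.seed, i * 100003 + t + 1)
            s = _render(config, step_rng, d, sid, i, geometry=geometry)
            s.metadata["step"] = t
            samples.append(s)
            entries.append(
                SplitEntry(
                    image=f"images/{sid}_t{t}.tif",
                    mask=f"masks/{sid}_t{t}.png",
                    spheroid_id=sid,
                )
            )
            d *= step_rng.uniform(*config.growth_per_step)
    return samples, entries


def perturb_as_rater(
    target: np.ndarray, jitter_amplitude: float, seed: int
) -> np.ndarray:
    """Simulate an independent human rater's boundary placement.

    The target boundary is displaced by a smooth random radial field
    (low-order angular modes around the mask centroid) with RMS
    amplitude ``jitter_amplitude`` in pixels, implemented by
    thresholding the signed Euclidean distance to the boundary.  With
    zero amplitude the target is returned unchanged.  The result is
    non-empty, single-component and overlaps the target.
    """
    target = np.asarray(target, dtype=bool)
    if not target.any():
        raise ValueError("target must be non-empty")
    if jitter_amplitude == 0:
        return target.copy()
    rng = np.random.default_rng(seed)
    d_in = ndimage.distance_transform_edt(target)
    d_out = ndimage.distance_transform_edt(~target)
    signed = d_in - d_out  # positive inside, negative outside
    com = ndimage.center_of_mass(target)
    rr, cc = np.mgrid[0 : target.shape[0], 0 : target.shape[1]]
    theta = np.arctan2(rr - com[0], cc - com[1])
    n_modes = 4
    ks = np.arange(1, n_modes + 1)
    a = rng.standard_normal(n_modes)
    b = rng.standard_normal(n_modes)
    rms = math.sqrt(float(np.sum(a**2 + b**2)) / 2.0) or 1.0
    fieldv = sum(
        a[i] * np.cos(ks[i] * theta) + b[i] * np.sin(ks[i] * theta)
        for i in range(n_modes)
    ) * (jitter_amplitude / rms)
    perturbed = signed >= fieldv
    comps = label_components(perturbed)
    if comps.k == 0:
        return target.copy()
    mask, _ = largest_component(comps)
    inter, _ = mask_overlap(mask, target)
    if inter == 0:
        return target.copy()
    return mask


def rater_panel(
    target: np.ndarray,
    n_raters: int,
    jitter_amplitude: float,
    seed: int,
) -> list[np.ndarray]:
    """Independent simulated raters for one image (convenience wrapper)."""
    return [
        perturb_as_rater(target, jitter_amplitude, seed=seed * 1000 + i)
        for i in range(n_raters)
    ]
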