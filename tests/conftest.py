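"""Shared fixtures: deterministic mask/blob factories, a brute-force
flood-fill oracle, and the desk-scale trained model reused by the
slow end-to-end tests."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

import spheroidseg as ss
from spheroidseg.nn import ModelConfig, TrainConfig, build_model, train


def rasterized_disk(radius: int, pad: int = 4) -> np.ndarray:
    """Boolean raster of a centered disk (pixel-center inclusion)."""
    size = 2 * radius + 2 * pad + 1
    c = radius + pad
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def random_blob(rng: np.random.Generator, shape=(64, 64), density=0.5) -> np.ndarray:
    """Random smooth blob mask; may have several components."""
    from scipy import ndimage

    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=4)
    thr = np.quantile(noise, 1 - 0.15 * density * rng.uniform(0.5, 2.0))
    mask = noise > thr
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    return mask


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """Brute-force 8-connected components by BFS, raster-scan order."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                comp = set()
                q = deque([(r0, c0)])
                seen[r0, c0] = True
                while q:
                    r, c = q.popleft()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                q.append((rr, cc))
                comps.append(comp)
    return comps


@pytest.fixture(scope="session")
def desk_dataset():
    """60/20/20 split of desk-scale synthetic images, moderate debris."""
    cfg = ss.synth.desk_scale_config(seed=0)
    samples, entries = ss.generate_dataset(cfg, 100, 1)
    entries = ss.split_by_spheroid(entries, (0.6, 0.2, 0.2), seed=0)
    split_of = {e.spheroid_id: e.split for e in entries}
    items = {"train": [], "val": [], "test": []}
    for s in samples:
        items[split_of[s.spheroid_id]].append((s.image, s.target, s.spheroid_id))
    return items


@pytest.fixture(scope="session")
def trained_tiny_model(desk_dataset):
    """Tiny U-Net trained on the desk-scale dataset (shared: slow)."""
    model = build_model(
        ModelConfig(depth=3, base_channels=8, input_size=(128, 128)), seed=0
    )
    history = train(
        model,
        desk_dataset["train"],
        desk_dataset["val"],
        TrainConfig(epochs=40, patience=10, seed=0),
    )
    return model, history
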