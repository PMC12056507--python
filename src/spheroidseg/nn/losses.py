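"""Segmentation losses: Dice (region-based), cross-entropy and focal
(distribution-based), each with its gradient w.r.t. the two-class
logits for the training loop.

Public loss functions operate on the foreground probability map and a
boolean target; the ``*_grad`` companions take logits and return
``(loss, dlogits)`` with the softmax Jacobian folded in.
"""

from __future__ import annotations

import numpy as np

from .model import softmax2

__all__ = [
    "dice_loss",
    "cross_entropy_loss",
    "focal_loss",
    "loss_and_grad",
]

DICE_EPS = 1.0  # smoothing constant, pixel-count units
LOG_CLIP = 1e-7  # probabilities clipped to [LOG_CLIP, 1 - LOG_CLIP] before log


def _check(prob: np.ndarray, target: np.ndarray):
    prob = np.asarray(prob, dtype=np.float64)
    target = np.asarray(target, dtype=bool)
    if prob.shape != target.shape:
        raise ValueError(f"shape mismatch: {prob.shape} vs {target.shape}")
    return prob, target


def dice_loss(prob: np.ndarray, target: np.ndarray, eps: float = DICE_EPS) -> float:
    """1 − (2·Σ p·t + ε) / (Σp + Σt + ε), in [0, 1]."""
    prob, target = _check(prob, target)
    t = target.astype(np.float64)
    num = 2.0 * float((prob * t).sum()) + eps
    den = float(prob.sum() + t.sum()) + eps
    return 1.0 - num / den


def cross_entropy_loss(prob: np.ndarray, target: np.ndarray) -> float:
    """Mean per-pixel −log p_true, with p clipped away from {0, 1}."""
    prob, target = _check(prob, target)
    p_true = np.where(target, prob, 1.0 - prob)
    p_true = np.clip(p_true, LOG_CLIP, 1.0 - LOG_CLIP)
    return float(-np.log(p_true).mean())


def focal_loss(prob: np.ndarray, target: np.ndarray, gamma: float = 2.0) -> float:
    """Mean −(1 − p_true)^γ · log p_true; γ = 0 recovers cross-entropy."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    prob, target = _check(prob, target)
    p_true = np.where(target, prob, 1.0 - prob)
    p_true = np.clip(p_true, LOG_CLIP, 1.0 - LOG_CLIP)
    return float(-((1.0 - p_true) ** gamma * np.log(p_true)).mean())


# ---------------------------------------------------------------------------
# logits-level losses for training


def _dice_grad(logits, t):
    p = softmax2(logits)
    pf = p[..., 1]
    tf = t.astype(np.float64)
    num = 2.0 * float((pf * tf).sum()) + DICE_EPS
    den = float(pf.sum() + tf.sum()) + DICE_EPS
    loss = 1.0 - num / den
    # d loss / d pf
    dpf = -(2.0 * tf * den - num) / den**2
    # through softmax: dz_fg = pf(1-pf)·dpf, dz_bg = −dz_fg
    dz_fg = (pf * (1.0 - pf) * dpf).astype(np.float32)
    dlogits = np.stack([-dz_fg, dz_fg], axis=-1)
    return loss, dlogits


def _ce_grad(logits, t):
    p = softmax2(logits)
    n_pix = t.size
    pf = np.clip(p[..., 1], LOG_CLIP, 1.0 - LOG_CLIP)
    p_true = np.where(t, pf, 1.0 - pf)
    loss = float(-np.log(p_true).mean())
    y = np.stack([(~t).astype(np.float32), t.astype(np.float32)], axis=-1)
    dlogits = (p - y).astype(np.float32) / n_pix
    return loss, dlogits


def _focal_grad(logits, t, gamma):
    p = softmax2(logits)
    n_pix = t.size
    tf = t.astype(bool)
    p_t = np.where(tf, p[..., 1], p[..., 0])
    p_t = np.clip(p_t, LOG_CLIP, 1.0 - LOG_CLIP)
    one_m = 1.0 - p_t
    loss = float((one_m**gamma * -np.log(p_t)).mean())
    # dL/dp_t, elementwise
    dL_dpt = (gamma * one_m ** (gamma - 1.0) * np.log(p_t) - one_m**gamma / p_t) / n_pix
    # softmax Jacobian for the true-class probability (2 classes):
    # dp_t/dz_true = p_t(1−p_t); dp_t/dz_other = −p_t(1−p_t)
    dz_true = (dL_dpt * p_t * one_m).astype(np.float32)
    dlogits = np.empty_like(p, dtype=np.float32)
    dlogits[..., 1] = np.where(tf, dz_true, -dz_true)
    dlogits[..., 0] = -dlogits[..., 1]
    return loss, dlogits


def loss_and_grad(
    name: str, logits: np.ndarray, target: np.ndarray, gamma: float = 2.0
) -> tuple[float, np.ndarray]:
    """Loss value and gradient w.r.t. logits for a (N, H, W, 2) batch.

    ``target`` is boolean (N, H, W).
    """
    target = np.asarray(target, dtype=bool)
    if logits.shape[:3] != target.shape or logits.shape[-1] != 2:
        raise ValueError("logits/target shape mismatch")
    if name == "dice":
        return _dice_grad(logits, target)
    if name in ("ce", "cross_entropy"):
        return _ce_grad(logits, target)
    if name == "focal":
        return _focal_grad(logits, target, gamma)
    raise ValueError(f"unknown loss {name!r}; choose dice, ce or focal")
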