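"""The 1-cycle learning-rate policy.

The learning rate is cycled exactly once between two bounds over the
whole run: a linear ramp from the lower to the upper bound across the
first half of the steps and a linear ramp back across the second
half.  The single cycle allows fast convergence without a separate
decay schedule.
"""

from __future__ import annotations

from typing import Callable

__all__ = ["one_cycle_schedule"]


def one_cycle_schedule(
    lr_bounds: tuple[float, float], total_steps: int
) -> Callable[[int], float]:
    """Return ``lr(step)`` for steps 0..total_steps.

    ``lr(0) = lr_min``, ``lr(total_steps/2) = lr_max``, and the ramps
    are linear, so e.g. ``lr(total_steps/4)`` is the midpoint of the
    bounds.
    """
    lr_min, lr_max = lr_bounds
    if not 0 < lr_min < lr_max:
        raise ValueError("need 0 < lr_min < lr_max")
    if total_steps < 2:
        raise ValueError("total_steps must be >= 2")
    mid = total_steps / 2.0

    def lr(step: int) -> float:
        s = min(max(step, 0), total_steps)
        if s <= mid:
            return lr_min + (lr_max - lr_min) * s / mid
        return lr_max - (lr_max - lr_min) * (s - mid) / (total_steps - mid)

    return lr
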