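"""Gait-event detection from vertical ground reaction force."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

STANCE_FORCE_THRESHOLD_N = 20.0
PUSHOFF_STANCE_FRACTION = 0.4  # push-off window = final 40% of stance


@dataclass(frozen=True)
class GaitEvents:
    """Stance and push-off windows as boolean frame masks."""

    times: np.ndarray
    stance: np.ndarray  # (T,) bool
    pushoff: np.ndarray  # (T,) bool, subset of stance

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, float).reshape(-1))
        object.__setattr__(self, "stance", np.asarray(self.stance, bool))
        object.__setattr__(self, "pushoff", np.asarray(self.pushoff, bool))
        if not (self.stance.shape == self.pushoff.shape == self.times.shape):
            raise DomainError("event mask shapes must match times")
        if (self.pushoff & ~self.stance).any():
            raise DomainError("push-off window must lie within stance")


def detect_gait_events(
    times,
    vertical_force,
    *,
    threshold: float = STANCE_FORCE_THRESHOLD_N,
    hysteresis: float = 5.0,
    pushoff_fraction: float = PUSHOFF_STANCE_FRACTION,
) -> GaitEvents:
    """Stance = vertical GRF above ``threshold`` (with hysteresis on exit);
    push-off = the final ``pushoff_fraction`` of each stance period."""
    times = np.asarray(times, dtype=float).reshape(-1)
    fy = np.asarray(vertical_force, dtype=float).reshape(-1)
    if fy.shape != times.shape:
        raise DomainError("force and times must have the same length")
    stance = np.zeros_like(fy, dtype=bool)
    on = False
    for i, f in enumerate(fy):
        if not on and f > threshold:
            on = True
        elif on and f < threshold - hysteresis:
            on = False
        stance[i] = on
    pushoff = np.zeros_like(stance)
    i = 0
    T = len(stance)
    while i < T:
        if stance[i]:
            j = i
            while j < T and stance[j]:
                j += 1
            start = j - max(1, int(np.ceil(pushoff_fraction * (j - i))))
            pushoff[start:j] = True
            i = j
        else:
            i += 1
    return GaitEvents(times=times, stance=stance, pushoff=pushoff)
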