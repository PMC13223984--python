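"""Sweep stimulus schedules.

A sweep trial steps one stimulus parameter (Michelson contrast, spatial
frequency, or orientation tilt) through 18 logarithmically spaced values,
one second per step, with the first and last step each repeated once as
preview/postview, for a total stimulation time of 20 s.  Pattern reversal
at 20 reversals/s drives a steady-state response at 20 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Condition",
    "Direction",
    "StimulusSweep",
    "make_sweep_design",
    "default_range",
    "easiness",
    "from_easiness",
    "intensity_increasing",
    "InvalidDesignError",
]


class Condition(str, Enum):
    CONTRAST = "contrast"
    SPATIAL_FREQUENCY = "spatial_frequency"
    ORIENTATION = "orientation"


class Direction(str, Enum):
    INCREASING = "increasing"
    DECREASING = "decreasing"


class InvalidDesignError(ValueError):
    """Raised for impossible sweep specifications."""


#: Native-unit sweep ranges per condition.  Contrast in % Michelson,
#: spatial frequency in cycles/degree, orientation in degrees of tilt.
#: The orientation sweep nominally starts at 0°, which a geometric ladder
#: cannot represent; 0.05° is the configured floor for the lowest step.
DEFAULT_RANGES: dict[Condition, tuple[float, float]] = {
    Condition.CONTRAST: (0.1, 30.0),
    Condition.SPATIAL_FREQUENCY: (2.7, 40.0),
    Condition.ORIENTATION: (0.05, 4.96),
}


def default_range(condition: Condition | str) -> tuple[float, float]:
    return DEFAULT_RANGES[Condition(condition)]


@dataclass(frozen=True)
class StimulusSweep:
    """One sweep trial's stimulus schedule.

    ``step_values`` holds the 18 core steps in presentation (sweep-time)
    order.  ``direction`` refers to the native stimulus parameter: an
    increasing contrast sweep runs 0.1 % -> 30 %, an increasing spatial
    frequency sweep runs 2.7 -> 40 cpd (which is *decreasing* in
    perceptual intensity: high spatial frequencies are harder to see).
    """

    condition: Condition
    direction: Direction
    step_values: tuple[float, ...]
    step_duration: float = 1.0
    preview: bool = True
    postview: bool = True
    reversal_rate: float = 20.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.step_values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise InvalidDesignError("step_values must hold at least two steps")
        if np.any(vals <= 0):
            raise InvalidDesignError("step values must be strictly positive")

    @property
    def n_steps(self) -> int:
        return len(self.step_values)

    @property
    def trial_values(self) -> tuple[float, ...]:
        """Presented values including preview/postview repeats."""
        vals = list(self.step_values)
        if self.preview:
            vals = [vals[0]] + vals
        if self.postview:
            vals = vals + [vals[-1]]
        return tuple(vals)

    @property
    def total_duration(self) -> float:
        """Total stimulation time in seconds (20 s for the default design)."""
        return len(self.trial_values) * self.step_duration

    def core_slice_in_trial(self) -> slice:
        """Index range of the core steps within :attr:`trial_values`."""
        start = 1 if self.preview else 0
        return slice(start, start + self.n_steps)


def make_sweep_design(
    condition: Condition | str,
    direction: Direction | str,
    low: float | None = None,
    high: float | None = None,
    n_steps: int = 18,
    *,
    step_duration: float = 1.0,
    reversal_rate: float = 20.0,
) -> StimulusSweep:
    """Build a geometric (log-spaced) sweep schedule.

    Parameters
    ----------
    condition, direction
        Stimulus parameter being swept and the native-unit sweep direction.
    low, high
        Range endpoints in native units; defaults to the condition's
        standard range (:data:`DEFAULT_RANGES`).
    n_steps
        Number of core steps (default 18).
    """
    condition = Condition(condition)
    direction = Direction(direction)
    if low is None or high is None:
        d_low, d_high = default_range(condition)
        low = d_low if low is None else low
        high = d_high if high is None else high
    if not (0 < low < high):
        raise InvalidDesignError(
            f"require 0 < low < high, got low={low!r} high={high!r}"
        )
    if n_steps < 2:
        raise InvalidDesignError("n_steps must be at least 2")
    values = np.geomspace(low, high, n_steps)
    if direction is Direction.DECREASING:
        values = values[::-1]
    return StimulusSweep(
        condition=condition,
        direction=direction,
        step_values=tuple(float(v) for v in values),
        step_duration=step_duration,
        reversal_rate=reversal_rate,
    )


def easiness(condition: Condition | str, values) -> np.ndarray:
    """Map native units onto the condition's 'easiness' axis.

    Amplitude-vs-stimulus behaviour is modelled as linear on this axis:
    log10 units for contrast and orientation (higher contrast / larger
    tilt = easier), negated linear cycles/degree for spatial frequency
    (finer gratings = harder).
    """
    condition = Condition(condition)
    vals = np.asarray(values, dtype=float)
    if condition is Condition.SPATIAL_FREQUENCY:
        return -vals
    with np.errstate(divide="raise", invalid="raise"):
        return np.log10(vals)


def from_easiness(condition: Condition | str, scaled) -> np.ndarray:
    """Inverse of :func:`easiness`."""
    condition = Condition(condition)
    scaled = np.asarray(scaled, dtype=float)
    if condition is Condition.SPATIAL_FREQUENCY:
        return -scaled
    return np.power(10.0, scaled)


def intensity_increasing(design: StimulusSweep) -> bool:
    """True when perceptual intensity (easiness) grows over sweep time."""
    e = easiness(design.condition, design.step_values)
    return bool(e[-1] > e[0])
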