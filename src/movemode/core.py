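"""Core containers shared by every stage of the pipeline.

A *trip* is a contiguous stretch of travel by a single mode, carrying two
parallel sensor channels sampled at different nominal rates: speed (from
GPS) at 1 Hz and the magnitude of the tri-axial acceleration vector at
5 Hz.  All downstream machinery — movelet dictionaries, windowed feature
tables, classifiers — consumes these objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The five transportation modes, in canonical (tie-breaking) order.
MODES: tuple[str, ...] = ("walk", "bike", "car", "bus", "rail")

#: Nominal speed sampling rate, Hz (one GPS fix per second).
FS: int = 1

#: Nominal accelerometer sampling rate, Hz.
FA: int = 5

#: Metres per second in one mile per hour.
MPS_PER_MPH: float = 0.44704

#: Minimum usable trip duration, seconds.  Shorter trips are dropped:
#: they are unlikely to be characteristic of their mode and cannot host
#: the longest feature windows.
MIN_TRIP_S: int = 120


@dataclass
class Trip:
    """A single-mode bivariate time series.

    Parameters
    ----------
    trip_id
        Identifier, unique within a dataset.
    mode
        One of :data:`MODES`.
    speed
        Speed in mph on the 1 Hz grid, length ``duration_s``.
    accel
        Acceleration magnitude in m/s^2 on the 5 Hz grid, length
        ``5 * duration_s``.
    """

    trip_id: str
    mode: str
    speed: np.ndarray
    accel: np.ndarray

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if len(self.accel) != FA * len(self.speed):
            raise ValueError(
                f"trip {self.trip_id}: accel length {len(self.accel)} is not "
                f"{FA}x speed length {len(self.speed)}"
            )

    @property
    def duration_s(self) -> int:
        """Whole seconds of data in the trip."""
        return len(self.speed)


@dataclass
class SplitAssignment:
    """A 60/20/20 train/validation/test partition of unit identifiers."""

    assignment: dict = field(default_factory=dict)
    seed: int = 0

    def ids(self, part: str) -> list:
        return [u for u, p in self.assignment.items() if p == part]
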