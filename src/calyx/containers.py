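"""Core in-memory containers shared across analysis modules.

Every container that carries physical measurements also carries its unit tag;
downstream code converts explicitly rather than guessing. Times are seconds,
amplitudes are nA (EPSCs) or pA (quanta), capacitance is pF, membrane
potential is mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: multiplicative factors into the "canonical" unit of each family
_AMPLITUDE_TO_NA = {"nA": 1.0, "pA": 1e-3}


class InsufficientDataError(ValueError):
    """Raised when an operation receives fewer observations than it needs."""


@dataclass
class AmplitudeSeries:
    """Ordered EPSC peak amplitudes for one cell under one condition."""

    amplitudes: np.ndarray
    unit: str = "nA"
    condition_label: str = ""
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 1:
            raise ValueError("amplitudes must be one-dimensional")
        if self.unit not in _AMPLITUDE_TO_NA:
            raise ValueError(f"unknown amplitude unit {self.unit!r}")

    def __len__(self) -> int:
        return self.amplitudes.size

    def in_nA(self) -> np.ndarray:
        return self.amplitudes * _AMPLITUDE_TO_NA[self.unit]


@dataclass
class Trace:
    """Uniformly sampled signal with sampling rate and unit tag.

    ``times`` is stored explicitly (strictly increasing, uniform spacing
    1/sampling_rate) so slices of a trace remain valid traces.
    """

    times: np.ndarray
    values: np.ndarray
    sampling_rate: float
    unit: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("time stamps must be strictly increasing")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.times.size else 0.0

    def window(self, t_start: float, t_stop: float) -> "Trace":
        """Sub-trace with t_start <= t < t_stop."""
        mask = (self.times >= t_start) & (self.times < t_stop)
        return Trace(self.times[mask], self.values[mask], self.sampling_rate, self.unit)


@dataclass
class EventSeries:
    """Spike or stimulus times (s) for one unit or terminal."""

    times: np.ndarray
    label: str = ""

    #: events closer than this are considered duplicates (s)
    MERGE_TOL: float = field(default=1e-4, repr=False)

    def __post_init__(self) -> None:
        t = np.sort(np.asarray(self.times, dtype=float))
        if t.size:
            keep = np.concatenate(([True], np.diff(t) > self.MERGE_TOL))
            t = t[keep]
        self.times = t

    def __len__(self) -> int:
        return self.times.size
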