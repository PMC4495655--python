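"""Core containers: uniformly sampled traces and linear temporal filters.

A :class:`Trace` is the universal currency of the pipeline — a uniformly
sampled time series with units (light intensity in R*/photoreceptor/s,
contrast drive, or synaptic-current-like arbitrary units).  A
:class:`LinearFilter` is the impulse response of one pathway (rod or cone)
defined on a lag axis starting at lag 0.
"""
from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "ParameterError",
    "UndefinedIndexError",
    "Trace",
    "LinearFilter",
    "apply_filter",
]


class ParameterError(ValueError):
    """An argument violates a precondition of an operation."""


class UndefinedIndexError(ArithmeticError):
    """An interaction or biphasic index is undefined (zero denominator)."""


def _as_float_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ParameterError(f"expected a 1-d sequence, got shape {arr.shape}")
    return arr


@dataclasses.dataclass(frozen=True)
class Trace:
    """A uniformly sampled time series.

    Parameters
    ----------
    values
        Sample values; finite, length >= 1.
    dt
        Sampling interval in seconds; > 0.
    start_time
        Time of the first sample in seconds.
    units
        Free-form unit label ("R*/s", "contrast", "a.u.", ...).
    """

    values: np.ndarray
    dt: float
    start_time: float = 0.0
    units: str = "a.u."

    def __post_init__(self):
        arr = _as_float_array(self.values)
        if arr.size < 1:
            raise ParameterError("trace must contain at least one sample")
        if not np.all(np.isfinite(arr)):
            raise ParameterError("trace values must be finite")
        if not (self.dt > 0):
            raise ParameterError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * self.values.size

    def index_at(self, t: float) -> int:
        """Index of the sample closest to time ``t`` (must be in range)."""
        i = int(round((t - self.start_time) / self.dt))
        if i < 0 or i >= self.values.size:
            raise ParameterError(f"time {t} s outside trace [{self.start_time}, "
                                 f"{self.start_time + self.duration}) s")
        return i

    def with_values(self, values, units: str | None = None) -> "Trace":
        """A copy of this trace carrying new values on the same time grid."""
        return Trace(values, self.dt, self.start_time,
                     self.units if units is None else units)

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Values of the closed sample window [t0, t1]."""
        i0, i1 = self.index_at(t0), self.index_at(t1)
        return self.values[i0:i1 + 1]


def _check_same_grid(a: Trace, b: Trace, what: str = "traces") -> None:
    if abs(a.dt - b.dt) > 1e-12 * max(a.dt, b.dt):
        raise ParameterError(f"{what} have mismatched dt: {a.dt} vs {b.dt}")
    if len(a) != len(b):
        raise ParameterError(f"{what} have mismatched length: {len(a)} vs {len(b)}")
    if abs(a.start_time - b.start_time) > 1e-9:
        raise ParameterError(f"{what} have mismatched start times")


@dataclasses.dataclass(frozen=True)
class LinearFilter:
    """Impulse response of a pathway, sampled on lags 0, dt, 2*dt, ...

    ``pathway`` labels which photoreceptor pathway the filter describes
    ("rod" or "cone"); None marks a filter of unspecified origin (e.g. an
    estimate before labelling).
    """

    dt: float
    taps: np.ndarray
    pathway: str | None = None

    def __post_init__(self):
        arr = _as_float_array(self.taps)
        if arr.size < 1:
            raise ParameterError("filter must contain at least one tap")
        if not np.all(np.isfinite(arr)):
            raise ParameterError("filter taps must be finite")
        if not (self.dt > 0):
            raise ParameterError(f"dt must be positive, got {self.dt}")
        if self.pathway not in (None, "rod", "cone"):
            raise ParameterError(f"pathway must be 'rod' or 'cone', got {self.pathway!r}")
        object.__setattr__(self, "taps", arr)

    def __len__(self) -> int:
        return self.taps.size

    @property
    def lags(self) -> np.ndarray:
        """Lag axis in seconds."""
        return self.dt * np.arange(self.taps.size)

    @property
    def duration(self) -> float:
        return self.dt * self.taps.size

    @property
    def peak_lag(self) -> float:
        """Lag of the largest positive tap, in seconds."""
        return float(np.argmax(self.taps)) * self.dt

    @property
    def trough_lag(self) -> float:
        """Lag of the most negative tap, in seconds."""
        return float(np.argmin(self.taps)) * self.dt


def apply_filter(filt: LinearFilter, stimulus: Trace) -> Trace:
    """Causal convolution of a stimulus with a filter.

    The discrete sum approximates the continuous convolution, so the output
    is scaled by ``dt``: y[n] = dt * sum_k taps[k] * x[n - k].  A unit-area
    impulse (one sample of height 1/dt) therefore reproduces the filter
    shape exactly.
    """
    if abs(filt.dt - stimulus.dt) > 1e-12 * max(filt.dt, stimulus.dt):
        raise ParameterError(
            f"filter dt {filt.dt} does not match stimulus dt {stimulus.dt}")
    y = np.convolve(stimulus.values, filt.taps)[:len(stimulus)] * filt.dt
    return stimulus.with_values(y, units="generator")
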