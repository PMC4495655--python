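"""Static nonlinearities of the cone bipolar -> ganglion cell synapse.

All nonlinearities are non-decreasing callables defined on the whole real
line, mapping a generator-signal value to an output value.  Closed-form
families (linear, threshold-linear, softplus) live here; the data-driven
piecewise-linear estimate lives in :mod:`rodcone.ln`.
"""
from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np

from .core import ParameterError

__all__ = [
    "Nonlinearity",
    "Linear",
    "ThresholdLinear",
    "Softplus",
    "nonlinearity_from_dict",
]


class Nonlinearity:
    """Base class: a non-decreasing map from generator signal to output."""

    family: str = "abstract"

    def __call__(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def to_dict(self) -> dict[str, Any]:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclasses.dataclass(frozen=True)
class Linear(Nonlinearity):
    """N(x) = baseline + gain * x.  With gain 1, baseline 0 this is the
    identity — the linear-summation null model in which all interaction
    indices vanish."""

    gain: float = 1.0
    baseline: float = 0.0
    family = "linear"

    def __post_init__(self):
        if self.gain < 0:
            raise ParameterError("gain must be >= 0 for a non-decreasing map")

    def __call__(self, x):
        return self.baseline + self.gain * np.asarray(x, dtype=float)

    def to_dict(self):
        return {"family": self.family, "gain": self.gain, "baseline": self.baseline}


@dataclasses.dataclass(frozen=True)
class ThresholdLinear(Nonlinearity):
    """Rectifier: N(x) = baseline + gain * max(x - threshold, 0).

    The half-wave rectification suppresses generator signals below the
    threshold — the property that converts the rod filter's hyperpolarizing
    overshoot into suppression of a subsequent cone response.
    """

    threshold: float
    gain: float = 1.0
    baseline: float = 0.0
    family = "threshold_linear"

    def __post_init__(self):
        if self.gain < 0:
            raise ParameterError("gain must be >= 0 for a non-decreasing map")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.baseline + self.gain * np.maximum(x - self.threshold, 0.0)

    def to_dict(self):
        return {"family": self.family, "threshold": self.threshold,
                "gain": self.gain, "baseline": self.baseline}


@dataclasses.dataclass(frozen=True)
class Softplus(Nonlinearity):
    """Smooth rectifier: N(x) = baseline + gain * s * log(1 + exp((x - threshold)/s)).

    ``sharpness`` (s) sets the width of the soft corner; as s -> 0 this
    approaches :class:`ThresholdLinear`.
    """

    threshold: float
    gain: float = 1.0
    baseline: float = 0.0
    sharpness: float = 1.0
    family = "softplus"

    def __post_init__(self):
        if self.gain < 0:
            raise ParameterError("gain must be >= 0 for a non-decreasing map")
        if self.sharpness <= 0:
            raise ParameterError("sharpness must be > 0")

    def __call__(self, x):
        z = (np.asarray(x, dtype=float) - self.threshold) / self.sharpness
        # log1p(exp(z)) computed stably for large |z|
        soft = np.where(z > 30, z, np.log1p(np.exp(np.minimum(z, 30.0))))
        return self.baseline + self.gain * self.sharpness * soft

    def to_dict(self):
        return {"family": self.family, "threshold": self.threshold,
                "gain": self.gain, "baseline": self.baseline,
                "sharpness": self.sharpness}


def nonlinearity_from_dict(d: dict[str, Any]) -> Nonlinearity:
    """Reconstruct a nonlinearity from its JSON-serializable dict."""
    d = dict(d)
    family = d.pop("family", None)
    if family == "linear":
        return Linear(**d)
    if family == "threshold_linear":
        return ThresholdLinear(**d)
    if family == "softplus":
        return Softplus(**d)
    if family == "estimate":
        from .ln import NonlinearityEstimate
        return NonlinearityEstimate.from_dict({"family": "estimate", **d})
    raise ParameterError(f"unknown nonlinearity family {family!r}")
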