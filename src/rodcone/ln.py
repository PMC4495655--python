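"""Linear-nonlinear (LN) cascade estimation from noise stimuli.

The linear filter is recovered by reverse correlation — cross-spectrum
divided by the (regularized) stimulus power spectrum — and the static
nonlinearity by comparing the filter output (the generator signal) with the
measured response in quantile bins.  Because the amplitude of an LN cascade
can sit in either stage, filters are peak-normalized and all gain is
absorbed into the nonlinearity.
"""
from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np
from scipy import fft as sp_fft

from .core import LinearFilter, ParameterError, Trace, apply_filter
from .nonlinearities import Nonlinearity

__all__ = [
    "LNModel",
    "NonlinearityEstimate",
    "estimate_filter",
    "estimate_nonlinearity",
    "evaluate_ln",
    "normalize_filter",
]


@dataclasses.dataclass(frozen=True)
class LNModel:
    """A linear filter followed by a static nonlinearity."""

    filter: LinearFilter
    nonlinearity: Nonlinearity
    dt: float

    def __post_init__(self):
        if abs(self.filter.dt - self.dt) > 1e-12 * self.dt:
            raise ParameterError("filter dt must equal model dt")


def estimate_filter(stimulus: Trace, response: Trace, max_lag: float = 0.5,
                    passband: tuple[float, float] = (0.0, 60.0),
                    ridge: float = 0.01,
                    pathway: str | None = None) -> LinearFilter:
    """Estimate the linear filter by regularized reverse correlation.

    The estimate is the inverse transform of

        H(f) = conj(S(f)) R(f) / (|S(f)|^2 + ridge * mean|S|^2)

    truncated to lags [0, max_lag] and restricted to the stimulus passband.
    The ridge regularizes frequencies the band-limited stimulus does not
    drive; without it the naive cross-correlation returns the filter
    convolved with the stimulus autocorrelation.

    ``stimulus`` should be the contrast drive; both traces are
    mean-subtracted internally.
    """
    if abs(stimulus.dt - response.dt) > 1e-12 * stimulus.dt:
        raise ParameterError("stimulus and response have mismatched dt")
    if len(stimulus) != len(response):
        raise ParameterError("stimulus and response have mismatched length")
    s = stimulus.values - stimulus.values.mean()
    if s.std() == 0:
        raise ParameterError("stimulus has zero variance; filter undefined")
    r = response.values - response.values.mean()

    dt = stimulus.dt
    n_lag = int(round(max_lag / dt))
    if n_lag < 1:
        raise ParameterError("max_lag must cover at least one sample")
    # zero-pad so the circular deconvolution approximates linear convolution
    nfft = sp_fft.next_fast_len(len(s) + n_lag)
    S = np.fft.rfft(s, nfft)
    R = np.fft.rfft(r, nfft)
    power = np.abs(S) ** 2
    H = np.conj(S) * R / (power + ridge * power.mean())
    freqs = np.fft.rfftfreq(nfft, dt)
    low, high = passband
    keep = (freqs >= low) & (freqs <= high)
    if low == 0:
        keep[0] = True
    H[~keep] = 0.0
    taps = np.fft.irfft(H, nfft)[:n_lag] / dt
    return LinearFilter(dt, taps, pathway)


def normalize_filter(filt: LinearFilter) -> LinearFilter:
    """Peak-normalize a filter: max |tap| becomes 1, positive (ON) peak."""
    taps = filt.taps
    peak = taps[np.argmax(np.abs(taps))]
    if peak == 0:
        raise ParameterError("cannot normalize an all-zero filter")
    # dividing by a negative peak flips the sign, enforcing a positive peak
    return LinearFilter(filt.dt, taps / peak, filt.pathway)


@dataclasses.dataclass(frozen=True)
class NonlinearityEstimate(Nonlinearity):
    """Piecewise-linear nonlinearity estimated from binned data.

    Knots pair the mean generator-signal value of each quantile bin with the
    mean response in that bin.  Between knots the map interpolates linearly;
    beyond the knot range it extrapolates linearly with the end-segment
    slopes, floored at the minimum observed response on the low side (flash
    prediction evaluates the map well outside the noise-sampled range, so
    the extrapolation rule matters and is part of the serialized model).
    """

    gen_knots: np.ndarray
    resp_knots: np.ndarray
    counts: np.ndarray
    family = "estimate"

    def __post_init__(self):
        g = np.asarray(self.gen_knots, dtype=float)
        y = np.asarray(self.resp_knots, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if not (g.size == y.size == c.size) or g.size < 2:
            raise ParameterError("need at least two aligned knots")
        if np.any(np.diff(g) <= 0):
            raise ParameterError("knot generator values must strictly increase")
        if np.any(np.diff(y) < -1e-12 * max(1.0, np.abs(y).max())):
            raise ParameterError("knot responses must be non-decreasing")
        object.__setattr__(self, "gen_knots", g)
        object.__setattr__(self, "resp_knots", y)
        object.__setattr__(self, "counts", c)

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        g, y = self.gen_knots, self.resp_knots
        out = np.interp(x, g, y)
        lo_slope = (y[1] - y[0]) / (g[1] - g[0])
        hi_slope = (y[-1] - y[-2]) / (g[-1] - g[-2])
        below, above = x < g[0], x > g[-1]
        out = np.where(below, np.maximum(y[0] + lo_slope * (x - g[0]), y.min()), out)
        out = np.where(above, y[-1] + hi_slope * (x - g[-1]), out)
        return out

    def to_dict(self) -> dict[str, Any]:
        return {"family": self.family,
                "gen_knots": self.gen_knots.tolist(),
                "resp_knots": self.resp_knots.tolist(),
                "counts": self.counts.tolist()}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "NonlinearityEstimate":
        return cls(np.asarray(d["gen_knots"]), np.asarray(d["resp_knots"]),
                   np.asarray(d["counts"]))


def _pool_adjacent_violators(gen, resp, counts):
    """Merge adjacent bins whose mean responses violate monotonicity
    (weighted pool-adjacent-violators on the binned means)."""
    blocks: list[list[float]] = []  # [sum_w*g, sum_w*y, w]
    for g, y, c in zip(gen, resp, counts):
        blocks.append([g * c, y * c, c])
        while len(blocks) > 1 and (blocks[-1][1] / blocks[-1][2]
                                   < blocks[-2][1] / blocks[-2][2]):
            b = blocks.pop()
            blocks[-1] = [blocks[-1][0] + b[0], blocks[-1][1] + b[1],
                          blocks[-1][2] + b[2]]
    g = np.array([b[0] / b[2] for b in blocks])
    y = np.array([b[1] / b[2] for b in blocks])
    c = np.array([b[2] for b in blocks])
    return g, y, c


def estimate_nonlinearity(stimulus: Trace, response: Trace,
                          filt: LinearFilter, n_bins: int = 40,
                          min_occupancy: int = 50) -> NonlinearityEstimate:
    """Estimate the static nonlinearity by quantile binning.

    The generator signal (stimulus convolved with the filter) is split into
    ``n_bins`` quantile bins; each knot is (bin mean generator value, bin
    mean response).  The initial convolution transient (one filter length)
    is discarded.  Monotonicity violations from noise are resolved by
    pooling adjacent violating bins.
    """
    if n_bins < 5:
        raise ParameterError("n_bins must be >= 5")
    gen = apply_filter(filt, stimulus).values
    skip = len(filt)
    if len(gen) - skip < n_bins * min_occupancy:
        raise ParameterError(
            f"need at least n_bins*min_occupancy = {n_bins * min_occupancy} "
            f"usable samples, got {max(len(gen) - skip, 0)}")
    g = gen[skip:]
    r = response.values[skip:]
    if np.unique(g).size < n_bins:
        raise ParameterError("fewer distinct generator values than bins")

    edges = np.quantile(g, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, g, side="right") - 1, 0, edges.size - 2)
    counts = np.bincount(idx, minlength=edges.size - 1)
    keep = counts > 0
    sums_g = np.bincount(idx, weights=g, minlength=edges.size - 1)[keep]
    sums_r = np.bincount(idx, weights=r, minlength=edges.size - 1)[keep]
    counts = counts[keep]
    gk, yk, ck = _pool_adjacent_violators(sums_g / counts, sums_r / counts, counts)
    # pooling can still leave exactly-equal generator means; nudge apart
    if np.any(np.diff(gk) <= 0):
        raise ParameterError("degenerate generator distribution")
    return NonlinearityEstimate(gk, yk, ck)


def evaluate_ln(model: LNModel, stimulus: Trace) -> Trace:
    """Evaluate an LN model on a stimulus: N(L * stimulus), causal."""
    gen = apply_filter(model.filter, stimulus)
    return gen.with_values(np.asarray(model.nonlinearity(gen.values)),
                           units="a.u.")
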