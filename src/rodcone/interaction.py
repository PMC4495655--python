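"""Paired-flash interaction prediction and the interaction/biphasic indices.

The interaction index quantifies how much an "adapt" flash suppresses the
response to a subsequent "test" flash:

    II = 1 - R_pair / R_single

where R_single is the integral of the test-alone response and R_pair the
integral of the test response in the paired condition (paired response
minus adapt-alone response).  II = 0 is linear summation; II = 1 is
complete suppression of the test response.

Parameter-free predictions follow the LN recipe: scale each pathway's
linear filter so its output through the shared nonlinearity matches the
measured single-flash amplitude, offset the scaled filters in time, sum
them, and pass the sum through the common nonlinearity.

The biphasic index quantifies the hyperpolarizing overshoot of a flash
response: BI = A_H / (A_H + A_D) with A_D the maximum depolarization and
A_H the maximum hyperpolarization within 400 ms of the flash.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize

from .core import LinearFilter, ParameterError, Trace, UndefinedIndexError
from .ln import LNModel
from .nonlinearities import Nonlinearity

__all__ = [
    "FlashScaling",
    "InteractionResult",
    "BiphasicResult",
    "OffsetSweep",
    "scale_filter_to_flash",
    "predict_flash_response",
    "predict_paired_response",
    "interaction_index",
    "offset_sweep",
    "biphasic_index",
    "DEFAULT_WINDOW",
    "DEFAULT_OFFSETS",
]

#: Integration window (s) for R_single / R_pair after test-flash onset.
DEFAULT_WINDOW = 0.6

#: Default adapt-test offset grid (s): 0 to 0.8 in 25 ms steps.
DEFAULT_OFFSETS = np.round(np.arange(0.0, 0.8 + 1e-9, 0.025), 6)


@dataclasses.dataclass(frozen=True)
class FlashScaling:
    """Filter amplitude scale matching a measured single-flash peak.

    ``alpha`` multiplies the (peak-normalized) linear filter so that
    max_t N(alpha * L(t)) - N(0) equals ``target_peak``.
    """

    alpha: float
    target_peak: float
    pathway: str | None = None

    def __post_init__(self):
        if self.alpha <= 0:
            raise ParameterError("alpha must be > 0 for an ON response")


@dataclasses.dataclass(frozen=True)
class InteractionResult:
    """R_single, R_pair (response integrals) and II for one protocol."""

    r_single: float
    r_pair: float
    window: tuple[float, float]

    @property
    def ii(self) -> float:
        return 1.0 - self.r_pair / self.r_single

    @property
    def facilitation(self) -> bool:
        """True when the adapt flash enhanced the test response (II < 0)."""
        return self.ii < 0

    @property
    def overshoot_suppression(self) -> bool:
        """True when R_pair went negative, driving II above 1."""
        return self.ii > 1


@dataclasses.dataclass(frozen=True)
class BiphasicResult:
    """Depolarization/hyperpolarization amplitudes and the biphasic index."""

    a_d: float
    a_h: float

    @property
    def bi(self) -> float:
        return self.a_h / (self.a_h + self.a_d)


def scale_filter_to_flash(model: LNModel, target_peak: float,
                          max_doublings: int = 60) -> FlashScaling:
    """Find the filter scale alpha whose LN output peak matches a flash.

    Solves max_t N(alpha * L(t)) - N(0) = target_peak by bisection; the
    left side is non-decreasing in alpha because N is non-decreasing, so
    the root is unique up to flat stretches of N.
    """
    if target_peak <= 0:
        raise ParameterError("target_peak must be > 0")
    taps = model.filter.taps
    nonlin = model.nonlinearity
    base = float(np.asarray(nonlin(0.0)))

    def excess(alpha: float) -> float:
        return float(np.max(nonlin(alpha * taps))) - base - target_peak

    lo, hi = 0.0, 1.0
    for _ in range(max_doublings):
        if excess(hi) > 0:
            break
        hi *= 2.0
    else:
        raise ParameterError(
            "nonlinearity appears bounded above; cannot reach target peak")
    alpha = optimize.brentq(excess, lo, hi, xtol=1e-12, rtol=1e-12)
    return FlashScaling(alpha=float(alpha), target_peak=target_peak,
                        pathway=model.filter.pathway)


def _flash_generator(filt: LinearFilter, alpha: float, onset: float,
                     n: int, dt: float) -> np.ndarray:
    """alpha * L(t - onset) on an n-sample grid starting at t = 0."""
    gen = np.zeros(n)
    i0 = int(round(onset / dt))
    if i0 < 0:
        raise ParameterError("flash onset must be >= 0")
    m = min(len(filt), n - i0)
    if m > 0:
        gen[i0:i0 + m] = alpha * filt.taps[:m]
    return gen


def predict_flash_response(model: LNModel, scaling: FlashScaling,
                           onset: float, duration: float) -> Trace:
    """Predicted response to a single flash: N(alpha * L(t - onset))."""
    dt = model.dt
    n = int(round(duration / dt))
    gen = _flash_generator(model.filter, scaling.alpha, onset, n, dt)
    return Trace(np.asarray(model.nonlinearity(gen)), dt, units="a.u.")


def predict_paired_response(adapt_filter: LinearFilter, adapt_alpha: float,
                            test_filter: LinearFilter, test_alpha: float,
                            offset: float, shared_nonlinearity: Nonlinearity,
                            adapt_onset: float, duration: float) -> Trace:
    """Predicted paired-flash response.

    The scaled adapt and test filters are offset in time by ``offset``,
    summed, and passed through the common nonlinearity:
    N(alpha_a L_a(t - t0) + alpha_t L_t(t - t0 - offset)).
    """
    if abs(adapt_filter.dt - test_filter.dt) > 1e-12 * adapt_filter.dt:
        raise ParameterError("adapt and test filters have mismatched dt")
    if offset < 0:
        raise ParameterError("offset must be >= 0")
    dt = adapt_filter.dt
    n = int(round(duration / dt))
    gen = (_flash_generator(adapt_filter, adapt_alpha, adapt_onset, n, dt)
           + _flash_generator(test_filter, test_alpha, adapt_onset + offset, n, dt))
    return Trace(np.asarray(shared_nonlinearity(gen)), dt, units="a.u.")


def _baseline(trace: Trace, baseline: float | None, adapt_onset: float | None,
              test_onset: float, pre_window: float = 0.5) -> float:
    if baseline is not None:
        return float(baseline)
    anchor = adapt_onset if adapt_onset is not None else test_onset
    t0 = max(trace.start_time, anchor - pre_window)
    i0 = trace.index_at(t0)
    i1 = max(trace.index_at(max(anchor - trace.dt, trace.start_time)), i0)
    return float(trace.values[i0:i1 + 1].mean())


def interaction_index(test_alone: Trace, paired: Trace, adapt_alone: Trace,
                      test_onset: float, window: float = DEFAULT_WINDOW,
                      baseline: float | None = None,
                      adapt_onset: float | None = None,
                      min_r_single: float = 1e-12) -> InteractionResult:
    """Compute the paired-flash interaction index from three traces.

    The baseline (explicit value, or the mean over the 0.5 s preceding the
    adapt flash — preceding the test flash if no adapt onset is given) is
    subtracted from each trace.  R_single integrates the test-alone trace
    over [test_onset, test_onset + window]; R_pair integrates
    (paired - adapt_alone) over the same window; II = 1 - R_pair/R_single.

    II is reported as computed: values < 0 flag facilitation and values > 1
    flag overshoot-driven suppression (see :class:`InteractionResult`).
    """
    for tr in (paired, adapt_alone):
        if abs(tr.dt - test_alone.dt) > 1e-12 * test_alone.dt or \
                len(tr) != len(test_alone) or \
                abs(tr.start_time - test_alone.start_time) > 1e-9:
            raise ParameterError("traces must share the time grid")
    dt = test_alone.dt
    t1 = test_onset + window
    b_test = _baseline(test_alone, baseline, adapt_onset, test_onset)
    b_pair = _baseline(paired, baseline, adapt_onset, test_onset)
    b_adapt = _baseline(adapt_alone, baseline, adapt_onset, test_onset)

    seg_test = test_alone.window(test_onset, t1) - b_test
    seg_pair = paired.window(test_onset, t1) - b_pair
    seg_adapt = adapt_alone.window(test_onset, t1) - b_adapt
    r_single = float(np.trapezoid(seg_test, dx=dt))
    r_pair = float(np.trapezoid(seg_pair - seg_adapt, dx=dt))
    if abs(r_single) < min_r_single:
        raise UndefinedIndexError(
            f"R_single = {r_single:g} below tolerance; interaction index undefined")
    return InteractionResult(r_single=r_single, r_pair=r_pair,
                             window=(test_onset, t1))


@dataclasses.dataclass(frozen=True)
class OffsetSweep:
    """Interaction index as a function of adapt-test offset."""

    offsets: np.ndarray
    indices: np.ndarray
    direction: str

    @property
    def peak_offset(self) -> float:
        """Offset of the maximal index; ties break toward the smaller offset."""
        return float(self.offsets[int(np.argmax(self.indices))])

    @property
    def peak_index(self) -> float:
        return float(np.max(self.indices))


def offset_sweep(rod: tuple[LinearFilter, float], cone: tuple[LinearFilter, float],
                 shared_nonlinearity: Nonlinearity,
                 offsets=DEFAULT_OFFSETS, direction: str = "rod-cone",
                 window: float = DEFAULT_WINDOW,
                 adapt_onset: float = 0.5) -> OffsetSweep:
    """Sweep the adapt-test offset and compute II at each offset.

    ``rod`` and ``cone`` are (filter, alpha) pairs from
    :func:`scale_filter_to_flash`.  ``direction`` selects which pathway
    delivers the adapt flash: "rod-cone" (rod adapts, cone tests) or
    "cone-rod".  Predictions are noise-free, so the model baseline N(0) is
    used exactly.
    """
    offsets = np.asarray(offsets, dtype=float)
    if np.any(offsets < 0) or np.any(np.diff(offsets) < 0):
        raise ParameterError("offsets must be non-negative and sorted")
    if direction == "rod-cone":
        (a_filt, a_alpha), (t_filt, t_alpha) = rod, cone
    elif direction == "cone-rod":
        (a_filt, a_alpha), (t_filt, t_alpha) = cone, rod
    else:
        raise ParameterError(f"direction must be 'rod-cone' or 'cone-rod', "
                             f"got {direction!r}")
    dt = a_filt.dt
    base = float(np.asarray(shared_nonlinearity(0.0)))
    duration = (adapt_onset + float(offsets.max())
                + max(window, t_filt.duration) + 0.1)
    n = int(round(duration / dt))

    gen_adapt = _flash_generator(a_filt, a_alpha, adapt_onset, n, dt)
    adapt_alone = Trace(np.asarray(shared_nonlinearity(gen_adapt)), dt)
    iis = np.empty(offsets.size)
    for k, off in enumerate(offsets):
        test_onset = adapt_onset + off
        gen_test = _flash_generator(t_filt, t_alpha, test_onset, n, dt)
        test_alone = Trace(np.asarray(shared_nonlinearity(gen_test)), dt)
        paired = Trace(np.asarray(shared_nonlinearity(gen_adapt + gen_test)), dt)
        res = interaction_index(test_alone, paired, adapt_alone,
                                test_onset=test_onset, window=window,
                                baseline=base)
        iis[k] = res.ii
    return OffsetSweep(offsets=offsets, indices=iis, direction=direction)


def biphasic_index(response: Trace, flash_onset: float,
                   window: float = 0.4,
                   baseline: float | None = None) -> BiphasicResult:
    """Biphasic index of a flash response.

    After subtracting the baseline (pre-flash mean by default), A_D is the
    maximum positive excursion and A_H the maximum negative excursion
    magnitude within ``window`` (400 ms) of the flash onset;
    BI = A_H / (A_H + A_D).
    """
    end = flash_onset + window
    if end > response.start_time + response.duration:
        raise ParameterError(
            f"trace must cover [{flash_onset}, {end}] s after the flash")
    b = _baseline(response, baseline, None, flash_onset)
    i0 = response.index_at(flash_onset)
    i1 = min(i0 + int(round(window / response.dt)), len(response) - 1)
    seg = response.values[i0:i1 + 1] - b
    a_d = float(max(seg.max(), 0.0)) + 0.0  # normalize -0.0
    a_h = float(max(-seg.min(), 0.0)) + 0.0
    if a_d + a_h == 0:
        raise UndefinedIndexError("flat response; biphasic index undefined")
    return BiphasicResult(a_d=a_d, a_h=a_h)
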