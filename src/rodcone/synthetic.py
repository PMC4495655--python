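"""Synthetic retina: ground-truth filters, stimuli, responses, calibration.

This module generates data with the statistical structure the analysis
assumes: band-limited Gaussian-noise light stimuli on a mesopic background
(~20 R*/rod/s), brief (10 ms) rod- and cone-preferring flashes, and
ganglion-cell-input-like responses built by convolving stimuli with
kinetically distinct rod/cone filters, summing, and passing the sum through
a shared rectifying nonlinearity plus additive noise.

The rod pathway filter is slow and strongly biphasic (a depolarizing lobe
followed by a hyperpolarizing overshoot); the cone filter is faster and only
weakly biphasic.  That kinetic difference, combined with the shared
rectifier, is the mechanism that produces asymmetric rod->cone vs cone->rod
suppression.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import optimize

from .core import LinearFilter, ParameterError, Trace, apply_filter
from .nonlinearities import Nonlinearity, ThresholdLinear

__all__ = [
    "ROD_FILTER_PRESET",
    "CONE_FILTER_PRESET",
    "DEFAULT_DT",
    "DEFAULT_BACKGROUND",
    "NoiseStimulusSpec",
    "FlashStimulus",
    "PhotoreceptorCalibration",
    "make_biphasic_filter",
    "rod_filter",
    "cone_filter",
    "generate_noise_stimulus",
    "generate_flash_stimulus",
    "contrast_drive",
    "simulate_response",
    "generator_sd",
    "default_shared_nonlinearity",
    "photoisomerization_rate",
    "rod_calibration",
    "cone_calibration",
]

#: Default sampling interval (s); 1 kHz resolves 10 ms flashes and 60 Hz noise.
DEFAULT_DT = 0.001

#: Default mesopic background in R*/rod/s.
DEFAULT_BACKGROUND = 20.0

#: Rod pathway: slow, strongly biphasic (large hyperpolarizing overshoot).
ROD_FILTER_PRESET = {"peak_time": 0.10, "undershoot_time": 0.20,
                     "undershoot_ratio": 0.5}

#: Cone pathway: fast, weakly biphasic.
CONE_FILTER_PRESET = {"peak_time": 0.05, "undershoot_time": 0.12,
                      "undershoot_ratio": 0.1}

_GAMMA_ORDER = 4  # shape order of each gamma lobe


def _gamma_lobe(t: np.ndarray, peak: float) -> np.ndarray:
    """Gamma-shaped lobe of order ``_GAMMA_ORDER``, unit peak at ``peak``."""
    n = _GAMMA_ORDER
    with np.errstate(invalid="ignore"):
        g = np.where(t > 0, (t / peak) ** n * np.exp(n * (1.0 - t / peak)), 0.0)
    return g


def make_biphasic_filter(peak_time: float, undershoot_time: float,
                         undershoot_ratio: float, dt: float = DEFAULT_DT,
                         duration: float = 0.5,
                         pathway: str | None = None) -> LinearFilter:
    """Build a biphasic impulse response as a difference of two gamma lobes.

    The depolarizing lobe is an order-4 gamma peaking at ``peak_time``; the
    hyperpolarizing lobe is an order-4 gamma delayed to start at
    ``peak_time`` (a delayed gamma rises with four vanishing derivatives,
    so it leaves the position of the positive peak untouched).  The delayed
    lobe's width and amplitude are solved so that the summed waveform has
    its minimum at ``undershoot_time`` and a trough/peak amplitude ratio of
    ``undershoot_ratio``.  The result is peak-normalized to a maximum of 1.

    Parameters
    ----------
    peak_time, undershoot_time
        Times (s) of the depolarizing peak and hyperpolarizing trough;
        require 0 < peak_time < undershoot_time < duration.
    undershoot_ratio
        |trough| / peak in [0, 1); 0 gives a monophasic filter.
    """
    if not (0 < peak_time < undershoot_time < duration):
        raise ParameterError(
            "require 0 < peak_time < undershoot_time < duration, got "
            f"{peak_time}, {undershoot_time}, {duration}")
    if not (0 <= undershoot_ratio < 1):
        raise ParameterError(
            f"undershoot_ratio must be in [0, 1), got {undershoot_ratio}")
    if dt <= 0:
        raise ParameterError("dt must be positive")

    t = dt * np.arange(int(round(duration / dt)))

    if undershoot_ratio == 0:
        taps = _gamma_lobe(t, peak_time)
        return LinearFilter(dt, taps / taps.max(), pathway)

    tp, tu = peak_time, undershoot_time
    # solve (width, amplitude) of the delayed lobe on an oversampled grid
    fine = (dt / 8.0) * np.arange(int(round(duration * 8.0 / dt)))
    pos = _gamma_lobe(fine, tp)
    width = tu - tp
    r = undershoot_ratio
    for _ in range(200):
        neg = _gamma_lobe(fine - tp, width)

        def ratio_error(rr):
            f = pos - rr * neg
            return -f.min() / f.max() - undershoot_ratio

        r = optimize.brentq(ratio_error, 1e-12, 50.0, xtol=1e-14)
        f = pos - r * neg
        trough_err = tu - fine[np.argmin(f)]
        if abs(trough_err) < dt / 8.0:
            break
        width = max(width + 0.6 * trough_err, dt)
    else:
        if abs(trough_err) > 2 * dt:
            raise ParameterError(
                f"could not place the undershoot trough at {undershoot_time} s "
                f"with ratio {undershoot_ratio}")
    taps = _gamma_lobe(t, tp) - r * _gamma_lobe(t - tp, width)
    return LinearFilter(dt, taps / taps.max(), pathway)


def rod_filter(dt: float = DEFAULT_DT, duration: float = 0.5) -> LinearFilter:
    """The default rod pathway filter (slow, strongly biphasic)."""
    return make_biphasic_filter(dt=dt, duration=duration, pathway="rod",
                                **ROD_FILTER_PRESET)


def cone_filter(dt: float = DEFAULT_DT, duration: float = 0.5) -> LinearFilter:
    """The default cone pathway filter (fast, weakly biphasic)."""
    return make_biphasic_filter(dt=dt, duration=duration, pathway="cone",
                                **CONE_FILTER_PRESET)


@dataclasses.dataclass(frozen=True)
class NoiseStimulusSpec:
    """Band-limited Gaussian noise stimulus specification.

    Defaults emulate the stimulus used for LN estimation: 50% contrast
    Gaussian noise, band-limited to 0-60 Hz, on a ~20 R*/rod/s background.
    """

    mean: float = DEFAULT_BACKGROUND
    contrast: float = 0.5
    bandwidth: tuple[float, float] = (0.0, 60.0)
    duration: float = 300.0
    dt: float = DEFAULT_DT

    def __post_init__(self):
        low, high = self.bandwidth
        nyquist = 0.5 / self.dt
        if self.contrast < 0:
            raise ParameterError("contrast must be >= 0")
        if not (0 <= low < high <= nyquist):
            raise ParameterError(
                f"bandwidth must satisfy 0 <= low < high <= Nyquist "
                f"({nyquist} Hz), got {self.bandwidth}")
        if self.duration <= 0 or self.dt <= 0:
            raise ParameterError("duration and dt must be positive")


def generate_noise_stimulus(spec: NoiseStimulusSpec, seed: int) -> Trace:
    """Generate a band-limited Gaussian noise stimulus.

    A Gaussian white sequence is brick-wall filtered in the frequency
    domain to the requested band, rescaled so its sample SD equals
    contrast * mean exactly, and offset to the requested mean.  Negative
    excursions are not clipped (the model operates on contrast drive, and
    clipping would distort the Gaussianity that reverse correlation
    assumes).
    """
    n = int(round(spec.duration / spec.dt))
    low, high = spec.bandwidth
    if low > 0 and spec.duration < 10.0 / low:
        warnings.warn(
            f"duration {spec.duration} s resolves fewer than 10 cycles of the "
            f"low cutoff {low} Hz; band-limiting will be imprecise",
            stacklevel=2)
    if spec.contrast == 0:
        return Trace(np.full(n, spec.mean), spec.dt, units="R*/s")

    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, spec.dt)
    keep = (freqs >= low) & (freqs <= high)
    keep[0] = False  # the mean is set explicitly below
    spectrum[~keep] = 0.0
    x = np.fft.irfft(spectrum, n)
    sd = x.std()
    if sd == 0:
        raise ParameterError("requested band contains no Fourier modes")
    x *= spec.contrast * spec.mean / sd
    return Trace(x - x.mean() + spec.mean, spec.dt, units="R*/s")


@dataclasses.dataclass(frozen=True)
class FlashStimulus:
    """A rectangular flash: ``strength`` units above background for
    ``duration`` seconds starting at ``onset``."""

    onset: float
    strength: float
    duration: float = 0.01
    pathway: str | None = None

    def __post_init__(self):
        if self.duration <= 0:
            raise ParameterError("flash duration must be > 0")
        if self.strength < 0:
            raise ParameterError("flash strength must be >= 0")


def generate_flash_stimulus(background: float, flashes: list[FlashStimulus],
                            duration: float, dt: float = DEFAULT_DT) -> Trace:
    """Constant background with rectangular flash pulses added on top."""
    n = int(round(duration / dt))
    values = np.full(n, float(background))
    intervals: list[tuple[float, float, str | None]] = []
    for fl in flashes:
        if fl.onset < 0 or fl.onset + fl.duration > duration + 1e-12:
            raise ParameterError(
                f"flash at {fl.onset} s does not fit in {duration} s")
        for (a, b, pw) in intervals:
            if pw == fl.pathway and fl.onset < b and a < fl.onset + fl.duration:
                raise ParameterError(
                    f"overlapping {pw} flashes at {a} s and {fl.onset} s")
        intervals.append((fl.onset, fl.onset + fl.duration, fl.pathway))
        i0 = int(round(fl.onset / dt))
        i1 = int(round((fl.onset + fl.duration) / dt))
        values[i0:i1] += fl.strength
    return Trace(values, dt, units="R*/s")


def contrast_drive(stimulus: Trace, mean: float | None = None) -> Trace:
    """Convert a raw-intensity stimulus to contrast drive (x - mean)/mean.

    This is the signal convolved with the linear filter; its SD equals the
    stimulus contrast.  ``mean`` defaults to the sample mean.
    """
    m = stimulus.values.mean() if mean is None else float(mean)
    if m == 0:
        raise ParameterError("cannot form contrast drive around a zero mean")
    return stimulus.with_values((stimulus.values - m) / m, units="contrast")


def simulate_response(rod_filter: LinearFilter, cone_filter: LinearFilter,
                      shared_nonlinearity: Nonlinearity,
                      rod_stimulus: Trace, cone_stimulus: Trace,
                      noise_sd: float = 0.0, seed: int | None = None) -> Trace:
    """Simulate a ganglion-cell-input-like response.

    response(t) = N( (L_rod * rod_stim)(t) + (L_cone * cone_stim)(t) ) + noise

    Stimuli must be expressed as contrast drive (deviation from background)
    on a common time grid; convolution is causal.
    """
    if abs(rod_stimulus.dt - cone_stimulus.dt) > 1e-12 * rod_stimulus.dt:
        raise ParameterError("rod and cone stimuli have mismatched dt")
    if len(rod_stimulus) != len(cone_stimulus):
        raise ParameterError("rod and cone stimuli have mismatched length")
    gen = (apply_filter(rod_filter, rod_stimulus).values
           + apply_filter(cone_filter, cone_stimulus).values)
    resp = np.asarray(shared_nonlinearity(gen), dtype=float)
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(0.0, noise_sd, size=resp.size)
    return Trace(resp, rod_stimulus.dt, rod_stimulus.start_time, units="a.u.")


def generator_sd(filt: LinearFilter, spec: NoiseStimulusSpec) -> float:
    """Analytic SD of the generator signal under a noise stimulus.

    The contrast drive of a brick-wall band-limited Gaussian stimulus has a
    flat power spectrum on [low, high] with total variance contrast^2, so
    its autocorrelation is

        R(tau) = contrast^2 * (f_h sinc(2 f_h tau) - f_l sinc(2 f_l tau)) / (f_h - f_l)

    and the generator variance is the quadratic form of R with the filter's
    tap autocorrelation (times dt^2 from the convolution scaling).
    """
    low, high = spec.bandwidth
    taps = filt.taps
    c = np.correlate(taps, taps, mode="full")[taps.size - 1:]
    tau = filt.dt * np.arange(taps.size)
    r = (high * np.sinc(2.0 * high * tau) - low * np.sinc(2.0 * low * tau))
    r *= spec.contrast ** 2 / (high - low)
    var = filt.dt ** 2 * (c[0] * r[0] + 2.0 * np.dot(c[1:], r[1:]))
    return float(np.sqrt(max(var, 0.0)))


def default_shared_nonlinearity(filt: LinearFilter | None = None,
                                spec: NoiseStimulusSpec | None = None,
                                threshold_factor: float = 0.3,
                                gain: float = 1.0) -> ThresholdLinear:
    """The default shared rectifier: threshold-linear with the threshold at
    ``threshold_factor`` times the generator-signal SD under the default
    noise stimulus (rod filter unless given).  This places the rectification
    corner inside the noise-sampled range, producing clear rectification
    while keeping responses in range."""
    if filt is None:
        filt = rod_filter()
    if spec is None:
        spec = NoiseStimulusSpec(dt=filt.dt)
    return ThresholdLinear(threshold=threshold_factor * generator_sd(filt, spec),
                           gain=gain, baseline=0.0)


# --------------------------------------------------------------------------
# Photoisomerization calibration
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PhotoreceptorCalibration:
    """Converts photon flux to photoisomerization rate for one receptor type.

    ``collecting_area`` is the effective light-collecting area in um^2
    (rod 1.0, cone 0.37).  Spectra are sampled on wavelength grids in nm:
    ``emission`` is the stimulus (LED/phosphor) relative power and
    ``absorption`` the photoreceptor relative sensitivity.
    """

    collecting_area: float
    emission_wavelengths: np.ndarray
    emission_power: np.ndarray
    absorption_wavelengths: np.ndarray
    absorption_sensitivity: np.ndarray

    def __post_init__(self):
        if self.collecting_area <= 0:
            raise ParameterError("collecting_area must be > 0")
        for name in ("emission_wavelengths", "emission_power",
                     "absorption_wavelengths", "absorption_sensitivity"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        if (self.emission_wavelengths.size != self.emission_power.size
                or self.absorption_wavelengths.size != self.absorption_sensitivity.size):
            raise ParameterError("spectrum grids and values must align")
        if np.any(self.emission_power < 0) or np.any(self.absorption_sensitivity < 0):
            raise ParameterError("spectra must be non-negative")

    @property
    def spectral_overlap(self) -> float:
        """sum(emission * absorption) / sum(emission) over the shared grid."""
        lo = max(self.emission_wavelengths.min(), self.absorption_wavelengths.min())
        hi = min(self.emission_wavelengths.max(), self.absorption_wavelengths.max())
        mask = (self.emission_wavelengths >= lo) & (self.emission_wavelengths <= hi)
        if not np.any(mask) or lo > hi:
            raise ParameterError(
                "emission and absorption spectra have disjoint wavelength grids")
        wl = self.emission_wavelengths[mask]
        em = self.emission_power[mask]
        ab = np.interp(wl, self.absorption_wavelengths, self.absorption_sensitivity)
        total = em.sum()
        if total == 0:
            raise ParameterError("emission spectrum is zero on the shared grid")
        return float((em * ab).sum() / total)


def photoisomerization_rate(flux: float, cal: PhotoreceptorCalibration) -> float:
    """Photoisomerization rate (R*/photoreceptor/s) from photon flux.

    rate = flux (photons/um^2/s) * collecting area (um^2) * spectral overlap.
    """
    if flux < 0:
        raise ParameterError("flux must be >= 0")
    return flux * cal.collecting_area * cal.spectral_overlap


def _gaussian_spectrum(grid: np.ndarray, peak: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - peak) / width) ** 2)


def rod_calibration() -> PhotoreceptorCalibration:
    """Synthetic rod calibration: blue LED (460 nm peak) emission against a
    rhodopsin-like sensitivity peaking near 500 nm; collecting area 1 um^2."""
    em_wl = np.arange(400.0, 521.0, 2.0)
    ab_wl = np.arange(380.0, 621.0, 2.0)
    return PhotoreceptorCalibration(
        collecting_area=1.0,
        emission_wavelengths=em_wl,
        emission_power=_gaussian_spectrum(em_wl, 460.0, 12.0),
        absorption_wavelengths=ab_wl,
        absorption_sensitivity=_gaussian_spectrum(ab_wl, 500.0, 40.0))


def cone_calibration() -> PhotoreceptorCalibration:
    """Synthetic L-cone calibration: red LED (640 nm peak) emission against
    an L-cone-like sensitivity peaking near 560 nm; collecting area 0.37 um^2."""
    em_wl = np.arange(580.0, 701.0, 2.0)
    ab_wl = np.arange(420.0, 701.0, 2.0)
    return PhotoreceptorCalibration(
        collecting_area=0.37,
        emission_wavelengths=em_wl,
        emission_power=_gaussian_spectrum(em_wl, 640.0, 12.0),
        absorption_wavelengths=ab_wl,
        absorption_sensitivity=_gaussian_spectrum(ab_wl, 560.0, 45.0))
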