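"""End-to-end experiment orchestration.

``run_experiment`` wires the modules into the reproducible desk-scale
experiment suite: generate ground-truth filters and stimuli, simulate
responses, fit LN components, predict paired-flash interactions across
offsets in both directions, run the dichoptic psychophysics simulation,
and write every output with a machine-readable manifest.

``compare_predicted_and_simulated_ii`` is the population-level check of the
mechanism: across random ground-truth systems, interaction indices
predicted from LN components fitted to noisy data are compared with indices
measured from simulated flash responses of the same systems.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from typing import Any

import numpy as np
import pandas as pd

from .core import LinearFilter, Trace
from .interaction import (DEFAULT_WINDOW, biphasic_index, interaction_index,
                          offset_sweep, predict_flash_response,
                          predict_paired_response, scale_filter_to_flash)
from .ln import (LNModel, estimate_filter, estimate_nonlinearity,
                 normalize_filter)
from .nonlinearities import Linear, Nonlinearity
from .psychophysics import (ObserverConfig, simulate_session,
                            summarize_session)
from .readwrite import filter_to_dict, write_model, write_trace
from .synthetic import (CONE_FILTER_PRESET, DEFAULT_DT, ROD_FILTER_PRESET,
                        FlashStimulus, NoiseStimulusSpec, contrast_drive,
                        default_shared_nonlinearity, generate_flash_stimulus,
                        generate_noise_stimulus, make_biphasic_filter,
                        simulate_response)

__all__ = [
    "RunConfig",
    "run_experiment",
    "fit_pathway",
    "compare_predicted_and_simulated_ii",
    "spawn_seeds",
]


def spawn_seeds(root_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent integer seeds (< 2**31) from a root seed."""
    ss = np.random.SeedSequence(root_seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Configuration of the full desk-scale experiment.

    All randomness flows from ``seed`` via named sub-streams, so reruns
    with the same config are deterministic.
    """

    seed: int = 0
    dt: float = DEFAULT_DT
    fit_duration: float = 120.0
    noise_mean: float = 20.0
    noise_contrast: float = 0.5
    noise_band: tuple[float, float] = (0.0, 60.0)
    rod_preset: dict = dataclasses.field(
        default_factory=lambda: dict(ROD_FILTER_PRESET))
    cone_preset: dict = dataclasses.field(
        default_factory=lambda: dict(CONE_FILTER_PRESET))
    filter_duration: float = 0.5
    nonlinearity: str = "threshold"  # "threshold" or "identity"
    threshold_factor: float = 0.3
    response_noise_sd_fraction: float = 0.1  # of the noise-free response SD
    target_peak: float = 1.0
    offset_start: float = 0.0
    offset_stop: float = 0.8
    offset_step: float = 0.025
    window: float = DEFAULT_WINDOW
    shared_estimate: str = "cone"  # which estimated N is shared: cone|average
    observers: int = 4
    trials_per_condition: int = 12
    reference: float = 1.0

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["noise_band"] = list(self.noise_band)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "noise_band" in d:
            d["noise_band"] = tuple(d["noise_band"])
        return cls(**d)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @property
    def offsets(self) -> np.ndarray:
        return np.round(np.arange(self.offset_start,
                                  self.offset_stop + 1e-9,
                                  self.offset_step), 9)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _true_components(config: RunConfig):
    rod = make_biphasic_filter(dt=config.dt, duration=config.filter_duration,
                               pathway="rod", **config.rod_preset)
    cone = make_biphasic_filter(dt=config.dt, duration=config.filter_duration,
                                pathway="cone", **config.cone_preset)
    spec = NoiseStimulusSpec(mean=config.noise_mean,
                             contrast=config.noise_contrast,
                             bandwidth=config.noise_band,
                             duration=config.fit_duration, dt=config.dt)
    if config.nonlinearity == "identity":
        nonlin: Nonlinearity = Linear()
    elif config.nonlinearity == "threshold":
        nonlin = default_shared_nonlinearity(rod, spec,
                                             threshold_factor=config.threshold_factor)
    else:
        raise ValueError(f"unknown nonlinearity {config.nonlinearity!r}")
    return rod, cone, nonlin, spec


def fit_pathway(true_filter: LinearFilter, other_filter: LinearFilter,
                nonlin: Nonlinearity, spec: NoiseStimulusSpec,
                stim_seed: int, noise_seed: int, noise_sd: float,
                max_lag: float = 0.5, n_bins: int = 40,
                min_occupancy: int = 50) -> tuple[LNModel, Trace, Trace]:
    """Fit one pathway's LN components from a noise experiment.

    Only the target pathway is stimulated (the other pathway's stimulus is
    held at background), matching the rod- or cone-preferring noise runs.
    Returns the fitted model (peak-normalized filter, binned nonlinearity)
    plus the stimulus drive and simulated response used for the fit.
    """
    stim = generate_noise_stimulus(spec, stim_seed)
    drive = contrast_drive(stim, mean=spec.mean)
    silent = drive.with_values(np.zeros(len(drive)))
    if true_filter.pathway == "cone":
        rod_drive, cone_drive = silent, drive
        rod_f, cone_f = other_filter, true_filter
    else:
        rod_drive, cone_drive = drive, silent
        rod_f, cone_f = true_filter, other_filter
    resp = simulate_response(rod_f, cone_f, nonlin, rod_drive, cone_drive,
                             noise_sd=noise_sd, seed=noise_seed)
    est = estimate_filter(drive, resp, max_lag=max_lag,
                          passband=spec.bandwidth,
                          pathway=true_filter.pathway)
    est = normalize_filter(est)
    est_n = estimate_nonlinearity(drive, resp, est, n_bins=n_bins,
                                  min_occupancy=min_occupancy)
    return LNModel(filter=est, nonlinearity=est_n, dt=spec.dt), drive, resp


def _response_noise_sd(rod, cone, nonlin, spec, fraction, seed) -> float:
    """Response noise scaled to a fraction of the noise-free response SD
    under the fitting stimulus (a short probe simulation)."""
    probe = dataclasses.replace(spec, duration=min(spec.duration, 30.0))
    stim = generate_noise_stimulus(probe, seed)
    drive = contrast_drive(stim, mean=probe.mean)
    silent = drive.with_values(np.zeros(len(drive)))
    resp = simulate_response(rod, cone, nonlin, drive, silent, noise_sd=0.0)
    return float(fraction * resp.values.std())


def run_experiment(config: RunConfig, outdir: str) -> dict[str, Any]:
    """Run the full pipeline and write the result bundle to ``outdir``.

    Emits true filters, fitted models, offset-sweep tables for both
    directions, interaction/biphasic indices, the psychophysics session
    summary, and a manifest of every output with its generating parameters.
    Deterministic given the config (byte-identical manifests on rerun).
    """
    os.makedirs(outdir, exist_ok=True)
    seeds = spawn_seeds(config.seed, 6)
    s_rod_stim, s_cone_stim, s_rod_noise, s_cone_noise, s_probe, s_obs = seeds

    rod, cone, nonlin, spec = _true_components(config)
    noise_sd = _response_noise_sd(rod, cone, nonlin, spec,
                                  config.response_noise_sd_fraction, s_probe)

    model_rod, drive_rod, resp_rod = fit_pathway(
        rod, cone, nonlin, spec, s_rod_stim, s_rod_noise, noise_sd)
    model_cone, drive_cone, resp_cone = fit_pathway(
        cone, rod, nonlin, spec, s_cone_stim, s_cone_noise, noise_sd)

    outputs: dict[str, str] = {}

    def _path(name: str) -> str:
        outputs[name] = name
        return os.path.join(outdir, name)

    for name, filt in [("rod_filter.json", rod), ("cone_filter.json", cone)]:
        with open(_path(name), "w") as fh:
            json.dump(filter_to_dict(filt), fh, indent=2, sort_keys=True)
            fh.write("\n")
    write_trace(drive_rod, _path("rod_noise_drive.csv"),
                {"seed": s_rod_stim, "contrast": config.noise_contrast})
    write_trace(resp_rod, _path("rod_noise_response.csv"),
                {"seed": s_rod_noise, "noise_sd": noise_sd})
    write_trace(drive_cone, _path("cone_noise_drive.csv"),
                {"seed": s_cone_stim, "contrast": config.noise_contrast})
    write_trace(resp_cone, _path("cone_noise_response.csv"),
                {"seed": s_cone_noise, "noise_sd": noise_sd})
    write_model(model_rod, _path("model_rod.json"))
    write_model(model_cone, _path("model_cone.json"))

    # parameter-free interaction predictions from the configured true
    # components (the estimated models are compared against these in the
    # population-level analysis)
    rod_scale = scale_filter_to_flash(
        LNModel(rod, nonlin, config.dt), config.target_peak)
    cone_scale = scale_filter_to_flash(
        LNModel(cone, nonlin, config.dt), config.target_peak)

    sweeps = {}
    for direction in ("rod-cone", "cone-rod"):
        sweep = offset_sweep((rod, rod_scale.alpha), (cone, cone_scale.alpha),
                             nonlin, offsets=config.offsets,
                             direction=direction, window=config.window)
        df = pd.DataFrame({"offset_s": sweep.offsets, "ii": sweep.indices})
        df.to_csv(_path(f"sweep_{direction}.csv"), index=False)
        sweeps[direction] = sweep

    # biphasic indices of the presynaptic (pre-rectification) flash
    # waveforms -- the kinetic property the suppression mechanism rests on
    rod_flash = predict_flash_response(LNModel(rod, Linear(), config.dt),
                                       rod_scale, onset=0.5, duration=1.2)
    cone_flash = predict_flash_response(LNModel(cone, Linear(), config.dt),
                                        cone_scale, onset=0.5, duration=1.2)
    indices = {
        "ii_rod_cone_0.2s": float(np.interp(0.2, sweeps["rod-cone"].offsets,
                                            sweeps["rod-cone"].indices)),
        "ii_cone_rod_0.2s": float(np.interp(0.2, sweeps["cone-rod"].offsets,
                                            sweeps["cone-rod"].indices)),
        "peak_offset_rod_cone_s": sweeps["rod-cone"].peak_offset,
        "peak_offset_cone_rod_s": sweeps["cone-rod"].peak_offset,
        "bi_rod_flash": biphasic_index(rod_flash, 0.5, baseline=0.0).bi,
        "bi_cone_flash": biphasic_index(cone_flash, 0.5, baseline=0.0).bi,
        "noise_sd": noise_sd,
    }
    with open(_path("indices.json"), "w") as fh:
        json.dump(indices, fh, indent=2, sort_keys=True)
        fh.write("\n")

    # psychophysics sessions
    rows = []
    for i, obs_seed in enumerate(spawn_seeds(s_obs, config.observers)):
        observer = ObserverConfig(seed=obs_seed)
        trials = simulate_session(observer, reference=config.reference,
                                  n_trials=config.trials_per_condition)
        for summary in summarize_session(trials, config.reference):
            rows.append({"observer": i, "condition": summary.condition,
                         "mean_same": summary.mean_same,
                         "mean_separate": summary.mean_separate,
                         "ii": summary.ii, "n_same": summary.n_same,
                         "n_separate": summary.n_separate,
                         "valid": summary.valid})
    pd.DataFrame(rows).to_csv(_path("psychophysics_summary.csv"), index=False)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": {"rod_stimulus": s_rod_stim, "cone_stimulus": s_cone_stim,
                  "rod_response_noise": s_rod_noise,
                  "cone_response_noise": s_cone_noise,
                  "noise_probe": s_probe, "observers": s_obs},
        "outputs": sorted(outputs),
        "indices": indices,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"manifest": manifest, "sweeps": sweeps, "indices": indices,
            "models": {"rod": model_rod, "cone": model_cone},
            "true": {"rod": rod, "cone": cone, "nonlinearity": nonlin}}


def _measured_ii(rod, cone, nonlin, rod_strength, cone_strength, offset,
                 direction, noise_sd, seed, n_trials=8, dt=DEFAULT_DT,
                 window=DEFAULT_WINDOW):
    """Interaction index 'measured' from simulated noisy flash responses,
    averaged over trials as in the recordings (5-20 repeats)."""
    adapt_onset = 0.5
    duration = adapt_onset + offset + max(window, 0.5) + 0.1
    if direction == "rod-cone":
        a_f, a_s, t_f, t_s = rod, rod_strength, cone, cone_strength
    else:
        a_f, a_s, t_f, t_s = cone, cone_strength, rod, rod_strength
    test_onset = adapt_onset + offset

    def mk(flashes, trial_seed):
        # build drive stimuli per pathway and simulate one noisy trial
        rod_flashes = [f for f in flashes if f.pathway == "rod"]
        cone_flashes = [f for f in flashes if f.pathway == "cone"]
        background = 20.0
        rod_stim = generate_flash_stimulus(background, rod_flashes, duration, dt)
        cone_stim = generate_flash_stimulus(background, cone_flashes, duration, dt)
        return simulate_response(rod, cone, nonlin,
                                 contrast_drive(rod_stim, background),
                                 contrast_drive(cone_stim, background),
                                 noise_sd=noise_sd, seed=trial_seed)

    a_flash = FlashStimulus(onset=adapt_onset, strength=a_s,
                            pathway=a_f.pathway)
    t_flash = FlashStimulus(onset=test_onset, strength=t_s,
                            pathway=t_f.pathway)
    seeds = spawn_seeds(seed, 3 * n_trials)
    avg = {}
    for j, flashes in enumerate([[t_flash], [a_flash, t_flash], [a_flash]]):
        trials = [mk(flashes, seeds[3 * k + j]).values
                  for k in range(n_trials)]
        avg[j] = Trace(np.mean(trials, axis=0), dt)
    res = interaction_index(avg[0], avg[1], avg[2], test_onset=test_onset,
                            window=window, adapt_onset=adapt_onset)
    return res.ii, avg


def compare_predicted_and_simulated_ii(
        n_systems: int = 10, seed: int = 0, offset: float = 0.2,
        fit_duration: float = 300.0,
        dt: float = DEFAULT_DT) -> pd.DataFrame:
    """Predicted vs 'measured' interaction indices across random systems.

    For each random ground-truth system (rod/cone filter kinetics and
    rectification threshold drawn from realistic ranges), the 'measured'
    IIs come from trial-averaged noisy flash simulations and the predicted
    IIs from LN components estimated on separate noise experiments, with
    the filters scaled to the measured single-flash amplitudes and the
    cone-derived nonlinearity shared.  Each system contributes both the
    rod->cone and the cone->rod interaction at the given offset, as each
    recorded cell does in the population comparison.  Returns one row per
    (system, direction).
    """
    master = np.random.default_rng(seed)
    rows = []
    for i in range(n_systems):
        sys_seeds = spawn_seeds(int(master.integers(2 ** 31)), 7)
        rod_ratio = float(master.uniform(0.25, 0.7))
        cone_ratio = float(master.uniform(0.02, 0.15))
        thr_factor = float(master.uniform(0.2, 1.2))
        rod = make_biphasic_filter(0.10, 0.20, rod_ratio, dt=dt, pathway="rod")
        cone = make_biphasic_filter(0.05, 0.12, cone_ratio, dt=dt, pathway="cone")
        spec = NoiseStimulusSpec(duration=fit_duration, dt=dt)
        nonlin = default_shared_nonlinearity(rod, spec,
                                             threshold_factor=thr_factor)
        noise_sd = _response_noise_sd(rod, cone, nonlin, spec, 0.1,
                                      sys_seeds[4])

        model_rod, _, _ = fit_pathway(rod, cone, nonlin, spec,
                                      sys_seeds[0], sys_seeds[1], noise_sd)
        model_cone, _, _ = fit_pathway(cone, rod, nonlin, spec,
                                       sys_seeds[2], sys_seeds[3], noise_sd)
        shared = model_cone.nonlinearity
        base = float(np.asarray(shared(0.0)))

        def peak_of(trace, onset):
            i0 = trace.index_at(onset)
            pre = trace.values[:i0].mean()
            return float(trace.values[i0:].max() - pre)

        # flash strengths (contrast units) producing comparable responses
        rod_strength, cone_strength = 60.0, 60.0
        adapt_onset = 0.5
        test_onset = adapt_onset + offset
        duration = adapt_onset + offset + max(DEFAULT_WINDOW, 0.5) + 0.1
        for d, direction in enumerate(("rod-cone", "cone-rod")):
            measured_ii, avg = _measured_ii(rod, cone, nonlin, rod_strength,
                                            cone_strength, offset, direction,
                                            noise_sd, sys_seeds[5 + d])
            if direction == "rod-cone":
                adapt_model, test_model = model_rod, model_cone
            else:
                adapt_model, test_model = model_cone, model_rod
            a_scale = scale_filter_to_flash(
                LNModel(adapt_model.filter, shared, dt), peak_of(avg[2], adapt_onset))
            t_scale = scale_filter_to_flash(
                LNModel(test_model.filter, shared, dt), peak_of(avg[0], test_onset))
            adapt_alone = predict_flash_response(
                LNModel(adapt_model.filter, shared, dt), a_scale, adapt_onset,
                duration)
            test_alone = predict_flash_response(
                LNModel(test_model.filter, shared, dt), t_scale, test_onset,
                duration)
            paired = predict_paired_response(
                adapt_model.filter, a_scale.alpha, test_model.filter,
                t_scale.alpha, offset, shared, adapt_onset, duration)
            predicted = interaction_index(test_alone, paired, adapt_alone,
                                          test_onset=test_onset,
                                          baseline=base).ii
            rows.append({"system": i, "direction": direction,
                         "rod_undershoot_ratio": rod_ratio,
                         "cone_undershoot_ratio": cone_ratio,
                         "threshold_factor": thr_factor,
                         "predicted_ii": predicted,
                         "measured_ii": measured_ii})
    return pd.DataFrame(rows)
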