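"""Dichoptic brightness-matching simulation and perceptual interaction index.

An observer views an adapt flash followed by two test flashes — one at the
adapted location, one spatially offset — and adjusts the offset flash until
the two appear equally bright.  Comparing matches when adapt and test
flashes enter the same eye versus separate eyes separates suppression
arising in the retina (monocular) from suppression arising in cortex
(binocular).  Retinal and cortical gains are assumed multiplicative and in
series, so the cortical factor cancels in the one-eye / two-eye sensitivity
ratio:

    II = 1 - S_1eye / S_2eye

with S the matched-intensity / reference ratio for each eye mode.

The observer's decision rule (noisy multiplicative brightness comparison,
stepping toward perceived equality) is a modelling choice; the staircase
bookkeeping — 6 direction reversals per trial, step reduced by 1/3 after
each crossing down to a hardware floor, crossing-weighted match estimator,
exclusion rules — follows the task design exactly.
"""
from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import ParameterError, UndefinedIndexError

__all__ = [
    "CONDITIONS",
    "DEFAULT_RETINAL_SUPPRESSION",
    "ObserverConfig",
    "Crossing",
    "StaircaseTrial",
    "MatchResult",
    "PerceptualInteractionResult",
    "SessionSummary",
    "StaircaseExclusion",
    "simulate_observer_trial",
    "staircase_match",
    "apply_exclusions",
    "perceptual_interaction_index",
    "simulate_session",
    "summarize_session",
]

#: Task conditions: pathway order and adapt-test interval class.
CONDITIONS = ("rod-cone-short", "rod-cone-long", "cone-rod-short")

#: Default monocular (retinal) gains per condition: rod->cone suppression is
#: strong at short offsets, weak at long offsets; cone->rod is modest.
DEFAULT_RETINAL_SUPPRESSION: dict[str, float] = {
    "rod-cone-short": 0.55,
    "rod-cone-long": 0.9,
    "cone-rod-short": 0.8,
}

EYE_MODES = ("same", "separate")


class StaircaseExclusion(Exception):
    """A trial has too few crossings to yield a match."""


@dataclasses.dataclass(frozen=True)
class ObserverConfig:
    """Simulated observer with serial multiplicative gain suppression.

    retinal_suppression
        Gain in (0, 1] applied to the adapted-location test flash only when
        adapt and test enter the same eye; either a scalar or a mapping
        from condition name to gain.
    cortical_suppression
        Gain in (0, 1] applied to the adapted-location test flash
        regardless of eye of origin.
    judgment_noise_sd
        SD of the multiplicative brightness-judgment noise (fraction of
        intensity).
    initial_step
        First adjustment increment, in intensity units.
    """

    retinal_suppression: Mapping[str, float] | float = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_RETINAL_SUPPRESSION))
    cortical_suppression: float = 0.85
    judgment_noise_sd: float = 0.05
    initial_step: float = 0.15
    seed: int = 0

    def __post_init__(self):
        gains = (self.retinal_suppression.values()
                 if isinstance(self.retinal_suppression, Mapping)
                 else [self.retinal_suppression])
        for g in itertools.chain(gains, [self.cortical_suppression]):
            if not (0 < g <= 1):
                raise ParameterError(f"suppression gains must be in (0, 1], got {g}")
        if self.judgment_noise_sd < 0:
            raise ParameterError("judgment_noise_sd must be >= 0")
        if self.initial_step <= 0:
            raise ParameterError("initial_step must be > 0")

    def retinal_gain(self, condition: str) -> float:
        if isinstance(self.retinal_suppression, Mapping):
            try:
                return self.retinal_suppression[condition]
            except KeyError:
                raise ParameterError(f"no retinal gain for condition {condition!r}")
        return float(self.retinal_suppression)

    @property
    def min_step(self) -> float:
        """Hardware floor on the adjustment increment (monitor quantization)."""
        return self.initial_step * (2.0 / 3.0) ** 8


@dataclasses.dataclass(frozen=True)
class Crossing:
    """A direction reversal: the intensity at which it occurred and the
    (reduced) step size in force until the next crossing."""

    value: float
    step: float


@dataclasses.dataclass(frozen=True)
class StaircaseTrial:
    condition: str
    eye_mode: str
    adjustments: tuple[tuple[float, int], ...]  # (intensity, direction +1/-1)
    crossings: tuple[Crossing, ...]
    completed: bool


@dataclasses.dataclass(frozen=True)
class MatchResult:
    matched_intensity: float
    n_crossings: int
    method: str  # "v1-manual" or "v2-weighted"

    def __post_init__(self):
        if self.matched_intensity <= 0:
            raise ParameterError("matched intensity must be > 0")


@dataclasses.dataclass(frozen=True)
class PerceptualInteractionResult:
    """One-eye and two-eye sensitivity ratios and the interaction index."""

    s_1eye: float
    s_2eye: float

    @property
    def ii(self) -> float:
        return 1.0 - self.s_1eye / self.s_2eye


def simulate_observer_trial(observer: ObserverConfig, condition: str,
                            eye_mode: str, true_reference: float,
                            seed: int | None = None, n_crossings: int = 6,
                            max_steps: int = 2000) -> StaircaseTrial:
    """Simulate one adjustment-staircase trial.

    The observer perceives the adapted-location flash at
    ``true_reference * cortical * (retinal if same eye)`` and, on each step,
    compares it to the adjustable flash under multiplicative Gaussian
    judgment noise, stepping the adjustable intensity toward perceived
    equality.  Each direction reversal is a crossing; the step shrinks by
    1/3 per crossing (floored at the hardware minimum) and the trial ends
    at ``n_crossings`` crossings.
    """
    if true_reference <= 0:
        raise ParameterError("true_reference must be > 0")
    if eye_mode not in EYE_MODES:
        raise ParameterError(f"eye_mode must be one of {EYE_MODES}")
    gain = observer.cortical_suppression
    if eye_mode == "same":
        gain *= observer.retinal_gain(condition)
    perceived_ref = true_reference * gain

    rng = np.random.default_rng(observer.seed if seed is None else seed)
    step = observer.initial_step
    adj = true_reference
    direction = 0
    adjustments: list[tuple[float, int]] = []
    crossings: list[Crossing] = []
    for _ in range(max_steps):
        noise = (rng.normal(0.0, observer.judgment_noise_sd)
                 if observer.judgment_noise_sd > 0 else 0.0)
        perceived_adj = adj * (1.0 + noise)
        new_dir = -1 if perceived_adj > perceived_ref else 1
        adjustments.append((adj, new_dir))
        if direction != 0 and new_dir != direction:
            step = max(observer.initial_step * (2.0 / 3.0) ** (len(crossings) + 1),
                       observer.min_step)
            crossings.append(Crossing(value=adj, step=step))
            if len(crossings) >= n_crossings:
                break
        direction = new_dir
        adj = max(adj + new_dir * step, observer.min_step)
    return StaircaseTrial(condition=condition, eye_mode=eye_mode,
                          adjustments=tuple(adjustments),
                          crossings=tuple(crossings),
                          completed=len(crossings) >= n_crossings)


def staircase_match(trial: StaircaseTrial) -> MatchResult:
    """Crossing-weighted match estimate (task v2).

    The match is the average of midpoints between contiguous crossing
    pairs, each midpoint weighted by the inverse of the step size in force
    between that pair of crossings.
    """
    c = trial.crossings
    if len(c) < 2:
        raise StaircaseExclusion(
            f"trial has {len(c)} crossing(s); need at least 2")
    mids = np.array([(a.value + b.value) / 2.0 for a, b in zip(c[:-1], c[1:])])
    weights = np.array([1.0 / a.step for a in c[:-1]])
    match = float(np.sum(weights * mids) / np.sum(weights))
    return MatchResult(matched_intensity=match, n_crossings=len(c),
                       method="v2-weighted")


def manual_match(trial: StaircaseTrial) -> MatchResult:
    """Task v1 match: midpoint of the final bracket of crossings."""
    c = trial.crossings
    if len(c) < 2:
        raise StaircaseExclusion(
            f"trial has {len(c)} crossing(s); need at least 2")
    match = (c[-1].value + c[-2].value) / 2.0
    return MatchResult(matched_intensity=match, n_crossings=len(c),
                       method="v1-manual")


def apply_exclusions(trials: Sequence[StaircaseTrial], version: str = "v2"
                     ) -> tuple[list[StaircaseTrial], dict[tuple[str, str], bool]]:
    """Apply the task's exclusion rules.

    v1 drops trials with fewer than 2 crossings and invalidates any
    (condition, eye mode) cell left with 3 or fewer trials; v2 keeps only
    trials that completed their 6 crossings.
    Returns (kept trials, validity per (condition, eye_mode)).
    """
    if version == "v1":
        kept = [t for t in trials if len(t.crossings) >= 2]
    elif version == "v2":
        kept = [t for t in trials if t.completed]
    else:
        raise ParameterError(f"version must be 'v1' or 'v2', got {version!r}")
    validity: dict[tuple[str, str], bool] = {}
    cells = {(t.condition, t.eye_mode) for t in trials}
    for cell in sorted(cells):
        n = sum(1 for t in kept if (t.condition, t.eye_mode) == cell)
        validity[cell] = n > 3 if version == "v1" else n > 0
    return kept, validity


def perceptual_interaction_index(same_eye_matches: Iterable[float],
                                 separate_eye_matches: Iterable[float],
                                 reference: float) -> PerceptualInteractionResult:
    """Perceptual interaction index from per-trial matches.

    S_1eye and S_2eye are the mean matched intensity over reference for
    same-eye and separate-eye delivery; II = 1 - S_1eye/S_2eye.
    """
    same = np.asarray(list(same_eye_matches), dtype=float)
    sep = np.asarray(list(separate_eye_matches), dtype=float)
    if same.size == 0 or sep.size == 0:
        raise ParameterError("need at least one match per eye mode")
    if reference <= 0:
        raise ParameterError("reference must be > 0")
    s1 = float(same.mean() / reference)
    s2 = float(sep.mean() / reference)
    if s2 == 0:
        raise UndefinedIndexError("separate-eye sensitivity is zero")
    return PerceptualInteractionResult(s_1eye=s1, s_2eye=s2)


@dataclasses.dataclass(frozen=True)
class SessionSummary:
    """Per-condition session outcome after exclusion."""

    condition: str
    mean_same: float | None
    mean_separate: float | None
    ii: float | None
    n_same: int
    n_separate: int
    n_total: int
    valid: bool


def simulate_session(observer: ObserverConfig, reference: float = 1.0,
                     n_trials: int = 12, version: str = "v2",
                     conditions: Sequence[str] = CONDITIONS
                     ) -> list[StaircaseTrial]:
    """Simulate a full session: ``n_trials`` per condition and eye mode.

    Per-trial seeds are spawned deterministically from the observer seed
    and indexed by (condition, eye mode, trial), so the trial set does not
    depend on interleaving order.
    """
    ss = np.random.SeedSequence(observer.seed)
    children = ss.spawn(len(conditions) * len(EYE_MODES) * n_trials)
    trials = []
    k = 0
    for cond in conditions:
        for eye in EYE_MODES:
            for _ in range(n_trials):
                seed = int(children[k].generate_state(1)[0] % (2 ** 31))
                trials.append(simulate_observer_trial(
                    observer, cond, eye, reference, seed=seed))
                k += 1
    return trials


def summarize_session(trials: Sequence[StaircaseTrial], reference: float,
                      version: str = "v2") -> list[SessionSummary]:
    """Apply exclusions, average matches within each cell, and compute the
    per-condition perceptual interaction index.

    The summary depends only on the set of trials, not their order
    (monocular and binocular trials were randomly interleaved in the task).
    """
    kept, validity = apply_exclusions(trials, version)
    match_fn = staircase_match if version == "v2" else manual_match
    conditions = sorted({t.condition for t in trials})
    summaries = []
    for cond in conditions:
        cell_matches: dict[str, list[float]] = {e: [] for e in EYE_MODES}
        for eye in EYE_MODES:
            matches = []
            for t in kept:
                if t.condition != cond or t.eye_mode != eye:
                    continue
                try:
                    matches.append(match_fn(t).matched_intensity)
                except StaircaseExclusion:
                    continue
            # sorting makes the summary independent of interleaving order
            cell_matches[eye] = sorted(matches)
        n_total = sum(1 for t in trials if t.condition == cond)
        valid = (validity.get((cond, "same"), False)
                 and validity.get((cond, "separate"), False))
        if valid and cell_matches["same"] and cell_matches["separate"]:
            res = perceptual_interaction_index(cell_matches["same"],
                                               cell_matches["separate"],
                                               reference)
            summaries.append(SessionSummary(
                condition=cond,
                mean_same=float(np.mean(cell_matches["same"])),
                mean_separate=float(np.mean(cell_matches["separate"])),
                ii=res.ii, n_same=len(cell_matches["same"]),
                n_separate=len(cell_matches["separate"]),
                n_total=n_total, valid=True))
        else:
            summaries.append(SessionSummary(
                condition=cond, mean_same=None, mean_separate=None, ii=None,
                n_same=len(cell_matches["same"]),
                n_separate=len(cell_matches["separate"]),
                n_total=n_total, valid=False))
    return summaries
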