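"""Synthetic observers for temporal-order and loudness-discrimination tasks.

The simulated participant replaces the patient or child of a randomized
temporal-training trial. Two psychophysical channels are modeled:

* **Temporal-order judgment** (2AFC): two monaural clicks, one per ear,
  separated by an inter-stimulus interval (ISI). The probability of
  reporting the order correctly is a logistic psychometric function of
  the ISI with a 0.5 guess rate, so the location parameter ``mu`` is the
  75%-correct auditory temporal-order threshold (ATOT) when the lapse
  rate is zero.
* **Loudness discrimination** (2AFC): paired tones of one carrier
  frequency differing by a fractional amplitude ``delta``; the same
  logistic form on the amplitude axis.

Training dynamics are modeled between sessions only: a temporal-training
session shrinks ``mu`` multiplicatively by the participant's improvement
rate (floored at the smallest presentable ISI), while a control session
leaves the order threshold untouched (and may optionally sharpen loudness
discrimination). Outcome batteries receive a transfer component linear in
the participant's relative ATOT gain, plus Gaussian noise, clamped to each
measure's legal range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

from .measures import (
    HIGHER,
    LOWER,
    STUDY1_REGISTRY,
    STUDY2_REGISTRY,
    MeasureSpec,
)

GROUP_TEMPORAL = "A_temporal"
GROUP_CONTROL = "B_control"

CONTROL_FREQUENCIES_HZ: Tuple[int, ...] = (400, 600, 800, 1000)

#: Smallest presentable ISI in milliseconds; thresholds never train below it.
DEFAULT_MU_FLOOR_MS = 1.0

#: Smallest presentable amplitude difference in the control task.
DELTA_FLOOR = 0.00025

_SIDES = ("left_right", "right_left")


@dataclass(frozen=True)
class PsychFun:
    """Logistic psychometric function for the order task.

    ``mu`` is in milliseconds and equals the 75%-correct point when
    ``lapse_rate`` is zero; ``spread`` is the logistic scale in ms.
    """

    mu: float
    spread: float
    guess_rate: float = 0.5
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (self.spread > 0):
            raise ValueError("spread must be positive")
        if not (0 <= self.guess_rate < 1 - self.lapse_rate <= 1):
            raise ValueError("require 0 <= guess_rate < 1 - lapse_rate <= 1")
        if not (self.mu > 0):
            raise ValueError("mu must be positive")


@dataclass(frozen=True)
class LoudnessFun:
    """Logistic discrimination function on the amplitude-difference axis.

    ``delta75`` is the amplitude fraction yielding 75% correct.
    """

    delta75: float
    spread: float
    guess_rate: float = 0.5

    def __post_init__(self) -> None:
        if not (self.delta75 > 0 and self.spread > 0):
            raise ValueError("delta75 and spread must be positive")
        if not (0 <= self.guess_rate < 1):
            raise ValueError("guess_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrialRecord:
    """One 2AFC trial: stimulus value, presentation order, response."""

    kind: str  # "order" or "loudness"
    stimulus: float  # ISI in ms, or amplitude-difference fraction
    presented_order: str
    reported_order: str
    correct: bool
    frequency_hz: Optional[int] = None


@dataclass
class ParticipantProfile:
    """A synthetic trial participant with true (latent) parameters."""

    id: str
    group: str  # GROUP_TEMPORAL or GROUP_CONTROL
    order_pf: PsychFun
    loudness_fun: LoudnessFun
    improvement_rate: float  # per temporal session, fraction of mu removed
    transfer_coeffs: Dict[str, float] = field(default_factory=dict)
    outcome_baselines: Dict[str, float] = field(default_factory=dict)
    noise_sd: Dict[str, float] = field(default_factory=dict)
    loudness_improvement_rate: float = 0.0  # per control session
    mu_floor: float = DEFAULT_MU_FLOOR_MS
    index: int = 0  # stable position in the cohort, used for seeding

    def __post_init__(self) -> None:
        if not (0 <= self.improvement_rate < 1):
            raise ValueError("improvement_rate must be in [0, 1)")
        if not (0 <= self.loudness_improvement_rate < 1):
            raise ValueError("loudness_improvement_rate must be in [0, 1)")
        if self.group not in (GROUP_TEMPORAL, GROUP_CONTROL):
            raise ValueError(f"unknown group {self.group!r}")


@dataclass(frozen=True)
class StudyDesign:
    """Sizes and schedule of a two-arm pre/post/follow-up study."""

    n_group_a: int
    n_group_b: int
    n_training_sessions: int
    trials_per_session: int
    n_assessment_sessions: int
    followup: bool
    measure_list: Tuple[Tuple[str, str], ...]

    def __post_init__(self) -> None:
        for name, value in (
            ("n_group_a", self.n_group_a),
            ("n_group_b", self.n_group_b),
            ("n_training_sessions", self.n_training_sessions),
            ("trials_per_session", self.trials_per_session),
            ("n_assessment_sessions", self.n_assessment_sessions),
        ):
            if value < 1:
                raise ValueError(f"{name} must be >= 1")
        for _, direction in self.measure_list:
            if direction not in (LOWER, HIGHER):
                raise ValueError(f"unknown direction {direction!r}")

    @property
    def directions(self) -> Dict[str, str]:
        return dict(self.measure_list)


@dataclass(frozen=True)
class EffectConfig:
    """Population distributions for cohort generation and training effects.

    Defaults follow the adult-cohort study conditions: baseline order
    thresholds around 172 ms (pooled mean of the two arms) with SD 53 ms,
    and a temporal-training improvement rate calibrated so sixteen
    sessions carry the group-mean threshold from 179 ms to 85 ms:
    ``rate = 1 - (85/179)**(1/16)``.
    """

    atot_mean: float = 172.0
    atot_sd: float = 53.0
    atot_range: Tuple[float, float] = (40.0, 450.0)
    observer_spread: float = 20.0
    improvement_rate_mean: float = 1.0 - (85.0 / 179.0) ** (1.0 / 16.0)
    improvement_rate_sd: float = 0.008
    control_order_rate: float = 0.0  # control training leaves ATOT alone
    control_loudness_rate: float = 0.0
    delta75_mean: float = 0.005
    delta75_sd: float = 0.0015
    delta75_range: Tuple[float, float] = (0.001, 0.02)
    loudness_spread: float = 0.0015
    transfer_scale: float = 1.0  # 0 -> null transfer
    noise_scale: float = 1.0
    mu_floor: float = DEFAULT_MU_FLOOR_MS


def study2_effect() -> EffectConfig:
    """Child-cohort calibration: 196 -> 127 ms over 24 sessions."""
    return EffectConfig(
        atot_mean=203.0,
        atot_sd=70.0,
        improvement_rate_mean=1.0 - (127.0 / 196.0) ** (1.0 / 24.0),
        improvement_rate_sd=0.004,
    )


@dataclass(frozen=True)
class OutcomeScore:
    measure: str
    phase: str  # "pre", "post", "followup"
    value: float
    direction: str


def order_prob(pf: PsychFun, isi: float) -> float:
    """Probability of a correct order report at the given ISI (ms)."""
    isi = float(isi)
    if not math.isfinite(isi):
        raise ValueError("isi must be finite")
    if isi < 0:
        raise ValueError("isi must be non-negative")
    span = 1.0 - pf.guess_rate - pf.lapse_rate
    return pf.guess_rate + span * float(expit((isi - pf.mu) / pf.spread))


def loudness_prob(lf: LoudnessFun, delta: float) -> float:
    """Probability of a correct louder-tone report at amplitude diff delta."""
    delta = float(delta)
    if not math.isfinite(delta) or delta <= 0:
        raise ValueError("delta must be positive and finite")
    span = 1.0 - lf.guess_rate
    return lf.guess_rate + span * float(expit((delta - lf.delta75) / lf.spread))


def _bernoulli_2afc(
    kind: str,
    p: float,
    stimulus: float,
    rng: np.random.Generator,
    frequency_hz: Optional[int] = None,
) -> TrialRecord:
    presented = _SIDES[rng.integers(2)]
    correct = bool(rng.random() < p)
    reported = presented if correct else _SIDES[1 - _SIDES.index(presented)]
    return TrialRecord(kind, stimulus, presented, reported, correct, frequency_hz)


def order_response(
    profile: ParticipantProfile, isi: float, rng: np.random.Generator
) -> TrialRecord:
    """Simulate one temporal-order trial at the given ISI."""
    p = order_prob(profile.order_pf, isi)
    return _bernoulli_2afc("order", p, float(isi), rng)


def loudness_response(
    profile: ParticipantProfile,
    delta: float,
    frequency: int,
    rng: np.random.Generator,
) -> TrialRecord:
    """Simulate one loudness-discrimination trial at one carrier frequency."""
    if frequency not in CONTROL_FREQUENCIES_HZ:
        raise ValueError(
            f"frequency must be one of {CONTROL_FREQUENCIES_HZ}, got {frequency}"
        )
    p = loudness_prob(profile.loudness_fun, delta)
    return _bernoulli_2afc("loudness", p, float(delta), rng, frequency)


def apply_session_effect(
    profile: ParticipantProfile,
    session_kind: str,
    control_order_rate: float = 0.0,
    control_loudness_rate: float = 0.0,
) -> ParticipantProfile:
    """Deterministic between-session threshold update.

    A temporal session multiplies the order threshold by
    ``1 - improvement_rate`` (floored); a control session leaves it
    unchanged unless a nonzero ``control_order_rate`` is configured, and
    optionally sharpens loudness discrimination.
    """
    if session_kind == "temporal":
        pf = profile.order_pf
        new_mu = max(profile.mu_floor, pf.mu * (1.0 - profile.improvement_rate))
        return replace(profile, order_pf=replace(pf, mu=new_mu))
    if session_kind == "control":
        new_profile = profile
        if control_order_rate > 0.0:
            pf = profile.order_pf
            new_mu = max(profile.mu_floor, pf.mu * (1.0 - control_order_rate))
            new_profile = replace(new_profile, order_pf=replace(pf, mu=new_mu))
        rate = control_loudness_rate or profile.loudness_improvement_rate
        if rate > 0.0:
            lf = new_profile.loudness_fun
            new_d = max(DELTA_FLOOR, lf.delta75 * (1.0 - rate))
            new_profile = replace(
                new_profile, loudness_fun=replace(lf, delta75=new_d)
            )
        return new_profile
    raise ValueError(f"unknown session kind {session_kind!r}")


def _default_directions() -> Dict[str, str]:
    out: Dict[str, str] = {}
    for reg in (STUDY1_REGISTRY, STUDY2_REGISTRY):
        for name, spec in reg.items():
            out[name] = spec.direction
    return out


def _default_bounds() -> Dict[str, Tuple[Optional[float], Optional[float]]]:
    out: Dict[str, Tuple[Optional[float], Optional[float]]] = {}
    for reg in (STUDY1_REGISTRY, STUDY2_REGISTRY):
        for name, spec in reg.items():
            out[name] = (spec.lower_bound, spec.upper_bound)
    return out


def emit_outcome_battery(
    profile: ParticipantProfile,
    phase: str,
    atot_pre: float,
    atot_now: float,
    rng: np.random.Generator,
    directions: Optional[Mapping[str, str]] = None,
    bounds: Optional[Mapping[str, Tuple[Optional[float], Optional[float]]]] = None,
) -> List[OutcomeScore]:
    """Generate one assessment battery for a participant.

    Each measure's value is its baseline shifted by the transfer
    component (transfer coefficient times relative ATOT gain, in the
    direction of improvement) plus Gaussian measurement noise, clamped to
    the measure's legal range.
    """
    if not (atot_pre > 0):
        raise ValueError("atot_pre must be positive")
    directions = directions if directions is not None else _default_directions()
    bounds = bounds if bounds is not None else _default_bounds()
    rel_gain = max(0.0, (atot_pre - atot_now) / atot_pre)
    scores: List[OutcomeScore] = []
    for measure, baseline in profile.outcome_baselines.items():
        direction = directions[measure]
        sign = 1.0 if direction == LOWER else -1.0
        coeff = profile.transfer_coeffs.get(measure, 0.0)
        sd = profile.noise_sd.get(measure, 0.0)
        value = baseline - sign * coeff * rel_gain * baseline
        if sd > 0:
            value += rng.normal(0.0, sd)
        lo, hi = bounds.get(measure, (None, None))
        if lo is not None:
            value = max(lo, value)
        if hi is not None:
            value = min(hi, value)
        scores.append(OutcomeScore(measure, phase, float(value), direction))
    return scores


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """Rejection-sampled normal draw inside [lo, hi]."""
    if sd == 0:
        return float(min(hi, max(lo, mean)))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated normal rejection sampling failed")


def make_cohort(
    design: StudyDesign,
    effect: EffectConfig,
    seed: int,
    measure_specs: Optional[Sequence[MeasureSpec]] = None,
) -> List[ParticipantProfile]:
    """Draw a randomized two-arm cohort.

    Baseline thresholds and outcome baselines are drawn from the
    configured population distributions. Group assignment is stratified
    on the baseline order threshold: participants are sorted by
    threshold, adjacent pairs are split by a coin flip, and overflow
    (for unequal arms) is routed to whichever group still has capacity,
    so the expected baseline difference between arms is null.
    """
    if design.n_group_a < 2 or design.n_group_b < 2:
        raise ValueError("need at least 2 participants per group")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if measure_specs is None:
        combined = {**STUDY2_REGISTRY, **STUDY1_REGISTRY}
        measure_specs = []
        for name, direction in design.measure_list:
            if name == "atot":
                continue
            spec = STUDY1_REGISTRY.get(name) if name in STUDY1_REGISTRY else None
            if spec is None or spec.direction != direction:
                spec = STUDY2_REGISTRY.get(name)
            if spec is None:
                spec = combined.get(name)
            if spec is None:
                raise KeyError(f"no measure spec registered for {name!r}")
            measure_specs.append(spec)

    total = design.n_group_a + design.n_group_b
    lo, hi = effect.atot_range
    mus = np.array(
        [_truncated_normal(rng, effect.atot_mean, effect.atot_sd, lo, hi) for _ in range(total)]
    )
    dlo, dhi = effect.delta75_range
    deltas = [
        _truncated_normal(rng, effect.delta75_mean, effect.delta75_sd, dlo, dhi)
        for _ in range(total)
    ]
    rates = np.clip(
        rng.normal(effect.improvement_rate_mean, effect.improvement_rate_sd, total),
        0.0,
        0.2,
    )
    baselines: List[Dict[str, float]] = []
    for _ in range(total):
        row: Dict[str, float] = {}
        for spec in measure_specs:
            b_lo = spec.lower_bound if spec.lower_bound is not None else -np.inf
            b_hi = spec.upper_bound if spec.upper_bound is not None else np.inf
            row[spec.name] = _truncated_normal(
                rng, spec.baseline_mean, spec.baseline_sd, b_lo, b_hi
            )
        baselines.append(row)

    # Stratified (pair-matched) randomization on baseline threshold.
    order = np.argsort(mus, kind="stable")
    groups: Dict[int, str] = {}
    count_a = count_b = 0

    def assign(idx: int, group: str) -> None:
        nonlocal count_a, count_b
        groups[idx] = group
        if group == GROUP_TEMPORAL:
            count_a += 1
        else:
            count_b += 1

    def capped(group: str) -> bool:
        if group == GROUP_TEMPORAL:
            return count_a >= design.n_group_a
        return count_b >= design.n_group_b

    pending = list(order)
    while pending:
        if len(pending) >= 2:
            first, second = pending[0], pending[1]
            pending = pending[2:]
            if rng.random() < 0.5:
                first, second = second, first
            pair = [(first, GROUP_TEMPORAL), (second, GROUP_CONTROL)]
        else:
            pair = [(pending.pop(0), GROUP_TEMPORAL)]
        for idx, preferred in pair:
            if capped(preferred):
                preferred = (
                    GROUP_CONTROL if preferred == GROUP_TEMPORAL else GROUP_TEMPORAL
                )
            assign(int(idx), preferred)

    profiles: List[ParticipantProfile] = []
    transfer = {
        spec.name: spec.transfer_coeff * effect.transfer_scale for spec in measure_specs
    }
    noise = {spec.name: spec.noise_sd * effect.noise_scale for spec in measure_specs}
    for i in range(total):
        profiles.append(
            ParticipantProfile(
                id=f"P{i + 1:02d}",
                group=groups[i],
                order_pf=PsychFun(mu=float(mus[i]), spread=effect.observer_spread),
                loudness_fun=LoudnessFun(
                    delta75=deltas[i], spread=effect.loudness_spread
                ),
                improvement_rate=float(rates[i]),
                transfer_coeffs=dict(transfer),
                outcome_baselines=dict(baselines[i]),
                noise_sd=dict(noise),
                loudness_improvement_rate=effect.control_loudness_rate,
                mu_floor=effect.mu_floor,
                index=i,
            )
        )
    return profiles
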