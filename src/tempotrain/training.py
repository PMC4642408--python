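"""Block-adaptive training schedulers.

Temporal training presents 10-trial blocks of the order task at a fixed
ISI. When a block reaches the 90% accuracy criterion the next block's
ISI decreases (harder); below the criterion it increases (easier). The
step size depends on the participant's *actual* order threshold: 5 ms
above 100 ms, 2 ms between 50 and 100 ms inclusive, 1 ms below 50 ms.
The first session opens at the pre-training threshold; the actual
threshold is refreshed after each session by a maximum-likelihood refit
over that session's trials.

Control (non-temporal) training mirrors the protocol on a loudness
discrimination task: 10-trial blocks at a single carrier frequency
(cycling 400 -> 600 -> 800 -> 1000 Hz), the amplitude difference moving
by a constant 0.00025 step inside [0.00025, 0.025] under the same block
criterion.

Both schedulers share the motivation bookkeeping: +1 point per correct
response, -1 per error, and one puzzle reward per completed block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .assessment import AssessmentResult, EstimatorConfig, batch_refit
from .observers import (
    CONTROL_FREQUENCIES_HZ,
    ParticipantProfile,
    TrialRecord,
    loudness_response,
    order_response,
)

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


@dataclass(frozen=True)
class TrainingConfig:
    block_size: int = 10
    criterion: float = 0.9  # proportion correct triggering a difficulty step
    trials_per_session: int = 300  # stands in for a 45-minute session
    control_trials_per_session: int = 150  # longer stimuli, fewer trials
    isi_bounds: Tuple[float, float] = (1.0, 600.0)
    delta_bounds: Tuple[float, float] = (0.00025, 0.025)
    delta_step: float = 0.00025
    start_delta: float = 0.0125
    frequencies_hz: Tuple[int, ...] = CONTROL_FREQUENCIES_HZ
    tone_duration_s: float = 1.0  # metadata only
    control_isi_s: float = 3.0  # metadata only

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if not (0 < self.criterion <= 1):
            raise ValueError("criterion must be in (0, 1]")


DEFAULT_TRAINING = TrainingConfig()


@dataclass(frozen=True)
class BlockScore:
    n_trials: int
    n_correct: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_correct <= self.n_trials):
            raise ValueError("n_correct must be within [0, n_trials]")

    @property
    def proportion(self) -> float:
        return self.n_correct / self.n_trials

    @property
    def net_points(self) -> int:
        return self.n_correct - (self.n_trials - self.n_correct)


@dataclass
class TemporalTrainingState:
    current_isi: float
    actual_atot: float
    session_index: int = 0
    block_index: int = 0
    cumulative_points: int = 0
    puzzles: int = 0

    def __post_init__(self) -> None:
        if not (self.actual_atot > 0):
            raise ValueError("actual_atot must be positive")


@dataclass
class ControlTrainingState:
    current_delta: float
    session_index: int = 0
    block_index: int = 0
    cumulative_points: int = 0
    puzzles: int = 0


@dataclass(frozen=True)
class BlockRecord:
    block_index: int
    kind: str  # "temporal" or "control"
    stimulus: float  # ISI in ms, or amplitude-difference fraction
    frequency_hz: Optional[int]
    trials: Tuple[TrialRecord, ...]
    score: BlockScore
    next_stimulus: float


@dataclass
class SessionLog:
    session_index: int
    kind: str
    blocks: List[BlockRecord] = field(default_factory=list)

    @property
    def points_total(self) -> int:
        return sum(b.score.net_points for b in self.blocks)

    @property
    def puzzles(self) -> int:
        return len(self.blocks)

    @property
    def trials(self) -> List[TrialRecord]:
        return [t for b in self.blocks for t in b.trials]


def init_temporal_state(
    pre_training_atot: float, config: TrainingConfig = DEFAULT_TRAINING
) -> TemporalTrainingState:
    """Starting state: first block at the pre-training threshold."""
    lo, hi = config.isi_bounds
    return TemporalTrainingState(
        current_isi=float(min(hi, max(lo, pre_training_atot))),
        actual_atot=float(pre_training_atot),
    )


def init_control_state(config: TrainingConfig = DEFAULT_TRAINING) -> ControlTrainingState:
    return ControlTrainingState(current_delta=config.start_delta)


def score_block(trials: Sequence[TrialRecord]) -> BlockScore:
    """Score a 10-trial block; rejects mixed-stimulus blocks."""
    if len(trials) == 0:
        raise ValueError("empty block")
    stimuli = {(t.kind, t.stimulus, t.frequency_hz) for t in trials}
    if len(stimuli) != 1:
        raise ValueError("block must use a single stimulus value")
    return BlockScore(
        n_trials=len(trials), n_correct=sum(1 for t in trials if t.correct)
    )


def temporal_step_size(actual_atot: float) -> int:
    """ISI step in ms for the given actual threshold regime.

    Above 100 ms: 5 ms; 50-100 ms inclusive: 2 ms; below 50 ms: 1 ms.
    """
    if not (actual_atot > 0):
        raise ValueError("actual_atot must be positive")
    if actual_atot > 100:
        return 5
    if actual_atot >= 50:
        return 2
    return 1


def next_temporal_isi(
    state: TemporalTrainingState,
    block: BlockScore,
    config: TrainingConfig = DEFAULT_TRAINING,
) -> float:
    """Next block's ISI: down a step at >=90% correct, up otherwise."""
    step = temporal_step_size(state.actual_atot)
    if block.proportion >= config.criterion - 1e-12:
        isi = state.current_isi - step
    else:
        isi = state.current_isi + step
    lo, hi = config.isi_bounds
    return float(min(hi, max(lo, isi)))


def next_loudness_delta(
    state: ControlTrainingState,
    block: BlockScore,
    config: TrainingConfig = DEFAULT_TRAINING,
) -> float:
    """Next block's amplitude difference: one constant step per block."""
    if block.proportion >= config.criterion - 1e-12:
        delta = state.current_delta - config.delta_step
    else:
        delta = state.current_delta + config.delta_step
    lo, hi = config.delta_bounds
    return float(min(hi, max(lo, delta)))


def _as_rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def run_temporal_session(
    profile: ParticipantProfile,
    state: TemporalTrainingState,
    config: TrainingConfig = DEFAULT_TRAINING,
    seed: SeedLike = 0,
) -> SessionLog:
    """Run one temporal-training session, mutating the scheduler state."""
    rng = _as_rng(seed)
    n_blocks = config.trials_per_session // config.block_size
    log = SessionLog(session_index=state.session_index, kind="temporal")
    for _ in range(n_blocks):
        isi = state.current_isi
        trials = tuple(
            order_response(profile, isi, rng) for _ in range(config.block_size)
        )
        score = score_block(trials)
        nxt = next_temporal_isi(state, score, config)
        log.blocks.append(
            BlockRecord(state.block_index, "temporal", isi, None, trials, score, nxt)
        )
        state.block_index += 1
        state.cumulative_points += score.net_points
        state.puzzles += 1
        state.current_isi = nxt
    state.session_index += 1
    return log


def run_control_session(
    profile: ParticipantProfile,
    state: ControlTrainingState,
    config: TrainingConfig = DEFAULT_TRAINING,
    seed: SeedLike = 0,
) -> SessionLog:
    """Run one control-training session (single carrier per block,
    frequencies rotating in a fixed cycle across blocks)."""
    rng = _as_rng(seed)
    n_blocks = config.control_trials_per_session // config.block_size
    log = SessionLog(session_index=state.session_index, kind="control")
    freqs = config.frequencies_hz
    for _ in range(n_blocks):
        delta = state.current_delta
        freq = freqs[state.block_index % len(freqs)]
        trials = tuple(
            loudness_response(profile, delta, freq, rng)
            for _ in range(config.block_size)
        )
        score = score_block(trials)
        nxt = next_loudness_delta(state, score, config)
        log.blocks.append(
            BlockRecord(state.block_index, "control", delta, freq, trials, score, nxt)
        )
        state.block_index += 1
        state.cumulative_points += score.net_points
        state.puzzles += 1
        state.current_delta = nxt
    state.session_index += 1
    return log


def update_actual_atot(
    state: TemporalTrainingState,
    session_log: Optional[SessionLog] = None,
    assessment: Optional[AssessmentResult] = None,
    estimator_config: Optional[EstimatorConfig] = None,
) -> float:
    """Refresh the scheduler's notion of the participant's threshold.

    Preferred source: an ML refit over the latest session's trials;
    fallback: the most recent assessment estimate.
    """
    if session_log is not None:
        estimate = batch_refit(session_log.trials, estimator_config)
    elif assessment is not None:
        estimate = assessment.estimate
    else:
        raise ValueError("provide a session log or an assessment result")
    state.actual_atot = float(estimate)
    return state.actual_atot
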