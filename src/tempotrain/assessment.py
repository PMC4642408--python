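"""Adaptive maximum-likelihood estimation of the temporal-order threshold.

The tracker maintains a log-likelihood over a grid of candidate
thresholds (default: every integer millisecond from 1 to 600). Each
trial is placed at the current best estimate of the threshold; each
response adds, for every candidate ``theta``, the log-probability of the
observed correctness under a logistic psychometric function with
location ``theta``, an assumed (not estimated) spread, guess rate 0.5,
and zero lapse. The run terminates once at least 95% of the normalized
likelihood mass lies within +/-5 ms of the current estimate, or when the
trial budget is exhausted.

Because updates are additive in log space, the sequential estimate is
identical to a batch maximum-likelihood refit on the same trial log;
``batch_refit`` exposes that refit directly (it also serves as the
"actual threshold" refresher during training).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Union

import numpy as np
from scipy.special import expit, logsumexp

from .observers import ParticipantProfile, TrialRecord, order_response

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


@dataclass(frozen=True)
class EstimatorConfig:
    """Tracker settings.

    ``start_isi`` is the first-trial placement (range midpoint by
    default, avoiding the floor-trapping that the flat-state argmax
    tie-break toward 1 ms would cause); ``min_trials`` gates the stop
    rule against spurious early convergence.
    """

    grid_min: int = 1
    grid_max: int = 600
    assumed_spread: float = 20.0
    guess_rate: float = 0.5
    lapse_rate: float = 0.0
    start_isi: Optional[float] = 300.0
    min_trials: int = 10
    max_trials: int = 500
    stop_mass: float = 0.95
    stop_halfwidth: float = 5.0

    def __post_init__(self) -> None:
        if self.grid_max < self.grid_min:
            raise ValueError("empty threshold grid")
        if not (self.assumed_spread > 0):
            raise ValueError("assumed_spread must be positive")
        if not (0 <= self.guess_rate < 1 - self.lapse_rate <= 1):
            raise ValueError("require 0 <= guess_rate < 1 - lapse_rate <= 1")


@dataclass
class EstimatorState:
    grid: np.ndarray
    log_likelihood: np.ndarray
    config: EstimatorConfig
    trial_count: int = 0
    converged: bool = False


@dataclass
class AssessmentResult:
    """Terminal estimate plus the full trial log of one session."""

    estimate: float
    interval_halfwidth_95: float
    trials: List[TrialRecord]
    converged: bool
    session_index: int = 0
    # per-trial running estimate / halfwidth, aligned with `trials`
    running_estimate: List[float] = field(default_factory=list)
    running_halfwidth: List[float] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def init_estimator(config: Optional[EstimatorConfig] = None) -> EstimatorState:
    """Flat (uniform) likelihood over the candidate grid."""
    config = config or EstimatorConfig()
    grid = np.arange(config.grid_min, config.grid_max + 1, dtype=float)
    return EstimatorState(
        grid=grid, log_likelihood=np.zeros_like(grid), config=config
    )


def posterior(state: EstimatorState) -> np.ndarray:
    """Normalized likelihood mass over the grid (sums to 1)."""
    ll = state.log_likelihood
    return np.exp(ll - logsumexp(ll))


def _trial_log_likelihood(state: EstimatorState, trial: TrialRecord) -> np.ndarray:
    cfg = state.config
    span = 1.0 - cfg.guess_rate - cfg.lapse_rate
    p = cfg.guess_rate + span * expit(
        (trial.stimulus - state.grid) / cfg.assumed_spread
    )
    return np.log(p) if trial.correct else np.log1p(-p)


def update_estimator(state: EstimatorState, trial: TrialRecord) -> EstimatorState:
    """Add one trial's log-likelihood contribution; returns a new state."""
    if not math.isfinite(trial.stimulus) or trial.stimulus < 0:
        raise ValueError("trial stimulus must be a non-negative finite ISI")
    contrib = _trial_log_likelihood(state, trial)
    new_ll = state.log_likelihood + contrib
    if not np.all(np.isfinite(new_ll)):
        raise ValueError("non-finite likelihood update")
    return EstimatorState(
        grid=state.grid,
        log_likelihood=new_ll,
        config=state.config,
        trial_count=state.trial_count + 1,
        converged=state.converged,
    )


def best_estimate(state: EstimatorState) -> float:
    """Argmax of the likelihood; ties break toward the smallest candidate."""
    return float(state.grid[int(np.argmax(state.log_likelihood))])


def propose_isi(state: EstimatorState) -> int:
    """Next trial placement: the best estimate, rounded (half up) and
    clamped to the grid range. Before any data, the configured start ISI."""
    cfg = state.config
    if state.trial_count == 0 and cfg.start_isi is not None:
        value = cfg.start_isi
    else:
        value = best_estimate(state)
    isi = int(math.floor(value + 0.5))
    return int(min(cfg.grid_max, max(cfg.grid_min, isi)))


def window_mass(state: EstimatorState, halfwidth: Optional[float] = None) -> float:
    """Normalized mass within +/-halfwidth of the current best estimate."""
    cfg = state.config
    hw = cfg.stop_halfwidth if halfwidth is None else halfwidth
    est = best_estimate(state)
    post = posterior(state)
    return float(post[np.abs(state.grid - est) <= hw + 1e-9].sum())


def stop_rule(state: EstimatorState) -> bool:
    """True once >=95% of likelihood mass sits within +/-5 ms of the
    estimate (after the minimum trial count)."""
    if state.trial_count < state.config.min_trials:
        return False
    return window_mass(state) >= state.config.stop_mass


def halfwidth95(state: EstimatorState, mass: float = 0.95) -> float:
    """Smallest symmetric half-width around the estimate holding >=mass."""
    est = best_estimate(state)
    post = posterior(state)
    d = np.abs(state.grid - est)
    order = np.argsort(d, kind="stable")
    cum = np.cumsum(post[order])
    idx = int(np.searchsorted(cum, mass - 1e-12))
    idx = min(idx, len(d) - 1)
    return float(d[order][idx])


def _as_rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _summarize(state: EstimatorState) -> tuple:
    """(estimate, halfwidth95, stop-mass reached) in one posterior pass.

    Exploits the uniform grid spacing for prefix-sum window masses;
    agrees with best_estimate / halfwidth95 / stop_rule exactly.
    """
    cfg = state.config
    ll = state.log_likelihood
    post = np.exp(ll - ll.max())
    post /= post.sum()
    i = int(np.argmax(ll))
    est = float(state.grid[i])
    cum = np.cumsum(post)
    n = len(post)
    spacing = float(state.grid[1] - state.grid[0]) if n > 1 else 1.0
    hs = np.arange(n)
    upper = np.minimum(i + hs, n - 1)
    lower = i - hs - 1
    w = cum[upper] - np.where(lower >= 0, cum[np.maximum(lower, 0)], 0.0)
    h95 = float(hs[np.searchsorted(w, 0.95 - 1e-12)] * spacing) if n > 1 else 0.0
    h_stop = int(np.floor(cfg.stop_halfwidth / spacing + 1e-9))
    stop_mass_ok = bool(w[min(h_stop, n - 1)] >= cfg.stop_mass)
    return est, h95, stop_mass_ok


def run_assessment_session(
    profile: ParticipantProfile,
    config: Optional[EstimatorConfig] = None,
    seed: SeedLike = 0,
    session_index: int = 0,
) -> AssessmentResult:
    """Run one adaptive threshold-estimation session to termination.

    Loops propose -> respond -> update until the stop rule fires or the
    trial budget is reached; in the latter case ``converged`` is False
    but the estimate is still reported.
    """
    config = config or EstimatorConfig()
    rng = _as_rng(seed)
    state = init_estimator(config)
    trials: List[TrialRecord] = []
    running_est: List[float] = []
    running_hw: List[float] = []
    converged = False
    est, hw = float(state.grid[0]), float(state.grid[-1] - state.grid[0])
    while state.trial_count < config.max_trials:
        isi = propose_isi(state)
        trial = order_response(profile, isi, rng)
        state = update_estimator(state, trial)
        trials.append(trial)
        est, hw, stop_mass_ok = _summarize(state)
        running_est.append(est)
        running_hw.append(hw)
        if state.trial_count >= config.min_trials and stop_mass_ok:
            converged = True
            break
    state.converged = converged
    return AssessmentResult(
        estimate=est,
        interval_halfwidth_95=hw,
        trials=trials,
        converged=converged,
        session_index=session_index,
        running_estimate=running_est,
        running_halfwidth=running_hw,
    )


def batch_refit(
    trials: Sequence[TrialRecord], config: Optional[EstimatorConfig] = None
) -> float:
    """Maximum-likelihood threshold refit over a full trial log.

    Exactly equals the sequential estimator on the same trials (sums of
    logs commute).
    """
    config = config or EstimatorConfig()
    state = init_estimator(config)
    for trial in trials:
        state = update_estimator(state, trial)
    return best_estimate(state)


def atot_from_sessions(results: Sequence[AssessmentResult]) -> float:
    """Mean threshold over assessment sessions (one or two in practice)."""
    if not results:
        raise ValueError("need at least one assessment session")
    return float(np.mean([r.estimate for r in results]))
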