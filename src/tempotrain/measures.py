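"""Outcome-measure registry for the two simulated training studies.

Each study's assessment battery (language tests, working-memory spans,
reaction-time tasks, executive-function scores) is modeled abstractly: a
measure is a named scalar with a direction of improvement, a population
baseline distribution, a per-assessment noise level, and a transfer
coefficient that scales how strongly relative temporal-order-threshold
(ATOT) improvement propagates into that measure.

Baseline means and SDs follow the published group-level pre-training
characteristics of the adult post-stroke aphasia cohort (study 1) and the
child SLI cohort (study 2). Transfer coefficients are calibrated so that,
at the calibrated group-mean ATOT improvement, the generator reproduces
the published group-mean pre-to-post changes:

    coeff = (relative change in the measure) / (relative ATOT gain)

with relative ATOT gain 0.525 for study 1 (179 -> 85 ms) and 0.352 for
study 2 (196 -> 127 ms). Negative coefficients encode measures that
drifted slightly against the direction of improvement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

LOWER = "lower_is_better"
HIGHER = "higher_is_better"


@dataclass(frozen=True)
class MeasureSpec:
    """Static description of one outcome measure."""

    name: str
    direction: str  # LOWER or HIGHER
    baseline_mean: float
    baseline_sd: float
    noise_sd: float  # per-assessment measurement noise
    transfer_coeff: float  # outcome gain per unit relative ATOT gain
    lower_bound: Optional[float] = 0.0
    upper_bound: Optional[float] = None

    def __post_init__(self) -> None:
        if self.direction not in (LOWER, HIGHER):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.baseline_sd < 0 or self.noise_sd < 0:
            raise ValueError("dispersions must be non-negative")


# Adult aphasia battery: percent-error language tests, spatial span,
# spatial working-memory errors, attention reaction times.
STUDY1_MEASURES: Tuple[MeasureSpec, ...] = (
    MeasureSpec("token_test", LOWER, 48.3, 22.6, 6.0, 0.50, 0.0, 100.0),
    MeasureSpec("pd_pseudo", LOWER, 21.1, 14.9, 4.0, 0.83, 0.0, 100.0),
    MeasureSpec("pd_words", LOWER, 14.0, 13.9, 3.5, 1.09, 0.0, 100.0),
    MeasureSpec("ph_noise", LOWER, 19.6, 7.2, 2.5, 0.04, 0.0, 100.0),
    MeasureSpec("ph_comp", LOWER, 15.2, 8.9, 3.0, 0.22, 0.0, 100.0),
    MeasureSpec("inflection", LOWER, 55.7, 37.2, 10.0, -0.22, 0.0, 100.0),
    MeasureSpec("compr_vc", LOWER, 38.0, 22.1, 8.0, 0.79, 0.0, 100.0),
    MeasureSpec("spatial_span", HIGHER, 4.2, 0.94, 0.35, 0.23, 0.0, 9.0),
    MeasureSpec("swm_errors", LOWER, 51.9, 26.4, 7.0, 0.48, 0.0, None),
    MeasureSpec("alertness_rt", LOWER, 341.0, 89.0, 25.0, 0.10, 1.0, None),
    MeasureSpec("vigilance_rt", LOWER, 741.0, 213.0, 40.0, -0.025, 1.0, None),
)

# Child SLI battery: percent-error language tests, verbal fluency,
# span scores, alertness RT, executive-function scores.
STUDY2_MEASURES: Tuple[MeasureSpec, ...] = (
    MeasureSpec("token_test", LOWER, 52.9, 25.2, 6.0, 1.17, 0.0, 100.0),
    MeasureSpec("pd_pseudo", LOWER, 34.3, 13.6, 4.0, 1.51, 0.0, 100.0),
    MeasureSpec("pd_words", LOWER, 18.9, 13.0, 3.5, 2.04, 0.0, 100.0),
    MeasureSpec("ssc", LOWER, 34.6, 28.7, 6.0, 1.08, 0.0, 100.0),
    MeasureSpec("cowat_words", HIGHER, 9.6, 5.6, 1.5, 0.24, 0.0, None),
    MeasureSpec("ssp_errors", LOWER, 12.4, 2.5, 1.2, 0.69, 0.0, None),
    MeasureSpec("digit_span", HIGHER, 1.7, 0.8, 0.4, 1.67, 0.0, None),
    MeasureSpec("vwm_score", HIGHER, 6.0, 2.0, 0.8, 0.66, 0.0, None),
    MeasureSpec("alertness_rt", LOWER, 438.0, 155.0, 35.0, 0.35, 1.0, None),
    MeasureSpec("mazes_score", HIGHER, 20.4, 6.9, 2.0, 0.59, 0.0, None),
    MeasureSpec("tol_moves", LOWER, 55.6, 19.7, 6.0, 0.62, 0.0, None),
)


def registry(specs: Sequence[MeasureSpec]) -> Mapping[str, MeasureSpec]:
    return {m.name: m for m in specs}


STUDY1_REGISTRY = registry(STUDY1_MEASURES)
STUDY2_REGISTRY = registry(STUDY2_MEASURES)


def measure_list(specs: Sequence[MeasureSpec]) -> Tuple[Tuple[str, str], ...]:
    """(name, direction) pairs in battery order, for StudyDesign."""
    return tuple((m.name, m.direction) for m in specs)
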