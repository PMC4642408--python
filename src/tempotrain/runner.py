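"""Full-protocol orchestration: cohort -> pre -> train -> post -> follow-up.

The runner wires the synthetic cohort, the adaptive threshold
assessment, the training schedulers, and the nonparametric analysis into
the complete randomized-trial protocol. Randomness is seeded
hierarchically (master seed, participant index, protocol stage) so that
changing the cohort size or disabling a stage never perturbs another
participant's streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as tio
from .assessment import (
    AssessmentResult,
    EstimatorConfig,
    atot_from_sessions,
    run_assessment_session,
)
from .measures import STUDY1_MEASURES, STUDY2_MEASURES, measure_list
from .observers import (
    EffectConfig,
    GROUP_TEMPORAL,
    ParticipantProfile,
    StudyDesign,
    apply_session_effect,
    emit_outcome_battery,
    make_cohort,
    study2_effect,
)
from .stats import StudyReport, analyze_study
from .training import (
    TrainingConfig,
    init_control_state,
    init_temporal_state,
    run_control_session,
    run_temporal_session,
    update_actual_atot,
)

# protocol stage codes for hierarchical seeding
_STAGE_PRE_ASSESS = 0
_STAGE_PRE_BATTERY = 1
_STAGE_TRAINING = 2
_STAGE_POST_ASSESS = 3
_STAGE_POST_BATTERY = 4
_STAGE_FU_ASSESS = 5
_STAGE_FU_BATTERY = 6
_STAGE_ATTRITION = 7  # cohort-level


@dataclass(frozen=True)
class ProtocolConfig:
    study_preset: str
    design: StudyDesign
    estimator: EstimatorConfig = EstimatorConfig()
    training: TrainingConfig = TrainingConfig()
    effect: EffectConfig = EffectConfig()
    alpha: float = 0.05
    seed: int = 0
    simulate_training_trials: bool = True
    followup_attrition: float = 0.0
    followup_groups: Tuple[str, ...] = (GROUP_TEMPORAL,)
    followup_label: str = ""
    output_dir: Optional[str] = None


def study1_config(seed: int = 0, **overrides) -> ProtocolConfig:
    """Adult-cohort preset: 15 vs 13, 16 sessions, two assessment
    sessions per phase, follow-up (labelled 8 months) in the temporal
    arm with 10 of 15 completing."""
    design = StudyDesign(
        n_group_a=15,
        n_group_b=13,
        n_training_sessions=16,
        trials_per_session=300,
        n_assessment_sessions=2,
        followup=True,
        measure_list=(("atot", "lower_is_better"),) + measure_list(STUDY1_MEASURES),
    )
    cfg = ProtocolConfig(
        study_preset="study1",
        design=design,
        seed=seed,
        followup_attrition=5.0 / 15.0,
        followup_groups=(GROUP_TEMPORAL,),
        followup_label="8 months",
    )
    return replace(cfg, **overrides) if overrides else cfg


def study2_config(seed: int = 0, **overrides) -> ProtocolConfig:
    """Child-cohort preset: 17 vs 15, 24 sessions, one assessment
    session per phase, follow-up (labelled 6 weeks) in both arms with
    9 completing per arm."""
    design = StudyDesign(
        n_group_a=17,
        n_group_b=15,
        n_training_sessions=24,
        trials_per_session=300,
        n_assessment_sessions=1,
        followup=True,
        measure_list=(("atot", "lower_is_better"),) + measure_list(STUDY2_MEASURES),
    )
    cfg = ProtocolConfig(
        study_preset="study2",
        design=design,
        effect=study2_effect(),
        seed=seed,
        followup_attrition=1.0 - 18.0 / 32.0,
        followup_groups=(GROUP_TEMPORAL, "B_control"),
        followup_label="6 weeks",
    )
    return replace(cfg, **overrides) if overrides else cfg


_PRESETS = {"study1": study1_config, "study2": study2_config}


def preset_config(name: str, seed: int = 0, **overrides) -> ProtocolConfig:
    if name == "custom":
        raise ValueError("custom protocols must be constructed directly")
    if name not in _PRESETS:
        raise ValueError(
            f"unknown study preset {name!r}; choose from {sorted(_PRESETS)}"
        )
    return _PRESETS[name](seed=seed, **overrides)


def _stage_rng(master_seed: int, pid: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(pid, stage))
    )


def _assess(
    profile: ParticipantProfile,
    config: ProtocolConfig,
    stage: int,
) -> Tuple[float, List[AssessmentResult]]:
    rng = _stage_rng(config.seed, profile.index, stage)
    results = [
        run_assessment_session(profile, config.estimator, seed=rng, session_index=k)
        for k in range(config.design.n_assessment_sessions)
    ]
    return atot_from_sessions(results), results


@dataclass
class StudyArtifacts:
    """Everything a full run produces, before any file is written."""

    cohort: List[ParticipantProfile]
    records: pd.DataFrame
    report: StudyReport
    training_logs: Dict[str, list] = field(default_factory=dict)
    assessments: Dict[str, Dict[str, List[AssessmentResult]]] = field(
        default_factory=dict
    )


def run_full_study(config: ProtocolConfig) -> StudyArtifacts:
    """Execute the whole protocol and analyze it.

    Phases per participant: pre assessment (threshold + outcome
    battery), the assigned training course with between-session effect
    updates, post assessment, and (for sampled completers) a follow-up
    assessment with thresholds frozen after training. If
    ``simulate_training_trials`` is off, the block-level training
    trials are skipped and only the deterministic between-session
    threshold dynamics are applied (the analysis stage is unaffected).
    """
    design = config.design
    cohort = make_cohort(design, config.effect, config.seed)
    directions = design.directions

    # cohort-level follow-up attrition: random without replacement
    fu_rng = _stage_rng(config.seed, 10**6, _STAGE_ATTRITION)
    completers: Dict[str, bool] = {}
    for group in set(p.group for p in cohort):
        members = [p for p in cohort if p.group == group]
        if not design.followup or group not in config.followup_groups:
            for p in members:
                completers[p.id] = False
            continue
        n_keep = int(round(len(members) * (1.0 - config.followup_attrition)))
        kept = set(
            fu_rng.choice(len(members), size=n_keep, replace=False).tolist()
        )
        for j, p in enumerate(members):
            completers[p.id] = j in kept

    rows: List[dict] = []
    training_logs: Dict[str, list] = {}
    assessments: Dict[str, Dict[str, List[AssessmentResult]]] = {}

    def record_battery(profile: ParticipantProfile, phase: str,
                       atot_pre: float, atot_now: float, stage: int) -> None:
        rng = _stage_rng(config.seed, profile.index, stage)
        for score in emit_outcome_battery(
            profile, phase, atot_pre, atot_now, rng, directions=directions
        ):
            rows.append(
                {
                    "participant_id": profile.id,
                    "group": profile.group,
                    "measure": score.measure,
                    "phase": phase,
                    "value": score.value,
                }
            )

    for profile in cohort:
        assessments[profile.id] = {}
        atot_pre, pre_results = _assess(profile, config, _STAGE_PRE_ASSESS)
        assessments[profile.id]["pre"] = pre_results
        rows.append(
            {
                "participant_id": profile.id,
                "group": profile.group,
                "measure": "atot",
                "phase": "pre",
                "value": atot_pre,
            }
        )
        record_battery(profile, "pre", atot_pre, atot_pre, _STAGE_PRE_BATTERY)

        # training course
        trained = profile
        kind = "temporal" if profile.group == GROUP_TEMPORAL else "control"
        if config.simulate_training_trials:
            train_rng = _stage_rng(config.seed, profile.index, _STAGE_TRAINING)
            logs = []
            if kind == "temporal":
                t_state = init_temporal_state(atot_pre, config.training)
                for _ in range(design.n_training_sessions):
                    log = run_temporal_session(
                        trained, t_state, config.training, seed=train_rng
                    )
                    logs.append(log)
                    update_actual_atot(
                        t_state, session_log=log,
                        estimator_config=config.estimator,
                    )
                    t_state.current_isi = min(
                        config.training.isi_bounds[1],
                        max(config.training.isi_bounds[0], t_state.current_isi),
                    )
                    trained = apply_session_effect(trained, "temporal")
            else:
                c_state = init_control_state(config.training)
                for _ in range(design.n_training_sessions):
                    log = run_control_session(
                        trained, c_state, config.training, seed=train_rng
                    )
                    logs.append(log)
                    trained = apply_session_effect(
                        trained,
                        "control",
                        control_order_rate=config.effect.control_order_rate,
                        control_loudness_rate=config.effect.control_loudness_rate,
                    )
            training_logs[profile.id] = logs
        else:
            for _ in range(design.n_training_sessions):
                trained = apply_session_effect(
                    trained,
                    kind,
                    control_order_rate=config.effect.control_order_rate,
                    control_loudness_rate=config.effect.control_loudness_rate,
                )

        atot_post, post_results = _assess(trained, config, _STAGE_POST_ASSESS)
        assessments[profile.id]["post"] = post_results
        rows.append(
            {
                "participant_id": profile.id,
                "group": profile.group,
                "measure": "atot",
                "phase": "post",
                "value": atot_post,
            }
        )
        record_battery(trained, "post", atot_pre, atot_post, _STAGE_POST_BATTERY)

        # follow-up: thresholds frozen after training (no forgetting model)
        if design.followup and completers.get(profile.id, False):
            atot_fu, fu_results = _assess(trained, config, _STAGE_FU_ASSESS)
            assessments[profile.id]["followup"] = fu_results
            rows.append(
                {
                    "participant_id": profile.id,
                    "group": profile.group,
                    "measure": "atot",
                    "phase": "followup",
                    "value": atot_fu,
                }
            )
            record_battery(
                trained, "followup", atot_pre, atot_fu, _STAGE_FU_BATTERY
            )

    records = pd.DataFrame(rows)
    report = analyze_study(records, design, alpha=config.alpha)
    artifacts = StudyArtifacts(
        cohort=cohort,
        records=records,
        report=report,
        training_logs=training_logs,
        assessments=assessments,
    )

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        records.to_csv(out / "records.csv", index=False)
        tio.write_report(out / "report", report)
        tio.write_cohort(out / "cohort.json", cohort)
        tio.write_metadata(out / "run_metadata.json", config, config.seed)
    return artifacts
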