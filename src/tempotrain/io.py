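"""CSV/JSON artifact plumbing: trial logs, session logs, reports, metadata.

All files are self-describing (header row; a JSON metadata sidecar with
the seed and a config hash accompanies full-study output). Floats are
written with ``repr`` so that write-then-read round-trips exactly.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Dict, List, Optional, Union

import pandas as pd

from .assessment import AssessmentResult
from .observers import ParticipantProfile, TrialRecord
from .stats import StudyReport
from .training import BlockRecord, BlockScore, SessionLog

PathLike = Union[str, Path]

ASSESSMENT_LOG_COLUMNS = [
    "session_id",
    "trial_index",
    "isi_ms",
    "presented_order",
    "reported_order",
    "correct",
    "running_estimate_ms",
    "halfwidth95_ms",
]

SESSION_LOG_COLUMNS = [
    "session_id",
    "block_index",
    "trial_index",
    "kind",
    "stimulus_value",
    "frequency_hz",
    "presented_order",
    "reported_order",
    "correct",
    "block_proportion",
    "net_points",
    "next_stimulus_value",
]

ISI_RANGE_MS = (1.0, 600.0)
DELTA_RANGE = (0.00025, 0.025)


class LogFormatError(ValueError):
    """Malformed or invalid log content; carries the offending line."""

    def __init__(self, message: str, line: Optional[int] = None) -> None:
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def write_assessment_log(
    path: PathLike, result: AssessmentResult, session_id: str = "S1"
) -> None:
    """One row per adaptive-assessment trial."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ASSESSMENT_LOG_COLUMNS)
        for i, trial in enumerate(result.trials):
            writer.writerow(
                [
                    session_id,
                    i,
                    repr(trial.stimulus),
                    trial.presented_order,
                    trial.reported_order,
                    int(trial.correct),
                    repr(result.running_estimate[i]),
                    repr(result.running_halfwidth[i]),
                ]
            )


def read_assessment_log(path: PathLike) -> AssessmentResult:
    """Rebuild trials and running estimates from an assessment log CSV."""
    trials: List[TrialRecord] = []
    running_est: List[float] = []
    running_hw: List[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise LogFormatError("empty log file") from None
        if header != ASSESSMENT_LOG_COLUMNS:
            raise LogFormatError(f"unexpected header {header}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(ASSESSMENT_LOG_COLUMNS):
                raise LogFormatError(
                    f"expected {len(ASSESSMENT_LOG_COLUMNS)} fields, got {len(row)}",
                    line=lineno,
                )
            try:
                isi = float(row[2])
                correct = bool(int(row[5]))
                est = float(row[6])
                hw = float(row[7])
            except ValueError as exc:
                raise LogFormatError(str(exc), line=lineno) from None
            if not (ISI_RANGE_MS[0] <= isi <= ISI_RANGE_MS[1]):
                raise LogFormatError(
                    f"isi_ms {isi} outside presentable range {ISI_RANGE_MS}",
                    line=lineno,
                )
            trials.append(
                TrialRecord("order", isi, row[3], row[4], correct, None)
            )
            running_est.append(est)
            running_hw.append(hw)
    if not trials:
        raise LogFormatError("log contains a header but no trials")
    return AssessmentResult(
        estimate=running_est[-1],
        interval_halfwidth_95=running_hw[-1],
        trials=trials,
        converged=False,  # not recoverable from the log alone
        running_estimate=running_est,
        running_halfwidth=running_hw,
    )


def write_session_log(path: PathLike, log: SessionLog) -> None:
    """One row per training trial, annotated with block bookkeeping."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SESSION_LOG_COLUMNS)
        for block in log.blocks:
            for j, trial in enumerate(block.trials):
                writer.writerow(
                    [
                        log.session_index,
                        block.block_index,
                        j,
                        block.kind,
                        repr(block.stimulus),
                        "" if block.frequency_hz is None else block.frequency_hz,
                        trial.presented_order,
                        trial.reported_order,
                        int(trial.correct),
                        repr(block.score.proportion),
                        block.score.net_points,
                        repr(block.next_stimulus),
                    ]
                )


def read_session_log(path: PathLike) -> SessionLog:
    """Rebuild a training session log from CSV, validating stimulus ranges."""
    rows: List[List[str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise LogFormatError("empty log file") from None
        if header != SESSION_LOG_COLUMNS:
            raise LogFormatError(f"unexpected header {header}", line=1)
        rows = list(reader)
    if not rows:
        raise LogFormatError("log contains a header but no trials")

    blocks: Dict[int, Dict[str, Any]] = {}
    session_index = None
    kind = None
    for lineno, row in enumerate(rows, start=2):
        if len(row) != len(SESSION_LOG_COLUMNS):
            raise LogFormatError(
                f"expected {len(SESSION_LOG_COLUMNS)} fields, got {len(row)}",
                line=lineno,
            )
        try:
            session_index = int(row[0])
            block_index = int(row[1])
            kind = row[3]
            stimulus = float(row[4])
            freq = int(row[5]) if row[5] else None
            correct = bool(int(row[8]))
            next_stim = float(row[11])
        except ValueError as exc:
            raise LogFormatError(str(exc), line=lineno) from None
        lo, hi = ISI_RANGE_MS if kind == "temporal" else DELTA_RANGE
        if not (lo <= stimulus <= hi):
            raise LogFormatError(
                f"stimulus_value {stimulus} outside range [{lo}, {hi}] "
                f"for kind {kind!r}",
                line=lineno,
            )
        entry = blocks.setdefault(
            block_index,
            {
                "kind": kind,
                "stimulus": stimulus,
                "frequency_hz": freq,
                "trials": [],
                "next": next_stim,
            },
        )
        entry["trials"].append(
            TrialRecord(
                "order" if kind == "temporal" else "loudness",
                stimulus,
                row[6],
                row[7],
                correct,
                freq,
            )
        )
    log = SessionLog(session_index=session_index, kind=kind)
    for bidx in sorted(blocks):
        entry = blocks[bidx]
        trials = tuple(entry["trials"])
        score = BlockScore(
            n_trials=len(trials), n_correct=sum(t.correct for t in trials)
        )
        log.blocks.append(
            BlockRecord(
                bidx,
                entry["kind"],
                entry["stimulus"],
                entry["frequency_hz"],
                trials,
                score,
                entry["next"],
            )
        )
    return log


def write_report(directory: PathLike, report: StudyReport) -> List[Path]:
    """Write each report table as CSV into the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in report.tables.items():
        out = directory / f"{name}.csv"
        table.to_csv(out, index=False)
        written.append(out)
    return written


def read_report(directory: PathLike, alpha: float = 0.05) -> StudyReport:
    directory = Path(directory)
    baseline = pd.read_csv(directory / "baseline.csv")
    prepost = pd.read_csv(directory / "prepost.csv")
    change = pd.read_csv(directory / "change_profile.csv")
    stability_path = directory / "stability.csv"
    stability = pd.read_csv(stability_path) if stability_path.exists() else None
    return StudyReport(baseline, prepost, change, stability, alpha=alpha)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    return repr(obj)


def config_hash(config: Any) -> str:
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_metadata(path: PathLike, config: Any, seed: int) -> None:
    meta = {
        "seed": seed,
        "config_hash": config_hash(config),
        "config": _jsonable(config),
    }
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def write_cohort(path: PathLike, cohort: List[ParticipantProfile]) -> None:
    Path(path).write_text(
        json.dumps([_jsonable(p) for p in cohort], indent=2, sort_keys=True)
    )
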