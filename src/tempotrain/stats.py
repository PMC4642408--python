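"""Study-level nonparametric analysis.

Within-group pre/post (and follow-up/post) comparisons use the Wilcoxon
signed-rank test; between-group baseline comparisons use the
Mann-Whitney U test. Both tests drop nothing silently: zero paired
differences are removed (the standard Wilcoxon convention), tied
magnitudes receive midranks, small samples get exact p-values by full
enumeration (all sign assignments / all group labelings), and larger
samples use the tie-corrected normal approximation with a continuity
correction. p-values are two-sided throughout.

The exact enumerations are small by construction (2^12 sign patterns,
C(14,7)=3432 labelings at the default cutoffs), which keeps the exact
regime instantaneous while matching the sample sizes of the simulated
studies.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import rankdata

from .measures import HIGHER, LOWER
from .observers import (
    EffectConfig,
    GROUP_TEMPORAL,
    StudyDesign,
    make_cohort,
)

EXACT_CUTOFF_SIGNED_RANK = 12  # n_effective at or below -> exact enumeration
EXACT_CUTOFF_RANK_SUM_TOTAL = 14  # n_a + n_b at or below -> exact enumeration


@dataclass(frozen=True)
class TestResult:
    test_name: str
    n_effective: int
    statistic: float
    z: float
    p_two_sided: float
    method: str  # "exact", "normal_approx", "degenerate", "not_testable"


@dataclass
class StudyReport:
    """Tables of a two-group pre/post/follow-up analysis."""

    baseline_table: pd.DataFrame
    prepost_tables: pd.DataFrame
    change_profile: pd.DataFrame
    stability_table: Optional[pd.DataFrame]
    alpha: float = 0.05
    tables: Dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tables = {
            "baseline": self.baseline_table,
            "prepost": self.prepost_tables,
            "change_profile": self.change_profile,
        }
        if self.stability_table is not None:
            self.tables["stability"] = self.stability_table


def _two_sided_from_dist(dist: np.ndarray, observed: float) -> float:
    """Doubled smaller tail of a discrete null distribution, capped at 1."""
    eps = 1e-9
    lo = float(np.mean(dist <= observed + eps))
    hi = float(np.mean(dist >= observed - eps))
    return min(1.0, 2.0 * min(lo, hi))


def _tie_term(values: np.ndarray) -> float:
    """sum(t^3 - t) over groups of tied values."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def wilcoxon_signed_rank(
    pre: Sequence[float],
    post: Sequence[float],
    exact_cutoff: int = EXACT_CUTOFF_SIGNED_RANK,
    test_name: str = "wilcoxon_signed_rank",
) -> TestResult:
    """Paired two-sided Wilcoxon signed-rank test of post vs pre."""
    pre_arr = np.asarray(pre, dtype=float)
    post_arr = np.asarray(post, dtype=float)
    if pre_arr.shape != post_arr.shape or pre_arr.ndim != 1:
        raise ValueError("pre and post must be 1-D samples of equal length")
    if pre_arr.size < 2:
        raise ValueError("need at least 2 pairs")
    d = post_arr - pre_arr
    nz = d != 0
    n = int(nz.sum())
    if n == 0:
        return TestResult(test_name, 0, 0.0, 0.0, 1.0, "degenerate")
    d = d[nz]
    ranks = rankdata(np.abs(d))  # midranks
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks.sum() - w_plus)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(np.abs(d)) / 48.0
    sign = float(np.sign(w_plus - w_minus)) or 1.0
    if var <= 0:
        z = 0.0
    else:
        shift = abs(w_plus - mean)
        z = sign * max(0.0, shift - 0.5) / np.sqrt(var)
    if n <= exact_cutoff:
        bits = np.array(list(itertools.product((0, 1), repeat=n)), dtype=float)
        dist = bits @ ranks
        p = _two_sided_from_dist(dist, w_plus)
        method = "exact"
    else:
        p = 2.0 * (1.0 - float(ndtr(abs(z)))) if var > 0 else 1.0
        method = "normal_approx"
    return TestResult(test_name, n, w_plus, float(z), float(p), method)


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    exact_cutoff_total: int = EXACT_CUTOFF_RANK_SUM_TOTAL,
    test_name: str = "mann_whitney_u",
) -> TestResult:
    """Two-sided Mann-Whitney U test between independent samples."""
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if a_arr.size == 0 or b_arr.size == 0:
        raise ValueError("both samples must be nonempty")
    na, nb = a_arr.size, b_arr.size
    pooled = np.concatenate([a_arr, b_arr])
    ranks = rankdata(pooled)
    ra = float(ranks[:na].sum())
    u_a = ra - na * (na + 1) / 2.0
    u_b = na * nb - u_a
    mean = na * nb / 2.0
    total = na + nb
    tie = _tie_term(pooled)
    var = na * nb / 12.0 * ((total + 1) - tie / (total * (total - 1)))
    sign = float(np.sign(u_a - mean)) or 1.0
    if var <= 0:
        z = 0.0
    else:
        z = sign * max(0.0, abs(u_a - mean) - 0.5) / np.sqrt(var)
    if total <= exact_cutoff_total:
        idx_all = range(total)
        u_dist = []
        base = na * (na + 1) / 2.0
        for combo in itertools.combinations(idx_all, na):
            u_dist.append(ranks[list(combo)].sum() - base)
        p = _two_sided_from_dist(np.asarray(u_dist), u_a)
        method = "exact"
    else:
        p = 2.0 * (1.0 - float(ndtr(abs(z)))) if var > 0 else 1.0
        method = "normal_approx"
    statistic = float(min(u_a, u_b))
    return TestResult(test_name, total, statistic, float(z), float(p), method)


def percent_change(pre: float, post: float, direction: str) -> float:
    """Signed percent improvement (positive always means improvement)."""
    if pre == 0:
        raise ValueError("percent change undefined for a zero baseline")
    if direction == LOWER:
        return 100.0 * (pre - post) / pre
    if direction == HIGHER:
        return 100.0 * (post - pre) / pre
    raise ValueError(f"unknown direction {direction!r}")


def _holm(pvals: List[float]) -> List[float]:
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def analyze_study(
    records: pd.DataFrame,
    design: StudyDesign,
    alpha: float = 0.05,
    holm: bool = False,
    min_testable_n: int = 4,
) -> StudyReport:
    """Build the four study tables from tidy per-participant records.

    ``records`` columns: participant_id, group, measure, phase, value.
    Produces baseline balance (between-group, pre), pre/post tests per
    group and measure, a percent-change profile of group means, and a
    follow-up stability table restricted to complete cases (participants
    assessed at both post and follow-up). Cells with fewer than
    ``min_testable_n`` effective pairs are flagged not testable.
    """
    required = {"participant_id", "group", "measure", "phase", "value"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    directions = design.directions
    measures = [m for m, _ in design.measure_list]
    groups = sorted(records["group"].unique())

    wide = records.pivot_table(
        index=["participant_id", "group", "measure"],
        columns="phase",
        values="value",
        aggfunc="first",
    ).reset_index()

    baseline_rows = []
    for measure in measures:
        sub = wide[wide["measure"] == measure]
        a = sub.loc[sub["group"] == groups[0], "pre"].dropna().to_numpy()
        b = sub.loc[sub["group"] == groups[1], "pre"].dropna().to_numpy()
        res = mann_whitney_u(a, b, test_name=f"baseline:{measure}")
        baseline_rows.append(
            {
                "measure": measure,
                "n_a": len(a),
                "n_b": len(b),
                "mean_a": a.mean() if len(a) else np.nan,
                "sd_a": a.std(ddof=1) if len(a) > 1 else np.nan,
                "mean_b": b.mean() if len(b) else np.nan,
                "sd_b": b.std(ddof=1) if len(b) > 1 else np.nan,
                "U": res.statistic,
                "z": res.z,
                "p": res.p_two_sided,
                "method": res.method,
                "significant": res.p_two_sided < alpha,
            }
        )
    baseline_table = pd.DataFrame(baseline_rows)

    prepost_rows = []
    change_rows = []
    for group in groups:
        for measure in measures:
            sub = wide[(wide["measure"] == measure) & (wide["group"] == group)]
            paired = sub.dropna(subset=["pre", "post"])
            pre_v = paired["pre"].to_numpy()
            post_v = paired["post"].to_numpy()
            direction = directions[measure]
            if len(pre_v) >= 2:
                res = wilcoxon_signed_rank(
                    pre_v, post_v, test_name=f"prepost:{group}:{measure}"
                )
            else:
                res = TestResult(
                    f"prepost:{group}:{measure}", len(pre_v), np.nan, np.nan,
                    np.nan, "not_testable",
                )
            prepost_rows.append(
                {
                    "group": group,
                    "measure": measure,
                    "n_effective": res.n_effective,
                    "mean_pre": pre_v.mean() if len(pre_v) else np.nan,
                    "mean_post": post_v.mean() if len(post_v) else np.nan,
                    "W": res.statistic,
                    "z": res.z,
                    "p": res.p_two_sided,
                    "method": res.method,
                    "significant": bool(res.p_two_sided < alpha)
                    if np.isfinite(res.p_two_sided)
                    else False,
                }
            )
            if len(pre_v) and pre_v.mean() != 0:
                pct = percent_change(pre_v.mean(), post_v.mean(), direction)
            else:
                pct = np.nan
            change_rows.append(
                {
                    "group": group,
                    "measure": measure,
                    "direction": direction,
                    "percent_change": pct,
                }
            )
    prepost_tables = pd.DataFrame(prepost_rows)
    if holm and len(prepost_tables):
        for group in groups:
            mask = prepost_tables["group"] == group
            ps = prepost_tables.loc[mask, "p"].fillna(1.0).tolist()
            prepost_tables.loc[mask, "p_holm"] = _holm(ps)
            prepost_tables.loc[mask, "significant"] = (
                prepost_tables.loc[mask, "p_holm"] < alpha
            )
    change_profile = pd.DataFrame(change_rows)

    stability_table: Optional[pd.DataFrame] = None
    if "followup" in wide.columns and wide["followup"].notna().any():
        stab_rows = []
        for group in groups:
            for measure in measures:
                sub = wide[(wide["measure"] == measure) & (wide["group"] == group)]
                cc = sub.dropna(subset=["post", "followup"])  # complete cases
                post_v = cc["post"].to_numpy()
                fu_v = cc["followup"].to_numpy()
                if len(post_v) >= min_testable_n:
                    res = wilcoxon_signed_rank(
                        post_v, fu_v, test_name=f"stability:{group}:{measure}"
                    )
                    testable = True
                else:
                    res = TestResult(
                        f"stability:{group}:{measure}", len(post_v), np.nan,
                        np.nan, np.nan, "not_testable",
                    )
                    testable = False
                stab_rows.append(
                    {
                        "group": group,
                        "measure": measure,
                        "n_effective": len(post_v),
                        "mean_post": post_v.mean() if len(post_v) else np.nan,
                        "mean_followup": fu_v.mean() if len(fu_v) else np.nan,
                        "W": res.statistic,
                        "z": res.z,
                        "p": res.p_two_sided,
                        "method": res.method,
                        "testable": testable,
                        "significant": bool(res.p_two_sided < alpha)
                        if testable and np.isfinite(res.p_two_sided)
                        else False,
                    }
                )
        stability_table = pd.DataFrame(stab_rows)
    elif design.followup:
        warnings.warn(
            "follow-up requested by the design but absent from the records; "
            "stability table omitted",
            stacklevel=2,
        )

    return StudyReport(
        baseline_table=baseline_table,
        prepost_tables=prepost_tables,
        change_profile=change_profile,
        stability_table=stability_table,
        alpha=alpha,
    )


def type_one_error_sim(
    design: StudyDesign,
    n_reps: int,
    seed: int,
    alpha: float = 0.05,
    effect: Optional[EffectConfig] = None,
    estimator_config=None,
) -> float:
    """Fraction of null replicates with a significant within-group
    threshold pre/post test.

    Each replicate draws a cohort under a null effect model (no training
    improvement), measures the order threshold pre and post with the
    adaptive procedure, and runs the paired test in the temporal arm.
    """
    from .assessment import (  # local import to avoid a cycle at module load
        EstimatorConfig,
        atot_from_sessions,
        run_assessment_session,
    )

    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    if effect is None:
        effect = EffectConfig(improvement_rate_mean=0.0, improvement_rate_sd=0.0,
                              transfer_scale=0.0)
    est_cfg = estimator_config or EstimatorConfig()
    hits = 0
    for rep in range(n_reps):
        rep_seed = np.random.SeedSequence(entropy=seed, spawn_key=(rep,))
        cohort_seed = int(rep_seed.generate_state(1)[0] % (2**31))
        cohort = make_cohort(design, effect, cohort_seed)
        group_a = [p for p in cohort if p.group == GROUP_TEMPORAL]
        pre_vals, post_vals = [], []
        for prof in group_a:
            streams = np.random.SeedSequence(
                entropy=seed, spawn_key=(rep, prof.index)
            ).spawn(2 * design.n_assessment_sessions)
            pre = atot_from_sessions(
                [
                    run_assessment_session(prof, est_cfg, seed=streams[k])
                    for k in range(design.n_assessment_sessions)
                ]
            )
            post = atot_from_sessions(
                [
                    run_assessment_session(
                        prof, est_cfg,
                        seed=streams[design.n_assessment_sessions + k],
                    )
                    for k in range(design.n_assessment_sessions)
                ]
            )
            pre_vals.append(pre)
            post_vals.append(post)
        res = wilcoxon_signed_rank(pre_vals, post_vals)
        if res.p_two_sided < alpha:
            hits += 1
    return hits / n_reps
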