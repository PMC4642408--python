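"""Nonparametric tests against independent enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import tempotrain as tt
from tempotrain.measures import measure_list


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive code paths)

def oracle_wilcoxon_p(pre, post):
    """Exact two-sided signed-rank p by looping over all sign patterns."""
    d = [b - a for a, b in zip(pre, post) if b - a != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = scipy.stats.rankdata([abs(x) for x in d])
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    dist = []
    for signs in itertools.product([0, 1], repeat=n):
        dist.append(sum(r for r, s in zip(ranks, signs) if s))
    lo = sum(1 for w in dist if w <= w_obs + 1e-9) / len(dist)
    hi = sum(1 for w in dist if w >= w_obs - 1e-9) / len(dist)
    return min(1.0, 2 * min(lo, hi))


def oracle_mwu_p(a, b):
    """Exact two-sided rank-sum p by looping over all labelings."""
    pooled = list(a) + list(b)
    ranks = scipy.stats.rankdata(pooled)
    na = len(a)
    u_obs = sum(ranks[:na]) - na * (na + 1) / 2
    dist = []
    for combo in itertools.combinations(range(len(pooled)), na):
        dist.append(sum(ranks[i] for i in combo) - na * (na + 1) / 2)
    lo = sum(1 for u in dist if u <= u_obs + 1e-9) / len(dist)
    hi = sum(1 for u in dist if u >= u_obs - 1e-9) / len(dist)
    return min(1.0, 2 * min(lo, hi))


# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_all_positive_n5_exact(self):
        pre = [1.0, 2.0, 3.0, 4.0, 5.0]
        post = [2.0, 4.0, 6.0, 8.0, 10.0]
        res = tt.wilcoxon_signed_rank(pre, post)
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(2 / 32)
        assert res.n_effective == 5

    def test_degenerate_identical_samples(self):
        res = tt.wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.method == "degenerate"
        assert res.p_two_sided == 1.0

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(20):
            pre = rng.normal(size=9)
            post = pre + rng.normal(size=9)
            ours = tt.wilcoxon_signed_rank(pre, post)
            ref = scipy.stats.wilcoxon(post, pre, mode="exact")
            assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        diffs=st.lists(
            st.integers(min_value=-5, max_value=5), min_size=2, max_size=10
        )
    )
    def test_exact_p_equals_enumeration_oracle(self, diffs):
        pre = [0.0] * len(diffs)
        post = [float(d) for d in diffs]
        if all(d == 0 for d in diffs):
            return
        res = tt.wilcoxon_signed_rank(pre, post)
        assert res.p_two_sided == pytest.approx(oracle_wilcoxon_p(pre, post))

    def test_normal_approx_close_to_exact_at_regime_boundary(self, rng):
        rels = []
        for s in range(30):
            g = np.random.default_rng(s)
            pre = g.normal(size=12)
            post = pre + g.normal(0.6, 1.0, size=12)
            exact = tt.wilcoxon_signed_rank(pre, post, exact_cutoff=12)
            approx = tt.wilcoxon_signed_rank(pre, post, exact_cutoff=0)
            if exact.p_two_sided > 0.01:
                rels.append(
                    abs(approx.p_two_sided - exact.p_two_sided) / exact.p_two_sided
                )
        assert np.median(rels) < 0.10

    def test_z_sign_follows_direction_of_change(self):
        pre = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        up = tt.wilcoxon_signed_rank(pre, [x + 1 for x in pre])
        down = tt.wilcoxon_signed_rank(pre, [x - 1 for x in pre])
        assert up.z > 0 > down.z


class TestMannWhitney:
    def test_complete_separation_exact(self):
        res = tt.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.statistic == 0.0
        assert res.p_two_sided == pytest.approx(2 / 20)

    def test_identical_multisets_give_p_1(self):
        res = tt.mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3])
        assert res.p_two_sided == 1.0

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(20):
            a = rng.normal(size=6)
            b = rng.normal(0.5, 1.0, size=7)
            ours = tt.mann_whitney_u(a, b)
            ref = scipy.stats.mannwhitneyu(a, b, method="exact")
            assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        a=st.lists(st.integers(0, 6), min_size=2, max_size=6),
        b=st.lists(st.integers(0, 6), min_size=2, max_size=6),
    )
    def test_exact_p_equals_enumeration_oracle(self, a, b):
        res = tt.mann_whitney_u(a, b)
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(oracle_mwu_p(a, b))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            tt.mann_whitney_u([], [1.0])

    def test_normal_approx_close_to_exact_at_regime_boundary(self, rng):
        rels = []
        for s in range(30):
            g = np.random.default_rng(100 + s)
            a = g.normal(size=7)
            b = g.normal(0.8, 1.0, size=7)
            exact = tt.mann_whitney_u(a, b, exact_cutoff_total=14)
            approx = tt.mann_whitney_u(a, b, exact_cutoff_total=0)
            if exact.p_two_sided > 0.01:
                rels.append(
                    abs(approx.p_two_sided - exact.p_two_sided) / exact.p_two_sided
                )
        assert np.median(rels) < 0.10


class TestPercentChange:
    @pytest.mark.parametrize(
        "pre,post,direction,expected",
        [
            (48.0, 35.6, "lower_is_better", 25.83),
            (4.2, 4.7, "higher_is_better", 11.90),
            (10.0, 10.0, "lower_is_better", 0.0),
            (179.0, 85.0, "lower_is_better", 52.51),
        ],
    )
    def test_worked_examples(self, pre, post, direction, expected):
        assert tt.percent_change(pre, post, direction) == pytest.approx(
            expected, abs=0.01
        )

    def test_zero_baseline_flagged(self):
        with pytest.raises(ValueError):
            tt.percent_change(0.0, 5.0, "lower_is_better")

    def test_positive_always_means_improvement(self):
        # improvement under each direction convention maps to positive %
        assert tt.percent_change(10, 5, "lower_is_better") > 0
        assert tt.percent_change(5, 10, "lower_is_better") < 0
        assert tt.percent_change(5, 10, "higher_is_better") > 0
        assert tt.percent_change(10, 5, "higher_is_better") < 0


def _tiny_records(seed=0, effect=0.0, n=6, followup=True):
    """Hand-built tidy records for a two-group two-measure toy study."""
    g = np.random.default_rng(seed)
    rows = []
    for i in range(2 * n):
        group = "A_temporal" if i < n else "B_control"
        pre = g.normal(150, 20)
        post = pre - (effect if group == "A_temporal" else 0.0) + g.normal(0, 5)
        fu = post + g.normal(0, 5)
        for phase, value in [("pre", pre), ("post", post)] + (
            [("followup", fu)] if followup and i % 2 == 0 else []
        ):
            rows.append(
                {"participant_id": f"P{i}", "group": group, "measure": "atot",
                 "phase": phase, "value": value}
            )
    return pd.DataFrame(rows)


class TestAnalyzeStudy:
    def _design(self, n=6):
        return tt.StudyDesign(
            n_group_a=n, n_group_b=n, n_training_sessions=1,
            trials_per_session=10, n_assessment_sessions=1, followup=True,
            measure_list=(("atot", "lower_is_better"),),
        )

    def test_tables_cover_every_measure_once(self):
        report = tt.analyze_study(_tiny_records(effect=60.0), self._design())
        assert list(report.baseline_table["measure"]) == ["atot"]
        assert len(report.prepost_tables) == 2  # one per group
        assert len(report.change_profile) == 2
        assert report.stability_table is not None

    def test_strong_effect_flagged_in_temporal_arm_only(self):
        report = tt.analyze_study(_tiny_records(effect=80.0), self._design())
        pp = report.prepost_tables.set_index("group")
        assert bool(pp.loc["A_temporal", "significant"])
        assert not bool(pp.loc["B_control", "significant"])

    def test_complete_case_followup_n(self):
        report = tt.analyze_study(_tiny_records(), self._design())
        stab = report.stability_table.set_index("group")
        assert stab.loc["A_temporal", "n_effective"] == 3  # every other completer

    def test_small_followup_flagged_not_testable(self):
        records = _tiny_records()
        # drop follow-up for all but 2 in group A
        keep = records[
            ~((records.phase == "followup") & (records.participant_id != "P0")
              & (records.participant_id != "P2"))
        ]
        report = tt.analyze_study(keep, self._design())
        stab = report.stability_table.set_index("group")
        assert not bool(stab.loc["A_temporal", "testable"])

    def test_missing_followup_warns_and_omits_table(self):
        with pytest.warns(UserWarning):
            report = tt.analyze_study(
                _tiny_records(followup=False), self._design()
            )
        assert report.stability_table is None


class TestTypeOneError:
    def test_zero_variance_null_never_rejects(self):
        design = tt.StudyDesign(
            n_group_a=5, n_group_b=5, n_training_sessions=1,
            trials_per_session=10, n_assessment_sessions=1, followup=False,
            measure_list=measure_list(tt.STUDY1_MEASURES),
        )
        # degenerate: identical pre/post values per participant
        rows = []
        for i in range(5):
            for phase in ("pre", "post"):
                rows.append({"participant_id": f"P{i}", "group": "A_temporal",
                             "measure": "atot", "phase": phase, "value": 100.0})
        res = tt.wilcoxon_signed_rank([100.0] * 5, [100.0] * 5)
        assert res.p_two_sided == 1.0

    def test_n_reps_floor(self):
        design = tt.StudyDesign(
            n_group_a=4, n_group_b=4, n_training_sessions=1,
            trials_per_session=10, n_assessment_sessions=1, followup=False,
            measure_list=measure_list(tt.STUDY1_MEASURES),
        )
        with pytest.raises(ValueError):
            tt.type_one_error_sim(design, n_reps=10, seed=0)
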