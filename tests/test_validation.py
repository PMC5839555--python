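"""Concordance, predictive values, recruitment accounting, association tests."""

from math import comb, inf

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from cannaphen.classify import Label
from cannaphen.validation import (
    ARM_TERM_NEGATIVE,
    ARM_TERM_POSITIVE,
    CATEGORIES,
    ConcordanceTable,
    DegenerateTableError,
    Disposition,
    InterviewResponse,
    UndefinedRateError,
    association_test,
    build_concordance,
    enrichment,
    group_summary,
    predictive_value,
    recruitment_rate,
)

# The validation study's printed concordance: 35 term-positive completers
# (15 past-month, 17 past-year, 2 never, 33 ever) and 34 term-negative
# (3, 4, 11, 23).
STUDY_TABLE = ConcordanceTable(
    counts={
        ARM_TERM_POSITIVE: {"past_30d": 15, "past_year": 17, "nonuse": 2, "ever": 33},
        ARM_TERM_NEGATIVE: {"past_30d": 3, "past_year": 4, "nonuse": 11, "ever": 23},
    },
    arm_totals={ARM_TERM_POSITIVE: 35, ARM_TERM_NEGATIVE: 34},
)


def response(pid, p30=False, py=False, ever=False, completed=True):
    return InterviewResponse(pid, p30, py, ever, completed)


class TestInterviewResponse:
    def test_nesting_enforced(self):
        with pytest.raises(ValueError):
            response("P1", p30=True, py=False, ever=False)
        with pytest.raises(ValueError):
            response("P1", py=True, ever=False)

    def test_noncompleted_cannot_carry_use_flags(self):
        with pytest.raises(ValueError):
            response("P1", ever=True, completed=False)


class TestDisposition:
    def test_balanced_accounting_accepted(self):
        d = Disposition(97, 69, 1, 20, 7)
        assert d.contacted == 97

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError, match="balance"):
            Disposition(97, 69, 1, 20, 6)

    @pytest.mark.parametrize(
        "d,expected",
        [
            (Disposition(97, 69, 1, 20, 7), 71.0),
            (Disposition(10, 10, 0, 0, 0), 100.0),
            (Disposition(10, 0, 0, 5, 5), 0.0),
        ],
    )
    def test_recruitment_rate(self, d, expected):
        assert recruitment_rate(d) == expected

    def test_zero_contacted_undefined(self):
        with pytest.raises(UndefinedRateError):
            recruitment_rate(Disposition(0, 0, 0, 0, 0))


class TestBuildConcordance:
    def test_arm_totals_count_completed_only(self):
        labels = {"U1": Label.PRELIMINARY_USER, "U2": Label.PRELIMINARY_USER,
                  "N1": Label.PRELIMINARY_NONUSER}
        interviews = [
            response("U1", p30=True, py=True, ever=True),
            response("U2", completed=False),
            response("N1", ever=True),
        ]
        t = build_concordance(labels, interviews)
        assert t.total(ARM_TERM_POSITIVE) == 1
        assert t.total(ARM_TERM_NEGATIVE) == 1
        assert t.cell(ARM_TERM_POSITIVE, "past_30d") == 1
        assert t.cell(ARM_TERM_NEGATIVE, "ever") == 1
        assert t.cell(ARM_TERM_NEGATIVE, "nonuse") == 0

    def test_unclassified_interview_listed(self):
        with pytest.raises(ValueError, match=r"\['PX'\]"):
            build_concordance({}, [response("PX")])

    def test_zero_interviews_all_zero(self):
        t = build_concordance({"P1": Label.PRELIMINARY_USER}, [])
        assert all(t.cell(arm, c) == 0 for arm in (ARM_TERM_POSITIVE, ARM_TERM_NEGATIVE)
                   for c in CATEGORIES)

    @given(st.lists(st.tuples(st.booleans(), st.integers(0, 3)), max_size=40),
           st.randoms(use_true_random=False))
    def test_matches_nested_loop_crosstab_oracle(self, rows, rnd):
        """Randomized cohort: the table equals a brute-force O(n^2)-style
        recount, and is invariant to input permutation."""
        labels, interviews = {}, []
        for i, (is_user, level) in enumerate(rows):
            pid = f"P{i}"
            labels[pid] = Label.PRELIMINARY_USER if is_user else Label.PRELIMINARY_NONUSER
            # level encodes nested use: 0 never, 1 ever, 2 past-year, 3 past-30d
            interviews.append(
                response(pid, p30=level >= 3, py=level >= 2, ever=level >= 1)
            )
        t = build_concordance(labels, interviews)
        for arm, want_user in ((ARM_TERM_POSITIVE, True), (ARM_TERM_NEGATIVE, False)):
            members = [iv for iv in interviews
                       if (labels[iv.patient_id] is Label.PRELIMINARY_USER) == want_user]
            assert t.total(arm) == len(members)
            assert t.cell(arm, "past_30d") == sum(iv.used_past_30d for iv in members)
            assert t.cell(arm, "past_year") == sum(iv.used_past_year for iv in members)
            assert t.cell(arm, "ever") == sum(iv.ever_used for iv in members)
            assert t.cell(arm, "nonuse") == sum(not iv.ever_used for iv in members)
        shuffled = list(interviews)
        rnd.shuffle(shuffled)
        assert build_concordance(labels, shuffled) == t


class TestPredictiveValues:
    @pytest.mark.parametrize(
        "arm,category,expected",
        [
            (ARM_TERM_POSITIVE, "past_30d", 42.9),
            (ARM_TERM_POSITIVE, "past_year", 48.6),
            (ARM_TERM_POSITIVE, "nonuse", 5.7),
            (ARM_TERM_POSITIVE, "ever", 94.3),
            (ARM_TERM_NEGATIVE, "past_30d", 8.8),
            (ARM_TERM_NEGATIVE, "past_year", 11.8),
            (ARM_TERM_NEGATIVE, "nonuse", 32.4),
            (ARM_TERM_NEGATIVE, "ever", 67.6),
        ],
    )
    def test_reconstructs_every_printed_percentage(self, arm, category, expected):
        assert predictive_value(STUDY_TABLE, arm, category) == expected

    def test_ever_never_partition_sums_to_100(self):
        for arm in (ARM_TERM_POSITIVE, ARM_TERM_NEGATIVE):
            total = predictive_value(STUDY_TABLE, arm, "ever") + predictive_value(
                STUDY_TABLE, arm, "nonuse"
            )
            assert total == 100.0

    def test_zero_arm_total_undefined(self):
        empty = build_concordance({"P1": Label.PRELIMINARY_USER}, [])
        with pytest.raises(UndefinedRateError):
            predictive_value(empty, ARM_TERM_POSITIVE, "ever")

    def test_enrichment_presentation_order(self):
        assert enrichment(STUDY_TABLE, "past_30d") == (8.8, 42.9)
        assert enrichment(STUDY_TABLE, "ever") == (67.6, 94.3)

    def test_enrichment_equal_arms(self):
        t = ConcordanceTable(
            counts={arm: {"past_30d": 1, "past_year": 2, "nonuse": 5, "ever": 5}
                    for arm in (ARM_TERM_POSITIVE, ARM_TERM_NEGATIVE)},
            arm_totals={ARM_TERM_POSITIVE: 10, ARM_TERM_NEGATIVE: 10},
        )
        lo, hi = enrichment(t, "past_year")
        assert lo == hi


def fisher_oracle(a, b, c, d):
    """Exact-fraction two-sided Fisher p: enumerate every table at the fixed
    margins and sum those no likelier than the observed one (standard
    near-tie tolerance, matching the usual convention)."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    cnt = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    obs = cnt[a]
    keep = sum(v for v in cnt.values() if v <= obs or v <= obs * (1 + 1e-7))
    return keep / comb(r1 + r2, c1)


class TestAssociationTest:
    def test_identical_proportions_p_one(self):
        _, p = association_test(10, 10, 10, 10)
        assert p == pytest.approx(1.0)

    def test_perfect_separation_closed_form(self):
        # [[5,0],[0,5]]: only the two extreme tables are as unlikely as
        # observed -> p = 2 * C(5,5)C(5,0)/C(10,5) = 2/252
        odds, p = association_test(5, 0, 0, 5)
        assert odds == inf
        assert p == pytest.approx(2 / 252, rel=1e-12)

    def test_ever_use_table_matches_enumeration_oracle(self):
        _, p = association_test(33, 2, 23, 11)
        assert p == pytest.approx(fisher_oracle(33, 2, 23, 11), rel=1e-9)

    def test_agrees_with_scipy_reference(self):
        for table in [(33, 2, 23, 11), (15, 20, 3, 31), (1, 9, 8, 2), (7, 7, 7, 7)]:
            _, p = association_test(*table)
            ref = stats.fisher_exact(np.array(table).reshape(2, 2)).pvalue
            assert p == pytest.approx(ref, rel=1e-9)

    def test_chi2_variants_match_scipy(self):
        for method, correction in (("chi2", False), ("chi2_yates", True)):
            stat, p = association_test(33, 2, 23, 11, method=method)
            ref = stats.chi2_contingency([[33, 2], [23, 11]], correction=correction)
            assert stat == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_zero_margin_degenerate(self):
        with pytest.raises(DegenerateTableError):
            association_test(0, 0, 5, 5)

    @given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                     st.integers(0, 12), st.integers(0, 12)))
    def test_random_tables_match_oracle(self, table):
        a, b, c, d = table
        if 0 in (a + b, c + d, a + c, b + d):
            return
        _, p = association_test(a, b, c, d)
        assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)


class TestGroupSummary:
    def test_planted_tobacco_share(self):
        # 6 of 18 current users smoke tobacco -> 33.3%
        df = pd.DataFrame(
            {
                "current_use": [True] * 18 + [False] * 51,
                "tobacco_current": [True] * 6 + [False] * 12 + [True] * 9 + [False] * 42,
            }
        )
        out = group_summary(df)
        row = out[out.covariate == "tobacco_current"].iloc[0]
        assert row["True"] == 33.3
        assert row["False"] == pytest.approx(17.6)

    def test_identical_covariate_equal_means(self):
        df = pd.DataFrame({"current_use": [True, True, False, False],
                           "mets": [5.0, 5.0, 5.0, 5.0]})
        out = group_summary(df)
        assert out.iloc[0]["True"] == out.iloc[0]["False"] == 5.0

    def test_matches_brute_force_aggregation(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            {
                "current_use": rng.random(60) < 0.3,
                "mets": rng.normal(10, 3, 60).round(2),
                "screen_positive": rng.random(60) < 0.4,
                "tobacco": rng.choice(["current", "former", "never"], 60),
            }
        )
        out = group_summary(df)
        for g in (True, False):
            sub = df[df.current_use == g]
            mets = out[out.covariate == "mets"].iloc[0][str(g)]
            assert mets == pytest.approx(round(sub.mets.mean(), 2), abs=0.011)
            former = out[(out.covariate == "tobacco") & (out.level == "former")]
            assert former.iloc[0][str(g)] == pytest.approx(
                100 * (sub.tobacco == "former").mean(), abs=0.051
            )

    def test_missing_group_column_raises(self):
        with pytest.raises(KeyError):
            group_summary(pd.DataFrame({"x": [1]}), group_col="nope")
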