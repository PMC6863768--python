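"""Association screen: contingency building, Fisher test, cutoffs, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from predgwas import (
    INFERIOR,
    MODERATE,
    SUPERIOR,
    BinaryLabelTable,
    ContingencyCounts,
    PresenceAbsenceMatrix,
    ScreenConfig,
    bh_adjust,
    build_contingency,
    compare_category_profiles,
    evaluate_gene,
    fisher_two_sided,
    run_association,
    sensitivity_specificity,
    summarize_overlaps,
)
from predgwas.containers import UNASSIGNED
from predgwas.errors import DegenerateDesignError, InsufficientAnnotationError

from _oracles import fisher_two_sided_oracle


def _labels(n_sup, n_inf, n_mod=0):
    labels = [SUPERIOR] * n_sup + [INFERIOR] * n_inf + [MODERATE] * n_mod
    return pd.Series(labels, index=[f"s{i}" for i in range(len(labels))])


class TestBuildContingency:
    def test_counts_by_label(self):
        labels = _labels(9, 9, 2)
        presence = pd.Series(
            [True] * 7 + [False] * 2 + [True] + [False] * 8 + [True, False],
            index=labels.index,
        )
        counts = build_contingency(presence, labels)
        assert counts == ContingencyCounts(7, 1, 2, 8)

    def test_gene_absent_everywhere(self):
        labels = _labels(9, 9)
        counts = build_contingency(pd.Series(False, index=labels.index), labels)
        assert counts == ContingencyCounts(0, 0, 9, 9)

    def test_all_moderate_is_degenerate(self):
        labels = _labels(0, 0, 6)
        with pytest.raises(DegenerateDesignError):
            build_contingency(pd.Series(True, index=labels.index), labels)


class TestFisherTwoSided:
    def test_worked_example(self):
        # frozen from the exact enumeration oracle
        p = fisher_two_sided(ContingencyCounts(7, 1, 2, 8))
        assert p == pytest.approx(0.015220074043603456, abs=1e-12)

    def test_empty_table_gives_one(self):
        assert fisher_two_sided(ContingencyCounts(0, 0, 0, 0)) == 1.0

    def test_perfect_separation_of_nine_vs_nine(self):
        # the two symmetric extreme tables, each of probability 1/C(18,9)
        p = fisher_two_sided(ContingencyCounts(9, 0, 0, 9))
        assert p == pytest.approx(2 / math.comb(18, 9), rel=1e-12)

    def test_matches_enumeration_oracle_on_moderate_margins(self):
        for n1 in range(0, 9):
            for n2 in range(0, 9):
                for a in range(n1 + 1):
                    for b in range(n2 + 1):
                        counts = ContingencyCounts(a, b, n1 - a, n2 - b)
                        assert fisher_two_sided(counts) == pytest.approx(
                            fisher_two_sided_oracle(a, b, n1 - a, n2 - b), abs=1e-9
                        )

    @given(
        a=st.integers(0, 10), b=st.integers(0, 10),
        c=st.integers(0, 10), d=st.integers(0, 10),
    )
    def test_swapping_presence_coding_preserves_p(self, a, b, c, d):
        p_gene = fisher_two_sided(ContingencyCounts(a, b, c, d))
        p_swapped = fisher_two_sided(ContingencyCounts(c, d, a, b))
        assert p_gene == pytest.approx(p_swapped, abs=1e-12)


class TestSensitivitySpecificity:
    def test_arithmetic(self):
        sens, spec = sensitivity_specificity(ContingencyCounts(7, 1, 2, 8))
        assert sens == pytest.approx(100 * 7 / 9)
        assert spec == pytest.approx(100 * 8 / 9)

    def test_perfect_marker(self):
        assert sensitivity_specificity(ContingencyCounts(9, 0, 0, 9)) == (100.0, 100.0)

    def test_minimum_carriers_for_70pct_of_nine_is_seven(self):
        reaching = [
            a for a in range(10)
            if sensitivity_specificity(ContingencyCounts(a, 0, 9 - a, 9))[0] >= 70
        ]
        assert min(reaching) == 7

    def test_empty_margin_is_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            sensitivity_specificity(ContingencyCounts(0, 1, 0, 8))


class TestEvaluateGene:
    def _record(self, a, b, c, d):
        labels = _labels(a + c, b + d)
        presence = pd.Series(
            [True] * a + [False] * c + [True] * b + [False] * d,
            index=[f"s{i}" for i in range(a + c)] + [f"s{i}" for i in range(a + c, a + b + c + d)],
        )
        return evaluate_gene(presence, labels, ScreenConfig(), "g", "p")

    def test_passing_record(self):
        rec = self._record(7, 1, 2, 8)
        assert rec.passes and rec.direction == "positive"
        assert rec.p_value < 0.05

    def test_low_sensitivity_fails_regardless_of_p(self):
        rec = self._record(5, 1, 4, 8)
        assert rec.sensitivity_pct < 70
        assert not rec.passes

    def test_negative_direction_never_passes(self):
        rec = self._record(1, 7, 8, 2)
        assert rec.direction == "negative"
        assert not rec.passes

    @given(a=st.integers(0, 8), b=st.integers(0, 9), d_margin=st.integers(1, 9))
    def test_adding_a_superior_carrier_never_unpasses(self, a, b, d_margin):
        if b > d_margin:
            return
        base = self._record(a, b, 9 - a, d_margin - b)
        more = self._record(a + 1, b, 8 - a, d_margin - b)
        if base.passes:
            assert more.passes


class TestBhAdjust:
    def test_step_up_hand_computed(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_identity_cases(self):
        assert bh_adjust([1.0]) == [1.0]
        assert bh_adjust([0.007]) == [0.007]
        assert bh_adjust([]) == []

    def test_order_preserved_and_monotone_in_rank(self):
        p = [0.04, 0.001, 0.5, 0.04]
        q = bh_adjust(p)
        assert len(q) == 4 and q[1] <= q[0] == q[3] <= q[2]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestRunAssociation:
    def test_all_core_matrix_yields_no_records(self, tiny_panel):
        presence = pd.DataFrame(
            True, index=["core1", "core2"], columns=tiny_panel.strain_ids
        )
        from predgwas import binarize_panel

        labels = binarize_panel(tiny_panel)
        records, summary = run_association(PresenceAbsenceMatrix(presence), labels)
        assert records == []
        assert summary.total_unique_hits == 0

    def test_prey_with_no_informative_strains_skipped(self, tiny_matrix, caplog):
        label = pd.DataFrame(
            {
                "allmod": [MODERATE] * 6,
                "ok": [SUPERIOR, SUPERIOR, INFERIOR, INFERIOR, MODERATE, MODERATE],
            },
            index=tiny_matrix.strain_ids,
        )
        with caplog.at_level("WARNING"):
            records, summary = run_association(
                tiny_matrix, BinaryLabelTable(label)
            )
        assert "allmod" not in summary.per_prey_hits
        assert any("allmod" in message for message in caplog.messages)

    def test_every_prey_degenerate_raises(self, tiny_matrix):
        label = pd.DataFrame(
            {"p": [MODERATE] * 6}, index=tiny_matrix.strain_ids
        )
        with pytest.raises(DegenerateDesignError):
            run_association(tiny_matrix, BinaryLabelTable(label))

    def test_bh_applied_within_prey(self, tiny_matrix):
        label = pd.DataFrame(
            {"p": [SUPERIOR, SUPERIOR, SUPERIOR, INFERIOR, INFERIOR, INFERIOR]},
            index=tiny_matrix.strain_ids,
        )
        records, _ = run_association(tiny_matrix, BinaryLabelTable(label))
        raw = [r.p_value for r in records]
        assert [r.p_value_bh for r in records] == pytest.approx(bh_adjust(raw))

    def test_mismatched_strain_sets_rejected(self, tiny_matrix):
        label = pd.DataFrame(
            {"p": [SUPERIOR, INFERIOR, MODERATE]}, index=["x1", "x2", "x3"]
        )
        with pytest.raises(KeyError):
            run_association(tiny_matrix, BinaryLabelTable(label))


class TestSummarizeOverlaps:
    def test_set_arithmetic(self):
        summary = summarize_overlaps({"P1": {"g1", "g2"}, "P2": {"g2"}})
        assert summary.pairwise_overlap.at["P1", "P2"] == 1
        assert summary.genes_by_prey_count == {1: 1, 2: 1}
        assert summary.total_unique_hits == 2

    def test_disjoint_sets_have_zero_overlap(self):
        summary = summarize_overlaps({"P1": {"g1"}, "P2": {"g2"}, "P3": set()})
        off_diag = summary.pairwise_overlap.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off_diag == 0).all()

    def test_identical_sets_overlap_fully(self):
        hits = {"g1", "g2", "g3"}
        summary = summarize_overlaps({"P1": set(hits), "P2": set(hits)})
        assert summary.pairwise_overlap.at["P1", "P2"] == 3
        assert summary.genes_by_prey_count == {2: 3}
        assert summary.total_unique_hits == 3


class TestCompareCategoryProfiles:
    def test_profile_matching_background_gives_zero_statistic(self):
        hits = {f"g{i}": "K" for i in range(5)} | {f"h{i}": "E" for i in range(5)}
        stat, p = compare_category_profiles(hits, {"K": 0.5, "E": 0.5})
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_fully_skewed_two_category_example(self):
        hits = {f"g{i}": "K" for i in range(10)}
        stat, _ = compare_category_profiles(hits, {"K": 0.5, "E": 0.5})
        assert stat == pytest.approx(10.0)

    def test_low_expectation_categories_pooled(self):
        # 10 hits; background spreads 10% over tiny categories (expected < 1 each)
        hits = {f"g{i}": "K" for i in range(6)} | {f"h{i}": "E" for i in range(4)}
        background = {"K": 0.55, "E": 0.35} | {c: 0.02 for c in "JALBD"}
        stat, p = compare_category_profiles(hits, background)
        assert np.isfinite(stat) and 0 < p <= 1

    def test_single_category_after_pooling_is_error(self):
        # one annotated hit: every expected count < 1, everything pools
        with pytest.raises(DegenerateDesignError):
            compare_category_profiles({"g1": "K"}, {"K": 0.5, "E": 0.5})

    def test_all_unassigned_is_error(self):
        with pytest.raises(InsufficientAnnotationError):
            compare_category_profiles({"g1": UNASSIGNED}, {"K": 1.0})

    def test_background_must_sum_to_one(self):
        with pytest.raises(ValueError):
            compare_category_profiles({"g1": "K"}, {"K": 0.7, "E": 0.2})
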