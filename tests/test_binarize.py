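"""Tertile binarization, tie handling, and predatory breadth."""

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
    PhenotypePanel,
    binarize_panel,
    binarize_prey,
    predatory_breadth,
)
from predgwas.errors import InsufficientDataError


def _series(values):
    return pd.Series(values, index=[f"s{i}" for i in range(len(values))], dtype=float)


def _counts(labels):
    return (
        int((labels == SUPERIOR).sum()),
        int((labels == INFERIOR).sum()),
        int((labels == MODERATE).sum()),
    )


class TestBinarizePrey:
    @pytest.mark.parametrize(
        "n, expected",
        [(29, (9, 9, 11)), (28, (9, 9, 10)), (6, (2, 2, 2)), (3, (1, 1, 1))],
    )
    def test_distinct_values_split_into_tertiles(self, n, expected):
        labels = binarize_prey(_series(np.arange(n)))
        assert _counts(labels) == expected

    def test_largest_values_are_superior(self):
        values = _series([5.0, 1.0, 3.0, 9.0, 7.0, 2.0])
        labels = binarize_prey(values)
        assert set(values[labels == SUPERIOR]) == {9.0, 7.0}
        assert set(values[labels == INFERIOR]) == {1.0, 2.0}

    def test_all_equal_values_are_all_moderate_under_demotion(self):
        labels = binarize_prey(_series([4.0] * 6))
        assert _counts(labels) == (0, 0, 6)

    def test_boundary_tie_demotes_whole_block(self):
        # k=2; the 2nd largest (8) ties with an excluded strain -> both demoted
        labels = binarize_prey(_series([9.0, 8.0, 8.0, 3.0, 2.0, 1.0]))
        assert _counts(labels) == (1, 2, 3)
        assert labels["s0"] == SUPERIOR

    def test_boundary_tie_expands_group_under_expand(self):
        labels = binarize_prey(
            _series([9.0, 8.0, 8.0, 3.0, 2.0, 1.0]), tie_rule="expand"
        )
        assert _counts(labels) == (3, 2, 1)

    def test_expand_overlap_collapses_to_moderate(self):
        labels = binarize_prey(_series([4.0] * 6), tie_rule="expand")
        assert _counts(labels) == (0, 0, 6)

    def test_missing_values_stay_missing(self):
        values = _series([1.0, 2.0, 3.0, 4.0])
        values["s1"] = np.nan
        labels = binarize_prey(values)
        assert pd.isna(labels["s1"])
        assert _counts(labels) == (1, 1, 1)

    def test_fewer_than_three_scored_strains_rejected(self):
        with pytest.raises(InsufficientDataError):
            binarize_prey(_series([1.0, 2.0]))

    @pytest.mark.parametrize("fraction", [0.0, 0.6, -0.1])
    def test_invalid_fraction_rejected(self, fraction):
        with pytest.raises(ValueError):
            binarize_prey(_series([1.0, 2.0, 3.0]), fraction=fraction)

    @given(
        values=st.lists(
            st.floats(0, 1000, allow_nan=False), min_size=3, max_size=40, unique=True
        ),
        seed=st.integers(0, 2**16),
    )
    def test_permutation_invariance(self, values, seed):
        series = _series(values)
        rng = np.random.default_rng(seed)
        shuffled = series.sample(frac=1.0, random_state=rng)
        original = binarize_prey(series)
        assert binarize_prey(shuffled).sort_index().equals(original.sort_index())

    @given(
        values=st.lists(
            st.floats(0, 1000, allow_nan=False), min_size=3, max_size=40, unique=True
        )
    )
    def test_distinct_value_group_sizes_are_exact(self, values):
        n = len(values)
        k = math.floor(n / 3)
        assert _counts(binarize_prey(_series(values))) == (k, k, n - 2 * k)

    @given(
        values=st.lists(
            st.floats(0, 100, allow_nan=False), min_size=5, max_size=25, unique=True
        ),
        bump=st.floats(0.001, 1000, allow_nan=False),
    )
    def test_raising_a_superior_strain_keeps_it_superior(self, values, bump):
        series = _series(values)
        labels = binarize_prey(series)
        superior = labels[labels == SUPERIOR].index
        target = superior[0]
        raised = series.copy()
        raised[target] = raised[target] + bump
        if raised[target] in set(raised.drop(target)):
            return  # bump created a tie; monotonicity holds ties aside
        assert binarize_prey(raised)[target] == SUPERIOR


class TestBinarizePanel:
    def test_columns_binarized_independently(self, tiny_panel):
        labels = binarize_panel(tiny_panel)
        assert _counts(labels.label["preyX"]) == (2, 2, 2)
        # preyY has one missing assay -> n=5, k=1
        assert _counts(labels.label["preyY"]) == (1, 1, 3)
        assert pd.isna(labels.label.at["s2", "preyY"])

    def test_identical_prey_columns_get_identical_labels(self):
        zone = pd.DataFrame(
            {"p1": [1.0, 5.0, 3.0, 9.0, 2.0, 7.0]},
            index=[f"s{i}" for i in range(6)],
        )
        zone["p2"] = zone["p1"]
        labels = binarize_panel(PhenotypePanel(zone))
        assert labels.label["p1"].equals(labels.label["p2"])

    def test_29_strain_panel_gives_9_9_11(self):
        zone = pd.DataFrame(
            {"prey": np.arange(29, dtype=float)},
            index=[f"s{i}" for i in range(29)],
        )
        labels = binarize_panel(PhenotypePanel(zone))
        assert labels.counts("prey") == {
            "superior": 9, "inferior": 9, "moderate": 11,
        }

    def test_skip_insufficient_leaves_prey_unlabelled(self):
        zone = pd.DataFrame(
            {
                "ok": [1.0, 2.0, 3.0, 4.0],
                "sparse": [1.0, np.nan, np.nan, np.nan],
            },
            index=[f"s{i}" for i in range(4)],
        )
        panel = PhenotypePanel(zone)
        with pytest.raises(InsufficientDataError):
            binarize_panel(panel)
        labels = binarize_panel(panel, skip_insufficient=True)
        assert labels.label["sparse"].isna().all()
        assert _counts(labels.label["ok"]) == (1, 1, 2)


class TestPredatoryBreadth:
    def test_counts_superior_labels_per_strain(self):
        label = pd.DataFrame(
            {
                "p1": [SUPERIOR, INFERIOR, MODERATE],
                "p2": [SUPERIOR, SUPERIOR, MODERATE],
                "p3": [SUPERIOR, MODERATE, np.nan],
            },
            index=["s1", "s2", "s3"],
        )
        table = predatory_breadth(BinaryLabelTable(label))
        by_strain = dict(zip(table["strain_id"], table["n_superior"]))
        assert by_strain == {"s1": 3, "s2": 1, "s3": 0}
        assert (table["n_prey"] == 3).all()
        assert table["strain_id"].tolist() == ["s1", "s2", "s3"]  # sorted by breadth

    def test_full_breadth_strain_scores_panel_size(self):
        label = pd.DataFrame(
            {f"p{i}": [SUPERIOR, INFERIOR] for i in range(10)},
            index=["broad", "narrow"],
        )
        table = predatory_breadth(BinaryLabelTable(label))
        top = table.iloc[0]
        assert (top["strain_id"], top["n_superior"], top["n_prey"]) == ("broad", 10, 10)
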