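"""SC identification, type classification and clustering analytics."""

import numpy as np
import pandas as pd
import pytest

import softcorona as sc
from softcorona.clustering import _control_stats, best_dendrogram_cut
from softcorona.errors import ConfigurationError, InsufficientDataError, InvalidInputError


def make_matrix(copies, roles=None):
    """CoronaMatrix straight from a copies array (Mw 5e4 Da everywhere)."""
    copies = np.asarray(copies, dtype=float)
    n, k = copies.shape
    if roles is None:
        roles = ["control"] * (k - 1) + ["captured"]
    mw = np.full(n, 5e4)
    masses = copies * mw[:, None] / sc.AVOGADRO
    return sc.CoronaMatrix(
        proteins=[f"P{i}" for i in range(n)],
        samples=[f"S{j}" for j in range(k)],
        roles=roles,
        copies=copies,
        masses=masses,
        mw=mw,
        m_total=masses.sum(axis=0),
    )


class TestTransformAndScale:
    def test_constant_row_zeroed_and_flagged(self):
        m = make_matrix([[4, 4, 4, 4, 4], [0, 0, 0, 0, 4]])
        z, flags = sc.transform_and_scale(m)
        assert np.all(z[0] == 0)
        assert flags.tolist() == [True, False]

    def test_hand_example(self):
        # sqrt -> [0,0,0,0,2]; mean 0.4, sd(ddof=1) ~0.894
        m = make_matrix([[0, 0, 0, 0, 4]])
        z, _ = sc.transform_and_scale(m)
        np.testing.assert_allclose(
            z[0], [-0.4472, -0.4472, -0.4472, -0.4472, 1.7889], atol=1e-4
        )

    def test_rows_are_zscores(self, corona_matrix):
        z, flags = sc.transform_and_scale(corona_matrix)
        live = ~flags
        np.testing.assert_allclose(z[live].mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z[live].std(axis=1, ddof=1), 1, rtol=1e-12)

    def test_single_sample_rejected(self):
        m = make_matrix([[4.0]], roles=["captured"])
        with pytest.raises(InsufficientDataError):
            sc.transform_and_scale(m)


class TestHierarchicalTwoWay:
    def test_two_rows_merge_at_their_distance(self):
        z = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 0.0]])
        res = sc.hierarchical_two_way(z)
        assert res.row_linkage.shape == (1, 4)
        assert res.row_linkage[0, 2] == pytest.approx(1.0)

    def test_planted_groups_merge_first(self):
        # two tight pairs far apart: first two merges stay within groups
        z = np.array([[0, 0], [0.01, 0], [10, 10], [10.01, 10]], dtype=float)
        res = sc.hierarchical_two_way(z)
        first_two = {frozenset(map(int, row[:2])) for row in res.row_linkage[:2]}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_nan_rejected(self):
        with pytest.raises(InvalidInputError):
            sc.hierarchical_two_way(np.array([[0.0, np.nan], [1.0, 0.0]]))

    def test_captured_outlier_joins_column_tree_last(self, corona_matrix):
        """SC enrichment dominates between-sample variance, so the captured
        column is the last leaf to join the column dendrogram."""
        z, _ = sc.transform_and_scale(corona_matrix)
        res = sc.hierarchical_two_way(z)
        last_merge = res.column_linkage[-1]
        # one side of the final merge must be the captured singleton
        assert corona_matrix.captured_index in last_merge[:2]

    def test_determinism(self, corona_matrix):
        z, _ = sc.transform_and_scale(corona_matrix)
        a = sc.hierarchical_two_way(z)
        b = sc.hierarchical_two_way(z)
        np.testing.assert_array_equal(a.row_linkage, b.row_linkage)
        np.testing.assert_array_equal(a.row_order, b.row_order)


class TestIdentifyScCluster:
    def test_enriched_consistent_controls(self):
        m = make_matrix([[10, 11, 9, 10, 25]])
        assert sc.identify_sc_cluster(m, 1.5, 0.5) == {"P0"}

    def test_inconsistent_controls_rejected_despite_enrichment(self):
        m = make_matrix([[10, 2, 15, 8, 25]])
        assert sc.identify_sc_cluster(m, 1.5, 0.5) == set()

    def test_all_zero_controls_positive_capture_is_new(self):
        m = make_matrix([[0, 0, 0, 0, 7]])
        assert sc.identify_sc_cluster(m) == {"P0"}
        cls = sc.classify_sc_types(m, {"P0"})
        assert cls.loc["P0", "sc_type"] == "new"

    def test_control_cv_uses_sample_sd(self):
        _, _, cv = _control_stats(make_matrix([[10, 11, 9, 10, 25]]))
        assert cv[0] == pytest.approx(0.0816, abs=1e-3)

    def test_monotone_in_enrichment_factor(self, corona_matrix):
        """Raising the enrichment factor never grows the SC set."""
        previous = None
        for f in (1.0, 1.5, 2.0, 3.0, 5.0):
            current = sc.identify_sc_cluster(corona_matrix, f, 0.5)
            if previous is not None:
                assert current <= previous
            previous = current

    def test_no_captured_column_rejected(self):
        m = make_matrix([[1, 2, 3]], roles=["control"] * 3)
        with pytest.raises(ConfigurationError):
            sc.identify_sc_cluster(m)


class TestClassifyScTypes:
    @pytest.mark.parametrize(
        "controls, captured, expected",
        [
            ([20, 20, 20, 20], 25, "type1"),  # hard 20, soft 5 -> ratio 4
            ([10, 10, 10, 10], 40, "type3"),  # soft 30 -> ratio 3
            ([10, 10, 10, 10], 18, "type2"),  # ratios 1.25 / 0.8
            ([0, 0, 0, 0], 7, "new"),
        ],
    )
    def test_rule_arithmetic(self, controls, captured, expected):
        m = make_matrix([controls + [captured]])
        cls = sc.classify_sc_types(m, {"P0"})
        assert cls.loc["P0", "sc_type"] == expected

    def test_soft_copies_floored_at_zero(self):
        m = make_matrix([[10, 10, 10, 10, 4]])
        cls = sc.classify_sc_types(m, set())
        assert cls.loc["P0", "soft_copies"] == 0.0

    def test_non_sc_marked_not_applicable(self):
        m = make_matrix([[10, 10, 10, 10, 40]])
        cls = sc.classify_sc_types(m, set())
        assert cls.loc["P0", "cluster"] == "HC"
        assert cls.loc["P0", "sc_type"] == "not_applicable"

    def test_recovers_planted_types(self, corona_exp, corona_matrix):
        truth = corona_exp.truth
        planted = set(truth.index[truth.is_sc])
        cls = sc.classify_sc_types(corona_matrix, planted)
        assert (
            cls.loc[sorted(planted), "sc_type"]
            == truth.loc[sorted(planted), "sc_type"]
        ).all()


class TestFoldIncrease:
    def test_ratio_new_and_undefined(self):
        m = make_matrix([[10, 10, 10, 10, 57], [0, 0, 0, 0, 3], [0, 0, 0, 0, 0],
                         [8, 8, 8, 8, 8]])
        fold = sc.fold_increase(m)
        assert fold["P0"] == pytest.approx(5.7)
        assert fold["P1"] == "New"
        assert np.isnan(fold["P2"])
        assert fold["P3"] == pytest.approx(1.0)


class TestCompositionSummary:
    def test_all_hc_means_zero_sc_share(self):
        m = make_matrix([[10, 10, 10, 10, 10], [5, 5, 5, 5, 5]])
        cls = sc.classify_sc_types(m, set())
        out = sc.composition_summary(m, cls)
        assert out["totals"].loc["SC", "captured"] == 0.0

    def test_percentages_sum_to_100(self, corona_matrix):
        cls = sc.classify_sc_types(
            corona_matrix, sc.identify_sc_cluster(corona_matrix)
        )
        out = sc.composition_summary(corona_matrix, cls)
        np.testing.assert_allclose(
            out["percentages"].sum(axis=0), [100.0, 100.0], rtol=1e-9
        )

    def test_planted_sc_doubling_on_capture(self):
        """SC proteins with captured = 2x hard double the SC-cluster total."""
        copies = np.array(
            [[10, 10, 10, 10, 10], [6, 6, 6, 6, 12], [4, 4, 4, 4, 8]],
            dtype=float,
        )
        m = make_matrix(copies)
        sc_set = {"P1", "P2"}
        out = sc.composition_summary(m, sc.classify_sc_types(m, sc_set))
        totals = out["totals"]
        assert totals.loc["SC", "captured"] / totals.loc["SC", "control"] == (
            pytest.approx(2.0)
        )


class TestDendrogramCut:
    def test_cut_matches_clean_partition(self):
        copies = np.vstack(
            [
                np.tile([10, 10, 10, 10, 10.5], (5, 1)) * np.arange(1, 6)[:, None],
                np.tile([2, 2, 2, 2, 20], (3, 1)) * np.arange(1, 4)[:, None],
            ]
        )
        m = make_matrix(copies)
        z, _ = sc.transform_and_scale(m)
        res = sc.hierarchical_two_way(z)
        sc_set = sc.identify_sc_cluster(m)
        assert sc_set == {"P5", "P6", "P7"}
        cut = best_dendrogram_cut(res, m.proteins, sc_set)
        assert cut["jaccard"] == 1.0
        assert cut["members"] == sc_set
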