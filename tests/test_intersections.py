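"""Harmonic-mean intersections, category enrichment, Venn partitions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from multimorbid import (
    CATEGORIES,
    CategoryMapping,
    DataError,
    EmptyProfileError,
    GlobalBaseline,
    build_intersection,
    category_percentages,
    global_baseline,
    harmonic_mean,
    high_importance,
    overlap_partition,
    permutation_z,
    z_enrichment,
)
from multimorbid.ontology import categorize_table
from conftest import make_table

unit = st.floats(0, 1, allow_nan=False)


class TestHarmonicMean:
    @pytest.mark.parametrize(
        "h1,h2,expected",
        [(0.6, 0.6, 0.6), (0.0, 0.9, 0.0), (0.4, 0.8, 2 / (1 / 0.4 + 1 / 0.8))],
    )
    def test_worked_values(self, h1, h2, expected):
        assert harmonic_mean(h1, h2) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(DataError):
            harmonic_mean(1.2, 0.5)
        with pytest.raises(DataError):
            harmonic_mean(0.5, -0.1)

    @given(unit, unit)
    @settings(max_examples=200, derandomize=True)
    def test_bounded_by_min_and_arithmetic_mean(self, h1, h2):
        hm = harmonic_mean(h1, h2)
        assert min(h1, h2) - 1e-12 <= hm <= (h1 + h2) / 2 + 1e-12
        if abs(h1 - h2) > 1e-9 and min(h1, h2) > 0:
            assert hm < (h1 + h2) / 2


def two_tables(scores_a, scores_b):
    cats = {n: CATEGORIES[i % 13] for i, n in enumerate(set(scores_a) | set(scores_b))}
    mapping = CategoryMapping(cats)
    ta = make_table("AD", scores_a, normalize=False)
    tb = make_table("ALS", scores_b, normalize=False)
    for t in (ta, tb):
        t.frame["percentile"] = t.frame["raw_score"]
    return ta, tb, mapping


class TestBuildIntersection:
    def test_disjoint_tables_empty_profile(self):
        ta, tb, mapping = two_tables({"a": 0.5}, {"b": 0.5})
        prof = build_intersection(ta, tb, mapping)
        assert prof.n_members == 0
        assert prof.category_counts.sum() == 0
        assert prof.category_percentages is None

    def test_threshold_boundary_inclusive(self):
        ta, tb, mapping = two_tables({"x": 0.5}, {"x": 0.5})
        prof = build_intersection(ta, tb, mapping, threshold=0.5)
        assert prof.n_members == 1

    def test_members_match_exhaustive_hm_evaluation(self):
        pairs = {
            "n1": (0.9, 0.9),
            "n2": (0.8, 0.2),
            "n3": (0.6, 0.7),
            "n4": (0.5, 0.5),
            "n5": (0.45, 0.55),
            "n6": (1.0, 0.3),
        }
        ta, tb, mapping = two_tables(
            {n: v[0] for n, v in pairs.items()}, {n: v[1] for n, v in pairs.items()}
        )
        prof = build_intersection(ta, tb, mapping, threshold=0.5)
        expected = {n for n, (a, b) in pairs.items() if harmonic_mean(a, b) >= 0.5}
        assert set(prof.members["node_id"]) == expected
        assert expected == {"n1", "n3", "n4"}  # brute-force check frozen

    def test_unnormalized_scores_rejected(self):
        ta, tb, mapping = two_tables({"x": 0.5}, {"x": 0.5})
        ta.frame["percentile"] = [1.5]
        with pytest.raises(DataError, match="unit interval"):
            build_intersection(ta, tb, mapping)

    def test_raising_threshold_never_adds_members(self):
        rng = np.random.default_rng(5)
        ids = [f"n{i}" for i in range(60)]
        ta, tb, mapping = two_tables(
            {n: s for n, s in zip(ids, rng.random(60))},
            {n: s for n, s in zip(ids, rng.random(60))},
        )
        sizes = [
            build_intersection(ta, tb, mapping, threshold=thr).n_members
            for thr in (0.2, 0.4, 0.6, 0.8, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestCategoryPercentages:
    def test_two_equal_categories(self):
        counts = pd.Series([2, 2] + [0] * 11, index=list(CATEGORIES))
        pct = category_percentages(counts)
        assert pct.iloc[0] == pct.iloc[1] == 50
        assert pct.sum() == pytest.approx(100, abs=1e-9)

    def test_single_category_is_hundred(self):
        counts = pd.Series([0, 7] + [0] * 11, index=list(CATEGORIES))
        assert category_percentages(counts).iloc[1] == 100

    def test_direct_arithmetic(self):
        counts = pd.Series([3, 2, 1] + [0] * 10, index=list(CATEGORIES))
        pct = category_percentages(counts)
        assert pct.iloc[:3].tolist() == pytest.approx([50, 100 / 3, 100 / 6])

    def test_all_zero_counts_signal_empty_profile(self):
        counts = pd.Series(0, index=list(CATEGORIES))
        with pytest.raises(EmptyProfileError):
            category_percentages(counts)


class TestZEnrichment:
    def baseline(self, props):
        p = pd.Series(props, index=list(CATEGORIES)[: len(props)]).reindex(
            list(CATEGORIES), fill_value=0.0
        )
        return GlobalBaseline(p / p.sum(), 100)

    def test_proportional_counts_give_zero(self):
        base = self.baseline([0.5, 0.3, 0.2])
        counts = (base.proportions * 20).astype(int)
        z = z_enrichment(counts, base)
        finite = base.proportions > 0
        assert np.allclose(z[finite], 0.0, atol=1e-9)

    @pytest.mark.parametrize("k,expected_sign", [(5, 1), (0, -1)])
    def test_binomial_formula_worked_value(self, k, expected_sign):
        base = self.baseline([0.25, 0.75])
        counts = pd.Series(0, index=list(CATEGORIES))
        counts.iloc[0] = k
        counts.iloc[1] = 10 - k
        z = z_enrichment(counts, base)
        expected = (k - 10 * 0.25) / np.sqrt(10 * 0.25 * 0.75)
        assert z.iloc[0] == pytest.approx(expected)
        assert np.sign(z.iloc[0]) == expected_sign
        assert abs(z.iloc[0]) == pytest.approx(1.8257, abs=1e-4)

    def test_zero_baseline_with_positive_count_flagged_infinite(self, caplog):
        base = self.baseline([1.0])
        counts = pd.Series(0, index=list(CATEGORIES))
        counts.iloc[1] = 3
        counts.iloc[0] = 7
        with caplog.at_level("WARNING"):
            z = z_enrichment(counts, base)
        assert np.isposinf(z.iloc[1])
        assert np.isneginf(z.iloc[0])  # p0 = 1 but k < n

    def test_weighted_numerators_sum_to_zero_against_own_pooled_baseline(self):
        rng = np.random.default_rng(8)
        counts = pd.Series(rng.integers(0, 30, 13), index=list(CATEGORIES))
        n = counts.sum()
        base = GlobalBaseline(counts / n, int(n))
        numerators = counts - n * base.proportions
        assert numerators.sum() == pytest.approx(0, abs=1e-9)
        z = z_enrichment(counts, base)
        assert np.allclose(z[base.proportions.between(0, 1, inclusive="neither")], 0, atol=1e-9)

    def test_permutation_null_agrees_in_sign_with_binomial(self):
        rng = np.random.default_rng(123)
        base_p = np.array([4, 3, 2, 2, 1, 1] + [0.5] * 7)
        base = GlobalBaseline(pd.Series(base_p / base_p.sum(), index=list(CATEGORIES)), 500)
        for _ in range(20):
            counts = pd.Series(
                rng.multinomial(80, np.roll(base_p, 2) / base_p.sum()), index=list(CATEGORIES)
            )
            zb = z_enrichment(counts, base)
            zp = permutation_z(counts, base, n_draws=4000, rng=rng)
            clear = np.abs(counts - counts.sum() * base.proportions) > 0.5
            assert (np.sign(zb[clear]) == np.sign(zp[clear])).all()


class TestOverlapPartition:
    def test_identical_sets(self):
        s = {"a", "b", "c", "d"}
        part = overlap_partition((s, s, s))
        assert part["AD∩ALS∩FTD"] == 4
        assert sum(part.values()) == 4

    def test_pairwise_disjoint_sets(self):
        part = overlap_partition(({"a", "b"}, {"c", "d", "e"}, {"f", "g", "h", "i"}))
        assert (part["AD only"], part["ALS only"], part["FTD only"]) == (2, 3, 4)
        assert sum(part.values()) == 9

    @pytest.mark.parametrize("seed", range(20))
    def test_regions_partition_the_union(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"n{i}" for i in range(40)]
        sets = [set(rng.choice(universe, rng.integers(0, 30))) for _ in range(3)]
        part = overlap_partition(tuple(sets))
        assert sum(part.values()) == len(set().union(*sets))
        # brute-force membership classification
        brute = {k: 0 for k in part}
        a, b, c = sets
        for n in set().union(*sets):
            key = (n in a, n in b, n in c)
            label = {
                (True, False, False): "AD only",
                (False, True, False): "ALS only",
                (False, False, True): "FTD only",
                (True, True, False): "AD∩ALS only",
                (True, False, True): "AD∩FTD only",
                (False, True, True): "ALS∩FTD only",
                (True, True, True): "AD∩ALS∩FTD",
            }[key]
            brute[label] += 1
        assert part == brute


class TestHighImportanceAndBaseline:
    def test_top_fraction_selection(self):
        scores = {f"n{i:02d}": i / 20 for i in range(20)}
        table = make_table("AD", scores)
        top = high_importance(table, 0.10)
        assert set(top.frame["node_id"]) == {"n18", "n19"}

    def test_union_baseline_counts_shared_nodes_once(self):
        cats = {"x": "Liver", "y": "Kidney", "z": "Liver"}
        mapping = CategoryMapping(cats)
        ta = categorize_table(make_table("AD", {"x": 0.9, "y": 0.5}), mapping)
        tb = categorize_table(make_table("ALS", {"x": 0.8, "z": 0.4}), mapping)
        union = global_baseline([ta, tb], mode="union")
        concat = global_baseline([ta, tb], mode="concat")
        assert union.total == 3
        assert concat.total == 4
        assert union.proportions["Liver"] == pytest.approx(2 / 3)
        assert concat.proportions["Liver"] == pytest.approx(3 / 4)
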