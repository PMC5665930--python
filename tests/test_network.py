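import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metabotyper.errors import UndefinedStatisticError, ValidationError
from metabotyper.network import (
    betweenness,
    build_network,
    centrality_tiers,
    classify_enrichment,
    compare_centrality,
    dichotomize,
    enrichment_table,
    odds_ratio,
    parse_reaction_table,
    score_topology_correlation,
    tier_enrichment,
)

from _oracles import brute_force_betweenness, brute_force_edges, random_digraph


class TestDichotomize:
    def test_median_split(self):
        assert dichotomize([1, 2, 3, 4]).tolist() == [0, 0, 1, 1]

    def test_constant_vector_all_low(self):
        assert dichotomize([5, 5, 5]).tolist() == [0, 0, 0]

    def test_alternating(self):
        assert dichotomize([5, 1, 5, 1]).tolist() == [1, 0, 1, 0]

    def test_tie_at_median_goes_low(self):
        assert dichotomize([1, 2, 2, 9]).tolist() == [0, 0, 0, 1]


class TestOddsRatio:
    def test_independence(self):
        assert odds_ratio(2, 2, 2, 2) == 1.0

    def test_arithmetic(self):
        assert odds_ratio(4, 1, 1, 4) == 16.0

    def test_haldane_correction(self):
        assert odds_ratio(5, 0, 0, 5) == pytest.approx(121.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            odds_ratio(-1, 1, 1, 1)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            odds_ratio(0, 0, 0, 0)

    def test_label_swap_inverts(self, rng):
        # swapping metabotype labels maps OR -> 1/OR, score unchanged
        for _ in range(40):
            a, b, c, d = rng.integers(0, 10, size=4)
            if a + b + c + d == 0:
                continue
            orv = odds_ratio(a, b, c, d)
            swapped = odds_ratio(b, a, d, c)
            assert swapped == pytest.approx(1.0 / orv)
            _, s1 = classify_enrichment(orv)
            _, s2 = classify_enrichment(swapped)
            assert s1 == pytest.approx(s2)


class TestClassifyEnrichment:
    @pytest.mark.parametrize(
        "orv,category",
        [
            (3.0, "enriched"),
            (2.0, "associated"),
            (1.5, "associated"),
            (1.0, "other"),
            (0.7, "other"),
            (0.5, "other"),
            (0.25, "depleted"),
        ],
    )
    def test_categories(self, orv, category):
        assert classify_enrichment(orv)[0] == category

    def test_scores(self):
        assert classify_enrichment(3.0)[1] == pytest.approx(math.log2(3))
        assert classify_enrichment(1.0)[1] == 0.0
        assert classify_enrichment(0.25)[1] == pytest.approx(2.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            classify_enrichment(0.0)

    def test_mirror_categories(self):
        assert classify_enrichment(4.0)[0] == "enriched"
        assert classify_enrichment(0.25)[0] == "depleted"


class TestEnrichmentTable:
    def test_planted_feature_is_enriched(self):
        cols = [f"s{i}" for i in range(8)]
        labels = pd.Series(["low"] * 6 + ["high"] * 2, index=cols)
        table = pd.DataFrame(
            {c: [10.0 if lab == "high" else 1.0] for c, lab in labels.items()},
            index=["enz1"],
        )
        out = enrichment_table(table, labels)
        assert out.loc["enz1", "category"] == "enriched"
        assert bool(out.loc["enz1", "associated"])


def annotation(**kwargs):
    return {k: (frozenset(v[0]), frozenset(v[1])) for k, v in kwargs.items()}


class TestBuildNetwork:
    def test_single_edge(self):
        g = build_network(annotation(A=([], ["x"]), B=(["x"], [])))
        assert list(g.edges()) == [("A", "B")]
        assert g.edges["A", "B"]["compounds"] == ["x"]

    def test_blacklisted_compound_gives_no_edge(self):
        g = build_network(annotation(A=([], ["x"]), B=(["x"], [])), blacklist={"x"})
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 2  # isolated nodes retained

    def test_chain_of_four(self):
        ann = annotation(
            E1=(["c0"], ["c1"]), E2=(["c1"], ["c2"]), E3=(["c2"], ["c3"]), E4=(["c3"], ["c4"])
        )
        g = build_network(ann)
        assert set(g.edges()) == brute_force_edges(ann)
        assert g.number_of_edges() == 3

    def test_self_loops_dropped(self):
        g = build_network(annotation(A=(["x"], ["x"])))
        assert g.number_of_edges() == 0

    def test_matches_brute_force_on_random_annotations(self, rng):
        compounds = [f"c{i}" for i in range(12)]
        for _ in range(30):
            ann = {
                f"E{i}": (
                    frozenset(rng.choice(compounds, size=rng.integers(1, 4), replace=False)),
                    frozenset(rng.choice(compounds, size=rng.integers(1, 4), replace=False)),
                )
                for i in range(8)
            }
            black = set(rng.choice(compounds, size=2, replace=False))
            g = build_network(ann, black)
            assert set(g.edges()) == brute_force_edges(ann, black)

    def test_parse_reaction_table_roundtrip(self):
        table = pd.DataFrame(
            {
                "enzyme_id": ["A", "B"],
                "substrates": ["c1;c2", "c3"],
                "products": ["c3", ""],
            }
        )
        ann = parse_reaction_table(table)
        assert ann["A"] == (frozenset({"c1", "c2"}), frozenset({"c3"}))
        assert ann["B"] == (frozenset({"c3"}), frozenset())

    def test_duplicate_enzyme_rejected(self):
        table = pd.DataFrame(
            {"enzyme_id": ["A", "A"], "substrates": ["c", "c"], "products": ["d", "d"]}
        )
        with pytest.raises(ValidationError):
            parse_reaction_table(table)


class TestBetweenness:
    def test_three_node_path(self):
        g = build_network(annotation(a=([], ["x"]), b=(["x"], ["y"]), c=(["y"], [])))
        bt = betweenness(g)
        assert bt["b"] == pytest.approx(0.5)  # 1 path / (n-1)(n-2)=2
        assert bt["a"] == bt["c"] == 0.0

    def test_isolated_node_zero(self):
        g = build_network(annotation(a=([], ["x"]), b=(["x"], []), z=([], [])))
        assert betweenness(g)["z"] == 0.0

    def test_matches_brute_force_oracle(self, rng):
        import networkx as nx

        for _ in range(40):
            nodes, edges = random_digraph(rng)
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            expected = brute_force_betweenness(nodes, edges)
            got = betweenness(g)
            for node in nodes:
                assert got[node] == pytest.approx(expected[node], abs=1e-12)


class TestCentralityTiers:
    def test_one_node_per_tier(self):
        tiers = centrality_tiers({"a": 0.0, "b": 0.1, "c": 0.9})
        assert tiers.tiers["a"] == "peripheral"
        assert tiers.tiers["b"] == "intermediate"
        assert tiers.tiers["c"] == "central"

    def test_all_equal_scores_balanced_by_id(self):
        scores = {f"e{i}": 0.5 for i in range(10)}
        tiers = centrality_tiers(scores)
        sizes = tiers.tiers.value_counts()
        assert sizes["peripheral"] == 4  # ceil(10/3)
        assert sizes["intermediate"] == 3 and sizes["central"] == 3
        assert tiers.tiers["e0"] == "peripheral"  # lexical tie-break

    def test_rank_consistent_with_sort_oracle(self, rng):
        scores = {f"e{i}": float(rng.random()) for i in range(9)}
        tiers = centrality_tiers(scores)
        ordered = sorted(scores, key=scores.get)
        assert set(tiers.members("peripheral")) == set(ordered[:3])
        assert set(tiers.members("central")) == set(ordered[6:])
        assert all(len(tiers.members(t)) == 3 for t in ("peripheral", "intermediate", "central"))

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValidationError):
            centrality_tiers({"a": 0.1, "b": 0.2})


class TestCompareCentrality:
    def test_identical_groups_of_identical_values(self):
        scores = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0})
        flags = pd.Series({"a": True, "b": True, "c": False, "d": False})
        _, p = compare_centrality(scores, flags)
        assert p == 1.0

    def test_exact_enumeration_example(self):
        scores = pd.Series({"a": 1, "b": 2, "c": 10, "d": 11, "e": 12}, dtype=float)
        flags = pd.Series({"a": True, "b": True, "c": False, "d": False, "e": False})
        w, p = compare_centrality(scores, flags)
        assert w == 3.0
        assert p == pytest.approx(0.2)  # 2 * 1/C(5,2)

    def test_empty_group_rejected(self):
        scores = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(ValidationError):
            compare_centrality(scores, pd.Series({"a": True, "b": True}))

    def test_large_sample_matches_scipy_ranksums(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(1, 1, 18)
        scores = pd.Series(np.concatenate([x, y]))
        flags = pd.Series([True] * 15 + [False] * 18)
        _, p = compare_centrality(scores, flags)
        ref = stats.ranksums(x, y)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_matches_scipy_mannwhitney_without_ties(self, rng):
        x = rng.permutation(20)[:6].astype(float)
        y = np.array([30.0, 31.0, 32.0, 33.0, 34.0])
        scores = pd.Series(np.concatenate([x, y]))
        flags = pd.Series([True] * 6 + [False] * 5)
        _, p = compare_centrality(scores, flags)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestTierEnrichment:
    def tiers_series(self):
        return pd.Series(
            ["peripheral"] * 5 + ["intermediate"] * 5 + ["central"] * 5,
            index=[f"e{i}" for i in range(15)],
        )

    def test_all_associated_in_one_tier(self):
        flags = pd.Series([True] * 5 + [False] * 10, index=[f"e{i}" for i in range(15)])
        p = tier_enrichment(self.tiers_series(), flags)
        assert p["peripheral"] == pytest.approx(1 / 3003)
        assert p["central"] == 1.0

    def test_zero_associated_in_tier_gives_one(self):
        flags = pd.Series([False] * 15, index=[f"e{i}" for i in range(15)])
        p = tier_enrichment(self.tiers_series(), flags)
        assert all(v == 1.0 for v in p.values())

    def test_proportional_spread_not_significant(self):
        flags = pd.Series(
            [True, False, False, False, False] * 3, index=[f"e{i}" for i in range(15)]
        )
        p = tier_enrichment(self.tiers_series(), flags)
        assert all(v > 0.05 for v in p.values())

    def test_inconsistent_universe_rejected(self):
        flags = pd.Series([True] * 3, index=["x", "y", "z"])
        with pytest.raises(ValidationError):
            tier_enrichment(self.tiers_series(), flags)


class TestScoreTopologyCorrelation:
    def test_increasing(self):
        rho, _ = score_topology_correlation([1, 2, 3], [10, 20, 30])
        assert rho == pytest.approx(1.0)

    def test_decreasing(self):
        rho, _ = score_topology_correlation([1, 2, 3], [30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_rank_formula_example(self):
        rho, _ = score_topology_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            score_topology_correlation([1, 1, 1], [1, 2, 3])


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_betweenness_conservation(seed):
    # sum of raw betweenness = total intermediate-node visits over shortest paths
    import networkx as nx

    rng = np.random.default_rng(seed)
    nodes, edges = random_digraph(rng, max_nodes=7)
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    expected = brute_force_betweenness(nodes, edges)
    got = betweenness(g)
    n = len(nodes)
    scale = (n - 1) * (n - 2)
    assert sum(got.values()) * scale == pytest.approx(sum(expected.values()) * scale, abs=1e-9)
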