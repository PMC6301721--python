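import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnvburden import synthetic_data as sd
from dnvburden.burden_stats import burden_frame
from dnvburden.cohort_io import CohortSpec, DeNovoVariant
from dnvburden.convergence import (
    ExpressionRanks,
    build_enrichment_map,
    expression_rank,
    hypergeom_enrichment_p,
    quartile_burden,
    set_similarity,
    target_shift_test,
    write_enrichment_map,
)


def matrix_from(values: dict[str, list[float]], samples=None) -> pd.DataFrame:
    df = pd.DataFrame(values).T
    df.columns = samples or [f"S{i}" for i in range(df.shape[1])]
    return df


class TestExpressionRank:
    def test_highest_expression_gets_smallest_percentile(self):
        m = matrix_from({"hi": [9.0, 9.0], "mid": [5.0, 5.0], "lo": [1.0, 1.0]})
        ranks = expression_rank(m)
        assert ranks.percentiles["hi"] < ranks.percentiles["mid"] < ranks.percentiles["lo"]
        assert ranks.percentiles["hi"] == pytest.approx(1 / 3)
        assert ranks.percentiles["lo"] == pytest.approx(1.0)

    def test_ortholog_max_rule(self):
        # a query gene mapping to source genes expressed at 3.0 and 7.5 is
        # ranked using 7.5
        m = matrix_from({"mA": [3.0], "mB": [7.5], "mC": [5.0]})
        ranks = expression_rank(m, ortholog_map={"HUM1": ["mA", "mB"], "HUM2": ["mC"]})
        assert ranks.percentiles["HUM1"] < ranks.percentiles["HUM2"]

    def test_unmapped_genes_tallied(self):
        m = matrix_from({"mA": [3.0]})
        ranks = expression_rank(m, ortholog_map={"H1": ["mA"], "H2": ["missing"]})
        assert ranks.n_unmapped == 1
        assert "H2" not in ranks.percentiles

    def test_all_equal_share_one_percentile(self):
        m = matrix_from({f"g{i}": [2.0] for i in range(8)})
        ranks = expression_rank(m)
        values = set(ranks.percentiles.values())
        assert values == {1 / 8}
        # tie rule: everything lands in the top quartile
        assert {ranks.quartile(f"g{i}") for i in range(8)} == {"Q1"}

    def test_tie_handling_matches_direct_sort(self):
        expr = {"a": 5.0, "b": 5.0, "c": 3.0, "d": 1.0}
        m = matrix_from({k: [v] for k, v in expr.items()})
        ranks = expression_rank(m)
        # direct sort oracle with min-rank for ties
        ordered = sorted(expr, key=lambda g: -expr[g])
        expected = {}
        for i, g in enumerate(ordered):
            same = [h for h in ordered if expr[h] == expr[g]]
            expected[g] = (min(ordered.index(h) for h in same) + 1) / len(ordered)
        assert ranks.percentiles == pytest.approx(expected)

    @given(st.lists(st.integers(1, 10_000), min_size=4, max_size=20, unique=True))
    @settings(max_examples=40, deadline=None)
    def test_invariant_to_monotone_transform(self, ints):
        # well-separated values: the invariant concerns order, not float
        # round-off collapsing near-ties under the transform
        values = [v / 7.0 for v in ints]
        genes = [f"g{i}" for i in range(len(values))]
        m1 = matrix_from({g: [v] for g, v in zip(genes, values)})
        m2 = matrix_from({g: [math.log(v) * 3 + 1] for g, v in zip(genes, values)})
        assert expression_rank(m1).percentiles == pytest.approx(
            expression_rank(m2).percentiles)

    def test_unranked_quartile(self):
        ranks = ExpressionRanks(percentiles={"a": 0.1})
        assert ranks.quartile("nope") == "unranked"


def make_variant(gene, consequence="nonsense", proband="P1", pos=50):
    return DeNovoVariant(chrom="chr1", pos=pos, ref_allele="A", alt_allele="T",
                         proband_id=proband, gene=gene, consequence=consequence,
                         cadd_phred=30.0, trinucleotide_context="CAT")


class TestQuartileBurden:
    def test_spiked_top_quartile(self, small_exome, small_catalog, small_rates):
        genes = sorted(small_rates)
        # top quartile by construction: first quarter of genes
        n = len(genes)
        pct = {g: (i + 1) / n for i, g in enumerate(genes)}
        ranks = ExpressionRanks(percentiles=pct)
        top = [g for g in genes if ranks.quartile(g) == "Q1"]
        cfg = sd.GeneratorConfig(seed=31, n_genes=40, cds_len_mean=600,
                                 n_trios=800, frac_two_exon=0.4, frac_chrx=0.1,
                                 risk_genes=tuple(top), relative_risk=8.0)
        variants, cohort, _ = sd.spike_risk(small_catalog, cfg)
        results, _ = quartile_burden(variants, ranks, small_rates, cohort,
                                     classes=("LGD",), strata=["all"])
        folds = {r.gene_set: r.fold for r in results}
        assert folds["Q1"] > max(v for k, v in folds.items() if k != "Q1")

    def test_null_quartiles_near_one(self, small_catalog, small_cfg, small_rates):
        genes = sorted(small_rates)
        pct = {g: (i + 1) / len(genes) for i, g in enumerate(genes)}
        ranks = ExpressionRanks(percentiles=pct)
        variants, cohort, _ = sd.gen_null_cohort(small_catalog, small_cfg)
        results, _ = quartile_burden(variants, ranks, small_rates, cohort,
                                     classes=("missense",), strata=["all"])
        for r in results:
            if r.expected > 5:
                assert abs(r.fold - 1) < 0.8

    def test_unranked_cell_not_dropped(self, small_catalog, small_cfg, small_rates):
        genes = sorted(small_rates)
        pct = {g: (i + 1) / len(genes) for i, g in enumerate(genes[:-4])}
        ranks = ExpressionRanks(percentiles=pct)
        variants, cohort, _ = sd.gen_null_cohort(small_catalog, small_cfg)
        results, _ = quartile_burden(variants, ranks, small_rates, cohort,
                                     classes=("missense",), strata=["all"])
        assert any(r.gene_set == "unranked" for r in results)

    def test_tiny_exome_empty_quartile(self, small_rates):
        # 3 ranked genes leave Q1 empty; remaining cells still computed
        genes = sorted(small_rates)[:3]
        rates3 = {g: small_rates[g] for g in genes}
        ranks = ExpressionRanks(percentiles={g: (i + 1) / 3 for i, g in enumerate(genes)})
        cohort = CohortSpec(4, 2, 2, {f"P{i}": ("M" if i < 2 else "F", "isolated")
                                      for i in range(4)})
        results, _ = quartile_burden([], ranks, rates3, cohort,
                                     classes=("missense",), strata=["all"])
        cells = {r.gene_set for r in results}
        assert "Q1" not in cells  # no rated genes -> no cell to report
        assert {"Q2", "Q3", "Q4"} <= cells


class TestTargetShift:
    def test_direction_and_power_under_shift(self):
        hits = 0
        for rep in range(40):
            cfg = sd.GeneratorConfig(seed=1000 + rep, expression_shift=-0.8)
            genes = [f"g{i}" for i in range(300)]
            matrix, _ = sd.gen_expression(cfg, genes, n_samples=30,
                                          carriers=["S001", "S002", "S003"],
                                          target_genes=genes[:60])
            res = target_shift_test(matrix, ["S001", "S002", "S003"], genes[:60])
            if res.direction < 0 and res.p_value < 0.01:
                hits += 1
        assert hits >= 36  # >=90% of replicates

    def test_null_calibration(self):
        ps = []
        for rep in range(120):
            cfg = sd.GeneratorConfig(seed=2000 + rep, expression_shift=0.0)
            genes = [f"g{i}" for i in range(200)]
            matrix, _ = sd.gen_expression(cfg, genes, n_samples=24,
                                          carriers=["S001", "S002"],
                                          target_genes=genes[:40])
            ps.append(target_shift_test(matrix, ["S001", "S002"], genes[:40]).p_value)
        ps = np.asarray(ps)
        # uniform p under the null: mean near 0.5, no excess of small values
        assert abs(ps.mean() - 0.5) < 0.12
        assert (ps < 0.05).mean() < 0.12

    def test_ks_statistic_matches_brute_force(self, rng):
        a = rng.normal(size=37)
        b = rng.normal(0.4, 1.0, size=53)
        genes = [f"t{i}" for i in range(len(a))] + [f"b{i}" for i in range(len(b))]
        # build a matrix in which carrier mean-z reduces to the raw values
        values = np.concatenate([a, b])
        matrix = pd.DataFrame({
            "S1": values, "S2": -values, "S3": 2 * values, "S4": -2 * values,
        }, index=genes)
        res = target_shift_test(matrix, ["S1"], [f"t{i}" for i in range(len(a))])
        mu, sdev = matrix.mean(axis=1), matrix.std(axis=1, ddof=1)
        z1 = ((matrix["S1"] - mu) / sdev).to_numpy()
        za, zb = z1[:len(a)], z1[len(a):]
        # brute-force two-sample KS: max ECDF gap over all pooled points
        pooled = np.concatenate([za, zb])
        gap = max(abs((za <= x).mean() - (zb <= x).mean()) for x in pooled)
        assert res.ks_statistic == pytest.approx(gap, rel=1e-12)

    def test_constant_genes_excluded(self):
        matrix = pd.DataFrame({"S1": [1.0, 5.0, 2.0], "S2": [1.0, 6.0, 3.0],
                               "S3": [1.0, 7.0, 4.0]}, index=["const", "a", "b"])
        res = target_shift_test(matrix, ["S1"], ["a"])
        assert res.n_excluded_constant == 1

    def test_errors(self):
        matrix = pd.DataFrame({"S1": [1.0, 2.0], "S2": [2.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="carrier"):
            target_shift_test(matrix, ["S9"], ["a"])
        with pytest.raises(ValueError, match="target"):
            target_shift_test(matrix, ["S1"], ["zz"])


class TestSimilarity:
    def test_worked_example(self):
        a = {"g1", "g2", "g3", "g4"}
        b = {"g3", "g4", "g5", "g6"}
        # Jaccard 2/6, overlap 2/4 -> mean 0.41667
        assert set_similarity(a, b) == pytest.approx((2 / 6 + 2 / 4) / 2)
        assert set_similarity(a, b) == pytest.approx(0.41667, abs=5e-6)

    def test_bounds(self):
        a = {"x", "y"}
        assert set_similarity(a, set(a)) == 1.0
        assert set_similarity(a, {"p", "q"}) == 0.0

    @given(st.sets(st.integers(0, 30), min_size=1, max_size=15),
           st.sets(st.integers(0, 30), min_size=1, max_size=15))
    @settings(max_examples=80, deadline=None)
    def test_jaccard_never_exceeds_overlap(self, a, b):
        inter = len(a & b)
        if inter == 0:
            assert set_similarity(a, b) == 0.0
            return
        jaccard = inter / len(a | b)
        overlap = inter / min(len(a), len(b))
        assert jaccard <= overlap
        assert jaccard <= set_similarity(a, b) <= overlap


class TestEnrichmentMap:
    def test_hypergeom_matches_direct_summation(self):
        # query of 10 with 5 hits in a 20-gene set over a 1000-gene universe
        p = hypergeom_enrichment_p(5, 20, 10, 1000)
        direct = sum(
            math.comb(20, k) * math.comb(980, 10 - k) / math.comb(1000, 10)
            for k in range(5, 11)
        )
        assert p == pytest.approx(direct, rel=1e-10)

    def test_zero_hits_p_is_one(self):
        assert hypergeom_enrichment_p(0, 20, 10, 1000) == 1.0

    @staticmethod
    def _toy_inputs(seed=0):
        rng = np.random.default_rng(seed)
        universe = [f"u{i}" for i in range(800)]
        enriched_pool = universe[:120]
        query = universe[:40]
        sets = {}
        for i in range(8):  # enriched sets drawn from the pool
            members = rng.choice(enriched_pool, size=60, replace=False)
            sets[f"hit{i}"] = set(members) | set(query[:15])
        for i in range(12):  # background sets
            sets[f"bg{i}"] = set(rng.choice(universe, size=80, replace=False))
        sets["too_small"] = set(universe[:10])
        sets["too_big"] = set(universe)
        return query, sets, universe

    def test_size_band_and_fdr(self):
        query, sets, universe = self._toy_inputs()
        graph = build_enrichment_map(query, sets, universe, fdr=0.1,
                                     size_band=(25, 750), sim_cutoff=0.3)
        assert "too_small" not in graph and "too_big" not in graph
        for _, data in graph.nodes(data=True):
            assert 25 <= data["size"] <= 750
            assert data["q_value"] < 0.1

    def test_node_set_invariant_to_read_order(self):
        query, sets, universe = self._toy_inputs()
        graph1 = build_enrichment_map(query, sets, universe)
        reordered = dict(reversed(list(sets.items())))
        graph2 = build_enrichment_map(query, reordered, universe)
        assert set(graph1.nodes) == set(graph2.nodes)
        assert set(map(frozenset, graph1.edges)) == set(map(frozenset, graph2.edges))

    def test_edges_score_band(self):
        query, sets, universe = self._toy_inputs()
        graph = build_enrichment_map(query, sets, universe, sim_cutoff=0.25)
        for _, _, data in graph.edges(data=True):
            assert 0.25 <= data["similarity"] <= 1.0

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="ALIEN"):
            build_enrichment_map(["ALIEN"], {"s": {"a"}}, ["a", "b"])

    def test_graphml_and_edge_list_roundtrip(self, tmp_path):
        query, sets, universe = self._toy_inputs()
        graph = build_enrichment_map(query, sets, universe, sim_cutoff=0.25)
        gml = tmp_path / "map.graphml"
        edges = tmp_path / "edges.tsv"
        write_enrichment_map(graph, gml, edges)
        back = nx.read_graphml(gml)
        assert set(back.nodes) == set(graph.nodes)
        edge_df = pd.read_csv(edges, sep="\t")
        assert len(edge_df) == graph.number_of_edges()
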