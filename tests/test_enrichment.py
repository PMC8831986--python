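"""Hypergeometric enrichment, information-content similarity, edge overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from cofitnet.enrichment import (
    OntologyDAG,
    compare_edge_similarity,
    edge_overlap,
    gene_pair_semantic_similarity,
    hypergeom_enrichment,
    module_enrichment_table,
    term_information_content,
)


def _pair(a, b):
    return frozenset((a, b))


class TestHypergeometric:
    def test_zero_overlap_is_certain(self):
        u = {f"g{i}" for i in range(20)}
        r = hypergeom_enrichment(set(list(u)[:5]), set(list(u)[15:]), u)
        assert r.p_value == pytest.approx(1.0)

    def test_exact_tail_example(self):
        # N=10, K=5, n=4, k=4 -> C(5,4)C(5,0)/C(10,4) = 5/210
        u = {f"g{i}" for i in range(10)}
        gene_set = {f"g{i}" for i in range(5)}
        module = {f"g{i}" for i in range(4)}
        r = hypergeom_enrichment(module, gene_set, u)
        assert (r.k, r.n, r.K, r.N) == (4, 4, 5, 10)
        assert r.p_value == pytest.approx(5 / 210, rel=1e-12)

    def test_module_equals_universe(self):
        u = {f"g{i}" for i in range(6)}
        r = hypergeom_enrichment(u, u, u)
        assert r.p_value == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeom_enrichment(set(), set(), set())

    def test_tail_matches_monte_carlo(self):
        """Exact P(X>=k) within 3 SE of 100k hypergeometric draws."""
        rng = np.random.default_rng(0)
        n_draws = 100_000
        for _ in range(10):
            N = int(rng.integers(20, 80))
            K = int(rng.integers(3, N - 2))
            n = int(rng.integers(3, N - 2))
            universe = [f"g{i}" for i in range(N)]
            gene_set = set(universe[:K])
            module = set(rng.choice(universe, size=n, replace=False))
            k = len(module & gene_set)
            p = hypergeom_enrichment(module, gene_set, set(universe)).p_value
            draws = rng.hypergeometric(K, N - K, n, size=n_draws)
            mc = (draws >= k).mean()
            se = max(np.sqrt(mc * (1 - mc) / n_draws), 1e-5)
            assert abs(p - mc) <= 3 * se + 1e-12

    def test_bh_within_family_monotone_and_geq_p(self):
        rng = np.random.default_rng(1)
        universe = {f"g{i}" for i in range(50)}
        modules = {
            f"CID-{i:02d}": set(rng.choice(sorted(universe), size=8, replace=False))
            for i in range(5)
        }
        sets = {
            f"S{i}": set(rng.choice(sorted(universe), size=10, replace=False))
            for i in range(4)
        }
        table = module_enrichment_table(modules, {"c": sets}, universe)
        assert (table["q"] >= table["p"] - 1e-12).all()
        ordered = table.sort_values("p")
        assert ordered["q"].is_monotonic_increasing


@pytest.fixture(scope="module")
def toy_ontology():
    """root <- {branch1, branch2}; branch1 <- {leaf1a, leaf1b}."""
    edges = pd.DataFrame(
        {
            "child": ["branch1", "branch2", "leaf1a", "leaf1b"],
            "parent": ["root", "root", "branch1", "branch1"],
        }
    )
    ont = OntologyDAG(edges)
    annotations = {
        "gA": {"leaf1a"},
        "gB": {"leaf1b"},
        "gC": {"branch2"},
        "gD": {"leaf1a"},
        "gE": {"branch2"},
        "gF": {"branch1"},
    }
    return ont, annotations


class TestInformationContent:
    def test_root_ic_zero(self, toy_ontology):
        ont, ann = toy_ontology
        ic = term_information_content(ont, ann)
        assert ic["root"] == 0.0

    def test_leaf_counts_after_propagation(self, toy_ontology):
        ont, ann = toy_ontology
        ic = term_information_content(ont, ann)
        # 6 annotated genes total; branch1 covers gA, gB, gD, gF
        assert ic["branch1"] == pytest.approx(-np.log(4 / 6))
        assert ic["leaf1a"] == pytest.approx(-np.log(2 / 6))
        assert ic["branch2"] == pytest.approx(-np.log(2 / 6))

    def test_single_gene_leaf_has_ic_ln_n(self):
        edges = pd.DataFrame({"child": ["t1", "t2"], "parent": ["root", "root"]})
        ont = OntologyDAG(edges)
        ann = {f"g{i}": {"t2"} for i in range(9)} | {"g9": {"t1"}}
        ic = term_information_content(ont, ann)
        assert ic["t1"] == pytest.approx(np.log(10))

    def test_missing_term_rejected_by_name(self, toy_ontology):
        ont, _ = toy_ontology
        with pytest.raises(KeyError, match="ghost"):
            term_information_content(ont, {"g": {"ghost"}})

    def test_cycle_rejected(self):
        edges = pd.DataFrame({"child": ["a", "b"], "parent": ["b", "a"]})
        with pytest.raises(ValueError, match="cycle"):
            OntologyDAG(edges)


class TestSemanticSimilarity:
    def test_same_single_term_gives_one(self, toy_ontology):
        ont, ann = toy_ontology
        assert gene_pair_semantic_similarity("gA", "gD", ont, ann) == pytest.approx(1.0)

    def test_disjoint_branches_give_zero(self, toy_ontology):
        ont, ann = toy_ontology
        assert gene_pair_semantic_similarity("gA", "gC", ont, ann) == pytest.approx(0.0)

    def test_unannotated_gene_gives_zero(self, toy_ontology):
        ont, ann = toy_ontology
        assert gene_pair_semantic_similarity("gA", "gZ", ont, ann) == 0.0

    def test_hand_evaluated_best_match_average(self, toy_ontology):
        """gA={leaf1a} vs gB={leaf1b}: MICA=branch1, Lin = 2 IC(b1)/(IC(l1a)+IC(l1b))."""
        ont, ann = toy_ontology
        ic = term_information_content(ont, ann)
        want = 2 * ic["branch1"] / (ic["leaf1a"] + ic["leaf1b"])
        got = gene_pair_semantic_similarity("gA", "gB", ont, ann)
        assert got == pytest.approx(want, rel=1e-12)

    def test_symmetry_and_range(self, toy_ontology):
        ont, ann = toy_ontology
        genes = sorted(ann)
        for a in genes:
            for b in genes:
                s1 = gene_pair_semantic_similarity(a, b, ont, ann)
                s2 = gene_pair_semantic_similarity(b, a, ont, ann)
                assert s1 == pytest.approx(s2, abs=1e-12)
                assert -1e-12 <= s1 <= 1 + 1e-12


class TestEdgeComparison:
    def test_identical_edge_sets(self, toy_ontology):
        ont, ann = toy_ontology
        edges = {_pair("gA", "gD"), _pair("gA", "gB"), _pair("gA", "gC")}
        ma, mb, p = compare_edge_similarity(edges, edges, ont, ann)
        assert ma == mb
        assert p == pytest.approx(1.0)

    def test_separated_edge_sets(self, toy_ontology):
        ont, ann = toy_ontology
        same = {_pair("gA", "gD"), _pair("gC", "gE")}  # identical-term pairs
        disjoint = {_pair("gA", "gC"), _pair("gB", "gE"), _pair("gD", "gC")}
        ma, mb, p = compare_edge_similarity(same, disjoint, ont, ann)
        assert ma == pytest.approx(1.0)
        assert mb == pytest.approx(0.0)
        assert p < 0.2  # tiny samples; direction is what matters

    def test_rank_sum_statistic_vs_brute_force(self, toy_ontology):
        """p-value reproduced from an exhaustive rank computation."""
        from scipy.stats import norm

        ont, ann = toy_ontology
        rng = np.random.default_rng(3)
        genes = sorted(ann)
        all_pairs = [
            _pair(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]
        ]
        ea = set(rng.choice(len(all_pairs), size=8, replace=False).tolist())
        edges_a = {all_pairs[i] for i in ea}
        edges_b = {all_pairs[i] for i in range(len(all_pairs)) if i not in ea}
        ma, mb, p = compare_edge_similarity(edges_a, edges_b, ont, ann)

        def sim(e):
            a, b = sorted(e)
            return gene_pair_semantic_similarity(a, b, ont, ann)

        xs = np.array([sim(e) for e in sorted(edges_a, key=sorted)])
        ys = np.array([sim(e) for e in sorted(edges_b, key=sorted)])
        pooled = np.concatenate([xs, ys])
        ranks = rankdata(pooled)
        n1, n2 = len(xs), len(ys)
        w = ranks[:n1].sum()
        mu = n1 * (n1 + n2 + 1) / 2
        # tie-corrected variance of the rank sum
        _, counts = np.unique(pooled, return_counts=True)
        tie = ((counts**3 - counts).sum()) / ((n1 + n2) * (n1 + n2 - 1))
        var = n1 * n2 / 12 * ((n1 + n2 + 1) - tie)
        z = (w - mu) / np.sqrt(var)
        want = 2 * norm.sf(abs(z))
        assert p == pytest.approx(want, rel=1e-8)

    def test_empty_edge_set_rejected(self, toy_ontology):
        ont, ann = toy_ontology
        with pytest.raises(ValueError, match="non-empty"):
            compare_edge_similarity(set(), {_pair("gA", "gB")}, ont, ann)


class TestEdgeOverlap:
    def test_subset_reference(self):
        a = {_pair("x", "y"), _pair("y", "z")}
        out = edge_overlap(a, {"ref": a | {_pair("p", "q")}})
        assert out["references"]["ref"]["overlap"] == 2
        assert out["unique"] == 0

    def test_disjoint_reference(self):
        a = {_pair("x", "y")}
        out = edge_overlap(a, {"ref": {_pair("p", "q")}})
        assert out["unique_percent"] == 100.0

    def test_toy_two_references_set_algebra(self):
        pairs = [_pair(f"a{i}", f"b{i}") for i in range(10)]
        a = set(pairs)
        ref1 = set(pairs[:2])            # hits 2
        ref2 = set(pairs[1:4])           # hits 3, 1 shared with ref1
        out = edge_overlap(a, {"r1": ref1, "r2": ref2})
        assert out["references"]["r1"]["overlap"] == 2
        assert out["references"]["r2"]["overlap"] == 3
        assert out["unique"] == 6
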