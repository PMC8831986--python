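"""Tests of the planted-module synthetic data generator."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cofitnet.simulate import (
    SimulationConfig,
    simulate_annotations,
    simulate_curated_studies,
    simulate_dataset,
)


def _pcc(a, b):
    return float(np.corrcoef(a, b)[0, 1])


class TestSimulateDataset:
    def test_fixed_seed_is_byte_identical(self):
        cfg = SimulationConfig(seed=1)
        f1, e1, t1 = simulate_dataset(cfg)
        f2, e2, t2 = simulate_dataset(cfg)
        assert f1.to_csv() == f2.to_csv()
        assert e1.to_csv() == e2.to_csv()
        assert t1.planted_edges == t2.planted_edges
        assert t1.module_assignment == t2.module_assignment

    def test_pair_universe_of_ten_genes(self):
        cfg = SimulationConfig(
            n_genes=10, n_cell_lines=5, n_modules=1, module_size_range=(3, 3),
            unexpressed_fraction=0.0, seed=0,
        )
        f, _, _ = simulate_dataset(cfg)
        assert len(list(itertools.combinations(f.index, 2))) == 45

    def test_planted_linear_pairs_outcorrelate_background(self):
        cfg = SimulationConfig(seed=1)
        fitness, _, truth = simulate_dataset(cfg)
        linear = [p for p, r in truth.pair_relation.items() if r == "linear"]
        planted_mean = np.mean(
            [abs(_pcc(fitness.loc[min(p)], fitness.loc[max(p)])) for p in linear]
        )
        background = sorted(set(fitness.index) - set(truth.module_assignment))
        rng = np.random.default_rng(0)
        rand_pcc = []
        for _ in range(1000):
            a, b = rng.choice(background, size=2, replace=False)
            rand_pcc.append(abs(_pcc(fitness.loc[a], fitness.loc[b])))
        assert planted_mean > np.mean(rand_pcc)

    def test_low_noise_linear_pairs_near_perfect_correlation(self):
        cfg = SimulationConfig(within_module_noise_sd=0.05, seed=3)
        fitness, _, truth = simulate_dataset(cfg)
        linear = [p for p, r in truth.pair_relation.items() if r == "linear"]
        pccs = [abs(_pcc(fitness.loc[min(p)], fitness.loc[max(p)])) for p in linear]
        assert min(pccs) > 0.95

    def test_nonlinear_pairs_low_pcc_high_mi(self):
        """|z|-transformed members decorrelate linearly but stay dependent."""
        from cofitnet.features import MetricParams, compute_metric

        # many cell lines: within a module every nonlinear pair inherits the
        # same latent draw, so decorrelation needs the sample to be wide
        cfg = SimulationConfig(n_cell_lines=150, within_module_noise_sd=0.1, seed=5)
        fitness, _, truth = simulate_dataset(cfg)
        nonlinear = [p for p, r in truth.pair_relation.items() if r == "nonlinear"]
        assert len(nonlinear) > 20
        pccs = [abs(_pcc(fitness.loc[min(p)], fitness.loc[max(p)])) for p in nonlinear]
        assert np.median(pccs) < 0.3

        params = MetricParams()
        mis = [
            compute_metric(
                fitness.loc[min(p)].to_numpy(), fitness.loc[max(p)].to_numpy(),
                "mutual_information", params,
            )
            for p in nonlinear
        ]
        background = sorted(set(fitness.index) - set(truth.module_assignment))
        rng = np.random.default_rng(0)
        bg_mis = []
        for _ in range(300):
            a, b = rng.choice(background, size=2, replace=False)
            bg_mis.append(
                compute_metric(
                    fitness.loc[a].to_numpy(), fitness.loc[b].to_numpy(),
                    "mutual_information", params,
                )
            )
        q95 = np.quantile(bg_mis, 0.95)
        assert np.mean(np.asarray(mis) > q95) >= 0.9

    def test_unexpressed_genes_are_background_only(self):
        _, expression, truth = simulate_dataset(SimulationConfig(seed=1))
        unexpressed = expression.index[(expression == 0).all(axis=1)]
        assert len(unexpressed) == 30  # 10% of 300
        assert not set(unexpressed) & set(truth.module_assignment)
        assert (expression.to_numpy() >= 0).all()

    def test_ground_truth_consistency(self):
        _, _, truth = simulate_dataset(SimulationConfig(seed=2))
        rebuilt = set()
        for members in truth.modules().values():
            for a, b in itertools.combinations(sorted(members), 2):
                rebuilt.add(frozenset((a, b)))
        assert rebuilt == truth.planted_edges
        assert set(truth.pair_relation) == truth.planted_edges
        assert all(len(p) == 2 for p in truth.planted_edges)

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            ({"n_modules": 40}, "exceeds n_genes"),
            ({"nonlinear_fraction": 1.5}, "nonlinear_fraction"),
            ({"unexpressed_fraction": -0.1}, "unexpressed_fraction"),
            ({"module_size_range": (5, 3)}, "module_size_range"),
            ({"essential_depth_mean": 0.5}, "essential_depth_mean"),
        ],
    )
    def test_invalid_config_rejected_with_named_bound(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            simulate_dataset(SimulationConfig(**kwargs))


@pytest.fixture(scope="module")
def truth():
    return simulate_dataset(SimulationConfig(seed=1))[2]


class TestCuratedStudies:
    def test_full_coverage_no_fpr_reproduces_planted(self, truth):
        studies = simulate_curated_studies(truth, 3, coverage=1.0, fpr=0.0, seed=0)
        assert all(s == truth.planted_edges for s in studies)

    def test_zero_coverage_gives_empty_studies(self, truth):
        studies = simulate_curated_studies(truth, 3, coverage=0.0, fpr=0.0, seed=0)
        assert all(s == set() for s in studies)

    def test_two_of_three_support_matches_binomial_expectation(self, truth):
        # P(>=2 of 3 at coverage 0.8) = 3*0.64*0.2 + 0.512 = 0.896
        assert len(truth.planted_edges) >= 200
        studies = simulate_curated_studies(truth, 3, coverage=0.8, fpr=0.001, seed=7)
        supported = sum(
            1 for p in truth.planted_edges
            if sum(p in s for s in studies) >= 2
        )
        assert supported / len(truth.planted_edges) == pytest.approx(0.896, abs=0.05)

    def test_requires_at_least_one_study(self, truth):
        with pytest.raises(ValueError, match="n_studies"):
            simulate_curated_studies(truth, 0)

    def test_seed_determinism(self, truth):
        a = simulate_curated_studies(truth, 3, seed=11)
        b = simulate_curated_studies(truth, 3, seed=11)
        assert a == b


class TestAnnotations:
    def test_module_members_share_a_term(self):
        _, _, truth = simulate_dataset(SimulationConfig(seed=1))
        ann, _ = simulate_annotations(truth, n_noise_terms=0, seed=0)
        for members in truth.modules().values():
            shared = set.intersection(*(ann[g] for g in members))
            assert shared - {"T:ROOT"}

    def test_background_genes_without_noise_terms_unannotated(self):
        _, _, truth = simulate_dataset(SimulationConfig(seed=1))
        genes = sorted(truth.module_assignment)
        ann, _ = simulate_annotations(
            truth, n_noise_terms=0, seed=0, gene_universe=genes + ["B1", "B2"]
        )
        assert ann["B1"] == set() and ann["B2"] == set()

    def test_toy_two_modules_three_terms(self):
        cfg = SimulationConfig(
            n_genes=6, n_cell_lines=5, n_modules=2, module_size_range=(3, 3),
            unexpressed_fraction=0.0, seed=0,
        )
        _, _, truth = simulate_dataset(cfg)
        ann, ontology = simulate_annotations(truth, n_noise_terms=0, seed=0)
        terms = set(ontology["child"]) | set(ontology["parent"])
        assert len(terms) == 3  # two module leaves + one root
        assert (ontology["parent"] == "T:ROOT").all()

    def test_ontology_is_acyclic_rooted(self):
        import networkx as nx

        _, _, truth = simulate_dataset(SimulationConfig(seed=1))
        _, ontology = simulate_annotations(truth, n_noise_terms=5, seed=0)
        g = nx.DiGraph(list(ontology.itertuples(index=False)))
        assert nx.is_directed_acyclic_graph(g)
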