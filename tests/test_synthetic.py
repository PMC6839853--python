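"""Generator properties: determinism, topology, planted signal, calibration."""

import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

from mitonet import (
    ConfigurationError,
    GenerationConfig,
    generate_annotations,
    generate_expression_datasets,
    generate_interaction_sources,
    generate_truth_network,
    write_inputs,
)
from mitonet.integration import filter_scored
from mitonet.synthetic import edge_pinned_correlation


def _tree_hash(root: Path) -> str:
    h = hashlib.sha256()
    for path in sorted(root.rglob("*")):
        if path.is_file():
            h.update(str(path.relative_to(root)).encode())
            h.update(path.read_bytes())
    return h.hexdigest()


class TestTruthNetwork:
    def test_m1_yields_spanning_tree(self):
        cfg = GenerationConfig(n_catalog=5, n_genes=10, scale_free_m=1, term_size=3, seed=0)
        truth = generate_truth_network(cfg)
        assert truth.graph.number_of_edges() == 4
        assert nx.is_tree(truth.graph)

    def test_graph_is_simple_connected_over_catalog(self, synthetic_study):
        g = synthetic_study["truth"].graph
        assert nx.is_connected(g)
        assert nx.number_of_selfloops(g) == 0
        assert set(g.nodes()) == set(synthetic_study["truth"].catalog)

    def test_m0_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_truth_network(GenerationConfig(scale_free_m=0))

    def test_catalog_larger_than_universe_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_truth_network(GenerationConfig(n_genes=10, n_catalog=20))

    def test_loglog_slope_stable_across_seeds(self):
        """Degree-distribution log-log slope varies little between runs.

        At 200 nodes the raw empirical tail is noisy (single nodes at high
        degree), so the frozen band is the spread this seeded procedure
        itself produces: every slope within 0.7 of the 20-run mean."""
        from mitonet import degree_distribution, fit_power_law
        from mitonet.topology import TissueNetwork

        slopes = []
        for seed in range(20):
            cfg = GenerationConfig(n_catalog=200, n_genes=200, scale_free_m=2, seed=seed)
            truth = generate_truth_network(cfg)
            dist = degree_distribution(TissueNetwork(graph=truth.graph))
            slopes.append(fit_power_law(dist).alpha)
        slopes = np.array(slopes)
        assert np.all(np.abs(slopes - slopes.mean()) < 0.7)
        assert 1.2 <= slopes.mean() <= 2.0


class TestEdgePinnedCorrelation:
    def test_edges_pinned_and_psd(self):
        g = nx.barabasi_albert_graph(100, 2, seed=7)
        corr, nodes = edge_pinned_correlation(g, 0.8)
        idx = {v: i for i, v in enumerate(nodes)}
        for u, v in g.edges():
            assert corr[idx[u], idx[v]] == pytest.approx(0.8, abs=0.01)
        assert np.linalg.eigvalsh(corr).min() > -1e-8
        assert np.allclose(np.diag(corr), 1.0)

    def test_zero_rho_is_identity(self):
        g = nx.path_graph(5)
        corr, _ = edge_pinned_correlation(g, 0.0)
        assert np.array_equal(corr, np.eye(5))


class TestInteractionSources:
    def test_source_count_and_evidence_columns(self, synthetic_study):
        sources = synthetic_study["sources"]
        assert len(sources) == 7
        kinds = [
            "score" if "score" in t.columns else
            "core_flag" if "core_flag" in t.columns else "pubs"
            for t in sources
        ]
        assert kinds == ["score"] * 4 + ["core_flag"] + ["pubs"] * 2

    def test_tables_reach_outside_catalog(self, synthetic_study):
        catalog = set(synthetic_study["truth"].catalog)
        outside = 0
        for t in synthetic_study["sources"]:
            genes = set(t["protein_a"]) | set(t["protein_b"])
            outside += len(genes - catalog)
        assert outside > 0

    def test_median_filter_favours_truth_edges(self, synthetic_study):
        """Decoys survive the score-median filter less often than truth edges."""
        for table in synthetic_study["sources"][:4]:
            kept = filter_scored(table)
            frac_true = kept["is_true"].sum() / table["is_true"].sum()
            frac_decoy = (~kept["is_true"]).sum() / (~table["is_true"]).sum()
            assert frac_decoy < frac_true

    def test_no_decoys_recovers_pure_truth_sample(self):
        cfg = GenerationConfig(seed=2, decoy_edge_fraction=0.0)
        truth = generate_truth_network(cfg)
        for table in generate_interaction_sources(truth, cfg):
            edges = {tuple(sorted(p)) for p in zip(table["protein_a"], table["protein_b"])}
            assert edges <= truth.truth_edges


class TestExpressionDatasets:
    def test_two_variants_with_positive_linear_values(self, synthetic_study):
        for ds_a, ds_b in synthetic_study["datasets"]:
            assert (ds_a.variant, ds_b.variant) == ("A", "B")
            assert (ds_a.scale, ds_b.scale) == ("linear", "log2")
            assert (ds_a.matrix.values > 0).all()
            assert ds_a.id == ds_b.id

    def test_variant_b_is_monotone_transform_of_a(self, synthetic_study):
        """Ranks agree between variants up to the small observation noise."""
        ds_a, ds_b = synthetic_study["datasets"][0]
        a = np.log2(ds_a.matrix.values.ravel())
        b = ds_b.matrix.values.ravel()
        assert np.corrcoef(a, b)[0, 1] > 0.99

    def test_full_coverage_measures_every_catalog_gene(self):
        cfg = GenerationConfig(seed=6, coverage_fraction=1.0, n_datasets=2)
        truth = generate_truth_network(cfg)
        for ds_a, _ in generate_expression_datasets(truth, cfg):
            assert set(truth.catalog) <= set(ds_a.genes)

    def test_too_few_cases_rejected(self):
        cfg = GenerationConfig(cases_per_dataset=2)
        truth = generate_truth_network(cfg)
        with pytest.raises(ConfigurationError):
            generate_expression_datasets(truth, cfg)

    def test_edge_partner_correlation_near_target(self):
        """Sample rho over truth edges approaches edge_rho (0.9, 50 cases)."""
        cfg = GenerationConfig(
            seed=3, edge_rho=0.9, cases_per_dataset=50, n_datasets=1,
            coverage_fraction=1.0,
        )
        truth = generate_truth_network(cfg)
        (ds_a, _), = generate_expression_datasets(truth, cfg)
        log2 = ds_a.log2_matrix()
        cases = ds_a.case_samples
        rhos = [
            np.corrcoef(log2.loc[u, cases], log2.loc[v, cases])[0, 1]
            for u, v in truth.truth_edges
        ]
        assert 0.8 <= np.mean(rhos) <= 0.95

    def test_null_generator_plants_nothing_and_calibrates(self):
        """effect_fold=1: empty planted sets; p<0.05 at ~5% on null genes."""
        cfg = GenerationConfig(
            seed=8, effect_fold=1.0, edge_rho=0.0, n_genes=1000, n_catalog=1000,
            n_datasets=1, coverage_fraction=1.0,
        )
        truth = generate_truth_network(cfg)
        (ds_a, _), = generate_expression_datasets(truth, cfg)
        assert truth.planted_up == set() and truth.planted_down == set()
        from mitonet import call_dataset

        calls = call_dataset(ds_a)
        p_rate = (calls["p_value"] < 0.05).mean()
        assert 0.03 <= p_rate <= 0.07
        call_rate = (calls["direction"] != "none").mean()
        assert call_rate <= 0.05


class TestAnnotations:
    def test_zero_terms(self, synthetic_study):
        cfg = GenerationConfig(seed=1, n_terms=0)
        assert generate_annotations(synthetic_study["truth"], cfg) == {}

    def test_terms_within_catalog_with_planted_enrichment(self, synthetic_study):
        truth = synthetic_study["truth"]
        terms = synthetic_study["annotations"]
        catalog = set(truth.catalog)
        assert len(terms) == synthetic_study["config"].n_terms
        assert all(members <= catalog for members in terms.values())
        planted = truth.planted_up | truth.planted_down
        best = max(len(m & planted) / len(m) for m in terms.values())
        assert best >= 0.5

    def test_oversized_terms_rejected(self, synthetic_study):
        cfg = GenerationConfig(n_catalog=10, n_genes=20, term_size=11)
        with pytest.raises(ConfigurationError):
            generate_annotations(synthetic_study["truth"], cfg)


def test_write_inputs_is_byte_deterministic(tmp_path):
    """Same seed and config give hash-identical file trees."""
    cfg = GenerationConfig(seed=42, n_genes=80, n_catalog=40, n_datasets=2,
                           cases_per_dataset=5, controls_per_dataset=4,
                           n_terms=4, term_size=8)
    write_inputs(cfg, tmp_path / "a")
    write_inputs(cfg, tmp_path / "b")
    assert _tree_hash(tmp_path / "a") == _tree_hash(tmp_path / "b")
    truth = json.loads((tmp_path / "a" / "truth.json").read_text())
    assert set(truth) == {
        "truth_edges", "planted_up", "planted_down", "term_memberships", "measured_genes",
    }
    assert not set(truth["planted_up"]) & set(truth["planted_down"])
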