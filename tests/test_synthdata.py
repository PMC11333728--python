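"""Synthetic-data generators: planted truth bookkeeping, determinism,
distributional fidelity."""

import numpy as np
import pytest

from crossdx.diffexpr import fit_moderated_t
from crossdx.drugrank import rank_bas_matrix
from crossdx.synthdata import (
    ConfigurationError,
    SimulationConfig,
    SyntheticNetworkSpec,
    generate_bas_matrix,
    generate_gene_set_collection,
    generate_ppi_graph,
    generate_two_disease_studies,
)


class TestExpressionGenerator:
    def test_class_counts_forced_by_config(self):
        cfg = SimulationConfig(seed=0, n_genes=1000, n_shared_up=50, n_shared_down=20,
                               n_specific_per_disease=30)
        _, _, truth = generate_two_disease_studies(cfg)
        frame = truth.frame()
        counts = frame["class"].value_counts()
        assert counts["shared_up"] == 50
        assert counts["shared_down"] == 20
        assert counts["specific_disease1"] == 30
        assert counts["specific_disease2"] == 30
        assert counts["null"] == 870

    def test_null_genes_have_zero_effect(self):
        cfg = SimulationConfig(seed=1, n_genes=300, n_shared_up=10, n_shared_down=5,
                               n_specific_per_disease=5)
        _, _, truth = generate_two_disease_studies(cfg)
        for g in truth.genes_of_class("null"):
            assert truth.effect_1[g] == 0.0 and truth.effect_2[g] == 0.0
        for g in truth.genes_of_class("specific_disease1"):
            assert truth.effect_2[g] == 0.0 and truth.effect_1[g] != 0.0

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=9, n_genes=100, samples_per_group=[(4, 4)],
                               n_datasets_per_disease=1, n_shared_up=10,
                               n_shared_down=5, n_specific_per_disease=5)
        a1, a2, _ = generate_two_disease_studies(cfg)
        b1, b2, _ = generate_two_disease_studies(cfg)
        np.testing.assert_array_equal(a1[0].matrix, b1[0].matrix)
        np.testing.assert_array_equal(a2[0].matrix, b2[0].matrix)

    def test_positive_intensities_and_group_sizes(self, small_sim):
        cfg, studies1, studies2, _ = small_sim
        assert len(studies1) == len(studies2) == cfg.n_datasets_per_disease
        for st in studies1 + studies2:
            assert np.all(st.matrix > 0)
            assert (st.n1, st.n2) == (12, 12)

    def test_default_cohort_sizes_mirror_study_design(self):
        cfg = SimulationConfig(seed=2, n_genes=50, n_shared_up=0, n_shared_down=0,
                               n_specific_per_disease=0)
        s1, s2, _ = generate_two_disease_studies(cfg)
        assert [(s.n1, s.n2) for s in s1] == [(6, 7), (12, 12), (12, 12), (12, 12)]
        assert [(s.n1, s.n2) for s in s2] == [(14, 14), (27, 27), (12, 12), (13, 13)]

    def test_planted_effect_correlation_near_target(self):
        """Shared-gene effect pairs carry the configured correlation."""
        cfg = SimulationConfig(seed=3, n_genes=300, n_shared_up=120, n_shared_down=0,
                               n_specific_per_disease=0, effect_mean=1.5,
                               cross_disease_effect_correlation=0.8)
        _, _, truth = generate_two_disease_studies(cfg)
        shared = truth.genes_of_class("shared_up")
        e1 = [truth.effect_1[g] for g in shared]
        e2 = [truth.effect_2[g] for g in shared]
        assert abs(np.corrcoef(e1, e2)[0, 1] - 0.8) <= 0.15

    def test_variance_prior_recovered(self):
        """Method-of-moments fit on generated data recovers (d0, s0^2)."""
        cfg = SimulationConfig(seed=4, n_genes=2000, n_datasets_per_disease=1,
                               samples_per_group=[(12, 12)], n_shared_up=0,
                               n_shared_down=0, n_specific_per_disease=0)
        studies, _, _ = generate_two_disease_studies(cfg)
        summary, _, _ = fit_moderated_t(studies[0])
        assert abs(summary.prior_df - 4.0) / 4.0 <= 0.5
        assert abs(summary.prior_variance - 0.05) / 0.05 <= 0.25

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_genes=10, n_shared_up=20)
        with pytest.raises(ConfigurationError):
            SimulationConfig(cross_disease_effect_correlation=1.5)
        with pytest.raises(ConfigurationError):
            SimulationConfig(variance_prior_df=0.0)


class TestNetworkGenerator:
    def test_hub_degree_with_empty_background(self):
        spec = SyntheticNetworkSpec(n_background_nodes=10, n_planted_hubs=1,
                                    hub_degree=8, background_density=0.0, seed=0)
        g = generate_ppi_graph(spec)
        assert g.degree("HUB00") == 8
        assert all(g.degree(v) <= 1 for v in g.nodes if v != "HUB00")

    def test_no_hubs_no_density_gives_empty_edge_set(self):
        spec = SyntheticNetworkSpec(n_background_nodes=5, n_planted_hubs=0,
                                    hub_degree=0, background_density=0.0, seed=0)
        assert generate_ppi_graph(spec).number_of_edges() == 0

    def test_deterministic_edge_lists(self):
        spec = SyntheticNetworkSpec(seed=5)
        assert sorted(generate_ppi_graph(spec).edges) == \
            sorted(generate_ppi_graph(spec).edges)

    def test_simple_graph_no_self_loops(self):
        g = generate_ppi_graph(SyntheticNetworkSpec(seed=6, background_density=0.1))
        assert all(u != v for u, v in g.edges)

    def test_hub_strictly_out_degrees_background(self):
        g = generate_ppi_graph(SyntheticNetworkSpec(
            n_background_nodes=60, n_planted_hubs=2, hub_degree=25,
            background_density=0.02, seed=7))
        hub_deg = min(g.degree(h) for h in ("HUB00", "HUB01"))
        bg_deg = max(g.degree(v) for v in g.nodes if not v.startswith("HUB"))
        assert hub_deg > bg_deg

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticNetworkSpec(n_background_nodes=5, n_planted_hubs=1,
                                 hub_degree=10)


class TestGeneSetGenerator:
    def test_planted_set_contains_planted_genes(self):
        universe = [f"g{i}" for i in range(200)]
        coll = generate_gene_set_collection(5, (10, 30), universe, universe[:10], seed=1)
        assert set(universe[:10]) <= coll.sets["PLANTED"]

    def test_empty_collection(self):
        coll = generate_gene_set_collection(0, (1, 2), ["a", "b"], [], seed=0)
        assert coll.sets == {}

    def test_reproducible(self):
        universe = [f"g{i}" for i in range(50)]
        a = generate_gene_set_collection(4, (5, 10), universe, universe[:3], seed=9)
        b = generate_gene_set_collection(4, (5, 10), universe, universe[:3], seed=9)
        assert a.sets == b.sets

    def test_planted_outside_universe_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_gene_set_collection(1, (2, 3), ["a"], ["zzz"], seed=0)


class TestBASGenerator:
    def test_planted_strong_ligands_rank_top(self):
        matrix, strong = generate_bas_matrix(10, 20, 2, strong_mean=-9.0,
                                             weak_mean=-5.0, noise_sd=0.1, seed=0)
        ranking = rank_bas_matrix(matrix)
        assert sorted(ranking.ligand_means.index[:2]) == sorted(strong)

    def test_zero_noise_exact_means(self):
        matrix, strong = generate_bas_matrix(4, 6, 3, strong_mean=-9.0,
                                             weak_mean=-5.0, noise_sd=0.0, seed=0)
        means = matrix.scores.mean(axis=0)
        for lig in strong:
            assert means[lig] == pytest.approx(-9.0)

    def test_reproducible(self):
        a, _ = generate_bas_matrix(3, 4, 1, seed=11)
        b, _ = generate_bas_matrix(3, 4, 1, seed=11)
        assert a.scores.equals(b.scores)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_bas_matrix(3, 2, 5)
        with pytest.raises(ConfigurationError):
            generate_bas_matrix(3, 2, 1, strong_mean=-5.0, weak_mean=-9.0)
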