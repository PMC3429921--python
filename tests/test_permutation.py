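"""Rotation algebra, empirical P estimation, and the permutation schemes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp, kstest

from pathperm import (
    DEFAULT_CHROMOSOME_ORDER,
    PathwayEnrichment,
    SimulationConfig,
    annotate_snps,
    build_genome_order,
    circular_null,
    empirical_pvalue,
    empirical_threshold,
    gene_random_null,
    rotate_pvalues,
    simulate_genome,
    snp_random_null,
)
from pathperm.permutation import PermutationDistribution, PermutationEngine
from tests.conftest import make_gwas, make_snp


class TestRotation:
    def test_unit_rotation_moves_first_value_to_second_slot(self):
        assert list(rotate_pvalues([0.1, 0.2, 0.3], 1)) == [0.3, 0.1, 0.2]

    def test_zero_offset_is_identity(self):
        x = [0.4, 0.1, 0.9, 0.3]
        assert list(rotate_pvalues(x, 0)) == x

    def test_rotations_compose_additively_mod_n(self):
        x = np.arange(7, dtype=float)
        for r in range(7):
            for s in range(7):
                twice = rotate_pvalues(rotate_pvalues(x, r), s)
                once = rotate_pvalues(x, (r + s) % 7)
                assert np.array_equal(twice, once)

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=30), st.integers(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_output_is_permutation_of_input(self, values, offset):
        offset = offset % len(values)
        rotated = rotate_pvalues(values, offset)
        assert sorted(rotated) == sorted(values)

    @pytest.mark.parametrize("offset", [-1, 3, 10])
    def test_out_of_range_offset_raises(self, offset):
        with pytest.raises(ValueError):
            rotate_pvalues([0.1, 0.2, 0.3], offset)


class TestEmpiricalEstimators:
    def _dist(self, values):
        return PermutationDistribution("P", "t", np.asarray(values, float),
                                       len(values), "circular", 0)

    def test_observation_below_all_permuted_values(self):
        dist = self._dist(np.linspace(0.1, 1.0, 10_000))
        assert empirical_pvalue(0.01, dist) == pytest.approx(1 / 10_001)

    def test_observation_above_all_permuted_values(self):
        dist = self._dist(np.linspace(0.001, 0.5, 100))
        assert empirical_pvalue(0.9, dist) == 1.0

    def test_constant_distribution_ties_count(self):
        dist = self._dist(np.full(500, 0.3))
        assert empirical_pvalue(0.3, dist) == 1.0

    def test_threshold_is_fifth_order_statistic(self):
        dist = self._dist(np.round(np.arange(0.01, 1.005, 0.01), 10))
        assert empirical_threshold(dist, 0.05) == pytest.approx(0.05)

    def test_threshold_of_constant_distribution(self):
        dist = self._dist(np.full(100, 0.42))
        assert empirical_threshold(dist, 0.05) == pytest.approx(0.42)

    def test_invalid_level_raises(self):
        with pytest.raises(ValueError):
            empirical_threshold(self._dist([0.5]), 1.5)


def small_genome(seed=0, **overrides):
    params = dict(n_snps=300, n_chromosomes=2, n_genes=40, snps_per_gene_mean=3.0,
                  ld_rho=0.5, n_pathways=5, pathway_size_range=(4, 10),
                  gene_clustering=0.5, n_traits=1, seed=seed)
    params.update(overrides)
    cfg = SimulationConfig(**params)
    gwas, genes, sets = simulate_genome(cfg)
    order = build_genome_order(gwas.snps, DEFAULT_CHROMOSOME_ORDER[: cfg.n_chromosomes])
    amap = annotate_snps(gwas.snps, genes, 0)
    return gwas, order, amap, genes, sets


class TestCircularNull:
    def test_constant_pvalues_leave_statistic_unchanged(self):
        snps = [make_snp(f"rs{i}", "1", 10 * (i + 1), 0.5) for i in range(20)]
        gwas = make_gwas(snps)
        gwas_, order, amap, genes, sets = small_genome()
        # reuse gene/pathway structure of a simulated genome but constant P values
        const = make_gwas(
            [make_snp(s.snp_id, s.chromosome, s.position, 0.5) for s in gwas_],
        )
        engine = PermutationEngine(const, order, amap, sets, "trait_1")
        p_obs, _, _ = engine.observed()
        matrix = engine.null_matrix("circular", 20, np.random.default_rng(0))
        assert np.allclose(matrix, p_obs[None, :])

    def test_fixed_seed_reproducibility(self):
        gwas, order, amap, genes, sets = small_genome(seed=3)
        a = circular_null(gwas, order, amap, sets, "trait_1", n_perm=30, seed=11)
        b = circular_null(gwas, order, amap, sets, "trait_1", n_perm=30, seed=11)
        for pid in a:
            assert np.array_equal(a[pid].values, b[pid].values)

    def test_per_chromosome_scheme_reproducible_and_valid(self):
        gwas, order, amap, genes, sets = small_genome(seed=4)
        a = circular_null(gwas, order, amap, sets, "trait_1", n_perm=20, seed=5,
                          per_chromosome=True)
        b = circular_null(gwas, order, amap, sets, "trait_1", n_perm=20, seed=5,
                          per_chromosome=True)
        for pid in a:
            assert np.array_equal(a[pid].values, b[pid].values)
            assert np.all((a[pid].values > 0) & (a[pid].values <= 1))

    def test_rejects_single_snp_genome(self):
        from pathperm.io import GeneRecord, GeneSet, GeneSetCollection

        gwas = make_gwas([make_snp("rs1", "1", 100, 0.5)])
        order = build_genome_order(gwas.snps, ["1"])
        amap = annotate_snps(gwas.snps, [GeneRecord("G1", "g", "1", 1, 200)], 0)
        sets = GeneSetCollection()
        sets.add(GeneSet("P1", "", frozenset({"G1"})))
        with pytest.raises(ValueError, match="at least 2"):
            circular_null(gwas, order, amap, sets, "trait_1", n_perm=5, seed=0)

    def test_empirical_p_of_null_observation_is_uniform(self):
        """Calibration at the heart of the method: on a null genome the
        observed statistic's empirical P value is uniform across replicates.

        The gene cutoff and pathway size are chosen so the hypergeometric
        statistic has a rich support (many attainable values); with a very
        discrete statistic the rank-based estimator is conservative by
        construction and uniformity only holds approximately.
        """
        emps = []
        for rep in range(200):
            cfg = SimulationConfig(
                n_snps=450, n_chromosomes=2, n_genes=150, snps_per_gene_mean=1.0,
                ld_rho=0.0, n_pathways=1, pathway_size_range=(40, 40),
                gene_clustering=0.0, n_traits=1, seed=20_000 + rep,
            )
            gwas, genes, sets = simulate_genome(cfg)
            order = build_genome_order(gwas.snps, DEFAULT_CHROMOSOME_ORDER[:2])
            amap = annotate_snps(gwas.snps, genes, 0)
            engine = PermutationEngine(gwas, order, amap, sets, "trait_1", alpha_gene=0.3)
            p_obs, _, _ = engine.observed()
            matrix = engine.null_matrix("circular", 2000, np.random.default_rng(rep))
            emps.append(empirical_pvalue(float(p_obs[0]), matrix[:, 0]))
        assert kstest(emps, "uniform").pvalue > 0.01


class TestSnpRandomNull:
    def test_gene_covering_all_snps_matches_circular(self):
        # one gene containing every SNP: any rearrangement preserves its
        # P-value multiset, so both schemes give a constant statistic
        from pathperm.io import GeneRecord, GeneSet, GeneSetCollection

        snps = [make_snp(f"rs{i}", "1", 10 * (i + 1), p)
                for i, p in enumerate(np.random.default_rng(0).uniform(0.01, 1, 30))]
        gwas = make_gwas(snps)
        genes = [GeneRecord("G1", "g", "1", 1, 10_000)]
        sets = GeneSetCollection()
        sets.add(GeneSet("P1", "", frozenset({"G1"})))
        order = build_genome_order(snps, ["1"])
        amap = annotate_snps(snps, genes, 0)
        circ = circular_null(gwas, order, amap, sets, "trait_1", n_perm=50, seed=1)
        rand = snp_random_null(gwas, amap, sets, "trait_1", n_perm=50, seed=2, order=order)
        assert np.array_equal(np.unique(circ["P1"].values), np.unique(rand["P1"].values))
        assert len(np.unique(circ["P1"].values)) == 1

    def test_fixed_seed_reproducibility(self):
        gwas, order, amap, genes, sets = small_genome(seed=6)
        a = snp_random_null(gwas, amap, sets, "trait_1", n_perm=25, seed=9, order=order)
        b = snp_random_null(gwas, amap, sets, "trait_1", n_perm=25, seed=9, order=order)
        for pid in a:
            assert np.array_equal(a[pid].values, b[pid].values)

    def test_matches_circular_for_independent_snps_singleton_genes(self):
        # with iid uniform P values and one SNP per gene, both schemes are
        # draws from the same exchangeable null
        gwas, order, amap, genes, sets = small_genome(
            seed=5, n_snps=500, n_chromosomes=1, n_genes=100,
            snps_per_gene_mean=1.0, ld_rho=0.0, n_pathways=1,
            pathway_size_range=(20, 20),
        )
        engine = PermutationEngine(gwas, order, amap, sets, "trait_1")
        a = engine.null_matrix("circular", 2000, np.random.default_rng(1))[:, 0]
        b = engine.null_matrix("snp-random", 2000, np.random.default_rng(2))[:, 0]
        assert ks_2samp(a, b).pvalue > 0.01


class TestGeneRandomNull:
    def test_pathway_covering_universe_gives_constant_statistic(self):
        gwas, order, amap, genes, sets = small_genome(seed=7)
        engine = PermutationEngine(gwas, order, amap, sets, "trait_1")
        scores = engine.gene_scores()
        from pathperm.io import GeneSet, GeneSetCollection

        full = GeneSetCollection()
        full.add(GeneSet("ALL", "", frozenset(engine.universe_genes)))
        dists = gene_random_null(scores, full, engine.universe_genes, n_perm=40, seed=1)
        assert len(np.unique(dists["ALL"].values)) == 1

    def test_fixed_seed_reproducibility(self):
        gwas, order, amap, genes, sets = small_genome(seed=8)
        engine = PermutationEngine(gwas, order, amap, sets, "trait_1")
        scores = engine.gene_scores()
        a = gene_random_null(scores, sets, engine.universe_genes, n_perm=30, seed=2)
        b = gene_random_null(scores, sets, engine.universe_genes, n_perm=30, seed=2)
        for pid in a:
            assert np.array_equal(a[pid].values, b[pid].values)

    def test_unscored_universe_gene_raises(self):
        gwas, order, amap, genes, sets = small_genome(seed=9)
        engine = PermutationEngine(gwas, order, amap, sets, "trait_1")
        scores = engine.gene_scores()
        with pytest.raises(KeyError):
            gene_random_null(scores, sets, list(engine.universe_genes) + ["GHOST"],
                             n_perm=5, seed=0)

    def test_empty_universe_raises(self):
        gwas, order, amap, genes, sets = small_genome(seed=9)
        engine = PermutationEngine(gwas, order, amap, sets, "trait_1")
        scores = engine.gene_scores()
        with pytest.raises(ValueError):
            gene_random_null(scores, sets, [], n_perm=5, seed=0)


class TestSchemeDeterminism:
    @pytest.mark.parametrize("scheme", ["circular", "circular-per-chrom",
                                        "snp-random", "gene-random"])
    def test_identical_seed_gives_bit_identical_results(self, scheme):
        cfg = SimulationConfig(n_snps=400, n_chromosomes=2, n_genes=60,
                               ld_rho=0.6, n_pathways=8, pathway_size_range=(4, 12),
                               n_traits=2, seed=12)
        gwas, genes, sets = simulate_genome(cfg)
        model = PathwayEnrichment(gwas, genes, sets)
        a = model.fit(scheme=scheme, n_perm=40, seed=77).to_frame()
        b = model.fit(scheme=scheme, n_perm=40, seed=77).to_frame()
        assert a.equals(b)
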