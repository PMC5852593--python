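"""Diversity, differentiation, AMOVA, trees, ordination, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tfssr import marker_stats as ms
from tfssr.io_formats import GenotypeMatrix
from tfssr.simulate import IslandModelSpec, simulate_genotypes_island

from conftest import make_genotype_matrix


def freqs(*p):
    alleles = [100 + 2 * i for i in range(len(p))]
    return ms.AlleleFrequencies(dict(zip(alleles, p)), n_gene_copies=1000)


class TestAlleleFrequencies:
    def test_direct_count(self, small_mixed_gm):
        f = ms.allele_frequencies(small_mixed_gm, "L1", subset=["a1", "a2"])
        assert f.freqs == {100: 0.75, 120: 0.25}
        assert f.n_gene_copies == 4

    def test_monomorphic(self, two_fixed_pops):
        f = ms.allele_frequencies(two_fixed_pops, "L1",
                                  subset=[a for a, p in
                                          zip(two_fixed_pops.accessions,
                                              two_fixed_pops.populations)
                                          if p == "PopA"])
        assert f.freqs == {100: 1.0}

    def test_missing_calls_excluded(self, small_mixed_gm):
        f = ms.allele_frequencies(small_mixed_gm, "L3")
        assert f.n_gene_copies == 6  # a1 missing at L3

    def test_all_missing_raises(self):
        gm = make_genotype_matrix({"a": ("P", [None]), "b": ("P", [None])}, ["L"])
        with pytest.raises(ValueError, match="L"):
            ms.allele_frequencies(gm, "L")

    def test_estimates_within_binomial_ci_at_n500(self):
        rng = np.random.default_rng(99)
        p_true = 0.3
        calls = {}
        for i in range(500):
            a, b = rng.choice([100, 102], size=2, p=[p_true, 1 - p_true])
            calls[f"i{i}"] = ("P", [tuple(sorted((int(a), int(b))))])
        gm = make_genotype_matrix(calls, ["L"])
        f = ms.allele_frequencies(gm, "L")
        se = np.sqrt(p_true * (1 - p_true) / 1000)
        assert abs(f.freqs[100] - p_true) < 2.58 * se * 1.5


class TestDiversityIndices:
    @pytest.mark.parametrize("p,he", [((1.0,), 0.0), ((0.5, 0.5), 0.5),
                                      ((0.25,) * 4, 0.75)])
    def test_expected_heterozygosity_closed_forms(self, p, he):
        assert ms.expected_heterozygosity(freqs(*p)) == pytest.approx(he)

    def test_observed_heterozygosity(self, small_mixed_gm):
        assert ms.observed_heterozygosity(
            small_mixed_gm, "L1", subset=["a1", "a2"]) == 0.5

    def test_all_homozygotes_gives_zero(self, two_fixed_pops):
        assert ms.observed_heterozygosity(two_fixed_pops, "L1") == 0.0

    def test_hwe_simulation_ho_close_to_he(self):
        spec = IslandModelSpec(n_pops=1, n_individuals_per_pop=500,
                               n_loci=20, target_fst=1e-6, seed=5)
        gm, _ = simulate_genotypes_island(spec)
        ho = np.mean([ms.observed_heterozygosity(gm, l) for l in gm.loci])
        he = np.mean([ms.expected_heterozygosity(ms.allele_frequencies(gm, l))
                      for l in gm.loci])
        assert ho == pytest.approx(he, abs=0.03)

    @pytest.mark.parametrize("p,expected", [
        ((1.0,), 0.0),
        ((0.5, 0.5), 0.375),
        ((0.25,) * 4, 0.703125),
    ])
    def test_pic_powermarker_closed_forms(self, p, expected):
        assert ms.pic(freqs(*p)) == pytest.approx(expected, abs=1e-12)

    def test_pic_equals_brute_force_double_sum(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            k = int(rng.integers(1, 8))
            p = rng.dirichlet(np.ones(k))
            f = freqs(*p)
            brute = 1.0 - sum(x ** 2 for x in p) - sum(
                2 * p[i] ** 2 * p[j] ** 2
                for i in range(k) for j in range(i + 1, k))
            assert ms.pic(f) == pytest.approx(brute, abs=1e-12)

    def test_pic_homozygosity_sum_variant(self):
        assert ms.pic(freqs(0.5, 0.5), "homozygosity_sum") == pytest.approx(0.5)

    @pytest.mark.parametrize("p,expected", [
        ((1.0,), 0.0),
        ((0.5, 0.5), np.log(2)),
        ((0.2,) * 5, np.log(5)),
    ])
    def test_shannon_index(self, p, expected):
        assert ms.shannon_index(freqs(*p)) == pytest.approx(expected)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8))
    def test_pic_bounded_by_he_on_simplex(self, weights):
        p = np.array(weights) / np.sum(weights)
        f = freqs(*p)
        he = ms.expected_heterozygosity(f)
        val = ms.pic(f)
        assert 0.0 <= val <= he + 1e-12 <= 1.0 + 1e-12

    def test_table_arithmetic_helpers(self):
        assert ms.mean_alleles_per_marker(207, 69) == 3.0
        assert ms.homo_hetero_ratio(12, 6) == "2:1"


class TestFst:
    def test_identical_frequencies_give_zero(self):
        calls = {}
        for pop in ("P1", "P2"):
            for i in range(6):
                call = (100, 102) if i % 2 else (100, 100)
                calls[f"{pop}_{i}"] = (pop, [call] * 4)
        gm = make_genotype_matrix(calls, [f"L{j}" for j in range(4)])
        assert ms.pairwise_fst(gm, "P1", "P2", "nei_gst") == pytest.approx(0.0)

    def test_fixed_different_alleles_gst_is_one(self, two_fixed_pops):
        assert ms.pairwise_fst(two_fixed_pops, "PopA", "PopB",
                               "nei_gst") == pytest.approx(1.0)

    def test_near_zero_differentiation_limit(self):
        gm, _ = simulate_genotypes_island(IslandModelSpec(
            n_pops=2, n_individuals_per_pop=50, n_loci=50,
            target_fst=1e-6, seed=17))
        assert abs(ms.weir_cockerham_theta(gm)) < 0.02

    def test_island_model_recovery_of_target(self):
        # three levels of differentiation; 10 replicates each
        for target in (0.05, 0.15, 0.30):
            thetas = []
            for rep in range(10):
                gm, _ = simulate_genotypes_island(IslandModelSpec(
                    n_pops=3, n_individuals_per_pop=50, n_loci=50,
                    target_fst=target, seed=1000 + 17 * rep))
                thetas.append(ms.weir_cockerham_theta(gm))
            assert np.mean(thetas) == pytest.approx(target, abs=0.05)

    def test_missing_data_tolerated(self):
        gm, _ = simulate_genotypes_island(IslandModelSpec(
            n_pops=2, n_individuals_per_pop=30, n_loci=30,
            target_fst=0.2, missing_rate=0.1, seed=3))
        theta = ms.weir_cockerham_theta(gm)
        assert 0.0 < theta < 0.5


class TestAmova:
    def test_all_identical_individuals_zero_components(self):
        calls = {f"x{i}": ("P1" if i < 4 else "P2", [(100, 100)] * 3)
                 for i in range(8)}
        gm = make_genotype_matrix(calls, ["L1", "L2", "L3"])
        res = ms.amova(gm)
        assert res.sigma2_among == 0.0 and res.sigma2_within == 0.0
        assert res.phi_pt == 0.0

    def test_fixed_populations_all_variance_among(self, two_fixed_pops):
        res = ms.amova(two_fixed_pops)
        assert res.pct_among == pytest.approx(100.0)
        assert res.phi_pt == pytest.approx(1.0)

    def test_percentages_sum_to_100(self):
        gm, _ = simulate_genotypes_island(IslandModelSpec(
            n_pops=3, n_individuals_per_pop=12, n_loci=20,
            target_fst=0.2, seed=8))
        res = ms.amova(gm)
        assert res.pct_among + res.pct_within == pytest.approx(100.0, abs=0.01)

    def test_sums_of_squares_match_brute_force(self):
        gm, _ = simulate_genotypes_island(IslandModelSpec(
            n_pops=3, n_individuals_per_pop=8, n_loci=10,
            target_fst=0.25, seed=12))
        dm = ms.genetic_distance(gm)
        res = ms.amova(gm, dm)
        labels = dm.labels
        pops = dict(zip(gm.accessions, gm.populations))
        n = len(labels)
        ss_total = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                ss_total += dm.d[i, j] ** 2
        ss_total /= n
        ss_within = 0.0
        for pop in set(pops.values()):
            members = [k for k, l in enumerate(labels) if pops[l] == pop]
            acc = 0.0
            for i in members:
                for j in members:
                    if i < j:
                        acc += dm.d[i, j] ** 2
            ss_within += acc / len(members)
        assert res.ss_among == pytest.approx(ss_total - ss_within, abs=1e-10)
        assert res.ss_within == pytest.approx(ss_within, abs=1e-10)

    def test_singleton_population_excluded_with_warning(self):
        calls = {f"x{i}": ("P1" if i < 4 else "P2", [(100, 100 + 2 * (i % 3))])
                 for i in range(8)}
        calls["solo"] = ("P3", [(120, 120)])
        gm = make_genotype_matrix(calls, ["L1"])
        with pytest.warns(UserWarning, match="P3"):
            ms.amova(gm)


class TestGeneticDistance:
    def test_identical_genotypes_distance_zero(self):
        calls = {"a": ("P", [(100, 102), (150, 150)]),
                 "b": ("P", [(100, 102), (150, 150)])}
        gm = make_genotype_matrix(calls, ["L1", "L2"])
        assert ms.genetic_distance(gm).d[0, 1] == 0.0

    def test_disjoint_alleles_distance_one(self):
        calls = {"a": ("P", [(100, 102), (150, 152)]),
                 "b": ("P", [(104, 106), (154, 156)])}
        gm = make_genotype_matrix(calls, ["L1", "L2"])
        assert ms.genetic_distance(gm).d[0, 1] == 1.0

    def test_matches_brute_force_per_pair(self):
        gm, _ = simulate_genotypes_island(IslandModelSpec(
            n_pops=2, n_individuals_per_pop=10, n_loci=12,
            target_fst=0.2, seed=77))
        dm = ms.genetic_distance(gm)
        for i in range(gm.n_accessions):
            for j in range(i + 1, gm.n_accessions):
                per_locus = []
                for l in range(gm.n_loci):
                    ci, cj = gm.calls[i][l], gm.calls[j][l]
                    if ci is None or cj is None:
                        continue
                    shared = 0
                    used = list(cj)
                    for a in ci:
                        if a in used:
                            used.remove(a)
                            shared += 1
                    per_locus.append(1 - shared / 2)
                assert dm.d[i, j] == pytest.approx(np.mean(per_locus))

    def test_no_shared_locus_raises_naming_pair(self):
        calls = {"a": ("P", [(100, 100), None]),
                 "b": ("P", [None, (100, 100)])}
        gm = make_genotype_matrix(calls, ["L1", "L2"])
        with pytest.raises(ValueError, match="'a'.*'b'"):
            ms.genetic_distance(gm)


def tree_tip_distance(tree, a, b):
    ta = tree.find(a)
    tb = tree.find(b)
    return ta.distance(tb)


def bipartitions(tree):
    tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        out.add(min(side, tips - side, key=sorted))
    return out, tips


class TestNeighborJoining:
    ADDITIVE = np.array([
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0.0],
    ])

    def test_additive_four_taxon_exact_recovery(self):
        dm = ms.DistanceMatrix(list("ABCD"), self.ADDITIVE)
        tree = ms.neighbor_joining(dm)
        # exact tip-to-tip distances (additivity)
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert tree_tip_distance(tree, a, b) == pytest.approx(
                        self.ADDITIVE[i, j])
        # AB|CD split with leaf edges 1, 2, 3, 4 and internal edge 1
        parts, _ = bipartitions(tree)
        assert frozenset({"A", "B"}) in parts or frozenset({"C", "D"}) in parts
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})

    def test_three_taxa_three_point_formulas(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0.0]])
        tree = ms.neighbor_joining(ms.DistanceMatrix(list("ABC"), d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 2.0, "B": 3.0, "C": 7.0})

    def test_random_additive_matrices_recover_topology_and_lengths(self):
        import random as pyrandom

        import dendropy
        rng = np.random.default_rng(123)
        for rep in range(50):
            n = int(rng.integers(5, 13))
            taxa = [f"t{i}" for i in range(n)]
            ns = dendropy.TaxonNamespace(taxa)
            true = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
                taxon_namespace=ns, rng=pyrandom.Random(1000 + rep))
            for e in true.preorder_edge_iter():
                e.length = float(rng.uniform(0.1, 2.0))
            pdm = true.phylogenetic_distance_matrix()
            tx = {t.label: t for t in true.taxon_namespace}
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = pdm.distance(tx[taxa[i]], tx[taxa[j]])
            tree = ms.neighbor_joining(ms.DistanceMatrix(taxa, d))
            for i in range(n):
                for j in range(i + 1, n):
                    assert tree_tip_distance(tree, taxa[i], taxa[j]) == \
                        pytest.approx(d[i, j], abs=1e-8)

    def test_three_population_panel_monophyletic_clusters(self):
        gm, _ = simulate_genotypes_island(IslandModelSpec(
            n_pops=3, n_individuals_per_pop=10, n_loci=50,
            target_fst=0.30, seed=2018))
        dm = ms.genetic_distance(gm)
        tree = ms.neighbor_joining(dm)
        parts, tips = bipartitions(tree)
        pops = dict(zip(gm.accessions, gm.populations))
        for pop in ("Pop1", "Pop2", "Pop3"):
            members = frozenset(a for a in gm.accessions if pops[a] == pop)
            canon = min(members, tips - members, key=sorted)
            assert canon in parts, f"{pop} not monophyletic"

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            ms.DistanceMatrix(list("ABC"),
                              np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]]))


class TestPcoa:
    def test_collinear_points_single_axis(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0.0]])
        res = ms.pcoa(ms.DistanceMatrix(list("ABC"), d))
        assert res.pct_variance[0] == pytest.approx(100.0)

    def test_euclidean_embedding_reconstructs_distances(self, rng):
        pts = rng.normal(size=(10, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = ms.pcoa(ms.DistanceMatrix([f"p{i}" for i in range(10)], d))
        rec = np.sqrt(((res.coordinates[:, None, :]
                        - res.coordinates[None, :, :]) ** 2).sum(-1))
        assert np.allclose(rec, d, atol=1e-8)

    def test_eigenvalues_match_dense_solver_oracle(self, rng):
        n = 12
        m = rng.random((n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        dm = ms.DistanceMatrix([f"s{i}" for i in range(n)], d)
        res = ms.pcoa(dm)
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d ** 2) @ j
        expected = np.sort(np.linalg.eigvalsh(b))[::-1]
        assert np.allclose(res.eigenvalues, expected, atol=1e-9)

    def test_pct_variance_non_increasing(self, rng):
        gm, _ = simulate_genotypes_island(IslandModelSpec(
            n_pops=3, n_individuals_per_pop=8, n_loci=15,
            target_fst=0.2, seed=55))
        res = ms.pcoa(ms.genetic_distance(gm))
        assert all(a >= b - 1e-12 for a, b in
                   zip(res.pct_variance, res.pct_variance[1:]))


class TestStructureCluster:
    def test_k1_memberships_all_one(self, small_mixed_gm):
        res = ms.structure_cluster(small_mixed_gm, K=1, n_iter=50, burn_in=10,
                                   seed=1)
        assert np.allclose(res.assignments.to_numpy(), 1.0)
        assert np.isfinite(res.ln_prob_data)

    def test_separable_populations_recovered_at_k2(self, two_fixed_pops):
        res = ms.structure_cluster(two_fixed_pops, K=2, n_iter=100, burn_in=50,
                                   seed=2)
        hard = res.assignments.to_numpy().argmax(axis=1)
        pops = np.array([0 if p == "PopA" else 1
                         for p in two_fixed_pops.populations])
        agreement = max(np.mean(hard == pops), np.mean(hard == 1 - pops))
        assert agreement >= 0.99

    def test_same_seed_bit_identical(self, small_mixed_gm):
        a = ms.structure_cluster(small_mixed_gm, K=2, n_iter=40, burn_in=10,
                                 seed=7)
        b = ms.structure_cluster(small_mixed_gm, K=2, n_iter=40, burn_in=10,
                                 seed=7)
        assert a.ln_prob_data == b.ln_prob_data
        assert a.assignments.equals(b.assignments)

    def test_memberships_rows_sum_to_one(self, small_mixed_gm):
        res = ms.structure_cluster(small_mixed_gm, K=3, n_iter=40, burn_in=10,
                                   seed=3)
        assert np.allclose(res.assignments.sum(axis=1), 1.0, atol=1e-9)

    def test_k_exceeding_n_raises(self, small_mixed_gm):
        with pytest.raises(ValueError):
            ms.structure_cluster(small_mixed_gm, K=10)


class TestEvannoDeltaK:
    def test_linear_lnp_gives_zero(self):
        runs = pd.DataFrame({k: [-1000 + 50 * k + off for off in (0, 1, -1)]
                             for k in range(1, 6)})
        dk = ms.evanno_delta_k(runs)
        assert np.allclose(dk.to_numpy(), 0.0)

    def test_hand_computed_kink_table(self):
        # L(K) linear up to K=3 then flat; per-run offsets (0,-2,+2) cancel
        # in the second difference, so |L''(3)| = 95 for every run, and
        # sd(L(3)) = 2  =>  delta-K(3) = 47.5 by the definition
        table = pd.DataFrame({
            1: [-500, -502, -498],
            2: [-400, -402, -398],
            3: [-300, -302, -298],
            4: [-295, -297, -293],
            5: [-290, -292, -288],
        }, dtype=float)
        dk = ms.evanno_delta_k(table)
        assert dk[2] == pytest.approx(0.0)   # still on the linear stretch
        assert dk[3] == pytest.approx(47.5)
        assert dk[4] == pytest.approx(0.0)
        assert dk.idxmax() == 3

    def test_zero_sd_warns_infinite(self):
        table = pd.DataFrame({1: [-500.0, -500.0], 2: [-400.0, -400.0],
                              3: [-390.0, -390.0]})
        with pytest.warns(UserWarning):
            dk = ms.evanno_delta_k(table)
        assert np.isinf(dk[2])

    def test_needs_three_consecutive_k(self):
        with pytest.raises(ValueError):
            ms.evanno_delta_k(pd.DataFrame({1: [0.0, 0.0], 3: [0.0, 0.0],
                                            5: [0.0, 0.0]}))
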