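"""Synthetic-data generators: trees, rates, sequences, perturbations,
calibrations, gene content."""

import math

import numpy as np
import pytest
from scipy import stats

from molclock.simulate import (FocalColumnSpec, SimulationConfig,
                               evolve_alignment, generate_calibrations,
                               nni_neighbors, perturb_gene_tree,
                               simulate_birth_death_tree,
                               simulate_branch_rates,
                               simulate_presence_absence)
from molclock.tree import parse_newick
from molclock.treeprior import bd_kernel_cdf


class TestBirthDeathTree:
    def test_determinism(self):
        cfg = SimulationConfig(seed=42, n_tips=12)
        t1 = simulate_birth_death_tree(cfg)
        t2 = simulate_birth_death_tree(cfg)
        assert t1.to_newick() == t2.to_newick()

    def test_shape_and_conditioning(self):
        cfg = SimulationConfig(seed=7, n_tips=16, root_age=3000)
        t = simulate_birth_death_tree(cfg)
        assert t.n_tips == 16
        assert len(t.internal_ids) == 15  # n_tips - 1 internal nodes
        assert t.root_age == pytest.approx(3000.0)

    def test_node_ages_follow_conditioned_kernel(self):
        """Pooled non-root node ages match the birth-death kernel CDF."""
        cfg = SimulationConfig(seed=1, n_tips=8, root_age=3000,
                               birth_rate=0.08, death_rate=0.04)
        rng = np.random.default_rng(99)
        ages = []
        for _ in range(500):
            t = simulate_birth_death_tree(cfg, rng)
            ages.extend(t.ages[v] for v in t.internal_ids if v != t.root)
        ks = stats.kstest(np.array(ages) / 100.0,
                          lambda x: bd_kernel_cdf(x, 0.08, 0.04, 30.0))
        assert ks.statistic < 0.03

    def test_forward_method_matches_conditioning(self):
        cfg = SimulationConfig(seed=3, n_tips=8, root_age=3000,
                               birth_rate=0.6, death_rate=0.2)
        t = simulate_birth_death_tree(cfg, method="forward")
        assert t.n_tips == 8 and t.root_age == pytest.approx(3000.0)


class TestBranchRates:
    def test_strict_constant(self, quartet):
        cfg = SimulationConfig(seed=0, n_tips=4, clock="strict", mean_rate=0.03)
        r = simulate_branch_rates(quartet, cfg)
        nonroot = [v for v in range(quartet.n_nodes) if v != quartet.root]
        assert np.all(r[nonroot] == 0.03)

    def test_ir_mean_preserved(self, quartet):
        """Lognormal mean identity: E[rate] = m when log-mean = log m - s2/2."""
        cfg = SimulationConfig(seed=0, n_tips=4, clock="IR", sigma2=0.3,
                               mean_rate=0.03)
        rng = np.random.default_rng(5)
        draws = []
        for _ in range(20000 // 6):
            r = simulate_branch_rates(quartet, cfg, rng)
            draws.extend(r[v] for v in range(quartet.n_nodes)
                         if v != quartet.root)
        assert np.mean(draws) == pytest.approx(0.03, rel=0.01)

    def test_ar_degenerates_to_strict(self, quartet):
        cfg = SimulationConfig(seed=0, n_tips=4, clock="AR", sigma2=1e-12,
                               mean_rate=0.03)
        r = simulate_branch_rates(quartet, cfg)
        nonroot = [v for v in range(quartet.n_nodes) if v != quartet.root]
        assert np.allclose(r[nonroot], 0.03, rtol=1e-4)


class TestEvolveAlignment:
    def test_zero_length_identical(self, quartet):
        cfg = SimulationConfig(seed=0, n_tips=4, sites=50)
        a = evolve_alignment(quartet, np.zeros(quartet.n_nodes), cfg)
        assert len(set(a.sequences())) == 1

    def test_two_taxon_jc_pdistance(self):
        t = parse_newick("(A:1000,B:1000);")
        cfg = SimulationConfig(seed=2, n_tips=4, sites=100000, mean_rate=0.02)
        rates = np.array([0.02, 0.02, 0.0])
        a = evolve_alignment(t, rates, cfg)
        b_total = 0.02 * 10.0 * 2  # rate x duration(100 Ma units) x 2 branches
        expect = 0.75 * (1 - math.exp(-4 * b_total / 3))
        obs = float((a.codes[0] != a.codes[1]).mean())
        se = math.sqrt(expect * (1 - expect) / a.n_sites)
        assert abs(obs - expect) < 4 * se

    def test_stationary_frequencies(self):
        from molclock.models import hky
        t = parse_newick("(A:2000,B:2000);")
        cfg = SimulationConfig(seed=3, n_tips=4, sites=50000,
                               subst_model="hky", kappa=3.0, mean_rate=0.05)
        a = evolve_alignment(t, np.full(3, 0.05), cfg)
        freqs = np.bincount(a.codes.ravel(), minlength=4) / a.codes.size
        assert np.allclose(freqs, 0.25, atol=0.01)

    def test_determinism(self, quartet):
        cfg = SimulationConfig(seed=8, n_tips=4, sites=100)
        a1 = evolve_alignment(quartet, np.full(7, 0.02), cfg)
        a2 = evolve_alignment(quartet, np.full(7, 0.02), cfg)
        assert a1 == a2


class TestPerturbGeneTree:
    def test_zero_moves_identity(self, balanced_tree):
        t = perturb_gene_tree(balanced_tree, 0, seed=1)
        assert t.same_unrooted_topology(balanced_tree)

    def test_single_nni_on_quartet_gives_alternative(self, quartet):
        """4 taxa have exactly 3 quartets; one NNI must yield one of the
        other 2."""
        seen = set()
        for seed in range(10):
            t = perturb_gene_tree(quartet, 1, seed=seed)
            assert not t.same_unrooted_topology(quartet)
            seen.add(t.unrooted_splits())
        assert len(seen) <= 2

    def test_rf_distance_positive(self, balanced_tree):
        """Oracle: dendropy's RF distance on the perturbed topologies."""
        import dendropy
        tns = dendropy.TaxonNamespace()
        d0 = dendropy.Tree.get(data=balanced_tree.to_newick(),
                               schema="newick", taxon_namespace=tns)
        d0.encode_bipartitions()
        for seed in range(5):
            t = perturb_gene_tree(balanced_tree, 2, seed=seed)
            d1 = dendropy.Tree.get(data=t.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            rf = dendropy.calculate.treecompare.symmetric_difference(d0, d1)
            assert rf > 0

    def test_too_small_rejected(self):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="4 tips"):
            perturb_gene_tree(t, 1, seed=0)


class TestCalibrationGeneration:
    def test_joint_offsets_exact(self, quartet):
        cals = generate_calibrations(quartet, {"root": quartet.root},
                                     style="joint", offset=0.2)
        assert cals[0].tL == pytest.approx(0.8 * 3000)
        assert cals[0].tU == pytest.approx(1.2 * 3000)

    def test_min_fraction(self, quartet):
        node = quartet.mrca({"A", "B"})
        cals = generate_calibrations(quartet, {"ab": node}, style="min",
                                     offset=0.2)
        assert cals[0].tL == pytest.approx(0.8 * quartet.ages[node])
        assert cals[0].tU is None

    def test_bracket_property_random_trees(self):
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, n_tips=10)
            tree = simulate_birth_death_tree(cfg)
            internal = [v for v in tree.internal_ids]
            cals = generate_calibrations(
                tree, {f"n{v}": v for v in internal[:4]},
                style="joint", seed=seed, offset=0.3)
            for cal in cals:
                node = tree.mrca({cal.tip_a, cal.tip_b})
                assert cal.tL <= tree.ages[node] <= cal.tU


class TestPresenceAbsence:
    def test_null_effect_uniform_fisher_p(self, balanced_tree):
        """Effect 0: the focal column is independent of group membership."""
        pvals = []
        for rep in range(300):
            mat, _ = simulate_presence_absence(
                balanced_tree, n_background=0,
                focal_specs=[FocalColumnSpec(effect=0.0, base=0.5)],
                group_tips=["A", "B", "C", "D"], seed=rep)
            col = mat[:, 0]
            grp = np.isin(balanced_tree.labels, ["A", "B", "C", "D"])
            table = [[int(col[grp].sum()), int((1 - col[grp]).sum())],
                     [int(col[~grp].sum()), int((1 - col[~grp]).sum())]]
            pvals.append(stats.fisher_exact(table).pvalue)
        # discrete p-values: check no excess of small ones
        assert np.mean(np.array(pvals) <= 0.05) < 0.1

    def test_infinite_conservation_constant_columns(self, balanced_tree):
        mat, _ = simulate_presence_absence(
            balanced_tree, n_background=10, focal_specs=[],
            group_tips=[], seed=3, conservation=np.inf)
        assert np.all((mat.sum(axis=0) == 0) | (mat.sum(axis=0) == mat.shape[0]))

    def test_full_effect_perfect_separation(self, balanced_tree):
        mat, _ = simulate_presence_absence(
            balanced_tree, n_background=0,
            focal_specs=[FocalColumnSpec(effect=1.0, base=0.0)],
            group_tips=["A", "B"], seed=5)
        grp = np.isin(balanced_tree.labels, ["A", "B"])
        assert np.all(mat[grp, 0] == 1) and np.all(mat[~grp, 0] == 0)
        table = [[2, 0], [0, 6]]
        odds, _ = stats.fisher_exact(table)
        assert math.isinf(odds)

    def test_bad_probability_rejected(self, balanced_tree):
        with pytest.raises(ValueError):
            simulate_presence_absence(
                balanced_tree, 0, [FocalColumnSpec(effect=0.9, base=0.5)],
                ["A"], seed=0)
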