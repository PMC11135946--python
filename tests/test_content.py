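"""Genome-content distances, ordination, permutation test, association."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from molclock.content import (DistanceMatrix, PAMatrix, association_battery,
                              bh_adjust, canonical_kmer_hashes,
                              convergence_permutation_test, manhattan_matrix,
                              mash_matrix, minhash_sketch, nmds_embed,
                              phylo_signal)
from molclock.simulate import SimulationConfig, simulate_birth_death_tree


def _pa(matrix, groups=None):
    m = np.asarray(matrix)
    ids = [f"G{i}" for i in range(m.shape[0])]
    genes = [f"g{j}" for j in range(m.shape[1])]
    return PAMatrix(ids, genes, m, groups or {})


class TestManhattan:
    def test_hand_counts(self):
        d = manhattan_matrix(_pa([[1, 0, 1], [0, 0, 1], [1, 0, 1]]))
        assert d.values[0, 1] == 1
        assert d.values[0, 2] == 0
        assert d.values[1, 2] == 1

    def test_triangle_inequality(self, rng):
        m = (rng.uniform(size=(10, 30)) < 0.4).astype(int)
        d = manhattan_matrix(_pa(m)).values
        for i, j, k in itertools.permutations(range(10), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12

    def test_binary_enforced(self):
        with pytest.raises(ValueError):
            _pa([[0, 2]])


class TestMash:
    def test_identical_sequences_zero(self, rng):
        s = "".join(rng.choice(list("ACGT"), 3000))
        d = mash_matrix({"a": s, "b": s}, k=15, sketch_size=200)
        assert d.values[0, 1] == 0.0

    def test_disjoint_kmers_capped(self):
        d = mash_matrix({"a": "A" * 200, "b": "C" * 200}, k=11,
                        sketch_size=50, max_distance=1.0)
        assert d.values[0, 1] == 1.0

    def test_reverse_complement_canonical(self):
        s = "ACGTTGCAGGTACCGTAGGCTTAACGT" * 20
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[c] for c in reversed(s))
        assert np.array_equal(canonical_kmer_hashes(s, 15),
                              canonical_kmer_hashes(rc, 15))

    def test_deterministic(self, rng):
        s1 = "".join(rng.choice(list("ACGT"), 2000))
        s2 = "".join(rng.choice(list("ACGT"), 2000))
        d1 = mash_matrix({"a": s1, "b": s2}, k=15, sketch_size=100)
        d2 = mash_matrix({"a": s1, "b": s2}, k=15, sketch_size=100)
        assert np.array_equal(d1.values, d2.values)

    def test_k_too_large(self):
        with pytest.raises(ValueError, match="shorter than k"):
            minhash_sketch("ACGT", k=21)

    def test_formula(self, rng):
        s = "".join(rng.choice(list("ACGT"), 5000))
        arr = np.array(list(s))
        idx = rng.choice(5000, 150, replace=False)
        arr[idx] = rng.choice(list("ACGT"), 150)
        s2 = "".join(arr)
        d = mash_matrix({"a": s, "b": s2}, k=15, sketch_size=400)
        ha, hb = canonical_kmer_hashes(s, 15), canonical_kmer_hashes(s2, 15)
        j = len(np.intersect1d(ha, hb)) / len(np.union1d(ha, hb))
        expect = -math.log(2 * j / (1 + j)) / 15
        assert d.values[0, 1] == pytest.approx(expect, rel=0.2)


class TestNmds:
    def test_euclidean_input_recovered(self, rng):
        pts = rng.normal(size=(12, 2))
        from scipy.spatial.distance import pdist, squareform
        d = DistanceMatrix([f"p{i}" for i in range(12)],
                           squareform(pdist(pts)))
        res = nmds_embed(d, dims=2, seed=1)
        assert res.stress < 0.01

    def test_stress_nesting_in_dimensions(self, rng):
        m = (rng.uniform(size=(14, 40)) < 0.3).astype(int)
        d = manhattan_matrix(_pa(m))
        s2 = nmds_embed(d, dims=2, seed=4).stress
        s3 = nmds_embed(d, dims=3, seed=4).stress
        assert s3 <= s2 + 1e-6

    def test_duplicate_items_coincide(self, rng):
        m = (rng.uniform(size=(8, 30)) < 0.4).astype(int)
        m[3] = m[0]
        d = manhattan_matrix(_pa(m))
        res = nmds_embed(d, dims=2, seed=2)
        c = res.coordinates.values
        assert np.linalg.norm(c[3] - c[0]) < 1e-3 * np.abs(c).max()

    def test_too_few_items(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            nmds_embed(d, dims=2)


class TestPermutationTest:
    def _matrices(self, rng, n=10):
        ids = [f"G{i}" for i in range(n)]
        m = rng.exponential(1.0, size=(n, n))
        v = np.triu(m, 1) + np.triu(m, 1).T
        return ids, DistanceMatrix(ids, v)

    def test_identical_matrices_statistic_zero(self, rng):
        ids, d = self._matrices(rng)
        res = convergence_permutation_test(d, d, ids[:3], ids[3:6],
                                           n_perm=99, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.null_distribution, 0.0)

    def test_p_respects_add_one_rule(self, rng):
        ids, d1 = self._matrices(rng)
        _, d2 = self._matrices(rng)
        res = convergence_permutation_test(d1, d2, ids[:3], ids[3:6],
                                           n_perm=99, seed=1)
        assert res.p_value >= 1 / 100

    def test_group_and_nperm_validation(self, rng):
        ids, d = self._matrices(rng)
        with pytest.raises(ValueError, match="n_perm"):
            convergence_permutation_test(d, d, ids[:2], ids[2:4], n_perm=10)
        with pytest.raises(ValueError, match="disjoint"):
            convergence_permutation_test(d, d, ids[:3], ids[2:5], n_perm=99)

    def test_rank_normalization_available(self, rng):
        ids, d1 = self._matrices(rng)
        _, d2 = self._matrices(rng)
        res = convergence_permutation_test(d1, d2, ids[:3], ids[3:6],
                                           n_perm=99, seed=1,
                                           normalization="rank")
        assert 0 < res.p_value <= 1


class TestPhyloSignal:
    @pytest.fixture(scope="class")
    def tree(self):
        return simulate_birth_death_tree(
            SimulationConfig(seed=13, n_tips=24, root_age=3000))

    def test_brownian_trait_high_lambda(self, tree):
        from molclock.content import _tree_vcv
        C = _tree_vcv(tree)
        rng = np.random.default_rng(3)
        lams = []
        for _ in range(50):
            x = rng.multivariate_normal(np.zeros(tree.n_tips), C / 1e6)
            lams.append(phylo_signal(tree, x).lam)
        assert 0.8 <= np.median(lams) <= 1.0

    def test_iid_noise_low_lambda_conservative_p(self, tree):
        """Under the boundary null (lambda = 0) the LR statistic is a 0 /
        chi2_1 mixture, so p-values are super-uniform: type-I error is
        controlled, with an atom of p-values at 1."""
        rng = np.random.default_rng(4)
        lams, ps = [], []
        for _ in range(50):
            res = phylo_signal(tree, rng.normal(size=tree.n_tips))
            lams.append(res.lam)
            ps.append(res.p_value)
        assert np.median(lams) < 0.2
        assert np.mean(np.asarray(ps) <= 0.05) <= 0.1

    def test_ml_at_least_boundary_values(self, tree, rng):
        from molclock.content import _lambda_loglik, _tree_vcv
        C = _tree_vcv(tree)
        x = rng.normal(size=tree.n_tips)
        res = phylo_signal(tree, x)
        assert res.loglik >= _lambda_loglik(0.0, x, C) - 1e-8
        assert res.loglik >= _lambda_loglik(1.0, x, C) - 1e-8

    def test_zero_variance_rejected(self, tree):
        with pytest.raises(ValueError, match="variance"):
            phylo_signal(tree, np.ones(tree.n_tips))


class TestBhAdjust:
    def test_single_and_constant(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_known_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_monotone_and_clipped(self, rng):
        p = rng.uniform(size=30)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestAssociationBattery:
    @pytest.fixture(scope="class")
    def setup(self):
        tree = simulate_birth_death_tree(
            SimulationConfig(seed=17, n_tips=12, root_age=3000))
        ids = tree.labels
        rng = np.random.default_rng(8)
        focal = np.array([1] * 4 + [0] * 8)
        linked = focal.copy()
        noise = (rng.uniform(size=12) < 0.5).astype(int)
        mat = np.column_stack([focal, linked, noise])
        groups = {g: ("in" if focal[i] else "out") for i, g in enumerate(ids)}
        pa = PAMatrix(ids, ["amo", "linked", "noise"], mat, groups)
        return pa, tree

    def test_fisher_hand_value(self, setup):
        pa, tree = setup
        df = association_battery(pa, tree, {"c": (["in"], ["out"])}, "amo")
        row = df[df.gene == "amo"].iloc[0]
        # table [[4,0],[0,8]]: two-sided p = 2/C(12,4)
        assert row.fisher_p == pytest.approx(1 / math.comb(12, 4) * 1, rel=1e-6)

    def test_identical_column_r_one(self, setup):
        pa, tree = setup
        df = association_battery(pa, tree, {"c": (["in"], ["out"])}, "amo")
        assert df[df.gene == "linked"].iloc[0].pearson_r == pytest.approx(1.0)

    def test_adjusted_ge_raw_and_flag_consistent(self, setup):
        pa, tree = setup
        df = association_battery(pa, tree, {"c": (["in"], ["out"])}, "amo")
        for t in ("fisher", "pearson"):
            assert np.all(df[f"{t}_p_adj"] >= df[f"{t}_p"] - 1e-12)
        for _, r in df.iterrows():
            expect = r.fisher_p_adj < 0.05 and r.pearson_p_adj < 0.05
            assert r.passed == expect

    def test_empty_group_rejected(self, setup):
        pa, tree = setup
        with pytest.raises(ValueError, match="empty"):
            association_battery(pa, tree, {"c": (["nope"], ["out"])}, "amo")
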