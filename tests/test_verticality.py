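"""dLL congruence scoring and the screening protocols."""

import numpy as np
import pytest

from molclock.alignment import Alignment, DNA_ALPHABET
from molclock.calibrations import CladeRef
from molclock.mcmc import PosteriorSample
from molclock.models import jc
from molclock.simulate import (SimulationConfig, evolve_alignment,
                               perturb_gene_tree, simulate_birth_death_tree)
from molclock.verticality import (GeneFamily, clade_age_gap, compute_delta_ll,
                                  enumerate_unrooted_topologies,
                                  gene_removal_series, sliding_window_series)


@pytest.fixture(scope="module")
def five_taxon():
    cfg = SimulationConfig(seed=7, n_tips=5, sites=300, mean_rate=0.015,
                           root_age=3000)
    tree = simulate_birth_death_tree(cfg)
    rates = np.full(tree.n_nodes, 0.015)
    rates[tree.root] = 0.0
    return tree, rates, cfg


def test_topology_enumeration_counts():
    assert len(enumerate_unrooted_topologies(list("ABCD"))) == 3
    tops = enumerate_unrooted_topologies(list("ABCDE"))
    assert len(tops) == 15
    assert len({t.unrooted_splits() for t in tops}) == 15


class TestDeltaLL:
    def test_congruent_gene_zero(self, five_taxon, rng):
        tree, rates, cfg = five_taxon
        aln = evolve_alignment(tree, rates, cfg, rng)
        dll, _ = compute_delta_ll(aln, tree, jc())
        assert dll == pytest.approx(0.0, abs=0.2)

    def test_perturbed_gene_positive(self, five_taxon):
        tree, rates, cfg = five_taxon
        pt = perturb_gene_tree(tree, 1, seed=3)
        aln = evolve_alignment(pt, rates, cfg, np.random.default_rng(2),
                               durations=tree.durations() / 100.0)
        dll, best = compute_delta_ll(aln, tree, jc())
        assert dll > 2.0
        assert best.same_unrooted_topology(pt)

    def test_invariant_to_taxon_order(self, five_taxon, rng):
        tree, rates, cfg = five_taxon
        aln = evolve_alignment(tree, rates, cfg, rng)
        shuffled = aln.subset(list(reversed(aln.labels)))
        d1, _ = compute_delta_ll(aln, tree, jc())
        d2, _ = compute_delta_ll(shuffled, tree, jc())
        assert d1 == pytest.approx(d2, abs=1e-6)

    def test_nni_search_agrees_with_exhaustive_here(self, five_taxon):
        tree, rates, cfg = five_taxon
        pt = perturb_gene_tree(tree, 1, seed=5)
        aln = evolve_alignment(pt, rates, cfg, np.random.default_rng(4),
                               durations=tree.durations() / 100.0)
        d_ex, _ = compute_delta_ll(aln, tree, jc(), search="exhaustive")
        d_nni, _ = compute_delta_ll(aln, tree, jc(), search="nni")
        assert d_nni == pytest.approx(d_ex, abs=1e-6)

    def test_too_few_taxa(self, five_taxon):
        tree, _, _ = five_taxon
        a = Alignment.from_sequences(["T1", "T2", "T3"], ["ACG"] * 3,
                                     DNA_ALPHABET)
        with pytest.raises(ValueError, match="4 taxa"):
            compute_delta_ll(a, tree, jc())


def _stub_genes(dlls):
    a = Alignment.from_sequences(["T1", "T2", "T3", "T4"], ["ACGT"] * 4,
                                 DNA_ALPHABET)
    return [GeneFamily(f"g{i:02d}", a, delta_ll=d)
            for i, d in enumerate(dlls)]


def _stub_date_fn(tree, gap_by_call):
    """Returns a date_fn yielding fixed clade ages from a queue."""
    calls = {"i": 0}

    def date_fn(aln):
        ages_ab = gap_by_call[min(calls["i"], len(gap_by_call) - 1)]
        calls["i"] += 1
        n = 150
        node_ids = tree.internal_ids
        ages = np.zeros((n, len(node_ids)))
        for j, v in enumerate(node_ids):
            ages[:, j] = tree.ages[v]
        # overwrite the two focal total-group nodes
        a_tot = tree.total_group_node(tree.mrca({"T1", "T2"}))
        b_tot = tree.total_group_node(tree.mrca({"T3", "T4"}))
        ages[:, list(node_ids).index(a_tot)] = ages_ab[0]
        ages[:, list(node_ids).index(b_tot)] = ages_ab[1]
        return PosteriorSample(node_ids=node_ids, ages=ages,
                               mean_rate=np.full(n, 0.02),
                               sigma2=np.zeros(n), loglik=np.zeros(n),
                               logpost=np.zeros(n), tree=tree)

    return date_fn


@pytest.fixture
def stub_tree():
    from molclock.tree import parse_newick
    # focal stems distinct: total(T1,T2) at 1200 Ma, total(T3,T4) at 2000 Ma
    return parse_newick(
        "((((T1:500,T2:500):700,T0:1200):800,(T3:300,T4:300):1700):1000,"
        "(T5:1000,T6:1000):2000);")


class TestRemovalSeries:
    def test_drops_exactly_step_genes(self, stub_tree):
        genes = _stub_genes([5.0, 4.0, 3.0, 2.0, 1.0, 0.5, 0.4, 0.3, 0.2, 0.1])
        fn = _stub_date_fn(stub_tree, [(2000.0, 1400.0)])
        ca, cb = CladeRef("a", "T1", "T2"), CladeRef("b", "T3", "T4")
        traj = gene_removal_series(genes, fn, ca, cb, step=2, floor=4)
        counts = [r["n_genes"] for r in traj.rows]
        assert counts == [10, 8, 6, 4]

    def test_removes_largest_dll_first_with_name_ties(self, stub_tree):
        genes = _stub_genes([1.0, 1.0, 3.0, 0.1, 0.1, 0.1, 0.1, 0.1])
        fn = _stub_date_fn(stub_tree, [(2000.0, 1400.0)])
        ca, cb = CladeRef("a", "T1", "T2"), CladeRef("b", "T3", "T4")
        traj = gene_removal_series(genes, fn, ca, cb, step=2, floor=6)
        first_removed = set(g.name for g in genes) - set(
            traj.rows[1]["genes_retained"].split(","))
        assert first_removed == {"g02", "g00"}  # largest dLL, then name order

    def test_mean_dll_non_increasing(self, stub_tree, rng):
        genes = _stub_genes(sorted(rng.uniform(0, 10, 12), reverse=True))
        fn = _stub_date_fn(stub_tree, [(2000.0, 1400.0)])
        ca, cb = CladeRef("a", "T1", "T2"), CladeRef("b", "T3", "T4")
        traj = gene_removal_series(genes, fn, ca, cb, step=2, floor=6)
        assert np.all(np.diff(traj.mean_dlls) <= 1e-12)

    def test_date_failure_truncates_with_error(self, stub_tree):
        genes = _stub_genes([3.0, 2.0, 1.0, 0.5, 0.4, 0.3, 0.2, 0.1])
        state = {"i": 0}

        def failing(aln):
            state["i"] += 1
            if state["i"] == 2:
                raise RuntimeError("boom")
            return _stub_date_fn(stub_tree, [(2000.0, 1400.0)])(aln)

        ca, cb = CladeRef("a", "T1", "T2"), CladeRef("b", "T3", "T4")
        traj = gene_removal_series(genes, failing, ca, cb, step=2, floor=4)
        assert len(traj.rows) == 1 and "boom" in traj.error


class TestSlidingWindow:
    def test_window_count(self, stub_tree):
        genes = _stub_genes(np.linspace(0, 5, 9))
        fn = _stub_date_fn(stub_tree, [(2000.0, 1400.0)])
        ca, cb = CladeRef("a", "T1", "T2"), CladeRef("b", "T3", "T4")
        traj = sliding_window_series(genes, fn, ca, cb, k=6)
        assert len(traj.rows) == 9 - 6 + 1

    def test_full_window_equals_all_genes(self, stub_tree):
        genes = _stub_genes(np.linspace(0, 5, 8))
        fn = _stub_date_fn(stub_tree, [(2000.0, 1400.0)])
        ca, cb = CladeRef("a", "T1", "T2"), CladeRef("b", "T3", "T4")
        traj = sliding_window_series(genes, fn, ca, cb, k=8)
        assert len(traj.rows) == 1
        assert traj.rows[0]["n_genes"] == 8

    def test_window_mean_dll_non_decreasing(self, stub_tree, rng):
        genes = _stub_genes(rng.uniform(0, 10, 10))
        fn = _stub_date_fn(stub_tree, [(2000.0, 1400.0)])
        ca, cb = CladeRef("a", "T1", "T2"), CladeRef("b", "T3", "T4")
        traj = sliding_window_series(genes, fn, ca, cb, k=4)
        assert np.all(np.diff(traj.mean_dlls) >= -1e-12)

    def test_oversized_window_rejected(self, stub_tree):
        genes = _stub_genes([1.0, 2.0])
        ca, cb = CladeRef("a", "T1", "T2"), CladeRef("b", "T3", "T4")
        with pytest.raises(ValueError, match="window"):
            sliding_window_series(genes, lambda a: None, ca, cb, k=5)


class TestCladeAgeGap:
    def test_same_clade_zero(self, stub_tree):
        fn = _stub_date_fn(stub_tree, [(2000.0, 1400.0)])
        post = fn(None)
        ca = CladeRef("a", "T1", "T2")
        assert clade_age_gap(post, ca, ca) == 0.0

    def test_sign_convention(self, stub_tree):
        """B 100 Ma younger than A => gap = -100 (negative: A older)."""
        fn = _stub_date_fn(stub_tree, [(1500.0, 1400.0)])
        post = fn(None)
        gap = clade_age_gap(post, CladeRef("a", "T1", "T2"),
                            CladeRef("b", "T3", "T4"))
        assert gap == pytest.approx(-100.0)

    def test_equals_bruteforce_trace_mean(self, stub_tree, rng):
        node_ids = stub_tree.internal_ids
        n = 300
        ages = np.tile([stub_tree.ages[v] for v in node_ids], (n, 1))
        ages += rng.normal(0, 20, ages.shape)
        post = PosteriorSample(node_ids=node_ids, ages=ages,
                               mean_rate=np.full(n, 0.02),
                               sigma2=np.zeros(n), loglik=np.zeros(n),
                               logpost=np.zeros(n), tree=stub_tree)
        ca, cb = CladeRef("a", "T1", "T2"), CladeRef("b", "T3", "T4")
        a_tot = stub_tree.total_group_node(stub_tree.mrca({"T1", "T2"}))
        b_tot = stub_tree.total_group_node(stub_tree.mrca({"T3", "T4"}))
        cols = list(node_ids)
        oracle = (ages[:, cols.index(b_tot)].mean()
                  - ages[:, cols.index(a_tot)].mean())
        assert clade_age_gap(post, ca, cb) == pytest.approx(oracle)
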