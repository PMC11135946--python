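"""The dating sampler: summaries, diagnostics, and exactness of the
prior-only chain against a rejection-sampling oracle."""

import math

import numpy as np
import pytest
from scipy import stats

from molclock.calibrations import Calibration, CladeRef
from molclock.mcmc import (ClockModel, McmcSettings, PosteriorSample,
                           check_convergence, clade_ages, hpd_interval,
                           run_chain, summarize)
from molclock.simulate import generate_calibrations
from molclock.tree import parse_newick


def _fake_posterior(tree, ages_by_node, n=200):
    node_ids = tree.internal_ids
    ages = np.tile([ages_by_node[int(v)] for v in node_ids], (n, 1))
    return PosteriorSample(node_ids=node_ids, ages=ages,
                           mean_rate=np.full(n, 0.02), sigma2=np.zeros(n),
                           loglik=np.zeros(n), logpost=np.zeros(n), tree=tree)


class TestHpd:
    def test_matches_bruteforce_window_scan(self, rng):
        draws = rng.lognormal(7, 0.4, 1500)
        lo, hi = hpd_interval(draws, 0.95)
        x = np.sort(draws)
        k = math.ceil(0.95 * len(x))
        best = min((x[i + k - 1] - x[i], i) for i in range(len(x) - k + 1))
        assert (lo, hi) == (pytest.approx(x[best[1]]),
                            pytest.approx(x[best[1] + k - 1]))

    def test_symmetric_sample_close_to_central(self, rng):
        draws = rng.normal(100, 10, 20000)
        lo, hi = hpd_interval(draws, 0.95)
        assert lo == pytest.approx(np.quantile(draws, 0.025), abs=1.0)
        assert hi == pytest.approx(np.quantile(draws, 0.975), abs=1.0)

    def test_constant_sample(self):
        lo, hi = hpd_interval(np.full(300, 7.0))
        assert (lo, hi) == (7.0, 7.0)


def test_summarize_requires_enough_draws(quartet):
    post = _fake_posterior(quartet, {4: 3000.0, 5: 1000.0, 6: 500.0}, n=50)
    with pytest.raises(ValueError, match="too few"):
        summarize(post)
    s = summarize(_fake_posterior(quartet, {4: 3000.0, 5: 1000.0, 6: 500.0}))
    row = s[s.node == quartet.root].iloc[0]
    assert (row["mean"], row.hpd_lo, row.hpd_hi) == (3000.0, 3000.0, 3000.0)


def test_clade_ages_crown_vs_total(quartet):
    post = _fake_posterior(quartet, {4: 3000.0, 5: 1000.0, 6: 500.0})
    crown = clade_ages(post, CladeRef("ab", "A", "B", "crown"))
    total = clade_ages(post, CladeRef("ab", "A", "B", "total"))
    assert np.all(crown == 1000.0) and np.all(total == 3000.0)
    assert np.all(crown <= total)
    with pytest.raises(ValueError, match="root"):
        clade_ages(post, CladeRef("all", "A", "C", "total"))


class TestRunChain:
    def test_requires_root_upper_bound(self, quartet):
        cals = [Calibration(tip_a="A", tip_b="B", kind="min", tL=500)]
        with pytest.raises(ValueError, match="root"):
            run_chain(quartet, cals, ClockModel("strict"),
                      McmcSettings(n_iter=100, prior_only=True), seed=0)

    def test_draws_respect_age_ordering(self, quartet):
        cals = generate_calibrations(quartet, {"root": quartet.root},
                                     style="joint", offset=0.2)
        post = run_chain(quartet, cals, ClockModel("strict"),
                         McmcSettings(n_iter=600, prior_only=True), seed=1)
        for v in quartet.internal_ids:
            if v != quartet.root:
                assert np.all(post.ages_for(int(quartet.parent[v]))
                              > post.ages_for(int(v)))

    def test_prior_chain_matches_rejection_oracle(self, quartet):
        """The full move set (slides, root scaling, whole-tree scaling)
        leaves the prior invariant: compare with direct rejection sampling."""
        cals = [Calibration(name="root", tip_a="A", tip_b="C", kind="joint",
                            tL=2400, tU=3600),
                Calibration(name="ab", tip_a="A", tip_b="B", kind="joint",
                            tL=800, tU=1200)]
        post = run_chain(quartet, cals, ClockModel("strict"),
                         McmcSettings(n_iter=24000, thin=2, prior_only=True),
                         seed=5)
        rng = np.random.default_rng(11)
        n = 40000
        roots = cals[0].sample(rng, 2000)
        roots = rng.choice(roots, n)
        t_ab = rng.choice(cals[1].sample(rng, 2000), n)
        from molclock.treeprior import bd_kernel_cdf
        u = rng.uniform(size=n)
        lo = np.zeros(n)
        hi = roots / 100.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            below = bd_kernel_cdf(mid, 0.08, 0.04, roots / 100.0) < u
            lo, hi = np.where(below, mid, lo), np.where(below, hi, mid)
        t_cd = 0.5 * (lo + hi) * 100.0
        keep = (roots > t_ab) & (roots > t_cd)
        for node, oracle in ((quartet.root, roots[keep]),
                             (quartet.mrca({"A", "B"}), t_ab[keep]),
                             (quartet.mrca({"C", "D"}), t_cd[keep])):
            ks = stats.ks_2samp(post.ages_for(node), oracle).statistic
            assert ks < 0.035

    def test_deterministic_given_seed(self, quartet):
        cals = generate_calibrations(quartet, {"root": quartet.root},
                                     style="joint", offset=0.2)
        kw = dict(topology=quartet, calibrations=cals,
                  clock=ClockModel("IR"), seed=9,
                  settings=McmcSettings(n_iter=500, prior_only=True))
        p1, p2 = run_chain(**kw), run_chain(**kw)
        assert np.array_equal(p1.ages, p2.ages)
        assert np.array_equal(p1.sigma2, p2.sigma2)

    def test_relaxed_prior_rate_marginals(self, quartet):
        """IR prior-only: branch-rate hyperparameter marginals stay at their
        hyperpriors (mean log-rate normal; the chain must not drift)."""
        cals = generate_calibrations(quartet, {"root": quartet.root},
                                     style="joint", offset=0.2)
        clock = ClockModel("IR", mu0=math.log(0.02), sd0=0.4,
                           tau_alpha=3.0, tau_beta=1.0)
        post = run_chain(quartet, cals, clock,
                         McmcSettings(n_iter=12000, thin=2, prior_only=True),
                         seed=3)
        logmu = np.log(post.mean_rate)
        assert logmu.mean() == pytest.approx(clock.mu0, abs=0.05)
        assert logmu.std() == pytest.approx(0.4, rel=0.15)


class TestConvergence:
    def _chain(self, quartet, seed):
        cals = generate_calibrations(quartet, {"root": quartet.root},
                                     style="joint", offset=0.2)
        return run_chain(quartet, cals, ClockModel("strict"),
                         McmcSettings(n_iter=6000, prior_only=True), seed=seed)

    def test_chain_vs_itself(self, quartet):
        c = self._chain(quartet, 1)
        rep = check_convergence(c, c)
        assert rep.correlation == pytest.approx(1.0)
        assert rep.max_abs_diff == 0.0

    def test_two_long_chains_pass(self, quartet):
        rep = check_convergence(self._chain(quartet, 1), self._chain(quartet, 2))
        assert rep.passed, rep

    def test_short_chains_warn_insufficient_ess(self, quartet):
        cals = generate_calibrations(quartet, {"root": quartet.root},
                                     style="joint", offset=0.2)
        short = [run_chain(quartet, cals, ClockModel("strict"),
                           McmcSettings(n_iter=40, thin=1, prior_only=True),
                           seed=s) for s in (1, 2)]
        rep = check_convergence(*short)
        assert any("insufficient ESS" in w for w in rep.warnings)
        assert not rep.passed

    def test_different_topologies_rejected(self, quartet, balanced_tree):
        cals_q = generate_calibrations(quartet, {"root": quartet.root},
                                       style="joint", offset=0.2)
        cals_b = generate_calibrations(balanced_tree,
                                       {"root": balanced_tree.root},
                                       style="joint", offset=0.2)
        c1 = run_chain(quartet, cals_q, ClockModel("strict"),
                       McmcSettings(n_iter=300, prior_only=True), seed=1)
        c2 = run_chain(balanced_tree, cals_b, ClockModel("strict"),
                       McmcSettings(n_iter=300, prior_only=True), seed=2)
        with pytest.raises(ValueError, match="topolog"):
            check_convergence(c1, c2)
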