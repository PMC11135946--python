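"""Posterior density fitting and two-step calibration propagation."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from molclock.calibrations import Calibration
from molclock.mcmc import ClockModel, McmcSettings, run_chain
from molclock.sequential import (FittedDensity, fit_posterior_density,
                                 propagate_calibrations)
from molclock.simulate import (SimulationConfig, generate_calibrations,
                               simulate_birth_death_tree)


class TestFitPosteriorDensity:
    def test_lognormal_self_fit(self, rng):
        x = rng.lognormal(7.0, 0.1, 4000)
        fd = fit_posterior_density(x)
        assert fd.family == "lognormal"
        s, scale = fd.params
        assert s == pytest.approx(0.1, rel=0.05)
        assert np.log(scale) == pytest.approx(7.0, rel=0.05)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_posterior_density(np.full(600, 5.0))

    def test_too_few_draws_rejected(self, rng):
        with pytest.raises(ValueError, match="500"):
            fit_posterior_density(rng.lognormal(7, 0.2, 100))

    def test_selected_family_has_smallest_ks(self, rng):
        x = rng.gamma(9.0, 120.0, 3000)
        fd = fit_posterior_density(x)
        from molclock.sequential import _FAMILIES, _fit_family
        for fam in _FAMILIES:
            try:
                _, _, cdf = _fit_family(fam, x)
            except Exception:
                continue
            assert fd.ks <= stats.kstest(x, cdf).statistic + 1e-12


class TestPropagation:
    @pytest.fixture(scope="class")
    def posterior(self):
        cfg = SimulationConfig(seed=21, n_tips=14, root_age=3000)
        tree = simulate_birth_death_tree(cfg)
        cals = generate_calibrations(tree, {"root": tree.root},
                                     style="joint", offset=0.2)
        return run_chain(tree, cals, ClockModel("strict"),
                         McmcSettings(n_iter=4000, thin=2, prior_only=True),
                         seed=2)

    def test_empty_map(self, posterior):
        assert propagate_calibrations(posterior, []) == []

    def test_twelve_shared_nodes_give_twelve_calibrations(self, posterior):
        tree = posterior.tree
        internal = [v for v in tree.internal_ids if v != tree.root][:12]
        shared = []
        for v in internal:
            ca, cb = tree.children[v]
            shared.append((min(tree.tip_set(ca)), min(tree.tip_set(cb))) * 2)
        cals = propagate_calibrations(posterior, shared)
        assert len(cals) == 12
        assert all(c.kind == "fitted_density" for c in cals)

    def test_propagated_densities_integrate_to_one(self, posterior):
        tree = posterior.tree
        v = [u for u in tree.internal_ids if u != tree.root][0]
        ca, cb = tree.children[v]
        pair = (min(tree.tip_set(ca)), min(tree.tip_set(cb)))
        for root_max in (None, 4000.0):
            cal = propagate_calibrations(posterior, [pair * 2],
                                         root_max=root_max)[0]
            hi = root_max if root_max else np.inf
            total = quad(lambda t: np.exp(cal.log_density(t)), 1e-6, hi,
                         limit=300)[0]
            assert total == pytest.approx(1.0, abs=1e-4)

    def test_truncation_respected(self, posterior):
        tree = posterior.tree
        v = [u for u in tree.internal_ids if u != tree.root][0]
        ca, cb = tree.children[v]
        pair = (min(tree.tip_set(ca)), min(tree.tip_set(cb)))
        cal = propagate_calibrations(posterior, [pair * 2], root_max=1500.0)[0]
        assert cal.log_density(2000.0) == -np.inf


class TestSequentialInvariants:
    @pytest.fixture(scope="class")
    def setup(self):
        from molclock.likelihood import fit_approx_surface
        from molclock.models import jc
        from molclock.simulate import (SimulationConfig, evolve_alignment,
                                       simulate_branch_rates)
        cfg = SimulationConfig(seed=31, n_tips=8, sites=800, clock="strict",
                               mean_rate=0.02, root_age=3000)
        tree = simulate_birth_death_tree(cfg)
        rng = np.random.default_rng(31)
        rates = simulate_branch_rates(tree, cfg, rng)
        block = evolve_alignment(tree, rates, cfg, rng)
        cals = generate_calibrations(tree, {"root": tree.root},
                                     style="joint", offset=0.2)
        internal = sorted((v for v in tree.internal_ids if v != tree.root),
                          key=lambda v: -tree.ages[v])
        v = internal[0]
        ca, cb = tree.children[v]
        pair = (min(tree.tip_set(ca)), min(tree.tip_set(cb)))
        surface = fit_approx_surface(block, tree, jc())
        return tree, cals, v, pair, surface

    def test_uninformative_step2_reproduces_propagated_density(self, setup):
        """Prior dominance: with no step-2 data, the shared node's marginal
        equals the propagated fitted density."""
        from molclock.sequential import run_sequential
        from scipy import stats
        tree, cals, v, pair, surface = setup
        res = run_sequential(
            tree, cals, tree, cals, [pair * 2], ClockModel("strict"),
            McmcSettings(n_iter=16000, thin=1), seed=5,
            step1_lik={"surface": surface}, step2_lik=None,
            step2_root_max=8000.0)
        cal = res.propagated[0]
        draws = res.step2.ages_for(v)
        ks = stats.kstest(draws, cal.cdf).statistic
        assert ks < 0.05, ks

    def test_propagation_tightens_with_informative_step2(self, setup):
        """The step-2 posterior sd of a shared node never exceeds its
        propagated (step-1 posterior) prior sd when step-2 data agree."""
        from molclock.sequential import run_sequential
        tree, cals, v, pair, surface = setup
        res = run_sequential(
            tree, cals, tree, cals, [pair * 2], ClockModel("strict"),
            McmcSettings(n_iter=8000), seed=6,
            step1_lik={"surface": surface},
            step2_lik={"surface": surface},
            step2_root_max=8000.0)
        step1_sd = float(np.std(res.step1.ages_for(v)))
        step2_sd = float(np.std(res.step2.ages_for(v)))
        assert step2_sd <= step1_sd * 1.1  # tolerance for MC noise
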