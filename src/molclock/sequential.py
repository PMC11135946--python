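"""Two-step sequential dating: fit parametric densities to first-step
posterior node ages and impose them as priors on shared nodes in the second
step.

This is the strategy for dating a fossil-poor clade (e.g. a bacterial tree)
with time information propagated from a fossil-rich one (e.g. eukaryotes):
date step 1 with its own calibrations, fit a best-fit density to each shared
node's posterior ages, then run step 2 with its fossils plus the fitted
densities as additional calibrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calibrations import Calibration
from .mcmc import (ClockModel, McmcSettings, PosteriorSample, run_chain)

__all__ = ["FittedDensity", "fit_posterior_density", "propagate_calibrations",
           "run_sequential"]

_FAMILIES = ("lognormal", "gamma", "skew-normal", "truncated-normal")


@dataclass(frozen=True)
class FittedDensity:
    """A parametric density fitted to posterior age draws.

    ``params`` follow the conventions of :mod:`molclock.calibrations`:
    lognormal (s, scale), gamma (a, scale), skew-normal (a, loc, scale),
    truncated-normal (loc, scale; truncated to (0, inf)).
    """

    family: str
    params: tuple
    ks: float          # KS statistic against the fitted sample
    aic: float

    def frozen(self):
        from .calibrations import _frozen_dist
        return _frozen_dist(self.family, self.params)


def _fit_family(family: str, x: np.ndarray):
    """ML fit of one candidate family; returns (params, loglik, cdf)."""
    if family == "lognormal":
        s, loc, scale = stats.lognorm.fit(x, floc=0.0)
        dist = stats.lognorm(s=s, scale=scale)
        return (s, scale), float(np.sum(dist.logpdf(x))), dist.cdf
    if family == "gamma":
        a, loc, scale = stats.gamma.fit(x, floc=0.0)
        dist = stats.gamma(a=a, scale=scale)
        return (a, scale), float(np.sum(dist.logpdf(x))), dist.cdf
    if family == "skew-normal":
        a, loc, scale = stats.skewnorm.fit(x)
        dist = stats.skewnorm(a=a, loc=loc, scale=scale)
        return (a, loc, scale), float(np.sum(dist.logpdf(x))), dist.cdf
    if family == "truncated-normal":
        # normal MLE then truncation to (0, inf); adequate when the posterior
        # sits far from 0, exact enough as a candidate shape otherwise
        loc, scale = float(np.mean(x)), float(np.std(x))
        dist = stats.truncnorm(a=(0.0 - loc) / scale, b=np.inf,
                               loc=loc, scale=scale)
        return (loc, scale), float(np.sum(dist.logpdf(x))), dist.cdf
    raise ValueError(family)


def fit_posterior_density(samples: np.ndarray, families=_FAMILIES,
                          min_draws: int = 500) -> FittedDensity:
    """Fit candidate families by ML and select the smallest KS statistic."""
    x = np.asarray(samples, dtype=float)
    if len(x) < min_draws:
        raise ValueError(f"need >= {min_draws} draws, got {len(x)}")
    if np.std(x) == 0:
        raise ValueError("degenerate (zero-variance) sample")
    best = None
    for fam in families:
        try:
            params, ll, cdf = _fit_family(fam, x)
        except Exception:
            continue
        ks = float(stats.kstest(x, cdf).statistic)
        aic = 2 * len(params) - 2 * ll
        cand = FittedDensity(fam, tuple(float(p) for p in params), ks, aic)
        if best is None or cand.ks < best.ks:
            best = cand
    if best is None:
        raise RuntimeError("no candidate family could be fitted")
    return best


def propagate_calibrations(step1_posterior: PosteriorSample,
                           shared_nodes: list,
                           root_max: float | None = None) -> list:
    """Fitted-density calibrations for nodes shared between the two steps.

    ``shared_nodes``: list of dicts (or tuples) with step-1 and step-2 anchor
    tip pairs: (step1_tip_a, step1_tip_b, step2_tip_a, step2_tip_b).  Each
    fitted density is truncated at ``root_max`` (a fitted prior must not place
    mass above the step-2 root maximum).
    """
    out = []
    for i, entry in enumerate(shared_nodes):
        if isinstance(entry, dict):
            a1, b1 = entry["step1_tip_a"], entry["step1_tip_b"]
            a2, b2 = entry["step2_tip_a"], entry["step2_tip_b"]
            name = entry.get("name", f"shared_{i+1}")
        else:
            a1, b1, a2, b2 = entry
            name = f"shared_{i+1}"
        node = step1_posterior.tree.mrca({a1, b1})
        draws = step1_posterior.ages_for(node)
        fd = fit_posterior_density(draws)
        out.append(Calibration(
            name=name, tip_a=a2, tip_b=b2, kind="fitted_density",
            tL=None, tU=None, density_family=fd.family,
            density_params=fd.params, upper_trunc=root_max))
    return out


@dataclass
class SequentialResult:
    step1: PosteriorSample
    step2: PosteriorSample
    fitted: pd.DataFrame          # node, family, params, KS per shared node
    propagated: list              # the fitted-density calibrations


def run_sequential(step1_tree, step1_cals, step2_tree, step2_cals,
                   shared_map, clock: ClockModel, settings: McmcSettings,
                   seed: int, *, step1_lik=None, step2_lik=None,
                   step2_root_max: float | None = None) -> SequentialResult:
    """Date step 1, fit densities on shared nodes, date step 2 with them.

    ``step1_lik`` / ``step2_lik``: dicts of likelihood keyword arguments for
    :func:`run_chain` (``surface=...`` or ``alignment=..., subst_model=...``);
    ``None`` means prior-only for that step.
    """
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))

    def _settings(lik):
        return (settings if lik else
                McmcSettings(**{**settings.__dict__, "prior_only": True}))

    try:
        post1 = run_chain(step1_tree, step1_cals, clock, _settings(step1_lik),
                          seed=s1, **(step1_lik or {}))
    except Exception as e:
        raise RuntimeError(f"sequential step 1 failed: {e}") from e

    if step2_root_max is None:
        for cal in step2_cals:
            node = step2_tree.mrca({cal.tip_a, cal.tip_b})
            if node == step2_tree.root and cal.tU is not None:
                step2_root_max = cal.tU * 2.0  # beyond the soft tail bulk
    try:
        propagated = propagate_calibrations(post1, shared_map,
                                            root_max=step2_root_max)
    except Exception as e:
        raise RuntimeError(f"sequential density fitting failed: {e}") from e

    rows = []
    for cal in propagated:
        rows.append({"name": cal.name, "family": cal.density_family,
                     "params": ",".join(f"{p:.6g}" for p in cal.density_params)})
    fitted = pd.DataFrame(rows)

    try:
        post2 = run_chain(step2_tree, list(step2_cals) + propagated, clock,
                          _settings(step2_lik), seed=s2, **(step2_lik or {}))
    except Exception as e:
        raise RuntimeError(f"sequential step 2 failed: {e}") from e
    return SequentialResult(post1, post2, fitted, propagated)
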