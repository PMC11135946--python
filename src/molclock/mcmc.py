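"""Bayesian node dating by Metropolis-within-Gibbs MCMC.

The model: node ages under a birth-death prior conditioned on the root age,
fossil calibrations as soft-bounded densities (the root must carry a maximum
or joint calibration), and a strict / independent-lognormal (IR) /
autocorrelated geometric-Brownian (AR) clock.  The sequence likelihood is
either the exact pruning likelihood or a quadratic approximate-likelihood
surface; a ``power`` exponent on the likelihood supports power posteriors
for marginal-likelihood estimation, and ``prior_only`` switches it off.

Internally time is measured in units of 100 Ma (ages are converted at the
I/O boundary); substitution rates are per site per 100 Ma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibrations import Calibration, CladeRef
from .likelihood import ApproxLikSurface, TreeLikelihood
from .treeprior import bd_kernel_logpdf
from .tree import TimeTree

__all__ = ["ClockModel", "McmcSettings", "PosteriorSample", "run_chain",
           "summarize", "hpd_interval", "check_convergence", "clade_ages"]

_MA = 100.0  # internal time unit, in Ma


@dataclass(frozen=True)
class ClockModel:
    """Clock kind plus hyperpriors.

    ``kind``: strict | IR | AR.  The mean log-rate has a normal hyperprior
    N(mu0, sd0^2); the rate-variance sigma^2 has a gamma hyperprior on the
    precision tau = 1/sigma^2 with shape ``tau_alpha`` and rate ``tau_beta``.
    Rates are substitutions/site/100 Ma.
    """

    kind: str = "strict"
    mu0: float = math.log(0.05)
    sd0: float = 1.5
    tau_alpha: float = 1.0
    tau_beta: float = 0.05

    def __post_init__(self):
        if self.kind not in ("strict", "IR", "AR"):
            raise ValueError(f"unknown clock kind {self.kind!r}")
        if self.sd0 <= 0 or self.tau_alpha <= 0 or self.tau_beta <= 0:
            raise ValueError("hyperprior parameters must be > 0")


@dataclass(frozen=True)
class McmcSettings:
    n_iter: int = 10_000
    burn_in_frac: float = 0.25
    thin: int = 5
    prior_only: bool = False
    power: float = 1.0
    tune: bool = True
    lam: float = 0.08  # birth rate, per lineage per 100 Ma
    mu: float = 0.04   # death rate


@dataclass
class PosteriorSample:
    """Retained MCMC draws of node ages (Ma) and clock parameters."""

    node_ids: np.ndarray          # internal node ids, column order of `ages`
    ages: np.ndarray              # (n_draws, n_internal), Ma
    mean_rate: np.ndarray         # per draw
    sigma2: np.ndarray
    loglik: np.ndarray            # unpowered log-likelihood per draw
    logpost: np.ndarray
    tree: TimeTree                # topology the chain ran on
    burn_in: int = 0
    thin: int = 1
    seed: int = 0
    chain_id: int = 0
    acceptance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ages.shape[0] < 2:
            raise ValueError("need >= 2 retained draws")

    @property
    def n_draws(self) -> int:
        return self.ages.shape[0]

    def ages_for(self, node_id: int) -> np.ndarray:
        col = int(np.flatnonzero(self.node_ids == node_id)[0])
        return self.ages[:, col]

    @property
    def root_ages(self) -> np.ndarray:
        return self.ages_for(self.tree.root)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ages,
                          columns=[f"t_n{int(v)}" for v in self.node_ids])
        df["mean_rate"] = self.mean_rate
        df["sigma2"] = self.sigma2
        df["loglik"] = self.loglik
        df["logpost"] = self.logpost
        return df


def clade_ages(posterior: PosteriorSample, clade: CladeRef) -> np.ndarray:
    """Posterior age draws (Ma) for a clade's crown or total-group node."""
    node = clade.resolve(posterior.tree)
    return posterior.ages_for(node)


# --------------------------------------------------------------------------
# sampler internals
# --------------------------------------------------------------------------

class _Target:
    """Log-posterior of the dating model, with per-node age-prior terms."""

    def __init__(self, tree: TimeTree, cals_by_node: dict, clock: ClockModel,
                 settings: McmcSettings, loglik_fn):
        self.tree = tree
        self.cals = cals_by_node
        self.clock = clock
        self.s = settings
        self.loglik_fn = loglik_fn  # blens(per-node) -> float, or None
        self.root = tree.root
        self.n_tips = tree.n_tips
        self.internal = np.arange(tree.n_tips, tree.n_nodes)
        self.nonroot = np.array([v for v in range(tree.n_nodes) if v != self.root])
        self.nonroot_internal = np.array(
            [v for v in self.internal if v != self.root])
        self.uncal_internal = np.array(
            [v for v in self.nonroot_internal if v not in cals_by_node])
        self.parent = tree.parent
        # AR: parent branch of each non-root node (-1 = root child)
        self.par_branch = np.array(
            [p if p != self.root else -1 for p in self.parent[self.nonroot]])

    # ages in 100-Ma units throughout
    def age_term(self, v: int, ages: np.ndarray) -> float:
        if v == self.root:
            return self.cals[v].log_density(ages[v] * _MA)
        if v in self.cals:
            return self.cals[v].log_density(ages[v] * _MA)
        t = ages[v]
        if not 0 < t < ages[self.root]:
            return -np.inf
        return float(bd_kernel_logpdf(t, self.s.lam, self.s.mu, ages[self.root]))

    def age_terms(self, ages: np.ndarray) -> np.ndarray:
        out = np.empty(len(self.internal))
        idx = {int(v): i for i, v in enumerate(self.internal)}
        if len(self.uncal_internal):
            tt = ages[self.uncal_internal]
            vals = bd_kernel_logpdf(tt, self.s.lam, self.s.mu, ages[self.root])
            for v, val in zip(self.uncal_internal, vals):
                out[idx[int(v)]] = val
        for v, cal in self.cals.items():
            out[idx[int(v)]] = cal.log_density(ages[v] * _MA)
        return out

    def rate_prior(self, ages, y, log_mu, log_s2) -> float:
        c = self.clock
        lp = -0.5 * ((log_mu - c.mu0) / c.sd0) ** 2 - math.log(c.sd0)
        if c.kind == "strict":
            return lp
        s2 = math.exp(log_s2)
        tau = 1.0 / s2
        # gamma prior on precision, with Jacobian to sigma^2 scale
        lp += (c.tau_alpha + 1.0) * math.log(tau) - c.tau_beta * tau
        yv = y[self.nonroot]
        if c.kind == "IR":
            m = log_mu - 0.5 * s2
            lp += float(np.sum(-0.5 * (yv - m) ** 2 / s2 - 0.5 * math.log(s2)))
        else:  # AR: geometric Brownian, child | parent branch
            dt = ages[self.parent[self.nonroot]] - ages[self.nonroot]
            if np.any(dt <= 0):
                return -np.inf
            ypar = np.where(self.par_branch >= 0, y[self.par_branch], log_mu)
            var = s2 * dt
            m = ypar - 0.5 * var
            lp += float(np.sum(-0.5 * (yv - m) ** 2 / var - 0.5 * np.log(var)))
        return lp

    def sample_rates_from_prior(self, rng, ages, log_mu, log_s2) -> np.ndarray:
        """Exact draw of branch log-rates from the clock prior given ages."""
        s2 = math.exp(log_s2)
        y = np.full(self.tree.n_nodes, log_mu)
        if self.clock.kind == "IR":
            y[self.nonroot] = rng.normal(log_mu - 0.5 * s2, math.sqrt(s2),
                                         len(self.nonroot))
        elif self.clock.kind == "AR":
            for v in self.tree.postorder[::-1]:  # preorder
                if v == self.root:
                    continue
                p = self.parent[v]
                ypar = log_mu if p == self.root else y[p]
                var = s2 * (ages[p] - ages[v])
                y[v] = rng.normal(ypar - 0.5 * var, math.sqrt(max(var, 1e-12)))
        return y

    def loglik(self, ages, y, log_mu) -> float:
        if self.loglik_fn is None:
            return 0.0
        dur = ages[self.parent[self.nonroot]] - ages[self.nonroot]
        if np.any(dur < 0):
            return -np.inf
        rates = (np.full(len(self.nonroot), math.exp(log_mu))
                 if self.clock.kind == "strict" else np.exp(y[self.nonroot]))
        blens = np.zeros(self.tree.n_nodes)
        blens[self.nonroot] = rates * dur
        return self.loglik_fn(blens)


def _resolve_calibrations(tree: TimeTree, calibrations) -> dict:
    cals = {}
    for cal in calibrations:
        node = tree.mrca({cal.tip_a, cal.tip_b})
        if node in cals:
            raise ValueError(f"multiple calibrations anchor node {node}")
        cals[node] = cal
    root_cal = cals.get(tree.root)
    if root_cal is None or root_cal.kind == "min":
        raise ValueError("the root must carry a max, joint, or fitted-density "
                         "calibration (an upper bound on the root age)")
    return cals


def _initial_ages(tree: TimeTree, cals: dict, rng: np.random.Generator,
                  max_tries: int = 500) -> np.ndarray:
    """Top-down draw of internal ages consistent with calibrations (100-Ma units)."""
    root = tree.root
    preorder_internal = [v for v in tree.postorder[::-1] if v >= tree.n_tips]
    root_lo, root_hi = cals[root].bracket()
    for _ in range(max_tries):
        ages = np.zeros(tree.n_nodes)
        ok = True
        for v in preorder_internal:
            if v == root:
                lo, hi = root_lo / _MA, root_hi / _MA
            else:
                hi = ages[tree.parent[v]]
                lo = 0.0
                if v in cals:
                    clo, chi = cals[v].bracket()
                    lo = max(lo, clo / _MA)
                    if chi is not None:
                        hi = min(hi, chi / _MA)
            if not lo < hi:
                ok = False
                break
            # keep strictly inside, away from coincident ages
            ages[v] = rng.uniform(lo + 0.02 * (hi - lo), hi - 0.02 * (hi - lo))
        if ok:
            return ages
    raise RuntimeError("no valid starting state found within calibration bounds")


def run_chain(topology: TimeTree, calibrations, clock: ClockModel,
              settings: McmcSettings, seed: int, *,
              alignment=None, subst_model=None,
              surface: ApproxLikSurface | None = None,
              chain_id: int = 0) -> PosteriorSample:
    """Sample node ages (and rates) from the dating posterior.

    Exactly one likelihood source is used: ``surface`` (quadratic
    approximation), or ``alignment`` + ``subst_model`` (exact pruning), or —
    with ``settings.prior_only`` — none.
    """
    rng = np.random.default_rng(seed)
    cals = _resolve_calibrations(topology, calibrations)

    if settings.prior_only:
        loglik_fn = None
    elif surface is not None:
        loglik_fn = surface.loglik_from_node_lengths
    elif alignment is not None and subst_model is not None:
        exact = TreeLikelihood(topology, alignment, subst_model)
        loglik_fn = exact.loglik_full
    else:
        raise ValueError("provide a surface, or alignment+subst_model, "
                         "or set prior_only")

    tgt = _Target(topology, cals, clock, settings, loglik_fn)
    relaxed = clock.kind in ("IR", "AR")

    ages = _initial_ages(topology, cals, rng)
    log_mu = clock.mu0 + 0.1 * rng.standard_normal()
    log_s2 = math.log(0.1)
    y = np.full(topology.n_nodes, log_mu)
    if relaxed:
        y = log_mu + 0.05 * rng.standard_normal(topology.n_nodes)

    A = tgt.age_terms(ages)
    R = tgt.rate_prior(ages, y, log_mu, log_s2)
    L = tgt.loglik(ages, y, log_mu)
    beta = settings.power
    aidx = {int(v): i for i, v in enumerate(tgt.internal)}

    steps = {"root": 0.2, "rate": 0.4, "mu": 0.3, "s2": 0.6, "scale": 0.15}
    acc = {k: [0, 0] for k in
           ("age", "root", "rate", "mu", "s2", "scale")}

    n_iter = settings.n_iter
    burn = int(settings.burn_in_frac * n_iter)
    thin = max(1, settings.thin)
    kept_ages, kept_mu, kept_s2, kept_ll, kept_lp = [], [], [], [], []

    children = topology.children
    parent = topology.parent
    n_int = len(tgt.internal)

    for it in range(n_iter):
        # --- interior node ages: gap-uniform slide -------------------------
        for v in tgt.nonroot_internal:
            lo = max(ages[c] for c in children[v])
            hi = ages[parent[v]]
            t_new = rng.uniform(lo, hi)
            old = ages[v]
            ages[v] = t_new
            a_new = tgt.age_term(v, ages)
            r_new = tgt.rate_prior(ages, y, log_mu, log_s2) if clock.kind == "AR" else R
            l_new = tgt.loglik(ages, y, log_mu)
            dlp = (a_new - A[aidx[v]]) + (r_new - R) + beta * (l_new - L)
            acc["age"][1] += 1
            if math.log(rng.uniform()) < dlp:
                A[aidx[v]], R, L = a_new, r_new, l_new
                acc["age"][0] += 1
            else:
                ages[v] = old

        # --- root age: multiplicative slide --------------------------------
        delta = steps["root"] * (rng.uniform() - 0.5) * 2.0
        t_new = ages[tgt.root] * math.exp(delta)
        if t_new > max(ages[c] for c in children[tgt.root]):
            old = ages[tgt.root]
            ages[tgt.root] = t_new
            A_new = tgt.age_terms(ages)
            r_new = tgt.rate_prior(ages, y, log_mu, log_s2) if clock.kind == "AR" else R
            l_new = tgt.loglik(ages, y, log_mu)
            dlp = (A_new.sum() - A.sum()) + (r_new - R) + beta * (l_new - L) + delta
            acc["root"][1] += 1
            if math.log(rng.uniform()) < dlp:
                A, R, L = A_new, r_new, l_new
                acc["root"][0] += 1
            else:
                ages[tgt.root] = old
        else:
            acc["root"][1] += 1

        # --- branch rates (relaxed clocks) ----------------------------------
        if relaxed and not settings.prior_only:
            for v in tgt.nonroot:
                old = y[v]
                y[v] = old + steps["rate"] * rng.standard_normal()
                r_new = tgt.rate_prior(ages, y, log_mu, log_s2)
                l_new = tgt.loglik(ages, y, log_mu)
                dlp = (r_new - R) + beta * (l_new - L)
                acc["rate"][1] += 1
                if math.log(rng.uniform()) < dlp:
                    R, L = r_new, l_new
                    acc["rate"][0] += 1
                else:
                    y[v] = old
        if relaxed:
            # joint independence proposal from the clock prior: exact Gibbs
            # when the (powered) likelihood is off, and the decorrelating
            # move that keeps low-power rungs mixing in stepping-stone runs
            y_prop = tgt.sample_rates_from_prior(rng, ages, log_mu, log_s2)
            if settings.prior_only:
                y = y_prop
                R = tgt.rate_prior(ages, y, log_mu, log_s2)
            else:
                l_new = tgt.loglik(ages, y_prop, log_mu)
                if math.log(rng.uniform()) < beta * (l_new - L):
                    y = y_prop
                    L = l_new
                    R = tgt.rate_prior(ages, y, log_mu, log_s2)

        # --- hyperparameters (repeated: cheap, and they gate rate mixing) ----
        for _ in range(3 if relaxed else 1):
            old = log_mu
            log_mu = old + steps["mu"] * rng.standard_normal()
            if clock.kind == "strict":
                y[:] = log_mu
            r_new = tgt.rate_prior(ages, y, log_mu, log_s2)
            l_new = tgt.loglik(ages, y, log_mu) if clock.kind == "strict" else L
            dlp = (r_new - R) + beta * (l_new - L)
            acc["mu"][1] += 1
            if math.log(rng.uniform()) < dlp:
                R, L = r_new, l_new
                acc["mu"][0] += 1
            else:
                log_mu = old
                if clock.kind == "strict":
                    y[:] = log_mu

            if relaxed:
                old = log_s2
                log_s2 = old + steps["s2"] * rng.standard_normal()
                r_new = tgt.rate_prior(ages, y, log_mu, log_s2)
                acc["s2"][1] += 1
                if math.log(rng.uniform()) < (r_new - R):
                    R = r_new
                    acc["s2"][0] += 1
                else:
                    log_s2 = old

        # --- whole-tree scale: ages * c, rates / c ---------------------------
        delta = steps["scale"] * (rng.uniform() - 0.5) * 2.0
        c = math.exp(delta)
        ages_new = ages.copy()
        ages_new[tgt.internal] *= c
        y_new = y - delta
        mu_new = log_mu - delta
        A_new = tgt.age_terms(ages_new)
        r_new = tgt.rate_prior(ages_new, y_new, mu_new, log_s2)
        l_new = tgt.loglik(ages_new, y_new, mu_new)
        dlp = ((A_new.sum() - A.sum()) + (r_new - R) + beta * (l_new - L)
               + n_int * delta)  # Jacobian of the age scaling
        acc["scale"][1] += 1
        if math.log(rng.uniform()) < dlp:
            ages, y, log_mu = ages_new, y_new, mu_new
            A, R, L = A_new, r_new, l_new
            acc["scale"][0] += 1

        # --- adapt step sizes during burn-in --------------------------------
        if settings.tune and it < burn and (it + 1) % 50 == 0:
            for k in ("root", "rate", "mu", "s2", "scale"):
                tries = acc[k][1]
                if tries == 0:
                    continue
                rate = acc[k][0] / tries
                if rate > 0.4:
                    steps[k] *= 1.4
                elif rate < 0.2:
                    steps[k] /= 1.4
                acc[k] = [0, 0]
            acc["age"] = [0, 0]

        if it >= burn and (it - burn) % thin == 0:
            kept_ages.append(ages[tgt.internal] * _MA)
            kept_mu.append(math.exp(log_mu))
            kept_s2.append(math.exp(log_s2))
            kept_ll.append(L)
            kept_lp.append(A.sum() + R + beta * L)

    acc_rates = {k: (a / t if t else 0.0) for k, (a, t) in acc.items()}
    return PosteriorSample(
        node_ids=tgt.internal.copy(), ages=np.array(kept_ages),
        mean_rate=np.array(kept_mu), sigma2=np.array(kept_s2),
        loglik=np.array(kept_ll), logpost=np.array(kept_lp),
        tree=topology, burn_in=burn, thin=thin, seed=seed,
        chain_id=chain_id, acceptance=acc_rates)


# --------------------------------------------------------------------------
# summaries and diagnostics
# --------------------------------------------------------------------------

def hpd_interval(draws: np.ndarray, mass: float = 0.95) -> tuple:
    """Shortest interval containing ``mass`` of the draws."""
    x = np.sort(np.asarray(draws, float))
    n = len(x)
    k = max(2, int(math.ceil(mass * n)))  # points inside the interval
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def summarize(posterior: PosteriorSample, nodes=None, mass: float = 0.95,
              min_draws: int = 100) -> pd.DataFrame:
    """Posterior mean and HPD interval per node (ages in Ma)."""
    if posterior.n_draws < min_draws:
        raise ValueError(f"too few draws for HPD: {posterior.n_draws} < {min_draws}")
    nodes = posterior.node_ids if nodes is None else nodes
    rows = []
    for v in nodes:
        draws = posterior.ages_for(int(v))
        lo, hi = hpd_interval(draws, mass)
        rows.append({"node": int(v), "mean": float(draws.mean()),
                     "hpd_lo": lo, "hpd_hi": hi})
    return pd.DataFrame(rows)


def effective_sample_sizes(posterior: PosteriorSample) -> np.ndarray:
    import arviz as az
    return np.array([float(az.ess(np.asarray(posterior.ages[:, j])))
                     for j in range(posterior.ages.shape[1])])


@dataclass
class ConvergenceReport:
    correlation: float
    max_abs_diff: float       # Ma, between per-node posterior means
    slope: float
    min_ess: float
    passed: bool
    warnings: list


def check_convergence(chain1: PosteriorSample, chain2: PosteriorSample,
                      tol_ma: float | None = None,
                      corr_threshold: float = 0.99,
                      ess_floor: float = 50.0) -> ConvergenceReport:
    """Compare per-node posterior means of two independent runs."""
    if not np.array_equal(chain1.node_ids, chain2.node_ids) or \
            chain1.tree.labels != chain2.tree.labels:
        raise ValueError("chains come from different topologies")
    m1 = chain1.ages.mean(axis=0)
    m2 = chain2.ages.mean(axis=0)
    corr = float(np.corrcoef(m1, m2)[0, 1]) if len(m1) > 1 else 1.0
    slope = float(np.polyfit(m1, m2, 1)[0]) if len(m1) > 1 else 1.0
    maxdiff = float(np.max(np.abs(m1 - m2)))
    if tol_ma is None:
        tol_ma = 0.05 * float(m1.max())
    warns = []
    ess = min(effective_sample_sizes(chain1).min(),
              effective_sample_sizes(chain2).min())
    if ess < ess_floor:
        warns.append(f"insufficient ESS: min {ess:.0f} < {ess_floor:.0f}")
    passed = corr > corr_threshold and maxdiff < tol_ma and not warns
    return ConvergenceReport(corr, maxdiff, slope, float(ess), passed, warns)
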