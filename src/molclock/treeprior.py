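"""Birth-death node-age prior, conditioned on the root age.

Given birth rate ``lam``, death rate ``mu`` (complete sampling) and the root
age t1, the non-root internal node ages of a rooted ultrametric tree are
i.i.d. draws from the kernel density

    g(t) = lam * p1(t) / v(t1),   0 < t < t1,

with ``p1(t) = P(0,t)^2 exp((mu-lam) t)``, ``P(0,t)`` the probability that a
lineage alive t time units ago leaves at least one extant descendant, and
``v(t1)`` the normalizer.  The lam == mu case is the analytic limit.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["bd_kernel_logpdf", "bd_kernel_cdf", "tree_prior_logdensity"]

_EQ_TOL = 1e-9


def _kernel_parts(t, lam, mu):
    r = lam - mu
    ert = np.exp(-r * t)
    P0 = r / (lam - mu * ert)
    return P0 * P0 * ert  # p1(t)


def bd_kernel_logpdf(t, lam: float, mu: float, root_age: float):
    """Log kernel density g(t) of a non-root node age given the root age."""
    t = np.asarray(t, dtype=float)
    if lam <= 0 or mu < 0:
        raise ValueError("need lam > 0, mu >= 0")
    if abs(lam - mu) < _EQ_TOL * max(lam, 1.0):
        # lam == mu limit: g(t) = (1 + lam t1) / (t1 (1 + lam t)^2)
        out = (np.log1p(lam * root_age) - np.log(root_age)
               - 2.0 * np.log1p(lam * t))
    else:
        p1 = _kernel_parts(t, lam, mu)
        r = lam - mu
        ert1 = np.exp(-r * np.asarray(root_age, dtype=float))
        v = 1.0 - r * ert1 / (lam - mu * ert1)
        out = np.log(lam) + np.log(p1) - np.log(v)
    return np.where((t > 0) & (t < root_age), out, -np.inf)


def bd_kernel_cdf(t, lam: float, mu: float, root_age: float):
    """CDF of the node-age kernel on (0, root_age)."""
    t = np.clip(np.asarray(t, dtype=float), 0.0, root_age)
    if abs(lam - mu) < _EQ_TOL * max(lam, 1.0):
        # integral of (1+lam t1)/(t1 (1+lam t)^2)
        return (1.0 + lam * root_age) / root_age * t / (1.0 + lam * t)
    r = lam - mu
    # integral of lam p1(s) ds from 0 to t = 1 - P(0,t) e^{-rt} (up to v)
    ert = np.exp(-r * t)
    P0 = r / (lam - mu * ert)
    num = 1.0 - P0 * ert
    ert1 = np.exp(-r * np.asarray(root_age, dtype=float))
    v = 1.0 - r * ert1 / (lam - mu * ert1)
    return num / v


def tree_prior_logdensity(ages, lam: float, mu: float, root_age: float) -> float:
    """Joint log-density of the non-root internal node ages given the root age.

    ``ages`` are the non-root internal node ages; ordering constraints are the
    caller's responsibility (enforced as sampler support).
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        return 0.0
    if np.any(ages <= 0) or np.any(ages >= root_age):
        return -np.inf
    return float(np.sum(bd_kernel_logpdf(ages, lam, mu, root_age)))
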