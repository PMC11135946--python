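"""Fossil calibrations as soft-bounded node-age densities.

All calibration kinds are proper densities on (0, inf), in Ma:

* ``joint`` — uniform on [tL, tU] with power-decay tails carrying masses
  ``pL`` below and ``pU`` above, continuous at the bounds.
* ``max`` — uniform on (0, tU] with mass ``1-pU``, power-decay tail above.
* ``min`` — soft lower bound: power-rise tail with mass ``pL`` below tL and a
  heavy (truncated-Cauchy) tail above, the usual choice when only a minimum
  is known.
* ``fitted_density`` — a parametric density fitted to a first-step posterior
  (see :mod:`molclock.sequential`), optionally truncated at a root maximum.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["Calibration", "CladeRef", "read_calibrations", "write_calibrations"]

_KINDS = ("min", "max", "joint", "fitted_density")


@dataclass(frozen=True)
class CladeRef:
    """A named clade anchored by two tips; crown = their MRCA, total = its parent."""
    name: str
    tip_a: str
    tip_b: str
    scope: str = "crown"  # or "total"

    def __post_init__(self):
        if self.scope not in ("crown", "total"):
            raise ValueError(f"scope must be crown|total, got {self.scope!r}")

    def resolve(self, tree) -> int:
        node = tree.mrca({self.tip_a, self.tip_b})
        if self.scope == "total":
            node = tree.total_group_node(node)
        return node


@dataclass
class Calibration:
    """Node-age constraint anchored at the MRCA of (tip_a, tip_b)."""

    tip_a: str
    tip_b: str
    kind: str
    tL: float | None = None
    tU: float | None = None
    pL: float = 0.025
    pU: float = 0.025
    name: str = ""
    density_family: str | None = None
    density_params: tuple = ()
    upper_trunc: float | None = None  # fitted densities: renormalize to (0, upper_trunc)
    # min-bound heavy-tail shape (offset, scale) of the truncated Cauchy
    cauchy_p: float = 0.1
    cauchy_c: float = 1.0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown calibration kind {self.kind!r}")
        if self.kind in ("min", "joint") and not (self.tL and self.tL > 0):
            raise ValueError("min/joint calibration needs tL > 0")
        if self.kind in ("max", "joint") and not (self.tU and self.tU > 0):
            raise ValueError("max/joint calibration needs tU > 0")
        if self.kind == "joint" and not self.tL < self.tU:
            raise ValueError("joint calibration needs tL < tU")
        if not (0 < self.pL < 0.5 and 0 < self.pU < 0.5):
            raise ValueError("tail probabilities must lie in (0, 0.5)")
        if self.kind == "min":
            # truncated-Cauchy upper tail: cache location/scale and the mass
            # above tL, plus the continuity exponent of the lower power tail
            loc = self.tL * (1.0 + self.cauchy_p)
            scale = self.cauchy_c * self.tL
            z = 0.5 - math.atan((self.tL - loc) / scale) / math.pi
            f_at_tL = (1.0 - self.pL) / z / (
                math.pi * scale * (1.0 + ((self.tL - loc) / scale) ** 2))
            self._min_loc, self._min_scale, self._min_z = loc, scale, z
            self._min_theta = self.tL * f_at_tL / self.pL
        if self.kind == "fitted_density":
            if self.density_family is None:
                raise ValueError("fitted_density needs a density family")
            self._frozen = _frozen_dist(self.density_family, self.density_params)
            self._fast_logpdf = _fast_logpdf_fn(self.density_family,
                                                self.density_params)
            if self.upper_trunc is not None:
                z = self._frozen.cdf(self.upper_trunc) - self._frozen.cdf(0.0)
                if z <= 0:
                    raise ValueError("fitted density has no mass below the truncation")
                self._log_trunc_z = math.log(z)
            else:
                self._log_trunc_z = -math.log1p(-float(self._frozen.cdf(0.0)))
                if not np.isfinite(self._log_trunc_z):
                    self._log_trunc_z = 0.0

    # -- piecewise densities -------------------------------------------------
    def log_density(self, age: float) -> float:
        if age <= 0:
            raise ValueError("age must be > 0")
        k = self.kind
        if k == "joint":
            h = (1.0 - self.pL - self.pU) / (self.tU - self.tL)
            if age < self.tL:
                theta = h * self.tL / self.pL
                return (math.log(self.pL * theta / self.tL)
                        + (theta - 1.0) * math.log(age / self.tL))
            if age <= self.tU:
                return math.log(h)
            theta = h * self.tU / self.pU
            return (math.log(self.pU * theta / self.tU)
                    - (theta + 1.0) * math.log(age / self.tU))
        if k == "max":
            h = (1.0 - self.pU) / self.tU
            if age <= self.tU:
                return math.log(h)
            theta = (1.0 - self.pU) / self.pU
            return (math.log(self.pU * theta / self.tU)
                    - (theta + 1.0) * math.log(age / self.tU))
        if k == "min":
            loc, scale, z = self._min_loc, self._min_scale, self._min_z
            if age >= self.tL:
                pdf = 1.0 / (math.pi * scale * (1.0 + ((age - loc) / scale) ** 2))
                return math.log((1.0 - self.pL) / z * pdf)
            theta = self._min_theta
            return (math.log(self.pL * theta / self.tL)
                    + (theta - 1.0) * math.log(age / self.tL))
        # fitted_density
        if self.upper_trunc is not None and age > self.upper_trunc:
            return -np.inf
        return self._fast_logpdf(age) - self._log_trunc_z

    def cdf(self, age):
        """Analytic CDF (used for KS checks of prior recovery); vectorizes."""
        if np.ndim(age) > 0:
            return np.array([self.cdf(float(a)) for a in np.asarray(age)])
        if age <= 0:
            return 0.0
        k = self.kind
        if k == "joint":
            h = (1.0 - self.pL - self.pU) / (self.tU - self.tL)
            if age < self.tL:
                theta = h * self.tL / self.pL
                return self.pL * (age / self.tL) ** theta
            if age <= self.tU:
                return self.pL + h * (age - self.tL)
            theta = h * self.tU / self.pU
            return 1.0 - self.pU * (self.tU / age) ** theta
        if k == "max":
            h = (1.0 - self.pU) / self.tU
            if age <= self.tU:
                return h * age
            theta = (1.0 - self.pU) / self.pU
            return 1.0 - self.pU * (self.tU / age) ** theta
        if k == "min":
            loc, scale, z = self._min_loc, self._min_scale, self._min_z
            if age >= self.tL:
                cdf_age = 0.5 + math.atan((age - loc) / scale) / math.pi
                cdf_tL = 0.5 + math.atan((self.tL - loc) / scale) / math.pi
                return self.pL + (1.0 - self.pL) * (cdf_age - cdf_tL) / z
            return self.pL * (age / self.tL) ** self._min_theta
        lo = float(self._frozen.cdf(0.0))
        hi = (float(self._frozen.cdf(self.upper_trunc))
              if self.upper_trunc is not None else 1.0)
        val = (min(float(self._frozen.cdf(age)), hi) - lo) / (hi - lo)
        return min(max(val, 0.0), 1.0)

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Inverse-CDF sampling (bisection on the analytic CDF)."""
        u = rng.uniform(size=size)
        out = np.empty(size)
        hi0 = max(filter(None, (self.tU, self.tL, self.upper_trunc)), default=1.0) * 50
        for i, ui in enumerate(u):
            lo, hi = 1e-12, hi0
            while self.cdf(hi) < ui:
                hi *= 2
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if self.cdf(mid) < ui:
                    lo = mid
                else:
                    hi = mid
            out[i] = 0.5 * (lo + hi)
        return out

    def bracket(self) -> tuple:
        """(hard-ish lower, upper) range where nearly all mass lies; for init."""
        lo = self.tL if self.tL else 1e-6
        hi = self.tU if self.tU else (self.tL * (1 + self.cauchy_p + 3 * self.cauchy_c)
                                      if self.tL else None)
        if self.kind == "fitted_density":
            lo = float(self._frozen.ppf(0.01))
            hi = float(self._frozen.ppf(0.99))
            if self.upper_trunc is not None:
                hi = min(hi, self.upper_trunc)
        return max(lo, 1e-6), hi


def _frozen_dist(family: str, params):
    params = tuple(float(p) for p in params)
    if family == "lognormal":
        s, scale = params
        return stats.lognorm(s=s, scale=scale)
    if family == "gamma":
        a, scale = params
        return stats.gamma(a=a, scale=scale)
    if family == "skew-normal":
        a, loc, scale = params
        return stats.skewnorm(a=a, loc=loc, scale=scale)
    if family == "truncated-normal":
        loc, scale = params
        return stats.truncnorm(a=(0.0 - loc) / scale, b=np.inf, loc=loc, scale=scale)
    raise ValueError(f"unknown density family {family!r}")


_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _norm_logpdf(z: float) -> float:
    return -0.5 * z * z - _LOG_SQRT_2PI


def _norm_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def _fast_logpdf_fn(family: str, params):
    """Closed-form logpdf closures (scipy frozen-dist calls are too slow for MCMC)."""
    params = tuple(float(p) for p in params)
    if family == "lognormal":
        s, scale = params
        mu = math.log(scale)

        def f(x):
            if x <= 0:
                return -np.inf
            lx = math.log(x)
            return -lx - math.log(s) - _LOG_SQRT_2PI - (lx - mu) ** 2 / (2 * s * s)
        return f
    if family == "gamma":
        a, scale = params
        const = -a * math.log(scale) - math.lgamma(a)

        def f(x):
            if x <= 0:
                return -np.inf
            return const + (a - 1.0) * math.log(x) - x / scale
        return f
    if family == "skew-normal":
        a, loc, scale = params

        def f(x):
            z = (x - loc) / scale
            c = _norm_cdf(a * z)
            if c <= 0:
                return -np.inf
            return math.log(2.0) + _norm_logpdf(z) - math.log(scale) + math.log(c)
        return f
    if family == "truncated-normal":
        loc, scale = params
        logz = math.log(1.0 - _norm_cdf(-loc / scale))

        def f(x):
            if x <= 0:
                return -np.inf
            return _norm_logpdf((x - loc) / scale) - math.log(scale) - logz
        return f
    raise ValueError(f"unknown density family {family!r}")


_COLUMNS = ["clade_name", "tip_a", "tip_b", "kind", "tL", "tU", "pL", "pU",
            "density_family", "density_params"]


def write_calibrations(cals, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_COLUMNS)
        for c in cals:
            w.writerow([c.name, c.tip_a, c.tip_b, c.kind,
                        "" if c.tL is None else c.tL,
                        "" if c.tU is None else c.tU,
                        c.pL, c.pU,
                        c.density_family or "",
                        ",".join(f"{p:.12g}" for p in c.density_params)])


def read_calibrations(path) -> list:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(Calibration(
                name=row["clade_name"], tip_a=row["tip_a"], tip_b=row["tip_b"],
                kind=row["kind"],
                tL=float(row["tL"]) if row["tL"] else None,
                tU=float(row["tU"]) if row["tU"] else None,
                pL=float(row["pL"] or 0.025), pU=float(row["pU"] or 0.025),
                density_family=row["density_family"] or None,
                density_params=tuple(float(x) for x in row["density_params"].split(","))
                if row["density_params"] else ()))
    return out
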