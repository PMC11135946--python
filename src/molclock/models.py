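"""Reversible substitution models (JC, HKY, Poisson+F).

Rate matrices are scaled to one expected substitution per unit branch
length.  Transition probabilities come from the spectral decomposition of
the symmetrized generator, so ``transition_matrices`` vectorizes over many
branch lengths at once.
"""

from __future__ import annotations

import numpy as np


class SubstModel:
    """Time-reversible substitution model with stationary frequencies ``pi``."""

    def __init__(self, name: str, Q: np.ndarray, pi: np.ndarray):
        self.name = name
        self.pi = np.asarray(pi, dtype=float)
        Q = np.asarray(Q, dtype=float)
        # scale: expected rate = -sum_i pi_i Q_ii = 1
        rate = -np.dot(self.pi, np.diag(Q))
        self.Q = Q / rate
        # symmetrize: S = diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric
        sq = np.sqrt(self.pi)
        S = (sq[:, None] * self.Q) / sq[None, :]
        S = 0.5 * (S + S.T)
        lam, U = np.linalg.eigh(S)
        self._lam = lam
        self._left = sq[:, None] * U          # diag(sqrt(pi)) U
        self._right = U.T / sq[None, :]       # U^T diag(1/sqrt(pi))

    @property
    def n_states(self) -> int:
        return len(self.pi)

    def transition_matrices(self, t: np.ndarray) -> np.ndarray:
        """P(t) for an array of branch lengths; shape (len(t), k, k)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        expl = np.exp(np.outer(t, self._lam))           # (B, k)
        P = np.einsum("ik,bk,kj->bij", self._left, expl, self._right)
        np.clip(P, 1e-300, None, out=P)
        return P

    def transition_matrix(self, t: float) -> np.ndarray:
        return self.transition_matrices(np.array([t]))[0]


def jc() -> SubstModel:
    """Jukes-Cantor: 4 states, uniform frequencies and exchange rates."""
    pi = np.full(4, 0.25)
    Q = np.ones((4, 4)) - 4 * np.eye(4)
    return SubstModel("JC", Q, pi)


def hky(kappa: float, pi=None) -> SubstModel:
    """HKY85 with transition/transversion ratio ``kappa`` (A,C,G,T order)."""
    pi = np.full(4, 0.25) if pi is None else np.asarray(pi, dtype=float)
    if abs(pi.sum() - 1) > 1e-8 or np.any(pi <= 0):
        raise ValueError("frequencies must be positive and sum to 1")
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i != j:
                Q[i, j] = (kappa if (i, j) in transitions else 1.0) * pi[j]
        Q[i, i] = -Q[i].sum()
    return SubstModel(f"HKY(k={kappa:g})", Q, pi)


def poisson_f(freqs=None) -> SubstModel:
    """Poisson+F amino-acid model: equal exchangeabilities, frequencies ``freqs``."""
    pi = np.full(20, 0.05) if freqs is None else np.asarray(freqs, dtype=float)
    pi = pi / pi.sum()
    if np.any(pi <= 0):
        raise ValueError("frequencies must be positive")
    Q = np.tile(pi, (20, 1))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return SubstModel("Poisson+F", Q, pi)


def get_model(name: str, **kw) -> SubstModel:
    name = name.lower()
    if name == "jc":
        return jc()
    if name == "hky":
        return hky(kw.get("kappa", 2.0), kw.get("pi"))
    if name in ("poisson", "poisson+f", "poisson_f"):
        return poisson_f(kw.get("freqs"))
    raise ValueError(f"unknown substitution model: {name!r}")
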