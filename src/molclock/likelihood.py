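"""Phylogenetic likelihood: Felsenstein pruning, analytic branch gradients,
ML branch-length fitting, and the quadratic approximate-likelihood surface
used for fast dating.

Branch lengths are parameterized on the *unrooted* tree: for a reversible
model the likelihood depends on the two root-child branches only through
their sum, so those two are merged into a single parameter.  This keeps the
ML optimum unique and the Hessian non-singular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .alignment import Alignment
from .models import SubstModel
from .tree import Tree

__all__ = ["BranchParam", "TreeLikelihood", "pruning_loglik",
           "fit_ml_branch_lengths", "ApproxLikSurface", "fit_approx_surface"]


class BranchParam:
    """Mapping between per-node rooted branch lengths and unrooted parameters.

    Parameter order is ``nodes``; the entry for the first root child carries
    the *sum* of both root-child lengths (the root-spanning unrooted branch).
    """

    def __init__(self, tree: Tree):
        self.tree = tree
        c1, c2 = tree.children[tree.root]
        self.c1, self.c2 = int(c1), int(c2)
        self.nodes = np.array(
            [v for v in range(tree.n_nodes) if v != tree.root and v != self.c2],
            dtype=int)
        self.n_params = len(self.nodes)
        self._slot = {int(v): i for i, v in enumerate(self.nodes)}

    def from_node_lengths(self, blens: np.ndarray) -> np.ndarray:
        params = np.asarray(blens, dtype=float)[self.nodes].copy()
        params[self._slot[self.c1]] += blens[self.c2]
        return params

    def to_node_lengths(self, params: np.ndarray) -> np.ndarray:
        blens = np.zeros(self.tree.n_nodes)
        blens[self.nodes] = params
        blens[self.c2] = 0.0
        return blens


class TreeLikelihood:
    """Pruning likelihood of an alignment on a fixed rooted binary topology."""

    def __init__(self, tree: Tree, aln: Alignment, model: SubstModel):
        if set(aln.labels) != set(tree.labels):
            raise ValueError("taxon sets of alignment and tree differ")
        if model.n_states != aln.alphabet.n_states:
            raise ValueError("model/alphabet state-count mismatch")
        self.tree = tree
        self.model = model
        self.param = BranchParam(tree)
        codes = aln.subset(tree.labels).codes
        patterns, counts = np.unique(codes.T, axis=0, return_counts=True)
        self.patterns = patterns.T  # (n_tips, n_patterns)
        self.counts = counts.astype(float)
        self.n_sites = aln.n_sites
        k = model.n_states
        npat = self.patterns.shape[1]
        self._tip_partials = np.empty((tree.n_tips, k, npat))
        for i in range(tree.n_tips):
            row = self.patterns[i]
            part = np.zeros((k, npat))
            obs = row >= 0
            part[row[obs], np.flatnonzero(obs)] = 1.0
            part[:, ~obs] = 1.0  # missing: marginalize
            self._tip_partials[i] = part
        self._post = tree.postorder
        self._QT = self.model.Q  # generator, for gradients

    # -- core passes --------------------------------------------------------
    def _up_pass(self, blens):
        """Scaled post-order partials; returns (L, U, logscale_root_part)."""
        tree, k = self.tree, self.model.n_states
        npat = self.patterns.shape[1]
        P = self.model.transition_matrices(blens)
        L = np.empty((tree.n_nodes, k, npat))
        U = np.empty((tree.n_nodes, k, npat))  # up message P_v @ L_v
        logscale = np.zeros((tree.n_nodes, npat))
        for v in self._post:
            if v < tree.n_tips:
                L[v] = self._tip_partials[v]
            else:
                a, b = tree.children[v]
                L[v] = U[a] * U[b]
                logscale[v] = logscale[a] + logscale[b]
                m = L[v].max(axis=0)
                m[m == 0] = 1.0
                L[v] /= m
                logscale[v] += np.log(m)
            if v != tree.root:
                U[v] = P[v] @ L[v]
        return P, L, U, logscale

    def loglik_full(self, blens: np.ndarray) -> float:
        """Log-likelihood given per-node rooted branch lengths."""
        _, L, _, logscale = self._up_pass(blens)
        site = self.model.pi @ L[self.tree.root]
        return float(self.counts @ (np.log(site) + logscale[self.tree.root]))

    def loglik(self, params: np.ndarray) -> float:
        return self.loglik_full(self.param.to_node_lengths(params))

    def loglik_grad(self, params: np.ndarray):
        """(log-likelihood, gradient w.r.t. unrooted branch parameters)."""
        tree = self.tree
        blens = self.param.to_node_lengths(params)
        P, L, U, logscale = self._up_pass(blens)
        root = tree.root
        site = self.model.pi @ L[root]
        ll = float(self.counts @ (np.log(site) + logscale[root]))

        # down pass: R[v] = conditional likelihood of everything outside v's
        # subtree, as seen from v's parent-side state; per-pattern scale is
        # arbitrary because the derivative is a ratio.
        R = np.empty_like(L)
        R[root] = self.model.pi[:, None]
        G = np.empty_like(L)  # R[parent] * sibling up-message
        for v in self._post[::-1]:  # preorder
            if v < tree.n_tips:
                continue
            a, b = tree.children[v]
            G[a] = R[v] * U[b]
            G[b] = R[v] * U[a]
            if a >= tree.n_tips:
                R[a] = P[a].T @ G[a]
                m = R[a].max(axis=0)
                m[m == 0] = 1.0
                R[a] /= m
            if b >= tree.n_tips:
                R[b] = P[b].T @ G[b]
                m = R[b].max(axis=0)
                m[m == 0] = 1.0
                R[b] /= m

        Q = self._QT
        grad = np.empty(self.param.n_params)
        for i, v in enumerate(self.param.nodes):
            QP = Q @ P[v]
            num = np.einsum("ip,ij,jp->p", G[v], QP, L[v])
            den = np.einsum("ip,ij,jp->p", G[v], P[v], L[v])
            grad[i] = float(self.counts @ (num / den))
        return ll, grad


def pruning_loglik(aln: Alignment, tree: Tree, blens: np.ndarray,
                   model: SubstModel) -> float:
    """Exact pruning log-likelihood for per-node rooted branch lengths."""
    if np.any(np.asarray(blens) < 0):
        raise ValueError("negative branch length")
    return TreeLikelihood(tree, aln, model).loglik_full(np.asarray(blens, float))


def fit_ml_branch_lengths(aln: Alignment, tree: Tree, model: SubstModel,
                          x0: np.ndarray | None = None,
                          bound: float = 20.0):
    """ML unrooted branch lengths by L-BFGS-B with analytic gradients.

    Returns ``(lik, params_hat, ll_hat)`` where ``lik`` is the
    :class:`TreeLikelihood` (exposing the parameter convention).
    """
    lik = TreeLikelihood(tree, aln, model)
    n = lik.param.n_params
    if x0 is None:
        x0 = np.full(n, 0.1)

    def negloglik(x):
        ll, g = lik.loglik_grad(x)
        return -ll, -g

    res = minimize(negloglik, x0, jac=True, method="L-BFGS-B",
                   bounds=[(1e-8, bound)] * n,
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})
    return lik, res.x, -float(res.fun)


@dataclass
class ApproxLikSurface:
    """Second-order expansion of the log-likelihood around the ML branch lengths.

    ``loglik(b) ~= ll0 + g.(b - b_hat) + 0.5 (b - b_hat)^T H (b - b_hat)``
    in the unrooted branch parameterization of ``param``.
    """

    param: BranchParam
    b_hat: np.ndarray
    grad: np.ndarray
    hessian: np.ndarray
    ll0: float
    n_sites: int = 0

    def loglik(self, params: np.ndarray) -> float:
        d = params - self.b_hat
        return self.ll0 + float(self.grad @ d) + 0.5 * float(d @ self.hessian @ d)

    def loglik_from_node_lengths(self, blens: np.ndarray) -> float:
        return self.loglik(self.param.from_node_lengths(blens))

    def validate(self, grad_tol: float | None = None):
        if not np.allclose(self.hessian, self.hessian.T, atol=1e-6):
            raise ValueError("Hessian not symmetric")
        if grad_tol is None:
            # optimizer leaves |g| ~ O(1) per unit branch length where the
            # curvature is O(n_sites / b); scale the check with the data
            grad_tol = max(1.0, 2.5e-3 * self.n_sites)
        interior = self.b_hat > 1e-6
        if np.max(np.abs(self.grad[interior]), initial=0.0) > grad_tol:
            raise ValueError("gradient not ~0 at interior ML point")


def fit_approx_surface(aln: Alignment, tree: Tree, model: SubstModel,
                       x0: np.ndarray | None = None) -> ApproxLikSurface:
    """Fit ML branch lengths and the local quadratic log-likelihood surface."""
    lik, b_hat, ll0 = fit_ml_branch_lengths(aln, tree, model, x0=x0)
    _, g = lik.loglik_grad(b_hat)
    n = len(b_hat)
    H = np.empty((n, n))
    for i in range(n):
        h = 1e-4 * max(b_hat[i], 1e-2)
        xp, xm = b_hat.copy(), b_hat.copy()
        xp[i] += h
        xm[i] = max(xm[i] - h, 1e-9)
        _, gp = lik.loglik_grad(xp)
        _, gm = lik.loglik_grad(xm)
        H[i] = (gp - gm) / (xp[i] - xm[i])
    H = 0.5 * (H + H.T)
    # boundary (zero-length) branches leave flat or spuriously convex
    # directions in the finite-difference Hessian; clip eigenvalues so the
    # surface stays concave and the powered posterior stays proper
    lam, U = np.linalg.eigh(H)
    lam = np.minimum(lam, -1e-4)
    H = (U * lam) @ U.T
    H = 0.5 * (H + H.T)
    return ApproxLikSurface(lik.param, b_hat, g, H, ll0, n_sites=lik.n_sites)
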