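"""Synthetic data with known ground truth for the dating pipeline.

Generates birth-death timetrees, per-branch clock rates (strict / IR / AR),
alignments evolved under the same substitution models the likelihood uses,
topology-perturbed ("transferred") gene families, calibrations bracketing
true node ages, and binary gene-content matrices mixing trait-associated
columns with purely phylogenetically conserved ones.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import AA_ALPHABET, DNA_ALPHABET, Alignment
from .calibrations import Calibration
from .models import SubstModel, get_model
from .tree import TimeTree, Tree

__all__ = ["SimulationConfig", "simulate_birth_death_tree",
           "simulate_branch_rates", "evolve_alignment", "perturb_gene_tree",
           "generate_calibrations", "simulate_presence_absence"]

_MA = 100.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Rates are per lineage per 100 Ma (birth/death) and substitutions per
    site per 100 Ma (clock); ages in Ma.
    """

    seed: int = 0
    n_tips: int = 16
    birth_rate: float = 0.08
    death_rate: float = 0.04
    root_age: float = 3000.0
    clock: str = "strict"          # strict | IR | AR
    mean_rate: float = 0.03
    sigma2: float = 0.0            # log-variance of the relaxed clock
    subst_model: str = "jc"        # jc | hky | poisson
    kappa: float = 2.0
    sites: int = 1000
    n_congruent: int = 10
    n_incongruent: int = 6
    nni_moves: int = 2
    calibration_offset: float = 0.2  # fractional bracket half-width

    def __post_init__(self):
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ValueError("need birth_rate > 0 and death_rate >= 0")
        if self.mean_rate <= 0 or self.root_age <= 0:
            raise ValueError("rates and root age must be > 0")
        if self.sigma2 < 0 or (self.sigma2 == 0) != (self.clock == "strict"):
            if self.sigma2 < 0:
                raise ValueError("sigma2 must be >= 0")
        if self.n_tips < 4:
            raise ValueError("need n_tips >= 4")

    def model(self) -> SubstModel:
        return get_model(self.subst_model, kappa=self.kappa)


# --------------------------------------------------------------------------
# trees
# --------------------------------------------------------------------------

def _sample_kernel_ages(n: int, lam: float, mu: float, root_age: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws from the birth-death node-age kernel given the root age."""
    from .treeprior import bd_kernel_cdf
    u = rng.uniform(size=n)
    t1 = root_age / _MA  # kernel works in 100-Ma units (rates are per 100 Ma)
    lo = np.zeros(n)
    hi = np.full(n, t1)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        below = bd_kernel_cdf(mid, lam, mu, t1) < u
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi) * _MA


def _tree_from_ages(node_ages: np.ndarray, root_age: float, n_tips: int,
                    rng: np.random.Generator) -> TimeTree:
    """Random labeled history with the given internal node ages (root first)."""
    ages_desc = np.sort(node_ages)[::-1]
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=int)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    ages = np.zeros(n_nodes)
    root = n_tips  # internal ids n_tips..n_nodes-1; root gets the oldest age
    next_internal = n_tips
    ages[root] = root_age
    open_slots = [root, root]  # parents awaiting a child
    next_internal += 1
    for t in ages_desc:
        v = next_internal
        next_internal += 1
        ages[v] = t
        i = rng.integers(len(open_slots))
        p = open_slots.pop(i)
        parent[v] = p
        children[p].append(v)
        open_slots.extend([v, v])
    tip_order = rng.permutation(n_tips)
    for tip, p in zip(tip_order, open_slots):
        parent[tip] = p
        children[p].append(int(tip))
    labels = [f"T{i+1}" for i in range(n_tips)]
    return TimeTree(parent, children, labels, ages)


def simulate_birth_death_tree(cfg: SimulationConfig,
                              rng: np.random.Generator | None = None,
                              method: str = "kernel",
                              max_tries: int = 5000) -> TimeTree:
    """Rooted binary ultrametric tree with ``n_tips`` extant tips, conditioned
    on ``n_tips`` and ``root_age``.

    ``method="kernel"`` (default) draws the non-root node ages directly from
    the birth-death age kernel conditional on the root age and assembles a
    random labeled history — the exact generative twin of the dating prior.
    ``method="forward"`` runs a forward Gillespie simulation, rejects unless
    exactly ``n_tips`` lineages survive, and rescales the reconstructed root
    to ``root_age``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lam, mu = cfg.birth_rate, cfg.death_rate
    if method == "kernel":
        node_ages = _sample_kernel_ages(cfg.n_tips - 2, lam, mu,
                                        cfg.root_age, rng)
        return _tree_from_ages(node_ages, cfg.root_age, cfg.n_tips, rng)
    if method != "forward":
        raise ValueError(f"unknown method {method!r}")

    # horizon with expected survivor count ~ n_tips
    if lam > mu:
        horizon = math.log(max(cfg.n_tips / 2.0, 1.5)) / (lam - mu)
    else:
        horizon = cfg.n_tips / (2.0 * lam)
    for _ in range(max_tries):
        tree = _forward_gillespie(cfg.n_tips, lam, mu, horizon, rng)
        if tree is None:
            continue
        scale = cfg.root_age / tree.ages[tree.root]
        ages = tree.ages * scale
        ages[: tree.n_tips] = 0.0
        return TimeTree(tree.parent, tree.children, tree.labels, ages)
    raise RuntimeError("birth-death simulation failed: non-viable parameters")


def _forward_gillespie(n_tips, lam, mu, horizon, rng):
    """One forward pass; returns the reconstructed survivor tree or None."""
    events = {0: [0.0, None]}  # id -> [birth_time, fate]
    alive, next_id, t = [0], 1, 0.0
    while alive:
        n = len(alive)
        t += rng.exponential(1.0 / (n * (lam + mu)))
        if t >= horizon:
            break
        v = alive.pop(rng.integers(n))
        if rng.uniform() < lam / (lam + mu):
            a, b = next_id, next_id + 1
            next_id += 2
            events[a] = [t, None]
            events[b] = [t, None]
            events[v][1] = (a, b, t)
            alive.extend([a, b])
            if len(alive) > 6 * n_tips:
                return None
        else:
            events[v][1] = ("dead", t)
    if len(alive) != n_tips:
        return None
    keep = set(alive)

    def build(v, birth):
        fate = events[v][1]
        if fate is None or fate[0] == "dead":
            return {"tip": True, "age": 0.0} if v in keep else None
        a, b, ts = fate
        left, right = build(a, ts), build(b, ts)
        if left is None and right is None:
            return None
        if left is None or right is None:
            return left or right
        return {"kids": (left, right), "age": horizon - ts}

    spec = build(0, 0.0)
    if spec is None or "kids" not in spec:
        return None
    tips, internals = [], []

    def walk(node):
        if "tip" in node:
            tips.append(node)
            return ("t", len(tips) - 1)
        refs = [walk(k) for k in node["kids"]]
        internals.append((node, refs))
        return ("i", len(internals) - 1)

    walk(spec)
    n_t = len(tips)
    n_nodes = n_t + len(internals)
    parent = np.full(n_nodes, -1, dtype=int)
    ch: list[list[int]] = [[] for _ in range(n_nodes)]
    ages = np.zeros(n_nodes)
    for j, (node, refs) in enumerate(internals):
        vid = n_t + j
        ages[vid] = node["age"]
        for kind, k in refs:
            cid = k if kind == "t" else n_t + k
            parent[cid] = vid
            ch[vid].append(cid)
    labels = [f"T{i+1}" for i in range(n_t)]
    try:
        return TimeTree(parent, ch, labels, ages)
    except ValueError:
        return None


def simulate_branch_rates(tree: TimeTree, cfg: SimulationConfig,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-node branch rates (subst/site/100 Ma); root entry unused (0).

    strict: all ``mean_rate``.  IR: iid lognormal with mean ``mean_rate``
    (log-mean = log m - sigma2/2).  AR: geometric Brownian along the tree,
    child log-rate ~ N(parent log-rate - sigma2*dt/2, sigma2*dt), dt the
    child branch duration in 100-Ma units; root-child parents start at log m.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    n = tree.n_nodes
    rates = np.zeros(n)
    nonroot = np.array([v for v in range(n) if v != tree.root])
    if cfg.clock == "strict" or cfg.sigma2 == 0.0:
        rates[nonroot] = cfg.mean_rate
        return rates
    m, s2 = cfg.mean_rate, cfg.sigma2
    if cfg.clock == "IR":
        rates[nonroot] = rng.lognormal(math.log(m) - s2 / 2.0,
                                       math.sqrt(s2), len(nonroot))
        return rates
    if cfg.clock != "AR":
        raise ValueError(f"unknown clock kind {cfg.clock!r}")
    logr = np.zeros(n)
    dur = tree.durations() / _MA
    for v in tree.postorder[::-1]:  # preorder: parents first
        if v == tree.root:
            logr[v] = math.log(m)
            continue
        var = s2 * dur[v]
        logr[v] = rng.normal(logr[tree.parent[v]] - var / 2.0, math.sqrt(var))
    rates[nonroot] = np.exp(logr[nonroot])
    return rates


# --------------------------------------------------------------------------
# sequences
# --------------------------------------------------------------------------

def evolve_alignment(tree: Tree, rates: np.ndarray, cfg: SimulationConfig,
                     rng: np.random.Generator | None = None,
                     durations: np.ndarray | None = None) -> Alignment:
    """Evolve ``cfg.sites`` iid sites along the tree.

    Branch length = rate x duration(100 Ma); expected substitutions per
    branch = rate x duration x sites.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    model = cfg.model()
    k = model.n_states
    if durations is None:
        if not isinstance(tree, TimeTree):
            raise ValueError("need a TimeTree or explicit durations")
        durations = tree.durations() / _MA
    blens = rates * durations
    P = model.transition_matrices(blens)
    cumP = np.cumsum(P, axis=2)
    states = np.empty((tree.n_nodes, cfg.sites), dtype=np.int8)
    root_cum = np.cumsum(model.pi)
    states[tree.root] = np.searchsorted(root_cum, rng.uniform(size=cfg.sites))
    for v in tree.postorder[::-1]:
        if v == tree.root:
            continue
        u = rng.uniform(size=cfg.sites)
        rowcum = cumP[v][states[tree.parent[v]]]  # (sites, k)
        states[v] = (u[:, None] > rowcum).sum(axis=1)
    alphabet = DNA_ALPHABET if k == 4 else AA_ALPHABET
    return Alignment(tree.labels, states[: tree.n_tips], alphabet)


# --------------------------------------------------------------------------
# gene-tree perturbation
# --------------------------------------------------------------------------

def nni_neighbors(tree: Tree):
    """All rooted trees one NNI away (on internal edges of the unrooted tree).

    Always returns plain topologies: node ages cannot survive a subtree swap.
    """
    if isinstance(tree, TimeTree):
        tree = Tree(tree.parent.copy(), [list(c) for c in tree.children],
                    list(tree.labels))

    def swap(t2, node_a, node_b):
        pa, pb = t2.parent[node_a], t2.parent[node_b]
        t2.children[pa][t2.children[pa].index(node_a)] = node_b
        t2.children[pb][t2.children[pb].index(node_b)] = node_a
        t2.parent[node_a], t2.parent[node_b] = pb, pa
        t2._postorder = None
        return t2

    out = []
    # internal edges below the root: swap a child of v with v's sibling
    for v in range(tree.n_tips, tree.n_nodes):
        u = tree.parent[v]
        if v == tree.root or u == tree.root:
            continue
        sib = [c for c in tree.children[u] if c != v][0]
        for ci in range(2):
            out.append(swap(tree.copy(), tree.children[v][ci], sib))
    # the root-spanning edge (internal in the unrooted tree iff both root
    # children are internal): swap across the root
    a, b = tree.children[tree.root]
    if a >= tree.n_tips and b >= tree.n_tips:
        for cj in range(2):
            out.append(swap(tree.copy(), tree.children[a][0],
                            tree.children[b][cj]))
    return out


def perturb_gene_tree(tree: Tree, n_moves: int, seed: int,
                      max_tries: int = 50) -> Tree:
    """Apply ``n_moves`` random NNI moves; re-draw until the unrooted topology
    differs from the input (guaranteed for n_moves >= 1)."""
    if tree.n_tips < 4:
        raise ValueError("tree too small for NNI (< 4 tips)")
    if n_moves == 0:
        return tree.copy()
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        t = tree.copy()
        for _ in range(n_moves):
            nbrs = nni_neighbors(t)
            t = nbrs[rng.integers(len(nbrs))]
        if not t.same_unrooted_topology(tree):
            return t
    raise RuntimeError("could not produce a distinct topology")


# --------------------------------------------------------------------------
# calibrations and gene content
# --------------------------------------------------------------------------

def generate_calibrations(true_tree: TimeTree, nodes, style: str = "joint",
                          seed: int = 0, offset: float = 0.2,
                          pL: float = 0.025, pU: float = 0.025) -> list:
    """Calibrations bracketing the true node ages.

    ``nodes`` maps a clade name to either a node id or a (tip_a, tip_b)
    anchor.  ``style``: joint (tL = (1-offset)*true, tU = (1+offset)*true),
    min (tL = (1-offset)*true), max (tU = (1+offset)*true).  The root, if
    listed, always receives a max-style component (joint when style=joint).
    """
    rng = np.random.default_rng(seed)
    out = []
    for name, anchor in nodes.items():
        if isinstance(anchor, tuple):
            node = true_tree.mrca(set(anchor))
            tip_a, tip_b = anchor
        else:
            node = int(anchor)
            ca, cb = true_tree.children[node]
            tip_a = min(true_tree.tip_set(ca))
            tip_b = min(true_tree.tip_set(cb))
        true_age = float(true_tree.ages[node])
        kind = style
        if node == true_tree.root and style == "min":
            kind = "joint"
        tL = (1.0 - offset) * true_age if kind in ("min", "joint") else None
        tU = (1.0 + offset) * true_age if kind in ("max", "joint") else None
        out.append(Calibration(name=name, tip_a=tip_a, tip_b=tip_b, kind=kind,
                               tL=tL, tU=tU, pL=pL, pU=pU))
        if not ((tL is None or tL <= true_age) and (tU is None or true_age <= tU)):
            raise RuntimeError("calibration does not bracket the true age")
    return out


@dataclass(frozen=True)
class FocalColumnSpec:
    """A gene-content column associated with a focal phenotype group."""
    effect: float          # shift of presence probability inside the group
    base: float = 0.15     # background presence probability


def simulate_presence_absence(tree: TimeTree, n_background: int,
                              focal_specs, group_tips, seed: int = 0,
                              conservation: float = 1.0):
    """Binary genome x gene-family matrix with planted associations.

    Focal columns are Bernoulli with presence probability ``base`` shifted by
    ``effect`` for genomes in ``group_tips``.  Background columns evolve as a
    symmetric two-state Markov process along the tree with persistence
    ``conservation`` (expected changes per branch = duration/(100 Ma x
    conservation)); they carry phylogenetic signal only.

    Returns (matrix (n_tips, n_cols) int8, column names); focal columns first.
    """
    rng = np.random.default_rng(seed)
    group = np.array([l in set(group_tips) for l in tree.labels])
    cols, names = [], []
    for i, spec in enumerate(focal_specs):
        p = np.where(group, spec.base + spec.effect, spec.base)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("focal presence probability outside [0, 1]")
        cols.append((rng.uniform(size=tree.n_tips) < p).astype(np.int8))
        names.append(f"focal_{i+1}")
    dur = tree.durations() / _MA
    rate = 1.0 / conservation if np.isfinite(conservation) else 0.0
    for j in range(n_background):
        state = np.zeros(tree.n_nodes, dtype=np.int8)
        state[tree.root] = rng.integers(2)
        for v in tree.postorder[::-1]:
            if v == tree.root:
                continue
            p_flip = 0.5 * (1.0 - math.exp(-2.0 * rate * dur[v]))
            flip = rng.uniform() < p_flip
            state[v] = state[tree.parent[v]] ^ int(flip)
        cols.append(state[: tree.n_tips].copy())
        names.append(f"bg_{j+1}")
    return np.column_stack(cols) if cols else np.zeros((tree.n_tips, 0), np.int8), names
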