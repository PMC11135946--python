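"""Gene-verticality screening by topology congruence (delta log-likelihood).

A gene family's dLL is the gap between its best topology's maximum
log-likelihood and the maximum log-likelihood constrained to the species
topology (branch lengths re-optimized in both terms).  Genes with large dLL
are topologically incongruent with the species tree — candidate transfers —
and the two screening protocols remove them stepwise (gene removal) or scan
them in rank order (sliding window), re-dating at each step and tracking the
age gap between two focal clades.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import Alignment, concatenate
from .calibrations import CladeRef
from .likelihood import fit_ml_branch_lengths
from .mcmc import PosteriorSample, clade_ages, hpd_interval
from .models import SubstModel
from .simulate import nni_neighbors
from .tree import Tree, prune_to

__all__ = ["GeneFamily", "ScreeningTrajectory", "compute_delta_ll",
           "gene_removal_series", "sliding_window_series", "clade_age_gap",
           "enumerate_unrooted_topologies"]


@dataclass
class GeneFamily:
    """One gene's alignment plus its congruence score against the species tree."""

    name: str
    alignment: Alignment
    delta_ll: float = np.nan
    gene_topology: Tree | None = None

    def __post_init__(self):
        if not np.isnan(self.delta_ll) and self.delta_ll < 0:
            raise ValueError("delta_ll must be >= 0")


# --------------------------------------------------------------------------
# topology search
# --------------------------------------------------------------------------

def enumerate_unrooted_topologies(labels):
    """All distinct unrooted binary topologies, as rooted representatives.

    The representative roots each tree on the branch leading to the first
    (sorted) label, so the rooted likelihood with merged root branches equals
    the unrooted likelihood.  Counts: 3 for 4 taxa, 15 for 5, 105 for 6...
    """
    labels = sorted(labels)
    if len(labels) < 4:
        raise ValueError("need >= 4 taxa to enumerate topologies")

    # nested-tuple trees over labels[1:], then attach labels[0] at the root
    def grow(trees, label):
        out = []
        for t in trees:
            for spot, sub in enumerate(_edges(t)):
                out.append(_insert(t, spot, label))
        return out

    def _edges(t):
        # count insertion spots = all subtree positions
        if isinstance(t, str):
            return [t]
        return [t] + _edges(t[0]) + _edges(t[1])

    def _insert(t, spot, label, counter=None):
        # re-walk positions in the same order as _edges
        state = {"i": -1}

        def rec(u):
            state["i"] += 1
            if state["i"] == spot:
                return (u, label)
            if isinstance(u, str):
                return u
            return (rec(u[0]), rec(u[1]))

        return rec(t)

    trees = [(labels[1], labels[2])]
    for lab in labels[3:]:
        trees = grow(trees, lab)
    return [_tuple_to_tree(labels[0], t, labels) for t in trees]


def _tuple_to_tree(first_label, nested, labels) -> Tree:
    lab_id = {l: i for i, l in enumerate(labels)}
    n_tips = len(labels)
    counter = [n_tips]
    parent_of, children_of = {}, {}

    def build(u):
        if isinstance(u, str):
            return lab_id[u]
        i = counter[0]
        counter[0] += 1
        kids = [build(u[0]), build(u[1])]
        children_of[i] = kids
        return i

    sub = build(nested)
    root = counter[0]
    counter[0] += 1
    children_of[root] = [lab_id[first_label], sub]
    n_nodes = counter[0]
    parent = np.full(n_nodes, -1, dtype=int)
    ch = [[] for _ in range(n_nodes)]
    for p, kids in children_of.items():
        ch[p] = kids
        for k in kids:
            parent[k] = p
    return Tree(parent, ch, labels)


def rooted_representative(topology: Tree) -> Tree:
    """Strip branch lengths; keep the rooted shape (for likelihood search)."""
    return Tree(topology.parent.copy(), [list(c) for c in topology.children],
                list(topology.labels))


def compute_delta_ll(gene: Alignment, species_topology: Tree,
                     subst_model: SubstModel, search: str = "auto",
                     max_nni_rounds: int = 5) -> tuple:
    """(dLL, best topology): congruence score of one gene family.

    dLL = max over topologies of the gene's ML log-likelihood minus its ML
    log-likelihood on the species topology.  Exhaustive search for <= 7 taxa
    (or ``search="exhaustive"``), NNI hill-climbing from the species topology
    otherwise.  The species topology is pruned to the gene's taxa.
    """
    taxa = sorted(gene.labels)
    if len(taxa) < 4:
        raise ValueError("need >= 4 taxa for topology comparison")
    if not set(taxa) <= set(species_topology.labels):
        raise ValueError("gene taxa not contained in the species tree")
    sp = prune_to(species_topology, taxa)
    sp = rooted_representative(sp)
    _, _, ll_sp = fit_ml_branch_lengths(gene, sp, subst_model)

    if search == "exhaustive" or (search == "auto" and len(taxa) <= 7):
        best_ll, best_tree = -np.inf, None
        for cand in enumerate_unrooted_topologies(taxa):
            _, _, ll = fit_ml_branch_lengths(gene, cand, subst_model)
            if ll > best_ll:
                best_ll, best_tree = ll, cand
    elif search in ("auto", "nni"):
        cur, cur_ll = sp, ll_sp
        for _ in range(max_nni_rounds):
            improved = False
            for cand in nni_neighbors(cur):
                _, _, ll = fit_ml_branch_lengths(gene, cand, subst_model)
                if ll > cur_ll + 1e-6:
                    cur, cur_ll, improved = cand, ll, True
            if not improved:
                break
        best_ll, best_tree = cur_ll, cur
    else:
        raise ValueError(f"unknown search {search!r}")
    return max(0.0, best_ll - ll_sp), best_tree


def score_genes(genes, species_topology, subst_model, search="auto"):
    """Fill in delta_ll for a list of GeneFamily objects (in place)."""
    for g in genes:
        g.delta_ll, g.gene_topology = compute_delta_ll(
            g.alignment, species_topology, subst_model, search=search)
    return genes


# --------------------------------------------------------------------------
# screening protocols
# --------------------------------------------------------------------------

@dataclass
class ScreeningTrajectory:
    """Per-step record of a screening run (one row per removal step / window)."""

    mode: str                     # "removal" | "window"
    rows: list = field(default_factory=list)
    error: str | None = None      # set when dating failed mid-trajectory

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    @property
    def age_gaps(self) -> np.ndarray:
        return np.array([r["age_gap"] for r in self.rows])

    @property
    def mean_dlls(self) -> np.ndarray:
        return np.array([r["mean_dll"] for r in self.rows])


def clade_age_gap(posterior: PosteriorSample, clade_a: CladeRef,
                  clade_b: CladeRef, scope: str = "total") -> float:
    """mean age of clade B's node minus clade A's (negative => A older)."""
    a = CladeRef(clade_a.name, clade_a.tip_a, clade_a.tip_b, scope)
    b = CladeRef(clade_b.name, clade_b.tip_a, clade_b.tip_b, scope)
    return float(np.mean(clade_ages(posterior, b))
                 - np.mean(clade_ages(posterior, a)))


def _sorted_by_dll(genes):
    missing = [g.name for g in genes if np.isnan(g.delta_ll)]
    if missing:
        raise ValueError(f"genes without delta_ll: {missing}")
    # descending dLL; ties broken lexicographically for reproducibility
    return sorted(genes, key=lambda g: (-g.delta_ll, g.name))


def _record(step_label, retained, post, clade_a, clade_b, scope):
    row = {"step": step_label,
           "n_genes": len(retained),
           "genes_retained": ",".join(g.name for g in retained),
           "mean_dll": float(np.mean([g.delta_ll for g in retained]))}
    for clade in (clade_a, clade_b):
        ref = CladeRef(clade.name, clade.tip_a, clade.tip_b, scope)
        draws = clade_ages(post, ref)
        lo, hi = hpd_interval(draws)
        row[f"{clade.name}_mean"] = float(draws.mean())
        row[f"{clade.name}_hpd_lo"] = lo
        row[f"{clade.name}_hpd_hi"] = hi
    row["age_gap"] = row[f"{clade_b.name}_mean"] - row[f"{clade_a.name}_mean"]
    return row


def gene_removal_series(genes, date_fn, clade_a: CladeRef, clade_b: CladeRef,
                        step: int = 2, floor: int = 6,
                        scope: str = "total") -> ScreeningTrajectory:
    """Drop the ``step`` most incongruent genes per iteration and re-date.

    ``date_fn(alignment) -> PosteriorSample`` dates a concatenate on the fixed
    species topology.  The trajectory records, per step, the retained genes,
    their mean dLL, the two focal clades' ages, and the age gap; it stops
    when ``floor`` genes remain.
    """
    retained = _sorted_by_dll(genes)
    if len(retained) < floor + step:
        raise ValueError("too few genes for a removal series")
    traj = ScreeningTrajectory(mode="removal")
    step_i = 0
    while True:
        try:
            post = date_fn(concatenate([g.alignment for g in retained]))
        except Exception as e:
            traj.error = f"dating failed at step {step_i}: {e}"
            break
        traj.rows.append(_record(step_i, retained, post, clade_a, clade_b, scope))
        if len(retained) - step < floor:
            break
        retained = retained[step:]  # drop the largest-dLL genes
        step_i += 1
    return traj


def sliding_window_series(genes, date_fn, clade_a: CladeRef, clade_b: CladeRef,
                          k: int = 10, step: int = 1,
                          scope: str = "total") -> ScreeningTrajectory:
    """Date every window of ``k`` genes along the dLL ranking (low to high).

    Number of windows = n_genes - k + 1 at step 1.
    """
    if k > len(genes):
        raise ValueError("window size exceeds the number of genes")
    ranked = _sorted_by_dll(genes)[::-1]  # ascending dLL
    traj = ScreeningTrajectory(mode="window")
    for i, start in enumerate(range(0, len(ranked) - k + 1, step)):
        window = ranked[start:start + k]
        try:
            post = date_fn(concatenate([g.alignment for g in window]))
        except Exception as e:
            traj.error = f"dating failed at window {i}: {e}"
            break
        traj.rows.append(_record(i, window, post, clade_a, clade_b, scope))
    return traj
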