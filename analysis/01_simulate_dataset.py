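#!/usr/bin/env python
"""Generate the study dataset: a 16-tip birth-death timetree with known node
ages, 10 vertically inherited + 6 topology-perturbed gene families, bracketing
fossil-style calibrations, and a binary gene-content matrix with planted
trait-associated columns.

Writes results/data/ (species tree, per-gene FASTA, calibration TSV, gene
truth table, presence/absence TSV).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from molclock.alignment import write_fasta
from molclock.calibrations import write_calibrations
from molclock.pipeline import RunContext, stage_seed
from molclock.simulate import (FocalColumnSpec, SimulationConfig,
                               evolve_alignment, generate_calibrations,
                               perturb_gene_tree, simulate_birth_death_tree,
                               simulate_branch_rates,
                               simulate_presence_absence)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/data")


def main():
    ctx = RunContext(OUT, SEED, {"stage": "simulate"}, force=True)
    cfg = SimulationConfig(seed=SEED, n_tips=16, sites=300, clock="strict",
                           mean_rate=0.015, root_age=3000,
                           n_congruent=10, n_incongruent=6, nni_moves=2)
    rng = np.random.default_rng(ctx.stage_seed("tree"))
    tree = simulate_birth_death_tree(cfg, rng)
    ctx.write_text(tree.to_newick(), "species_tree.nwk")
    print(f"species tree: {tree.n_tips} tips, root {tree.root_age:.0f} Ma")

    # focal clades for the screening analysis: A's total group pushed older
    # and B's younger in the transferred genes' history (planted age offset)
    internal = sorted((v for v in tree.internal_ids if v != tree.root),
                      key=lambda v: -tree.ages[v])
    crown_a = next(v for v in internal if tree.parent[v] != tree.root
                   and v >= tree.n_tips)
    crown_b = next(v for v in internal
                   if not (tree.tip_set(v) & tree.tip_set(crown_a))
                   and tree.parent[v] != tree.root
                   and tree.parent[v] != tree.parent[crown_a])
    dist_ages = tree.ages.copy()
    a_tot, b_tot = tree.parent[crown_a], tree.parent[crown_b]
    dist_ages[a_tot] = 0.95 * tree.ages[tree.parent[a_tot]]
    dist_ages[b_tot] = 1.1 * max(tree.ages[c] for c in tree.children[b_tot])
    from molclock.tree import TimeTree
    distorted = TimeTree(tree.parent.copy(),
                         [list(c) for c in tree.children],
                         list(tree.labels), dist_ages)
    rows = []
    for name, crown, tot in (("cladeA", crown_a, a_tot),
                             ("cladeB", crown_b, b_tot)):
        ca, cb = tree.children[crown]
        rows.append({"clade": name,
                     "tip_a": min(tree.tip_set(ca)),
                     "tip_b": min(tree.tip_set(cb)),
                     "true_total_age": float(tree.ages[tot]),
                     "distorted_total_age": float(dist_ages[tot])})
    ctx.write(pd.DataFrame(rows), "focal_clades.tsv")
    print("planted screening offset:", rows)

    (OUT / "genes").mkdir(exist_ok=True)
    durs = tree.durations() / 100.0
    durs_d = distorted.durations() / 100.0
    truth = []
    grng = np.random.default_rng(ctx.stage_seed("genes"))
    for i in range(cfg.n_congruent + cfg.n_incongruent):
        incongruent = i >= cfg.n_congruent
        top = (perturb_gene_tree(distorted, cfg.nni_moves,
                                 seed=int(grng.integers(2**31 - 1)))
               if incongruent else tree)
        rates = simulate_branch_rates(tree, cfg, grng)
        aln = evolve_alignment(top, rates, cfg, grng,
                               durations=durs_d if incongruent else durs)
        name = f"gene_{i+1:02d}"
        write_fasta(aln, OUT / "genes" / f"{name}.fasta")
        truth.append({"gene": name, "incongruent": incongruent})
    ctx.write(pd.DataFrame(truth), "gene_truth.tsv")
    print(f"genes: {cfg.n_congruent} congruent + {cfg.n_incongruent} "
          f"transferred (NNI-perturbed, age-shifted), {cfg.sites} sites each")

    internal = sorted((v for v in tree.internal_ids if v != tree.root),
                      key=lambda v: -tree.ages[v])
    cals = generate_calibrations(
        tree, {"root": tree.root, "old": internal[0],
               "mid": internal[len(internal) // 2]},
        style="joint", seed=ctx.stage_seed("cals"), offset=0.2)
    write_calibrations(cals, OUT / "calibrations.tsv")
    for c in cals:
        print(f"calibration {c.name}: {c.kind} [{c.tL:.0f}, {c.tU:.0f}] Ma")

    # gene content: two phylogenetically distant clades share the planted
    # focal columns — convergent gene content against a divergent backbone
    group_a = sorted(tree.tip_set(crown_a))
    group_b = sorted(tree.tip_set(crown_b))
    mat, names = simulate_presence_absence(
        tree, n_background=40,
        focal_specs=[FocalColumnSpec(effect=0.8, base=0.1)] * 12,
        group_tips=group_a + group_b, seed=ctx.stage_seed("content"),
        conservation=2.0)
    pa = pd.DataFrame(mat, index=tree.labels, columns=names)
    pa.insert(0, "group", ["focalA" if l in group_a else
                           "focalB" if l in group_b else "other"
                           for l in tree.labels])
    ctx.write(pa, "pa_matrix.tsv", index=True)
    print(f"gene content: {mat.shape[1]} families (12 focal shared by "
          f"{group_a} + {group_b}, 40 background)")
    ctx.flush_log()


if __name__ == "__main__":
    main()
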