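#!/usr/bin/env python
"""Genome-content convergence and association analyses on the simulated
presence/absence matrix.

Computes Manhattan (metabolic) and mash (nucleotide) distance matrices,
embeds both with non-metric MDS, runs the normalized-dissimilarity
permutation test between the focal group and a phylogenetically distant
clade, and the three-test association battery with BH correction.
Writes results/content/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from molclock.content import (PAMatrix, association_battery,
                              convergence_permutation_test, manhattan_matrix,
                              mash_matrix, nmds_embed)
from molclock.pipeline import RunContext, read_table
from molclock.simulate import SimulationConfig, evolve_alignment
from molclock.tree import parse_newick

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
DATA = Path("results/data")
OUT = Path("results/content")


def main():
    ctx = RunContext(OUT, SEED, {"stage": "content"}, force=True)
    nwk = "\n".join(l for l in (DATA / "species_tree.nwk").read_text().splitlines()
                    if not l.startswith("#"))
    tree = parse_newick(nwk)
    df = read_table(DATA / "pa_matrix.tsv", index_col=0)
    groups = df.pop("group").to_dict()
    pa = PAMatrix(list(df.index), list(df.columns), df.values, groups)

    met = manhattan_matrix(pa)
    ctx.write(met.to_frame(), "manhattan.tsv", index=True)
    emb = nmds_embed(met, dims=2, seed=ctx.stage_seed("nmds"))
    ctx.write(emb.coordinates.assign(stress=emb.stress),
              "nmds_metabolic.tsv", index=True)
    print(f"NMDS of the Manhattan matrix: stress {emb.stress:.3f}")

    # nucleotide dissimilarity from genome sequences evolved on the tree
    cfg = SimulationConfig(seed=ctx.stage_seed("genomes"), n_tips=tree.n_tips,
                           sites=4000, clock="strict", mean_rate=0.02,
                           root_age=3000)
    rates = np.full(tree.n_nodes, cfg.mean_rate)
    aln = evolve_alignment(tree, rates, cfg,
                           np.random.default_rng(cfg.seed))
    by_label = dict(zip(aln.labels, aln.sequences()))
    seqs = {g: by_label[g] for g in pa.genomes}  # align id order with met
    nuc = mash_matrix(seqs, k=15, sketch_size=400)
    ctx.write(nuc.to_frame(), "mash.tsv", index=True)

    group_a = [g for g, grp in groups.items() if grp == "focalA"]
    group_b = [g for g, grp in groups.items() if grp == "focalB"]
    res = convergence_permutation_test(met, nuc, group_a, group_b,
                                       n_perm=999, seed=ctx.stage_seed("perm"))
    ctx.write(pd.DataFrame([{"statistic": res.statistic,
                             "p_value": res.p_value, "n_perm": res.n_perm}]),
              "convergence_test.tsv")
    print(f"normalized metabolic vs nucleotide dissimilarity between the two "
          f"focal clades: T = {res.statistic:.3f}, "
          f"one-sided p = {res.p_value:.3f} ({res.n_perm} permutations)")

    table = association_battery(
        pa, tree, {"focal_vs_other": (["focalA", "focalB"], ["other"])},
        focal_gene="focal_1")
    ctx.write(table, "associations.tsv")
    hits = table[table.passed]
    print(f"association battery: {len(hits)}/{len(table)} genes pass all "
          f"BH-adjusted tests at 0.05; "
          f"{sum(hits.gene.str.startswith('focal'))} of the passes are "
          f"planted focal columns")
    ctx.flush_log()


if __name__ == "__main__":
    main()
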