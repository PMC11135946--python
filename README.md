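# molclock

Bayesian relaxed molecular-clock dating for deep-time phylogenies, with the
surrounding machinery an ancient-lineage dating study needs: fossil
calibrations as soft-bounded node-age priors, two-step sequential
calibration propagation from a fossil-rich to a fossil-poor clade,
gene-verticality (ΔLL) screening against horizontally transferred gene
families, clock-model selection by stepping-stone Bayes factors, and
genome-content convergence/association statistics. The package is aimed at
researchers who date microbial radiations (e.g. ammonia-oxidizing bacteria
against geochemical anchors) and want every step of that workflow as tested,
reusable code exercised end-to-end on synthetic data with known truth.

## The model in brief

For a fixed rooted topology with node ages **t** and branch rates **r**, the
posterior is

> p(**t**, **r**, θ | D) ∝ L(D | **b**(**t**, **r**)) · π(**t**) · π(**r** | θ) · π(θ)

where **b** = rate × duration are branch lengths, L is the pruning
likelihood (or its quadratic approximation around the ML branch lengths,
ℓ(b) ≈ ℓ(b̂) + gᵀΔ + ½ΔᵀHΔ), π(**t**) combines a birth–death kernel
conditioned on the root age with soft-bounded fossil calibrations (uniform
between bounds with power-decay tails; minimum bounds carry a heavy
truncated-Cauchy tail), and rates follow a strict, independent-lognormal
(IR), or autocorrelated geometric-Brownian (AR) clock. Sampling is
Metropolis-within-Gibbs with a whole-tree scale move; a power setting on the
likelihood gives the power posteriors used for stepping-stone marginal
likelihoods. A gene family's verticality score is
ΔLL = max_T ℓ(gene | T) − ℓ(gene | species topology), both terms with
re-optimized branch lengths.

## Worked example

```bash
python analysis/01_simulate_dataset.py 1   # synthetic study data -> results/data/
python analysis/02_date_species_tree.py 1  # two-chain dating -> results/dating/
python analysis/05_gene_screening.py 1     # dLL screening -> results/screening/
```

The simulated data set is a 16-tip birth–death timetree (root 3000 Ma), ten
vertically inherited genes plus six NNI-perturbed "transferred" genes whose
history carries a planted age offset between two focal clades, and three
±20% joint calibrations. The dating step prints:

```
dating on 10 vertical genes, 3000 sites
two-run convergence: correlation 1.0000, max mean diff 24 Ma, min ESS 66 -> PASS
true age inside 95% HPD at 93% of nodes; max |posterior mean - truth| = 3.2% of root age
```

i.e. two independent chains agree, and the posterior recovers the known node
ages to ~3% of the root age. The screening step ranks genes by ΔLL (the six
planted transfers carry the largest scores) and re-dates while removing the
two most incongruent genes per step:

```
total-group age gap (B - A): true -185 Ma, in the transferred genes' history -2258 Ma
gene removal (16 -> 6 genes; true gap -185 Ma):
 n_genes  mean_dll      age_gap
      16 15.569192 -1012.267891
      14  5.282297  -869.901921
      12  1.208939  -583.391709
      10  0.495121  -491.189602
       8  0.246206  -184.041345
       6  0.096749  -233.409718
sliding window (k=6): corr(age gap, window mean dLL) = -0.78
```

With all 16 genes the transferred families drag the estimated gap to
−1012 Ma; as they are removed the estimate converges on the true −185 Ma,
and sliding-window gaps correlate negatively with window mean ΔLL — the
screening signature the protocol is designed to expose. The remaining
drivers run sequential-vs-joint dating (`03`), IR-vs-AR clock selection by
stepping stone (`04`), and the genome-content analyses (`06`: Manhattan +
mash distances, NMDS, the convergence permutation test, and the
Fisher/Pearson/phylogenetic-signal association battery with BH correction).

A `molclock` command-line interface wraps the same library for user data:
`molclock simulate | date | seqdate | select-clock | screen | content | demo`
(see `molclock --help`).

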