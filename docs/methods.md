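# Methods

`molclock` implements a Bayesian node-dating pipeline for deep-time
phylogenies — the kind of analysis used to place ancient bacterial lineages
(e.g. ammonia-oxidizing bacteria) on an absolute timescale — together with
the procedures that such a study needs around the dating step: sequential
calibration propagation from a fossil-rich to a fossil-poor clade,
gene-verticality screening against horizontal transfer, clock-model
selection by Bayes factor, and genome-content convergence/association
statistics. Everything is exercised end-to-end on synthetic data with known
ground truth; this note records the models, the defaults and why, and what
the validation studies do and do not show.

## The dating model

**Data and likelihood.** A fixed rooted binary topology with alignments
evolved along it. The exact likelihood is Felsenstein pruning under a
reversible substitution model (Jukes–Cantor, HKY(κ), or Poisson+F for amino
acids), with gaps/ambiguities marginalized as fully missing. Because a
reversible likelihood depends on the two root-child branches only through
their sum, branch lengths are parameterized on the unrooted tree (the two
root branches merged), which keeps the ML optimum unique.

**Approximate likelihood.** For speed, the log-likelihood is replaced by its
second-order expansion around the ML branch lengths
ℓ(b) ≈ ℓ(b̂) + gᵀ(b−b̂) + ½(b−b̂)ᵀH(b−b̂). b̂ is found by L-BFGS-B with
analytic gradients (a down-pass of per-branch derivative messages computed in
one extra tree traversal); H by central finite differences of the analytic
gradient. The expansion is accurate within a radius of ~0.05
substitutions/site around interior optima but poor near zero-length branches
(log-curvature); the validation suite therefore checks surface-based against
exact-pruning dating directly (posterior means agree to well under 3% of the
root age on a 10-tip instance). Default: exact pruning for ≤ 30 taxa on
request, surface otherwise; both exposed everywhere.

**Time prior.** Node ages (internally in units of 100 Ma) follow a
birth–death kernel conditioned on the root age: non-root ages are i.i.d.
from g(t) = λ p₁(t)/v(t₁) with complete sampling, the λ=μ case handled by
its analytic limit, and parent>child ordering enforced as sampler support.
Defaults λ=0.08, μ=0.04 per lineage per 100 Ma: a net diversification that
spreads node ages over a ~3 Ga root-to-present span for trees of 8–24 tips
(ln(n/2)/t₁ ≈ 0.07 per 100 Ma for n=16, t₁=30), i.e. deep splits are not
crammed against the present.

**Calibrations.** Fossil constraints are proper soft-bounded densities:

* joint bound: uniform on [t_L, t_U] with power-decay tails holding masses
  p_L and p_U (default 0.025 each), continuous at the bounds;
* maximum: uniform on (0, t_U] plus an upper power tail;
* minimum: a power rise holding p_L below t_L and a heavy truncated-Cauchy
  tail above (offset 0.1·t_L, scale c·t_L, default c = 1, the usual choice
  when only a minimum is known);
* fitted density: a parametric density fitted to a first-step posterior,
  optionally truncated at the second step's root maximum and renormalized.

The root must carry a maximum, joint, or fitted calibration — the model is
not proper otherwise, and the run is refused. Calibrated non-root nodes take
their calibration density in place of the birth–death kernel term. As in all
node-dating software, the *marginal* prior at a node equals its calibration
density only up to truncation by the age ordering; the prior-recovery study
(below) quantifies this on a layout designed to keep the coupling small.

**Clocks.** Strict (one rate), independent lognormal rates
(IR: log r ~ N(log m − σ²/2, σ²) per branch, mean-preserving), and
autocorrelated geometric Brownian rates (AR: child branch log-rate ~
N(parent log-rate − σ²Δt/2, σ²Δt), Δt the child branch duration in 100 Ma;
the parent of a root-child branch is the mean log-rate). Hyperpriors: mean
log-rate ~ N(log 0.05, 1.5²); precision 1/σ² ~ Gamma(1, rate 0.05). Rates
are substitutions/site/100 Ma.

**Sampler.** Metropolis-within-Gibbs, one sweep =
gap-uniform slides of each interior node age (proposal uniform between the
oldest child and the parent; the window does not depend on the current
value, so the Hastings ratio is 1), a multiplicative root-age move, random
walks on each branch log-rate, a joint independence proposal of all branch
rates from the clock prior (exact Gibbs when the likelihood is off; it keeps
low-power rungs of stepping-stone runs mixing), repeated random-walk updates
of the hyperparameters, and a whole-tree scale move (ages × c, log-rates
− log c, Jacobian c^{n_internal}). Step sizes adapt to 20–40% acceptance
during burn-in (default 25% of iterations). A `power` setting exponentiates
the likelihood for power posteriors; `prior_only` switches it off.

## Validation studies (what the tests show)

All studies live in `molclock.validation` and are re-run from scratch by
`scripts/acceptance.py` and `tests/test_acceptance.py`. Problem sizes were
chosen once so the whole battery runs in minutes on one CPU.

1. **Prior recovery.** A fixed 8-tip tree carries a root joint bound
   [2400, 3600] Ma, a min bound (t_L=800, c=0.15) on a cherry hanging
   directly off the root, and a joint bound [400, 600] on a deeper cherry.
   This layout isolates what the check measures — that the sampler
   reproduces each calibration density (KS < 0.05 at 20,000+ draws) — by
   construction: cherries have no descendant truncation, and the min-bound
   node's only ancestor is the root, whose maximum sits far above the
   Cauchy bulk. Tail masses of the soft bounds are verified by quadrature.
   With heavy tails under interior nodes of crowded trees the marginal
   prior deviates visibly from the calibration density; that truncation is
   a property of the model (shared with standard dating software), not of
   the sampler, which is separately validated against exact rejection
   sampling on a 4-tip tree.
2. **Parameter recovery.** Twenty 16-tip/2,000-site strict-clock data sets
   (m = 0.02/100 Ma, root 3 Ga, three ±20% joint calibrations): the true
   root age must fall in the 95% HPD in ≥ 18/20 replicates with mean
   relative error < 10% (observed ~2–3%).
3. **Simulation-based calibration.** Fifty replicates draw truth from the
   model's own prior (a prior-only chain's final state plus a rate from its
   hyperprior), simulate 500 sites, re-infer, and record the posterior
   quantile of the true root age; the quantiles must pass a KS test against
   Uniform(0,1) at α = 0.01.
4. **Approximate vs exact.** Same data, same calibrations, surface vs
   pruning likelihood: posterior mean ages agree within 3% of the root age.
5. **ΔLL oracle.** The gene-verticality score (below) equals an
   independently enumerated exhaustive 5-taxon search, gene by gene.
6. **Screening recovery** (see below).
7. **Sequential vs joint** (see below).
8. **Clock-model selection** (see below).
9. **Genome-content statistics** (see below).

## Sequential (two-step) dating

Step 1 is dated with its own calibrations; for each shared node the
posterior ages are fitted by maximum likelihood to four candidate families —
lognormal, gamma, skew-normal, truncated-normal (covering right-skewed,
symmetric, and bounded shapes) — and the family with the smallest KS
statistic against the sample wins (AIC reported as a diagnostic). The
fitted densities enter step 2 as independent marginal calibrations
(posterior correlations between step-1 nodes are discarded — the method's
standard simplification and its main caveat), truncated at the step-2 root
maximum. On a partitioned toy data set (two gene blocks on one topology,
step 2 keeping only the root maximum) the sequential shared-node posterior
means match a joint run on all data within 5% of the root age.

## Gene-verticality screening

ΔLL = (max over topologies of the gene's ML log-likelihood) − (its ML
log-likelihood on the species topology), branch lengths re-optimized in both
terms under the same substitution model; exhaustive search for ≤ 7 taxa,
NNI hill-climbing otherwise. ΔLL ≥ 0 by construction, 0 when the species
topology is among the gene's ML topologies; ties in rankings break
lexicographically by gene name.

Two protocols re-date a concatenate while tracking the age gap between two
focal clades (total-group = parent of the crown node; gap = mean age of B −
mean age of A, negative when A is older): *gene removal* drops the `step`
(default 2) largest-ΔLL genes per iteration down to a floor of 6 genes;
*sliding window* dates every window of k genes (default 10; 6, 8, 10, 12
supported) along the ascending ΔLL ranking. Screening uses shortened MCMC
settings — trajectories need relative, not publication-grade, precision.

The recovery study plants the truth: a fixed 8-tip tree with clade A's total
group at 2000 Ma and clade B's at 1200 Ma (gap −800 Ma); 10 congruent genes
evolve on it, 6 "transferred" genes evolve on an age-warped tree (A at 2800,
B at 700 Ma) whose topology receives one NNI move constrained *away from the
focal clades*. The constraint is what makes the planted effect coherent: a
transferred family is flagged by its topology change elsewhere in the tree,
while its warped focal-stem durations transmit into the concatenate's
branch-length signal; a move through a focal stem would scramble the very
time signal the gene is meant to carry (heavily perturbed gene trees
contribute noise, not bias, to the focal ages). The distance between the
replicate-median estimated gap and the truth must fall monotonically while
transferred genes are being removed and stay below its starting value
afterwards — once every planted transfer is gone, the remaining steps remove
congruent genes and the trajectory only fluctuates around the truth, so
step-to-step monotonicity of that noise is not required (nor is it
meaningful). A few NNI perturbations can still be near-invisible to ΔLL, so
the study uses the median transfer-free step across replicates.

## Clock-model selection

log marginal likelihoods by stepping-stone sampling over power posteriors
p(D|θ)^β p(θ); log BF = log mL(IR) − log mL(AR), verdict at |log BF| > 1.15
(BF ≈ 3.2). Per rung, the estimator averages w = exp(Δβ·ℓ); its Monte Carlo
error comes from batch means (robust to the occasionally heavy-tailed
weights), and a rung aborts if the implied effective sample size falls
below 30. Two schedules: Beta(0.3, 1) quantiles (K = 8 default), and a
log-spaced schedule (K = 16, β_min = 10⁻⁴) for targets whose log-likelihood
spread under the power posterior scales like 1/β — exactly what a diffuse
rate prior against a sharp likelihood surface produces, so the clock
comparison uses the log-spaced schedule with moderately informative, equal
hyperpriors for both clocks (mean log-rate N(log 0.02, 0.5²), precision
Gamma(3, 1)). Data simulated under IR with σ² = 0.5 on 8 tips/500 sites
yield an IR verdict in ≥ 9/10 replicates; the estimator itself is validated
against the analytic marginal likelihood of a conjugate normal toy and
against a known normalizer.

## Genome content

* **Manhattan distance** on binary presence/absence profiles (count of
  differing gene families) — the metabolic dissimilarity.
* **Mash distance** d = −(1/k)·ln(2j/(1+j)) from bottom-s MinHash sketches
  of canonical k-mers (k = 21, sketch 1,000 by default — conventional
  genome-sketching settings); the hash is a fixed splitmix64-style mixer
  over 2-bit-encoded k-mers, so sketches are deterministic. Disjoint
  sketches map to a declared cap (default 1.0).
* **NMDS** (Kruskal stress-1, nonmetric, via iterative majorization with
  monotone regression) embeds either matrix; stress is reported.
* **Convergence permutation test.** Both matrices are z-scored over their
  off-diagonal entries (rank normalization available behind a flag); the
  statistic is the mean normalized metabolic minus mean normalized
  nucleotide distance over between-group pairs; the null permutes genome
  identities jointly in both matrices (group sizes fixed), and the
  one-sided p uses the add-one rule. The permutation null assumes genome
  labels are exchangeable under H0 — the type-I study uses an exchangeable
  generator; with strongly structured data the test is anti-conservative in
  principle, which is inherent to this design.
* **Association battery.** Per gene and contrast: two-sided Fisher's exact
  test (presence × group membership), Pearson correlation with the focal
  gene column, and Pagel's λ phylogenetic-signal test (ML over the
  λ-transformed Brownian covariance, mean and variance profiled out by GLS;
  LR against λ = 0 referred to χ²₁ — conservative, because λ = 0 is a
  boundary, so null p-values are super-uniform with an atom at 1). Binary
  traits enter as 0/1 continuous values, the common phylosig shortcut; the
  binary-appropriate D-statistic would be the rigorous alternative and is
  deliberately out of scope. BH adjustment is applied within each test
  family across genes; `passed` requires both association tests (Fisher and
  Pearson) significant after adjustment, while the phylogenetic-signal
  column describes the gene's distribution and is left to the analyst.

## Synthetic data: what it emulates, what it does not

The generator produces birth–death timetrees **conditioned on tip count and
root age by drawing node ages directly from the conditioned kernel** and
assembling a uniform labeled history — the exact generative twin of the
dating prior, which is why prior-recovery and SBC checks are meaningful
(a forward Gillespie simulator with rejection on the survivor count and
rescaling to the root age is available as `method="forward"`). Branch rates
follow the strict/IR/AR models exactly as the sampler assumes; alignments
evolve site-i.i.d. under the same substitution models the likelihood uses
(Poisson+F rather than LG for amino acids, keeping simulator and likelihood
exactly matched; LG-style exchangeabilities could be slotted behind the same
interface). Incongruent families are NNI-perturbations — a topological
discordance dial, not a mechanistic HGT model. Gene content mixes Bernoulli
trait-associated columns with two-state Markov (phylogenetically conserved)
background columns.

Passing tests therefore show the *machinery* is correct and well calibrated
under its own assumptions. They do not show robustness to model violations
real data carry: among-site rate heterogeneity, selection, alignment error,
incomplete lineage sorting, non-i.i.d. gene content, or calibration
misspecification — the dominant uncertainties in real deep-time dating.

## Numerical choices and degenerate inputs

Ages in Ma at every interface, 100-Ma units internally. Ultrametricity
enforced at parse time (relative tolerance 10⁻⁶); polytomies and duplicate
tips rejected rather than repaired. ML branch lengths bounded to
[10⁻⁸, 20]; surfaces validate Hessian symmetry and a data-scaled gradient
norm at interior optima. HPD = shortest sorted-sample window containing the
target mass (≥ 100 draws required). Zero-variance traits, degenerate
(zero-variance) posterior samples, empty groups, oversized windows, and
sub-4-taxon topology searches are rejected with named errors. Two-run
convergence requires per-node mean correlation > 0.99, a mean-difference
tolerance (default 5% of the root age), and a minimum ESS (arviz), else
warnings are attached and the check fails.
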