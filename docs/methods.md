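# Methods

## The problem

Demographic inference from the joint allele-frequency spectrum (jAFS)
routinely contrasts an isolation-with-migration history (IM: continuous gene
flow since the split) with a secondary-contact history (SC: strict isolation
from the split time T_S until a contact time T_SC).  Both model families are
usually written with an ancestral population at mutation–drift equilibrium
and daughter populations of constant size.  `jafsim` packages the machinery
needed to ask how badly that convention misleads: a two-population coalescent
simulator that *can* include recent bottlenecks with regrowth and ancestral
expansions/contractions, an inference engine over IM/SC model catalogues that
*cannot* (unless asked to), and the bookkeeping to measure the damage —
divergence-time misestimation (TS_mis), support for the wrong gene-flow
family (W_AIC), and spurious strict-isolation periods (TSI/TS).

## Units and scaling

Everything is scaled by a reference diploid size N_REF (ms conventions):

* times in units of 4·N_REF generations;
* population sizes as ratios x = N/N_REF;
* migration as M_ij = 4·N_REF·m_ij, where m_ij is the fraction of
  population i replaced by migrants from population j per generation
  (backward in time a lineage in deme i jumps to deme j at rate M_ij);
* pair coalescence at rate 2/x within a deme of relative size x;
* mutation at per-locus intensity theta = 4·N_REF·mu·L per unit of branch
  length, so E[S] = theta·a_{n-1} for a panmictic constant-size population.

The study conditions fix N_REF = 20,000 diploids, mu = 1e-8 per base per
generation and L = 36 bp (unlinked short-tag loci), giving theta = 0.0288
per locus.

## The simulator

`coalsim` is an event-driven structured coalescent over a compiled sequence
of epochs (piecewise-exponential deme sizes, piecewise-constant migration,
one merge event at T_S).  Exponential growth is handled exactly by inverting
the integrated pair-coalescence rate in closed form — no time
discretisation; a regression test checks the growth epoch against a
60-step piecewise-constant staircase of the same trajectory.  The hot path
is a numba-compiled kernel that accumulates, per genealogy, the total branch
length subtending every (i, j) class of sample counts; tree topologies are
never stored because only the jAFS is consumed downstream.
`simulate_genealogy` provides a readable pure-Python per-genealogy
counterpart, and a test asserts the two paths agree in expectation.  The
simulator is validated against msprime (branch-class expectations of the
baseline IM scenario agree within Monte-Carlo error) and against the
analytic single-population AFS E[xi_i] = theta/i.

Mutation counts per cell are Poisson given the genealogies.  Two observed-
spectrum conventions are exposed:

* **one SNP per locus** (default): each polymorphic locus contributes a
  single randomly chosen SNP.  Short-tag loci are 36 bp, so SNPs within a
  locus are perfectly linked; retaining one per locus is what makes every
  spectrum entry an independent site, which is the assumption behind the
  Poisson composite likelihood and the AIC.  Under the baseline IM study
  condition this yields ≈116,000 unlinked SNPs from 1e6 loci (20 haploid
  samples per population) and ≈9,600 from the small design (1e5 loci, 10
  haploid samples per population).
* **all sites** (`max_snps_per_locus=None`): every mutation is kept.  Used
  by the Watterson and law-of-total-expectation validation tests, where the
  exact E[S] = theta·a_{n-1} identity must hold.

Because loci are independent and Poisson superposition is exact, the
all-sites spectrum is drawn as one Poisson per cell with mean theta times
the class branch length summed over loci; the thinned mode keeps per-locus
branch-class vectors and draws the single SNP proportionally to them.

A per-genealogy event budget (200,000 events) bounds the cost of
migration-dominated corners of parameter space, where the number of
migration events grows like M times the total tree length; exceeding it
raises an error, which the fitting machinery treats as a likelihood
penalty.  Ordinary histories use well under a hundred events per genealogy,
so the budget is far from any realistic trajectory.

## Scenario grids

`build_recent_grid` reproduces a fully orthogonal 256-scenario design:
{IM with T_S = 0.05, SC with T_S = 0.1 and T_SC = 0.25·T_S} × {symmetric
M = 4, asymmetric m12 = 4 / m21 = 16} × eight ancestral-expansion levels
(none, then deep ancestral size N1/2 … N1/128 expanding at absolute time
0.5) × eight founder-bottleneck levels (none, then N2 at the split equal to
1–64 % of its present size, with exponential regrowth lasting 2,000
generations).  `build_older_grid` covers T_S = 0.05–1.6 with recent
bottlenecks at T_B = 0.05 (regrowth to the present and recovery of the
pre-crash size deeper than T_B), ancestral expansions and ancestral
contraction-with-recovery episodes.  The bottleneck-severity list for the
older grid defaults to eight log2 steps (0.5–64 %), which reproduces the
canonical 6 + 48 = 54 sub-grid size; the list is an argument, so the
7-level reading (1–64 %) can be run as well.  Ancestral-event lead times
default to {0.25, 0.5, 1} and are likewise configurable.

## Inference models

The catalogue crosses {IM, SC} × {∅, B, AE, AEB} × {∅, 2N, 2M, 2N2M} — 8
basic and 32 extended models.  SC models are parameterised by durations
(t_si of strict isolation plus t_sc of contact), which keeps the constraint
T_SC ≤ T_S implicit.  In B inference models exponential growth runs from the
onset of gene flow (the split for IMB, the contact time for SCB) to the
present — deliberately not the simulator's fixed 2,000-generation growth, to
mirror how growth is written in the standard speciation-model catalogues.
AE models let the ancestral population change size t_ae before the split.
Heterogeneity mixtures are disjoint: a fraction P of loci ("barrier
islands") has both migration rates multiplied by a factor in [0, 1]; a
fraction Q (linked-selection proxy) has all sizes multiplied by hrf ≤ 1;
P + Q ≤ 1 and the classes never overlap, which keeps the mixture convex and
the optimisation stable.

Free-parameter bounds (sizes 1e-4–100, times 1e-5–10, migration 0–50,
class fractions 0–0.5, hrf 1e-3–1) are generous envelopes around every
simulated value.

## Likelihood and optimisation

Expected spectra come from Monte-Carlo branch expectation — the mean class
branch length over `mc_reps` genealogies — rather than a diffusion/ODE
engine: it is exact in expectation for any history the simulator can
express, and it shares code with the generator, so model and data live on
the same scale.  Each optimisation fixes one random stream (common random
numbers): every likelihood evaluation re-uses the same genealogy
randomness, making the surface deterministic in the parameters.  The
remaining ruggedness scales like 1/sqrt(mc_reps); `mc_reps` defaults to
20,000 genealogies (a few-percent per-cell error for n ≤ 20 per
population) and is the explicit noise/accuracy knob.

The fit criterion is the Poisson composite likelihood standard in SFS
inference: cell counts independent Poisson with mean theta·m_ij, theta
profiled analytically as sum(obs)/sum(model) and counted as one parameter
in K (so the basic IM model has K = 6).  Model densities are floored at
1e-12 before logs (Monte-Carlo zeros in far corners).

Optimisation is the multi-round perturbed-restart recipe: each round draws
restarts by multiplying the incumbent parameters by factors log-uniform in
[1/fold, fold] and polishes each with Nelder-Mead in log-parameter space
under box bounds.  Three numerical choices matter on a Monte-Carlo-rough
surface and are deliberate:

* the schedule's `maxiter` is interpreted per free parameter (a 10-iteration
  round on a 5-parameter model allows 50 simplex iterations), matching the
  effective work of a gradient-based iteration;
* the initial simplex is wide (edge 0.6·ln(fold), floored at 0.2 log
  units) so the search strides over the noise instead of contracting into
  it, and the final round restarts the simplex once where it collapsed;
* early rounds run on a coarser surface (20 % of `mc_reps`, floored at
  2,000 genealogies); the final round and all cross-routine comparisons use
  the full resolution.

Restarts with fold = 1 are identical deterministic searches and collapse to
one.  The default schedule for simulated data is three rounds of ten
restarts (3-, 2-, 1-fold; 10/20/30 iterations); an `empirical` preset (five
rounds, five routines) mirrors heavier analyses.  Validation on the
baseline IM scenario (1e6 loci, three seeds, `mc_reps` = 40,000, starts
perturbed two-fold around the truth) recovers nu1, nu2 and T_S within a few
percent and both migration rates within ~12 % on average — the
`test_parameter_recovery` acceptance test recomputes this.

One-population models (SNM, 2EP, 3EPB) share the machinery; the SNM
expected AFS is analytic (xi_i ∝ 1/i) and needs no search.

## Model choice and bias metrics

AIC = −2·loglik + 2K per fitted model; Akaike weights
w_i = exp(−ΔAIC_i/2)/Σ exp(−ΔAIC_j/2) computed after subtracting the
minimum.  The weight of a gene-flow family is the sum over member models.
LRTs between nested fits use a plain chi-squared reference (optional
user-supplied mixture weights for boundary parameters); the Godambe
adjustment for composite likelihoods is intentionally out of scope.

`pipeline.run_scenario` simulates a scenario, fits the candidates and
reports TS_mis = T_S(est)/T_S(sim), the family weight of the true gene-flow
scenario, and TSI/TS of the winning model.  `run_grid` iterates scenarios ×
folding modes × seeds into a fixed-schema CSV and is resumable (existing
rows are skipped).

One unit subtlety matters for TS_mis: every fit carries its own reference
size, because the profiled theta pins that fit's N_ANC = theta/(4·µ·L).  A
fit can trade a smaller reference against a larger coalescent-unit split
time at no cost, so raw t_s values from different fits are not comparable.
Estimated split times are therefore rescaled by theta_fit/theta_truth —
theta profiled under the generating history on the same observed spectrum —
before the ratio to the simulated T_S is taken; this is the same
θ-anchored unscaling used to convert parameters to generations and years.
On the strongest ancestral-expansion scenario the raw coalescent-unit ratio
can exceed 20 while the physically scaled inflation is ≈4–6, capped by the
expansion time at ten times the simulated T_S.

## Summary statistics

pi (per-site heterozygosity from a 1-D AFS), d_xy (absolute divergence) and
Hudson-type F_ST (ratio of averages: one minus mean within-population over
mean between-population heterozygosity) are all linear or ratio statistics
of spectrum cells with coefficients symmetric under allele relabelling, so
they are invariant to folding.  The F_ST within-term uses the unbiased
(n/(n−1)-corrected) heterozygosity, so samples with *identical* allele
frequencies score slightly below zero (−1/(n−1) scale) rather than exactly
zero.  Folding follows the total-derived-count convention of the jAFS
inference tools: cell (i, j) with i + j > (n1+n2)/2 folds onto
(n1−i, n2−j), ties split half-and-half.

## What the generator does and does not emulate

The synthetic data are unlinked, freely recombining 36-bp loci with
infinite-sites mutation, no recombination within loci, no selection, no
sequencing error, no missing data, and exchangeable loci.  Passing tests
therefore demonstrate properties of the inference machinery under the
Wright–Fisher neutral model, not robustness to genotyping noise, reference
bias, linked selection beyond the 2N proxy, or spatial structure (no ghost
demes, no more than two populations).

## Desk-scale problem sizes

The package's own test suite and acceptance script run the full 1e6-locus
simulations for SNP counts, but fit models at desk scale: 10 haploid
samples per population, 1e4–4e4 Monte-Carlo genealogies per expected
spectrum, three replicate seeds for stochastic claims, and reduced locus
counts (2e4–1e5) for the directional bias suite.  These sizes are the
package's choice of a reproducible desk experiment; the same code runs the
full design via `run_grid` presets.  Directional claims (bottleneck ⇒ SC
chosen; TSI/TS increasing with bottleneck severity; folded inference no
worse than unfolded under strong expansion) are asserted as majorities over
seeds, not single runs.

## Which full-scale results survive desk scale

Most of the directional bias results are driven by enormous effect sizes
(an unmodeled 1 % founder bottleneck shifts the model choice by tens of
log-likelihood units even at 2–3 × 10⁴ loci) and reproduce robustly at
reduced locus counts.  One does not: on *baseline* secondary-contact data
(no size changes), the composite-likelihood gap between the converged SC
fit and the best IM fit scales linearly with the number of loci, while the
AIC penalty for SC's extra parameter is constant.  At 10⁵ loci (folded,
10 haploid samples per population) the measured gap is ≈2 log-likelihood
units — of the same order as the penalty and as the Monte-Carlo noise of
the branch-expectation engine at affordable resolutions — so the
full-design result that SC data always select the SC family holds at the
10⁶-locus scale but is seed-dependent at desk scale.  The corresponding
test is kept at the reduced-data conditions and documents this, rather
than being resized until it passes.

Two desk-scale devices improve every comparison and are on by default in
`run_scenario`: candidates are fitted in order of increasing parameter
count with starts seeded from the best simpler fit (a model ladder — the
perturbed restarts of the first round preserve global exploration), and
the final AIC ranking can be computed after re-evaluating every model's
best parameters on one shared high-resolution random stream
(`reeval_mc_reps`), which removes the per-model tilt each fit acquires by
adapting to its own common-random-number stream during optimization.

## Known limitations

* Expected spectra are Monte-Carlo estimates; with common random numbers
  the likelihood surface is deterministic but inherits an O(1/sqrt(mc_reps))
  tilt, so parameter estimates carry a small model-noise component on top
  of data noise.  Increase `mc_reps` for final reporting.
* The composite likelihood treats cells as independent Poisson; with the
  default one-SNP-per-locus spectra this is a good approximation, but
  model-selection p-values (LRT) are uncorrected for residual
  misspecification.
* The one-SNP-per-locus thinning slightly downweights loci with long
  genealogies relative to the branch-expectation model (the retention
  probability 1 − exp(−theta·L_tree) is concave in tree length); at
  theta = 0.0288 per locus the distortion is at the percent level and is
  absorbed almost entirely by the profiled theta.
* Optimisation is stochastic global search; convergence is checked by
  restarts and (optionally) independent routines, not guaranteed.
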