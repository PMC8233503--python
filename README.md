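# jafsim

Structured-coalescent simulation and jAFS-based demographic inference for
two-population divergence histories — and a test bench for how unmodeled
population-size changes bias divergence-model choice.

## The problem

When two populations of a non-model organism exchange genes today, did they
diverge *with* continuous gene flow (isolation-with-migration, **IM**) or
diverge in isolation and meet again (**secondary contact, SC**)?  The
standard answer fits both model families to the joint allele-frequency
spectrum (jAFS) by composite likelihood and ranks them with Akaike weights.
Those model families almost always assume an ancestral population at
mutation–drift equilibrium and daughter populations of constant size.  Real
histories — postglacial invasions, founder bottlenecks, ancestral
expansions — violate both assumptions, and the violations are not harmless:
a founder bottleneck mimics the excess of intermediate-frequency variants
that secondary contact produces, and an ancestral expansion drags the
estimated split time toward the expansion time.

`jafsim` packages everything needed to quantify those biases:

* a **two-population structured-coalescent simulator** (numba-accelerated,
  msprime-validated) with split, secondary contact, founder bottlenecks
  followed by exponential regrowth, and ancestral expansions/contractions,
  producing observed jAFS over unlinked 36-bp loci;
* the **scenario grids** of the bias study: 256 fully orthogonal recent
  divergence scenarios (IM/SC × symmetric/asymmetric migration × 8 ancestral
  expansions × 8 bottlenecks) plus the older-divergence grids;
* an **inference engine**: Monte-Carlo expected spectra with common random
  numbers, Poisson composite likelihood with profiled θ, multi-round
  perturbed-restart optimization, over a catalogue of 8 basic and 32
  extended models (IM/SC × B × AE × 2N/2M genomic-heterogeneity mixtures),
  plus one-population models (SNM, 2EP, 3EPB);
* **model selection**: AIC, Akaike weights, gene-flow family weights, LRTs;
* a **bias pipeline** and CLI producing, per scenario, the divergence-time
  misestimation TS_mis = T_S(est)/T_S(sim), the Akaike weight of the correct
  gene-flow family, and the inferred strict-isolation fraction TSI/TS.

The model at the core: in units of 4·N_REF generations with sizes relative
to N_REF, lineages coalesce pairwise at rate 2/x within a deme of size x,
migrate backward at rate M_ij = 4·N_REF·m_ij, and mutate at per-locus
intensity θ = 4·N_REF·µ·L per unit branch length.  Fits maximise the Poisson
composite likelihood Σ [d ln(θ̂m) − θ̂m − ln d!] with θ̂ profiled
analytically, and models are ranked by W_AIC = exp(−ΔAIC/2)/Σ exp(−ΔAIC/2).

## A worked example

The headline phenomenon from the shell.  Simulate a history that diverged
4,000 generations ago *with continuous gene flow* (IM truth: N_REF = 20,000
diploids, N₂ = 0.25·N₁, symmetric M = 4) but whose second population was
founded through a severe bottleneck — 1 % of its present size at the split,
then exponential regrowth — and ask which gene-flow family fits:

```bash
jafsim simulate --scenario recent_IM_sym_ae0_b1 --loci 100000 --seed 1 \
    --folded --out obs.fs
# wrote obs.fs: S = 10735
jafsim fit obs.fs --model IM --seed 1 --mc-reps 10000 --out im.json
jafsim fit obs.fs --model SC --seed 1 --mc-reps 10000 --out sc.json
jafsim compare im.json sc.json
```

```
model,family,K,loglik,AIC,dAIC,W_AIC
SC,SC,7,-792.389866317858,1598.779732635716,0.0,1.0
IM,IM,6,-999.0505164848153,2010.1010329696305,411.32130033391445,4.816310615530153e-90
```

The true history has gene flow at every generation since the split, yet the
secondary-contact model wins with W_AIC = 1.0 and a ΔAIC of 411: the
unmodeled founder bottleneck manufactures overwhelming support for a period
of strict isolation that never happened.  (`jafsim stats obs.fs` shows the
companion signal — F_ST ≈ 0.32 between populations that exchange four
migrants per scaled time unit.)

The same comparison through the bias pipeline, which scores the outcome
against the scenario's truth — first on the *baseline* scenario (no
bottleneck), then on the bottleneck scenario:

```python
from jafsim import build_recent_grid, build_model_catalogue
from jafsim.pipeline import run_scenario

grid = build_recent_grid("small")
im_sc = [m for m in build_model_catalogue() if m.name in ("IM", "SC")]
for sid in ("recent_IM_sym_ae0_b0", "recent_IM_sym_ae0_b1"):
    metrics, comparison, fits = run_scenario(
        grid[sid], im_sc, folded=True, seed=1, mc_reps=10_000)
    print(sid, metrics.best_model, round(metrics.w_aic_correct, 2),
          round(metrics.ts_mis, 2), round(metrics.tsi_ts, 2))
# recent_IM_sym_ae0_b0 IM 0.91 1.03 0.0
# recent_IM_sym_ae0_b1 SC 0.13 34.45 0.4
```

With no unmodeled events the correct family wins (W_AIC = 0.91) and the
split time is recovered (`ts_mis` = 1.03).  With the bottleneck, SC wins,
the divergence time is overestimated many-fold and 40 % of it is assigned
to a spurious strict-isolation phase.  `ts_mis` is computed on the physical
scale — each fit's split time is converted through its own profiled θ
(N_ANC = θ/4µL) before being compared with the simulated truth.

## Layout

```
src/jafsim/demography.py   scenario grids, model catalogue, parameter types
src/jafsim/coalsim.py      structured-coalescent kernels, jAFS simulation
src/jafsim/spectrum.py     jAFS container, folding, SFS I/O, pi/dxy/FST
src/jafsim/inference.py    expected spectra, composite likelihood, fitting
src/jafsim/selection.py    AIC, Akaike weights, family weights, LRT
src/jafsim/pipeline.py     scenario/grid runners, bias metrics
src/jafsim/cli.py          command-line interface
docs/methods.md            model, conventions, numerical choices, limits
```
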