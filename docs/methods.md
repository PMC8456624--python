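# Methods

## The enzyme-constrained formulation

A metabolic model is a stoichiometric matrix `S` over irreversible
reactions with flux bounds; steady state requires `S·v = 0`. The
enzyme-constrained (GECKO-style) augmentation introduces one
pseudo-metabolite per enzyme: a reaction `j` catalysed by enzyme `i`
consumes it at `1/kcat_ij` per unit flux, a per-enzyme *usage* reaction
`e_i` produces it while drawing `mw_i` grams of enzyme mass per mmol
from a shared pool metabolite, and a single *pool exchange* reaction
supplies the pool with upper bound `P`. Mass balance of the
pseudo-metabolites then encodes `v_j ≤ kcat_ij · e_i` and
`Σ_i mw_i · e_i ≤ P` inside an ordinary LP.

Units: fluxes mmol gDW⁻¹ h⁻¹; kcat h⁻¹ (files may declare per-second
values, converted ×3600 on load); mw g mmol⁻¹ (numerically kDa); pool
bound g gDW⁻¹, making `Σ mw·e ≤ P` dimensionally consistent. Default
`P = 0.1`.

Conventions adopted where the formulation leaves a choice:

* **Irreversibility.** Reversible reactions are split into forward and
  reverse copies (`[−a, b] → [0, b] + [0, a]` with reversed
  stoichiometry) before augmentation, so enzyme demand couples to
  non-negative flux. Uptake reactions carry positive flux.
* **Isozymes vs complexes.** Several enzymes listed on one reaction are
  treated as a complex (every subunit's pseudo-metabolite is consumed);
  alternative catalysts are expressed as parallel reaction copies, one
  per enzyme. This is the standard arm/complex treatment; the synthetic
  model exercises both (the AAD-family analog is a parallel copy of the
  fermentative alcohol-dehydrogenase direction).
* **Usage bounds.** Each usage reaction is bounded above by the
  pool-only limit `P/mw_i` — the most the pool could ever allocate to
  one enzyme. "Removing" an enzyme constraint restores this bound, not
  infinity, keeping every computation inside the ec-formulation.

All LPs are solved with HiGHS (`scipy.optimize.linprog`) at 1e-9
feasibility tolerances; optimal distributions are checked to satisfy
mass balance and bounds within 1e-6. Solutions at degenerate optima are
whichever vertex the solver returns; identical inputs give identical
outputs, and no result in this package depends on the full flux vector
of a degenerate optimum, only on objective values and invariants.

## Flexibilized constraints and lexicographic objectives

Observed values are imposed as windows: fixing a flux to `x` with
flexibilization `δ` sets bounds `[max(0, x(1−δ)), x(1+δ)]`. Growth is
fixed at 0.22 h⁻¹ with δ = 0.05 (the window [0.209, 0.231]); enzyme
bounds use δ = 0.20.

Multi-objective steps ("maximize ethanol consumption and maintenance")
are solved lexicographically: each stage's optimum `z` is fixed as
`c·v ≥ z − tol·max(1, |z|)` (default `tol = 1e-6`) before the next
solve. A weighted-sum alternative is available by passing a combined
objective map to `fba` directly. Ethanol consumption is maximized as
*net* uptake (uptake minus the secretion copy of the split exchange
pair), since gross uptake of a split pair admits an unbounded futile
exchange cycle.

The maximum-NGAM computation fixes exchange fluxes (uptake, by-product
secretion, biomass formation) to observed windows and maximizes flux
through the non-growth-associated maintenance ATP-hydrolysis reaction;
constraints are applied one at a time so an infeasibility is reported
with the constraint that caused it.

## Flux sampling

The reference condition is: chosen carbon source only (all other
registered carbon uptakes closed) and growth in the flexibilized
window. Each sample maximizes `w₁·v_i + w₂·v_j` where `(i, j)` are two
distinct reactions drawn uniformly from the candidate set (default: all
reactions except the pool exchange) and `w₁, w₂ ~ U(0,1)` are drawn
independently. Draws consume one seeded generator in a fixed order —
pair first, then weights — so sample lists are bitwise reproducible.
Unbounded draws are rejected and redrawn, keeping every retained sample
a vertex of the constrained polytope. This sampler characterizes the
spread of optimal behaviours; it makes no claim of uniform coverage of
the flux polytope.

## Expression integration and the screens

* **Poorly induced genes**: `log2FC > 1` and `FDR < 0.01` in the
  reference glucose→ethanol contrast, and induced at least two-fold
  less in the mutant (`log2FC_wt − log2FC_mut ≥ 1`). Inequalities are
  strict on the published thresholds; genes absent from the mutant
  table count as not induced there (with a warning). Raising the gap
  can only shrink the set.
* **CPM filter**: a gene is removed when its counts-per-million fall
  below 1 in every sample of at least three condition groups (the
  per-sample reading — below threshold in ≥ 3 individual samples — is
  available as `mode="samples"`). Dubious ORFs are always removed.
* **Perturbations**: each differentially expressed enzyme gets
  multiplier `2^log2FC` (0 for deleted genes; an enzyme with several
  mapped genes takes the minimum — a conservative bottleneck
  assumption). Per sampled background, the usage bound becomes
  `usage_i(sample) · multiplier_i · (1 + 0.20)`. Up-regulated enzymes
  are raised as well by default; `direction="down_only"` restricts to
  down-regulated ones.
* **Perturbed-growth screen**: maximize growth per background;
  infeasible backgrounds are flagged and excluded from downstream
  means; for feasible ones growth is fixed to its maximum ±5 % and net
  ethanol consumption, then maintenance, are maximized
  lexicographically. With the default zero maintenance floor every
  perturbed model is feasible (zero growth is always admissible);
  infeasibilities appear once a maintenance floor (`ngam_min > 0`) or
  the deletion of a growth-critical enzyme is configured.
* **Rescue screen**: per enzyme and feasible background, restore only
  that enzyme's usage bound to `P/mw` and re-maximize growth; an enzyme
  is a rescuer when its mean μmax re-enters the reference window
  (`≥ 0.22·0.95`). Release can never lower μmax.
* **Enrichment**: upper-tail hypergeometric `P(X ≥ overlap)` with the
  supplied universe, BH adjustment across all tested terms. The
  ">5 genes" reporting rule is applied to the term/query overlap by
  default; applying it to term size instead is a flag, since either
  reading is defensible.

## Growth-curve metrics

Doubling time comes from nonlinear least squares of `A·e^{μt}` over an
automatically selected exponential window, `Td = ln2/μ`. Window rule:
contiguous runs of ≥ 5 points with OD between 0.15 and half the curve
maximum; among maximal runs with log-linear `R² ≥ 0.995` the highest
fitted rate wins, falling back to the longest passing sub-window for
multi-phase or saturating curves. The OD band edges and the R² gate
are package choices (exposed as keyword arguments); no published
window rule exists for this procedure.

Lag is the linearly interpolated first crossing of OD 0.25 from an
inoculation at OD 0.1. That span is log2(2.5) ≈ 1.32 doublings; the
"first 1.5 doublings" description sometimes attached to this
measurement is inconsistent with its own OD endpoints, and the OD
thresholds are taken as operative since they are what is measured.
Final OD is read off the curve at a requested time. These metrics are
time-unit covariant: rescaling time rescales Td and lag identically.

## The synthetic study

The generators emulate the study design end to end; all planted truth
is recorded alongside the outputs, and every generator is a pure
function of (scenario, seed) through per-stage sub-streams.

* **Toy ec-model** (27 reactions, 9 enzymes): glucose and ethanol
  exchange, lumped glycolysis (2 ATP), pyruvate decarboxylase and
  dehydrogenase, a reversible alcohol dehydrogenase split pair plus an
  AAD-analog isozyme copy, acetaldehyde→acetate (ALD), the ATP-costing
  acetate→acetyl-CoA step (ACS), lumped TCA + oxidative phosphorylation
  (9 ATP per acetyl-CoA), a glyoxylate-shunt precursor reaction, a
  biomass reaction (1 precursor + 20 ATP per unit growth) and an NGAM
  reaction. Ethanol assimilation must pass through ACS — the model does
  not include acetate overflow, so ACS is the gateway whose
  down-regulation throttles both growth and net ethanol use, mirroring
  the bottleneck the screens are designed to find. Gene/enzyme names
  are yeast-inspired analogs (ACS1x, ADH2x, CIT2x …), not claims about
  real stoichiometry or kinetics.
* **Calibration**: all kcats are scaled uniformly until maximum growth
  on ethanol equals 0.22 h⁻¹ (exact in one step with the default zero
  maintenance floor; iterated otherwise), then the model must grow
  faster on glucose — it does, ≈ 0.45 h⁻¹, since glycolytic ATP is
  cheaper in enzyme mass than the ethanol chain.
* **DE tables** (2000 genes): 111 poorly induced genes planted with
  reference log2FC ~ N(2.5, 0.5) truncated above 1.2 and FDR well below
  0.01, attenuated by N(1.8, 0.3) (truncated above 1.05) in the mutant;
  300 genes induced equally in both strains; the rest null. These
  margins place planted and background genes on opposite sides of every
  classifier threshold, so exact recovery is the correct expectation —
  the generator emulates a clean post-shrinkage DE result, not the
  borderline calls of a real experiment.
* **Enzyme DE**: the ACS analog is planted at multiplier 0.1; the other
  perturbed enzymes carry mild fold-changes whose bounds stay
  non-binding on ethanol, and one AAD-family gene is deleted
  (multiplier 0). This yields a unique planted rescuer.
* **Counts**: negative-binomial (dispersion 0.05, shape 20) with
  designated-set read shares of 7.1 % (reference ethanol), 3.56 %
  (mutant ethanol) and 1.8 % (both glucose phases, a typical
  pre-induction baseline), library size 1e5 per sample, 2 strains × 2
  phases × 3 replicates. Depth is ~80× below real sequencing; the
  assertions concern fractions, not depth.
* **Growth curves**: logistic from OD 0.1 with exponential-phase
  doubling times 111 min (reference) and 120 min (mutant), carrying
  capacity 10, optional dead time and multiplicative noise, sampled
  every 10 min for 12 h. A finite capacity bends the curve away from
  pure exponential growth throughout the fit band (instantaneous rate
  `μ(1 − OD/K)`), so fits on saturating curves read several percent
  above the generative Td; `capacity=inf` gives exact recovery and is
  what the reference-quantity script uses.

What passing tests on this synthetic study do **not** show: recovery on
real data with noisy DE calls near thresholds, genome-scale models
(thousands of reactions, isozyme/complex ambiguity), realistic kcat
uncertainty, or growth curves with instrument artifacts. The synthetic
study validates the machinery and its contracts, not the biology.

## Pipeline reproducibility

One config seed governs every stochastic stage: the flux sampler
consumes it directly and the synthetic generators derive fixed
per-stage child streams from it. Output files use fixed float
formatting and contain no timestamps, so identical configs produce
byte-identical output directories. The manifest records the seed, a
config hash, per-stage counts (samples, feasible/infeasible, perturbed
enzymes, rescuers, enriched terms) and the headline results.

Default problem sizes (1000 samples in the pipeline; 200 in the test
study) keep a full run in the tens of seconds on one CPU for the toy
model while leaving the per-sample screens well resolved.

## Known limitations

* The sampler is an optimal-vertex sampler, not a uniform polytope
  sampler (no hit-and-run / artificial centering).
* No SBML/MAT import; models use the package's JSON schema.
* No thermodynamic constraints, no FVA, no quadratic objectives.
* DE tables are consumed, never fitted; dispersion estimation and
  shrinkage belong to the upstream RNA-seq pipeline.
* The enrichment module uses locally supplied GMT gene sets only.
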