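# Methods

## Overview

`organflux` implements an integrated constraint-based pipeline for
building a context-specific organ metabolic model and predicting the
phenotypic consequences of drug off-target inhibition and single-gene
deficiencies. The organ of interest is a filtering organ (the
motivating case is the kidney): its physiology is summarized as a set
of *objective components* — metabolite secretions and reabsorptions —
and the model is asked which genes and drug targets can compromise
each of them.

All simulation rests on flux balance analysis (FBA): given a
stoichiometric matrix S, flux bounds lb ≤ v ≤ ub and a linear
objective, solve

    max c·v   s.t.   S v = 0,   lb ≤ v ≤ ub

with scipy's HiGHS solver. Bounds are dimensionless "flux units"
capped at Vmax = 1000 in magnitude. Only objective values are treated
as deterministic; flux vectors at degenerate optima are
solver-dependent and are never used as a contract surface.

## Model representation

A model is a compartmentalized network: metabolites (each in a
declared compartment; the synthetic organ uses blood `b`, cytosol `c`
and urine `u`), reactions with signed stoichiometry, bounds, a
subsystem and a kind (enzymatic, transport, exchange, demand,
objective), and a gene–protein–reaction (GPR) boolean rule per
reaction. GPR rules use `and` for enzyme complexes (all subunits
required) and `or` for isozymes (any suffices). Exchange reactions are
single-metabolite drains whose negative flux is uptake; demand
reactions are irreversible single-metabolite sinks. Boundary reactions
get deterministic ids (`EX_<met>` / `DM_<met>`) so configurations and
tests can reference them.

SBML I/O uses the classic Level 2 constraint-based dialect: bounds in
kinetic-law parameters `LOWER_BOUND`/`UPPER_BOUND`, rule/subsystem/
kind in `GENE_ASSOCIATION:` / `SUBSYSTEM:` / `KIND:` notes lines. GPRs
are rendered canonically on write, making write→read→write
byte-identical. SBML Level 3 FBC is out of scope.

## Expression processing

Inputs are two replicate probe-intensity tables (background-subtracted,
hence nonnegative) and a probeset→gene map.

1. **Global normalization** — replicate 2 is multiplied by
   Σrep1/Σrep2 so totals match exactly.
2. **Lowess smoothing** — intensity-dependent bias between replicates
   is removed in MA space: M = log2(r1/r2) is regressed on
   A = ½(log2 r1 + log2 r2) by lowess (span 0.3, one robustifying
   iteration) over shared probesets, and the fitted trend is split
   symmetrically between the replicates so A is preserved. Probesets
   present in only one replicate, or with non-positive intensity, pass
   through unchanged (warned). The span and the MA-space formulation
   are package choices; they are configurable.
3. **Averaging** — the per-probeset mean of the two normalized
   replicates; singletons pass through at their own value to maximize
   gene coverage.
4. **Gene values** — a gene's value is the *maximum* over its mapped
   probesets. Genes with no probeset are absent and propagate as "no
   data".
5. **Reaction scores** — the GPR rule evaluated numerically: minimum
   over `and` children, maximum over `or` children, with data-free
   genes excluded from the aggregation. A reaction whose rule is EMPTY
   or entirely data-free scores `None` and is never penalized
   downstream.
6. **Significance threshold** — a single Gaussian is fitted to the
   gene values by moments; each value gets an upper-tail probability
   1 − Φ((x−μ̂)/σ̂), and the threshold is the smallest *observed*
   value whose tail probability does not exceed the target (default
   0.05). Because the threshold value itself is significant, the
   "expressed" calls downstream are inclusive (value ≥ threshold). On
   a pure Normal(μ, σ²) sample this lands at μ + 1.645σ up to sampling
   noise. On real organ data the fit is over a mixture of silent and
   expressed genes, so the resulting threshold is a data-driven
   compromise, not a quantile of either component.

## Context-specific model construction

**Exchange bounds from evidence.** Each exchange metabolite carries
detection flags (blood/urine/tissue) plus curated overrides. Rules:
detected in blood and tissue (or curated freely exchangeable) → uptake
and efflux allowed; urine and tissue only → efflux only; no evidence →
closed. Metabolites that are secretion objectives never take up —
the model must synthesize what it secretes. Every allowed efflux is
capped at one shared value, the **system boundary flux constraint
(sbfc)**, base value 13.5 flux units, so that all candidate pathways
can operate concurrently in a single optimum instead of competing
winner-take-all.

**Objective assembly.** Each curated component gets its own boundary
reaction (an efflux exchange for secretions, a cytosolic demand sink
for reabsorptions — the demand formulation lets direct and indirect,
catabolize-then-return, reabsorption routes both count). Components
that cannot carry positive flux even in the fully unconstrained
network are reported incompatible and excluded. The remaining
components are combined, with unit stoichiometric weights, into one
`combined_objective` reaction, optionally together with an ATP
maintenance term (1 ATP + 1 H₂O → 1 ADP + 1 Pi + 1 H⁺, a package
choice as the coefficients are conventional). The combined reaction is
used only for model extraction; simulations always optimize individual
component boundaries.

**GIMME extraction.** The GIMME linear program finds a flux state that
attains at least a required fraction (default 0.90) of the combined
objective's optimum while minimizing expression-inconsistent flux:

    min Σᵢ wᵢ·|vᵢ|,   wᵢ = max(0, threshold − scoreᵢ)

with unscored reactions unpenalized (w = 0), subject to S v = 0, the
bounds, and v_obj ≥ 0.9·v_obj^max. Absolute values are handled by
splitting reversible reactions into nonnegative halves. Because the
optimum is usually degenerate, activity classification does not trust
one LP vertex: each penalized reaction is probed by maximizing and
minimizing its net flux under an inconsistency budget of the minimum
plus 1e-6; a below-threshold reaction that cannot carry flux in any
such near-optimal state is **inactive**, everything else is **active**
(**unpenalized-active** when no expression evidence exists). This
makes the classification deterministic across solvers. Inactive
reactions are closed to produce the full context model.

**Reduction.** For each component, its boundary flux is anchored at
≥ ε (ε = 1e-6 — *possible* support, not optimal support) and flux
variability analysis marks every reaction that can carry flux. The
reduced model is the union across components of flux-capable reactions
plus their metabolites. This preserves each component's optimum
exactly (asserted within 1e-6), i.e. the reduced model spans the same
effective solution space for the organ functions. Connectivity of the
reaction–metabolite graph is verified; disconnected islands are
warned about but retained.

## Perturbation simulation

**Protocol per component.** Secretion: maximize the component's efflux
under standing bounds. Reabsorption: raise the component's own uptake
bound to Vmax, cap all other allowed uptakes at sbfc, maximize the
component's demand sink — so alternative direct and indirect routes
are concurrently active in one optimum.

**Perturbations.** Gene deletion closes every reaction whose GPR
evaluates false under the deletion. Drug-target inhibition scales the
bounds of each targeted reaction by a remaining fraction f ∈ [0, 1]
(default 0, full inhibition). The cumulative ALL row inhibits every
target simultaneously.

**Phenotype ratio.** ratio = (perturbed max flux)/(matched unperturbed
max flux), clipped into [0, 1] with 1e-6 slack for LP noise. A ratio
below the disorder threshold (default 1, strict comparison with 1e-6
tolerance) is a disorder call. Treated scans normalize by the
treated-normal model, so a cryptic risk factor — untreated ratio 1 but
treated ratio < 1 — measures the gene's effect *on top of* the drug.
Degenerate 0/0 cells (the component already dead in the reference) are
defined as ratio 1: no *additional* disorder. An infeasible perturbed
model scores 0 (a dead model secretes nothing), keeping the ratio
total.

**Sensitivity.** For a parameter sweep (sbfc over {0, 13.5, 50, …,
1000}; inhibition fraction over {0, 0.1, …, 1}), the normalized
sensitivity coefficient is

    NSC = (r − r_base) / max(r_base − 0, 1 − r_base)

the deviation from the base-case ratio divided by the largest
deviation the [0, 1] outcome range allows; NSC ∈ [−1, 1] and is 0 at
the base grid point. This absolute-deviation form is the only one that
stays defined when r_base = 0, the signature of a single-route total
loss — whose NSC is identically 0 across the whole sweep, since no
boundary-flux setting can substitute a missing unique pathway. Note
one degenerate grid point: at sbfc = 0 every efflux is capped at zero,
the reference flux is 0, and the 0/0 → 1 convention reports all ratios
as 1 there.

## Validation

**ROC/AROC.** The benchmark is a table of (gene, component) pairs
labelled clinically positive or negative. The disorder-call threshold
sweeps the closed set of observed ratios ∪ {0, 1} (an exact
step-function ROC with no discretization error), classification is
strict `<`, the curve is closed at the call-everything corner (1, 1),
and the AROC is the trapezoidal integral of TPR against FPR. Ties are
merged per unique threshold. With all ratios distinct the AROC equals
the rank-based Mann–Whitney statistic (asserted to 1e-9). The mean
true positive rate over the sweep is reported both with and without
the endpoint thresholds, since which sweep points enter that mean is a
convention.

**Permutation null.** Each of n trials (default 100) shuffles the
computed ratio values across all matrix cells (a per-gene variant is
available behind a flag) and recomputes the AROC; shuffling symmetry
centers the null on 0.5. Significance of the observed AROC (and mean
TPR) is a one-sample left-tailed t-test of the null values against the
observed one, at α = 0.05.

**Cross-validation.** Network genes with data are ranked by
expression; the ranked list is split into `folds` contiguous blocks of
`fraction` each (defaults 5 × 20%), so the first fold holds out the
most highly expressed block. Per fold, the held-out data is removed,
the threshold and GIMME classification are recomputed, and recall is
the share of held-out genes among the genes of active reactions.
Enrichment significance is the hypergeometric upper tail
(population = network genes, successes = held-out set, draws =
predicted-active set), Bonferroni-multiplied by the fold count.

**Set overlaps.** Predicted-active genes, expressed genes and
proteomically detected genes are summarized as all seven disjoint
regions of the three-way diagram.

## Synthetic study conditions

The generator emulates the real pipeline's five inputs with known
ground truth. The default toy organ (≈ 82 reactions, ≈ 71 metabolites,
≈ 70 genes — sized so exhaustive LP-oracle checks finish in seconds)
always contains: a secretion with a unique two-subunit synthesis route
(total-loss plant), a reabsorption with direct (capacity 6–12) and
indirect (capacity 2–5) routes giving exact fractional-loss ratios, an
isozyme pair (silent plant), a drug-targeted primary route with a
genetic backup (cryptic plant), and decoy pathways with unexpressed
genes, alternating flux-capable (GIMME should inactivate them) and
dead-end (reduction should drop them).

Synthetic expression draws probe intensities from Normal(1500, 100²)
for genes on objective routes and Normal(400, 100²) otherwise
(3 probes/gene, 5% probeset dropout), truncated at zero; replicate 2
carries a 2× global scale and a multiplicative intensity-dependent
bias (x/400)^0.1 so the normalization stages have real work to do.
These defaults keep the expressed fraction low enough (~13%) that the
single-Gaussian threshold fit separates the components.

What the generator does **not** emulate: realistic organ network
topology, realistic microarray noise beyond Gaussian + scale + trend,
double-gene interactions, or metabolite-level readouts. Passing the
planted-recovery suite therefore demonstrates the correctness of the
machinery — GPR logic, LP optima, ratio statistics, GIMME
classification — not predictive performance on real clinical data,
whose headline numbers depend on the curated genome-scale inputs.

## Numerical choices

- Mass-balance/bound tolerance 1e-6; a flux is "nonzero" above 1e-9.
- Reversible reactions are native signed bounds everywhere except
  inside the GIMME objective, where they are split.
- GIMME alternative-optimum probes use an inconsistency budget of
  minimum + 1e-6 and a flux-capability cutoff of 1e-6.
- Ratio cells are clipped into [0, 1]; a cell may exceed 1 by at most
  1e-6 before a warning fires.
- All randomness flows through `numpy.random.default_rng` with
  explicit seeds; every generator is deterministic per seed (same-seed
  SBML output is byte-identical).

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on synthetic
fixtures: 200 random ≤ 8-reaction LPs against a vertex-enumeration
oracle, 1000 random GPR trees against recursive oracles, 20 reduction
fixtures, 50 planted-recovery seeds (compact 2-pathway toys), 100–1000
permutation trials, and 100k-sample threshold checks. These sizes are
the package's choice of a thorough-but-quick regression envelope.

## Known limitations

- The expression threshold is only as meaningful as the
  single-Gaussian fit; strongly multimodal data yields a conservative
  threshold.
- GIMME activity is a flux-capability statement under one required
  objective fraction; it does not distinguish "needed" from "usable".
- The drug model is purely capacity-based (bound scaling); no binding
  kinetics, dosage or competitive-inhibition detail.
- Benchmark validation treats each (gene, component) pair
  independently; clinical pleiotropy across components is not modeled.
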