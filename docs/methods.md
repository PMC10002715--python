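# Methods

## The model

`mcmm` predicts short-chain fatty-acid (SCFA: acetate, propionate, butyrate)
production fluxes of a gut microbial community from its taxonomic
composition. The community is represented as a microbial community-scale
metabolic model (MCMM): the abundance-weighted union of per-taxon
genome-scale metabolic models (GEMs) coupled through one shared external
compartment. Each taxon keeps its own namespaced reaction network with
fluxes in mmol per gram dry weight *of that taxon* per hour; its exchange
reactions become transfer reactions whose contribution to the shared mass
balance is scaled by the taxon's relative abundance a_i, so community-level
exchanges are per gram dry weight of *community*. Relative sequencing
abundance is used as a proxy for relative biomass.

Growth is solved by **cooperative tradeoff flux balance analysis (ctFBA)**,
a two-step scheme:

1. maximize community growth mu_c = sum_i a_i mu_i subject to steady state
   S v = 0 and flux bounds (an LP), giving mu_c*;
2. minimize the L2 norm of taxon growth rates, sum_i mu_i^2, subject to the
   same constraints plus mu_c >= tf * mu_c* (a convex QP).

The tradeoff tf (default **0.7**) balances individual against community-wide
growth: tf = 1 forces the community optimum (often leaving most taxa at zero
growth), lower tf spreads growth across taxa. 0.7 is the highest value at
which most (>90%) taxa typically still grow; `mcmm.ctfba.tradeoff_scan`
reproduces that selection procedure on any community. Production rates are
the nonnegative net community export fluxes at the step-2 optimum —
production accessible to the colonic epithelium.

Only growth rates enter the quadratic objective. Fluxes not coupled to
growth (overflow metabolites such as acetate) can therefore be degenerate at
the optimum; instead of hiding this behind extra regularization, the
degeneracy is quantified by `flux_range_at_optimum`, which minimizes and
maximizes a community exchange flux with every taxon growth rate pinned at
its fitted value. A metabolite whose production is uniquely coupled to
growth reports width ~0; an overflow metabolite reports a strictly positive
width.

## Media

A medium is a map from exchangeable metabolite to maximal import flux
(mmol/gDW/h), applied as lower bounds on community exchanges. Media are
derived from diet definitions by a fixed transformation sequence:

- **host absorption**: components flagged `host_absorbable` are diluted to
  20% of dietary flux (absorption in the small intestine);
- **host supplementation**: mucins, bile acids and similar host-supplied
  metabolites are added (merge rule: max of existing and host flux);
- **completion**: a minimal augmentation is added so every model in the
  library reaches a community growth floor of 0.3 1/h. Minimality is minimum
  total added flux (one LP with slack variables per model, union of
  supports), not minimum metabolite count: the LP is deterministic and fast,
  and its support is reported as the added set. Additions below 1e-9 are
  treated as zero, making completion idempotent;
- (*ex vivo* only) **carbon stripping**: entries whose formula contains
  carbon (or with `carbon_source_override`) are removed, except residual
  fiber (resistant starch, dextrin, cellulose) and host-supplied entries.
  Formula-free metabolites are treated as carbon-free, so users reproduce
  "manual" stripping decisions via flags;
- (*ex vivo* only) **dilution**: everything is diluted to 10% of its flux to
  mimic the fecal microenvironment, except residual fiber, which is instead
  reset to its *dietary* value divided by the study's slurry dilution factor
  (1:5 homogenate -> x0.2) — indigestible fiber persists in stool at dietary
  levels and is only diluted by sample preparation. This replaces, not
  composes with, the 10% rule for flagged entries.

Single-fiber supplements use bounds set from each polymer's carbon content:
pectin 1.0, inulin 10.0, FOS 100 mmol/gDW/h. The completion guarantee is
asserted on the pre-strip medium only; stripping can lower growth below the
floor, and whether completion should re-run post-strip is left to the user
(the default recipe does not).

Every mutation is recorded per metabolite (`provenance`) and as a replayable
`history`; replaying the history against the raw diet reproduces the medium
bit-exactly (completion steps re-apply their recorded additions rather than
re-solving).

## Interventions

Individuals are simulated on an average European and a high-fiber diet and
classified by predicted butyrate response: **regressor** if butyrate falls
on the high-fiber diet; **non-responder** if European-diet butyrate is below
15 mmol/gDW/h and the relative gain is below 20%; **responder** otherwise.
Conventions at the boundary: with zero butyrate on both diets the relative
gain is taken as 0 (non-responder); with zero European-diet butyrate and any
high-fiber production the gain is infinite (responder). The baseline cutoff
is interpreted in the pipeline's native flux unit, mmol/gDW/h.

The probiotic intervention rescales all abundances to (1 - f) and adds the
probiotic taxon at relative abundance f. The default f = 0.05; 0.10 has also
been used for the same construction, so f is always an explicit argument
rather than a hidden constant. The screen runs one full medium build + ctFBA
solve per intervention spec (background diet x optional single fiber x
optional probiotic), flags infeasible solves without aborting, and marks the
butyrate argmax per individual, ties broken in spec order.

## Statistics

- Endpoint flux estimation: (c_end - c_start)/hours, optionally divided by
  OD600 for biomass normalization; negative values mean net consumption.
- Z-scoring is performed within each study (sample sd, n-1 denominator)
  before cross-study comparison of predicted and measured fluxes; measured
  fluxes (concentration/time) and predicted fluxes (mmol/gDW/h) are
  expected to be proportional, not equal, so only the Z scale is compared.
- Pearson r with the two-sided t-transform p-value (n-2 df).
- Mann-Whitney U, exact two-sided p for combined n <= 20 without ties,
  midrank normal approximation with continuity correction otherwise
  (exact-with-ties enumeration is out of scope).
- Clinical association scan: each marker is regressed on the predicted flux
  plus age, sex (binary indicator) and sequencing vendor (categorical
  dummies) by OLS; continuous variables are z-standardized on the marker's
  complete cases, so the reported beta is a standardized coefficient.
  Markers with fewer than 10 complete cases are skipped and logged; a
  rank-deficient design or a marker collinear with the design raises an
  error naming the marker. P-values are adjusted across markers with
  Benjamini-Yekutieli FDR, which is valid under arbitrary dependence. BMI
  is not a covariate: it is itself downstream of butyrate production and
  adjusting for it would block part of the effect being tested.

## Synthetic data

The generator emulates the inputs of the real pipeline with known ground
truth. Six taxon archetypes (fiber degrader, butyrogen, propionogen,
acetogen, acetate-to-butyrate cross-feeder, non-producer) define minimal
GEMs: one substrate exchange, one catabolic reaction realizing the stated
biomass and SCFA yields, one biomass reaction, one export exchange per SCFA.
Default yields give lone-taxon growth rates of 1-4 1/h on 10 mmol/gDW/h of
substrate; the cross-feeder grows only on community-derived acetate,
exercising the shared-metabolite coupling path. Community compositions are
Dirichlet(alpha = 1) over the archetype set (heterogeneous but rarely
dominated), cohorts default to 20 samples, and one integer seed fixes every
stochastic draw.

"Measured" fluxes are the forward-model predictions times exp(eps) with
eps ~ N(0, sigma^2), sigma = 0.3 by default — multiplicative lognormal
error matches the positivity and proportional scale of flux measurements.
Clinical markers are beta_j * flux_z + 0.2 * age_z + 0.1 * sex + 0.15 *
vendor + N(0, 1), with age ~ N(45, 12), sex ~ Bernoulli(0.5), two vendors;
null markers (beta = 0) support FDR calibration.

What the generator does **not** emulate: database-scale networks (hundreds of
reactions, cofactor coupling, redundant pathways), taxonomic
misclassification and compositional noise in sequencing profiles,
database/sample strain mismatch, or nonlinear marker-flux relationships.
Passing tests therefore demonstrate correctness of the algorithmic pipeline
under its own assumptions, not predictive accuracy on real microbiomes.

## Numerical choices

- LPs (growth maximization, medium completion, flux ranges, polish) use
  HiGHS via `scipy.optimize.linprog`, deterministic with default pivoting.
- The step-2 QP is solved with `scipy.optimize.minimize(trust-constr)`
  (constant sparse Hessian, gtol 1e-10, xtol 1e-12) started from the step-1
  vertex; the flux vector is then polished by a feasibility LP with growth
  rates pinned within 1e-7, so reported solutions satisfy ||S v||_inf at LP
  precision. Reported solutions are rechecked at 1e-6 (one order looser than
  the solver targets) and demoted to `numeric_failure` if violated.
- Degenerate QP optima are accepted as returned by the deterministic solver
  configuration; flux ranges make the degeneracy visible.
- Flux-range LPs pin growth rates within a 1e-6 band: reported widths for
  uniquely determined fluxes are O(1e-6), not exactly zero.
- Abundance normalization tolerance 1e-9; completion additions below 1e-9
  treated as zero; exchange "unbounded" sentinel 1000 mmol/gDW/h.

## Design choices where the design was open

- Renormalization after the 0.001 abundance cutoff and after model matching
  is over the *matched* taxa (unmatched mass is dropped, not lumped into an
  "other" sink): communities are built only from taxa with models.
- Duplicate library models for one taxon id are an error rather than a
  silent choice.
- Completion runs before carbon stripping (augment, then strip), and the
  growth-floor guarantee is therefore a pre-strip statement.
- Mann-Whitney U exact enumeration is limited to the untied case.
- Predicted and measured fluxes are correlated on the raw (Z-scored) scale;
  no log transform is applied before correlation.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run entirely on synthetic
fixtures: the two-taxon reference community (9 reactions), 200 randomized
2-4 taxon communities for the invariant sweep, 20-seed x 50-sample studies
for the noise-attenuation check, 200 replicates of a 128-null-marker cohort
at n = 500 for FDR calibration, and a single n = 2687 cohort for
planted-effect recovery. These sizes keep every check exact or
statistically well-powered at desk scale.

## Known limitations

- Toy GEMs are linear chains; they cannot exhibit pathway redundancy within
  a taxon (except the purpose-built degenerate fixture).
- The acceptance toy's stated yields are not elementally balanceable, so
  default archetypes carry no formulas; carbon conservation is exercised on
  a dedicated balanced fixture whose biomass-precursor carbon closes the
  balance exactly.
- Exact identifier matching only; no taxonomy harmonization.
- No dynamic FBA, thermodynamic constraints, or strain-level refinement.
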