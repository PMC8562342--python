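# Methods

This note documents the models, algorithms, parameter choices and
limitations of `vinoflux`.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and derived quantities

Fermentation measurements are a tidy long table (strain, replicate,
time_h, analyte, value, unit).  Invariants enforced at construction: every
series contains time 0, times are unique per series, units are constant
per analyte, and concentrations are non-negative.

**Utilization** is `u_j(t) = C_j(0) − C_j(t)` at *exactly sampled* times —
no interpolation, mirroring how discrete fermentation samples are actually
compared.  Negative utilization (net excretion back into the medium, seen
for some amino acids in stationary phase) is retained, never clipped.

**Depletion time** is the earliest time at which utilization reaches a
fraction (default 95%) of the initial pool, *with* linear interpolation
between samples, because threshold crossings generally fall between
sampling points.  Crossing times map to consumption-timing groups:
I ≤ 28 h, II ≤ 44 h, III ≤ 72 h, IV > 96 h.  Times in (72, 96] h fall
between the named groups and are reported as unassigned rather than forced
into a bin.

**Specific exchange fluxes** use a finite difference over a window with
both endpoints sampled:

    q_i = ΔC_i / (M_i · X̄ · Δt)   [mmol gDW⁻¹ h⁻¹]

with `X̄` the trapezoidal-mean biomass over the window.  How concentration
changes become specific rates is genuinely open in this kind of study; the
finite-difference form is standard practice and is isolated in one
function so a regression-slope estimator can be swapped in.  Sign
convention throughout: uptake negative, secretion positive.  The default
pipeline window is (20, 72) h — inside the growth phase, and wide enough
that concentration drops dominate measurement noise; two-point differences
over short windows are fragile against noisy endpoints.

Biomass comes from OD600 via a per-strain affine calibration
(`od_to_dcw`); whether an intercept is used is the caller's choice and
negative outputs are clipped to zero with a warning.

## Synthetic fermentations

The simulator produces the study conditions the analysis stages are
validated under: 4 strains × 3 replicates × 11 sampling times over 404 h
(grid 0, 20, 28, 44, 72, 96, 120, 168, 240, 312, 404 h; the early points
sit on the group-boundary times so interpolated crossings respect group
membership, and the first five cover the window of near-complete nitrogen
uptake).

* **Growth**: logistic with lag (defaults X₀ = 0.05 gDW/L — an OD600 of
  ~0.1 at a 0.5 gDW/L-per-OD calibration — µ = 0.08 h⁻¹, lag 5 h,
  X_max = 2.5 gDW/L), reaching maximum biomass by ~120 h.
* **Sugars**: glucose + fructose 110 + 110 g/L, depleted exponentially in
  integrated biomass (glucose slightly faster), residual < 4 g/L at the
  end; ethanol accumulates at 0.44 g/g consumed sugar (~95 g/L final).
* **Nitrogen**: 11 mg/L ammonium plus a 20-amino-acid profile.  The
  amino-acid-wise composition is an assumption (only the ammonium level
  and the ~123 mg N/L assimilable-nitrogen total are anchored); proline
  (300 mg/L) is never assimilated.  The un-consumed fraction of each
  compound decays as `exp(−k·G(t)^h)` in integrated biomass `G` past an
  uptake delay — biomass-coupled, Monod-like kinetics — optionally
  biphasic (a partial early phase ahead of the bulk, as catabolite
  derepression produces).  For every analyte the bulk rate is *solved* so
  the noise-free curve crosses 95% utilization exactly at its target
  time; targets respect the group thresholds with margin for the seeded
  strain (±7%) and replicate (±2%) timing jitter, which therefore stays
  within ±10% of each group target and preserves group membership.  The
  shape exponents and early fractions vary per strain *and* replicate:
  biological replicates of a fermentation genuinely differ in uptake
  kinetics, and that variation propagates into the volatiles through the
  true coefficient map, which is what makes the map identifiable from
  pooled data.
* **Volatiles**: `Y_v(t) = Σ_j B[v,j]·u_j(t) + c_v·(X(t) − X₀) + noise`,
  with the sign pattern of `B` defaulting to the qualitative correlation
  structure reported for wine-yeast nitrogen-to-aroma relations and
  magnitudes drawn per seed (each variable's full-depletion contribution
  comparable in size, i.e. coefficients scale inversely with the pool).
  Negative coefficients are shrunk by an exact one-pass factor where
  needed so no noise-free trajectory goes below zero — the emitted data
  then follow the *returned* `B_true` without clipping.  A consequence
  worth knowing: for responses whose positive drivers act late and
  negative drivers early, the surviving negative coefficients can be
  small, and their signs are then genuinely hard to recover at the default
  noise level.  Production plateaus once nitrogen is spent and growth
  stops, matching the observed stagnation after ~96–120 h.
* **Noise**: multiplicative Gaussian truncated at zero, per analyte class
  (defaults: sugars 2%, biomass 3%, nitrogen 5%, volatiles 5%).  The
  t = 0 sample is left exact — in a defined synthetic must the initial
  composition is the formulation itself.  The volatile assay is emulated
  as technical duplicates (the mean of two draws), as such assays are
  commonly run.
* **Determinism**: all draws flow from one `numpy` generator seeded by
  `SimulationSpec.seed`; identical specs give bit-identical datasets.

What the simulator does *not* emulate: mechanistic uptake regulation
(transporter competition, NCR dynamics), CO₂/heat balances, non-linear
aroma chemistry (ester hydrolysis, volatilization losses — the linear map
is the minimal structure under which the PLS analysis is well-posed), or
strain-specific genetics.  Passing recovery tests therefore demonstrate
that the analysis recovers a linear generative structure under realistic
kinetics and noise — not that real fermentation aroma chemistry is linear.

## Chemometrics

* **Preprocessing**: auto-scaling (centering plus unit sample variance).
  The conventional phrase "auto-scaling followed by mean centering" is
  redundant — auto-scaling already centers — so one transform is applied.
  Zero-variance columns cannot be scaled; they are flagged and excluded
  via the variable mask.
* **SIMPLS** (de Jong's algorithm): factors maximize covariance with the
  response under orthogonal scores, deflating the cross-product matrix
  `S = XᵀY` through an orthonormal basis of X-loadings.  For a single
  response its predictions coincide with NIPALS-PLS at every factor count,
  and at full rank with ordinary least squares — both serve as independent
  references in the tests.  Coefficients are kept in preprocessed space
  (scale-free; used for sign reports) and back-transformed to original
  units (used for prediction and recovery checks).
* **Cross-validation**: Venetian blinds — fold j holds rows {j, j+k, …} —
  with k = 24 splits by default; preprocessing is re-estimated inside each
  training fold (no leakage).  Q² = 1 − PRESS/TSS on held-out predictions;
  the LV count is the argmin of RMSECV with ties resolved toward fewer
  LVs (the simplest defensible rule; published tables rarely state one).
  Because interleaved folds depend on row order, the X-block assembly
  fixes it: strain-major, then replicate, then time.
* **Reverse iPLS** (interval size one variable, max 18 LVs): greedy
  backward elimination; at each pass remove the interval whose exclusion
  minimizes RMSECV, stop when no removal improves it.  By construction the
  selected subset's RMSECV never exceeds the full model's, and the mask is
  never empty.
* **Sign summary**: "+"/"−" from the preprocessed-space coefficient of
  selected variables; "0" for unselected ones.  An exactly zero
  coefficient on a selected variable also reports "0" (with a warning):
  "0" denotes non-use, and exact zeros are a measure-zero event.
* **Outliers**: the 0.95 confidence limit is applied to Hotelling-T²
  leverage flagging in score space only — flagged, never auto-removed.
* **ANOVA/Tukey**: one-way F-test plus Tukey HSD pairwise p-values
  (scipy), at the conventional 0.05 level.
* Replicate handling is pooled by default (replicates as rows);
  averaging before regression is possible by pre-aggregating the dataset.

## Constraint-based stage

The model container is a plain stoichiometric matrix with per-reaction
bounds, a gene-association flag, and a subsystem label.  Two readers:
a documented two-section TSV dialect (equations as `a A + b B -> c C`,
`<=>` for reversible) and an optional SBML L3/FBC adapter via cobrapy.
The unit of classification is the **reaction**; gene-level logic (GPR
evaluation) is out of scope, and the gene-association flag is what the
parsimonious objective needs.

**Anaerobic conditioning** is a pure function driven by identifier lists
(block exchanges, open uptakes at the −1000 mmol gDW⁻¹ h⁻¹ sentinel, block
internal reactions, zero biomass components).  Genome-scale-specific
identifiers (the yeast sterol/oleate exchanges, shuttle reactions, heme)
live in a shipped YAML template, not in code, so toy models use analogous
templates.  The operation is idempotent.

**Exchange constraining** imposes measured rates as `[q − δ|q|, q + δ|q|]`;
δ = 0 (the default) reproduces hard LB = UB constraining.  The tolerance
parameter exists because exact equality constraints derived from noisy
measurements are frequently infeasible; `check_feasibility` additionally
diagnoses infeasibility with an elastic-variable LP that reports the
minimal bound relaxation per exchange.

**pFBA** fixes the FBA growth optimum with a relative slack of 1e−9
(strict equality is prone to degeneracy infeasibility) and minimizes the
L1 norm of gene-associated fluxes by variable splitting — a pure LP.

**Classification cascade** (first match wins):

1. *blocked* — zero FVA range even with every exchange opened to ±1000;
2. *essential* — knockout (lb = ub = 0) growth below ε = 1e−6 (absolute,
   configurable; infeasible knockouts count as zero growth);
3. *no_flux* — zero FVA range under the experimental bounds;
4. *MLE* — can carry flux, but not at optimal growth;
5. *pfba_optima* — carries flux within the minimal-total-flux optimum
   (FVA under growth ≥ g*(1−1e−9) and Σ|v_gene| ≤ minimum·(1+1e−9));
6. *ELE* — the rest: flux at optimal growth requires exceeding the
   minimal total flux.

Numerical detail that matters: FVA maxima under slack-carrying constraints
can legitimately reach the slack itself, so the "carries flux" threshold
for steps 4–5 is `flux_tol + 100·1e−9·scale` (scale = max of growth and
minimal flux), which dominates the slack while sitting far below any real
flux in these models.  Under constraints without slack (steps 1 and 3) the
plain threshold (default 1e−9) applies; classifications on the bundled
templates are invariant to it across [1e−10, 1e−8].

Ground truth for toy networks is produced by an independent brute-force
classifier written directly against `scipy.optimize.linprog` (no code
shared with the production classifier), so every classification test is a
two-route comparison.  The Ehrlich-motif template couples biomass to
glutamate produced only by transamination of the imported amino acid,
which makes the uptake, transaminase, decarboxylase and reductase steps
structurally essential, with the ester branch enzymatically less
efficient — the qualitative picture expected for fusel-alcohol formation
under growth pressure.

## Enrichment

Upper-tail hypergeometric per subsystem (over-representation only),
BH-adjusted across subsystems by default (`--adjust none` available),
significant at adjusted P < alpha (default 0.01).  The default universe in
the pipeline is all non-blocked reactions; published analyses of this type
usually leave the universe unstated, so it is explicit and configurable
here.  Exactness is verified against complete enumeration of all draws for
universes up to N = 12 and against the closed-form worked value
C(5,4)/C(10,4) = 5/210.

## Pipeline

One `RunConfig` drives simulate → chemometrics → model-setup → pFBA → FEA.
Five CSV artifacts plus a JSON manifest (package version, seed, config
hash, per-stage wall time, SHA-256 per artifact); every CSV carries the
seed and config hash in a header comment.  The config hash excludes the
output directory and log level so runs into different directories compare
equal.  Re-running with the same config and seed is bit-identical; stage
failures preserve partial outputs and mark the failed stage in the
manifest.

## Problem sizes

Recovery and equivalence checks run at deliberately modest sizes chosen as
a sensible compromise between statistical resolution and runtime: 50
seeded problems for the PLS/NIPALS/OLS equivalences, 10 pooled synthetic
datasets (60 samples each) for aggregate sign recovery, 100 seeded trials
for the predictivity-vs-null comparison, 50 trials for iPLS support
recovery, and 20 random networks (≤ 20 reactions) plus the four named
templates for classification exactness.  The acceptance script uses
slightly smaller trial counts with the same estimators.

## Known limitations

* The chemometric sign table reports the regression vector of one chosen
  model; coefficients of strongly collinear predictors (amino acids
  depleted with near-identical timing) are individually fragile even when
  predictions are excellent — sign recovery is a statement about the
  ensemble, not any single coefficient.
* LB = UB exchange constraining with real (noisy) measurements frequently
  needs δ > 0 or the elastic diagnosis; the default δ = 0 is faithful to
  hard constraining but brittle by nature.
* The classification treats reactions, not genes; models with GPR logic
  will count essentials differently.
* Genome-scale SBML models are supported through the adapter, but all
  bundled validation targets are toy-scale; FVA at genome scale is O(2n)
  LPs and would need a dedicated solver loop.
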