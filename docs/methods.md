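# Methods

## Mechanisms

Both hydrolysis stages are built from the reversible elementary-step
mechanism E + S ⇌ ES ⇌ E + P, i.e. four mass-action constants per
enzymatic conversion: forward binding (k_bind), unbinding (k_unbind),
catalytic product release (k_cat), and product re-binding into the complex
(k_rebind). The reverse product step is retained because the fitted
constant tables report a full set of four constants per step and the
observed yield plateaus (pretreatment ≈ 36%, saccharification ≈ 54% of
substrate under the defaults) are equilibrium effects of that reversibility.

* **Pretreatment** (cellulase + xylanase): two steps in parallel —
  cellulase/cellulose (k1–k4) and xylanase/hemicellulose (k5–k8) — feeding
  a single pooled glucose product. Pooling matches the single observable
  (one glucose assay) of the experimental design.
* **Saccharification** (α-amylase + glucoamylase): two steps in series —
  α-amylase/starch → dextrin (k9–k12) and glucoamylase/dextrin → glucose
  (k13–k16). We fix ES1 = α-amylase·starch and ES2 = glucoamylase·dextrin;
  the alternative labelling that occasionally appears in discussion of
  this cascade contradicts the ordering of the two intermediates and the
  roles of k11 (dextrin formation) and k15 (glucose formation), so it is
  not used.

Each mechanism is also represented as data (`MechanismSpec`: species plus
a mass-action edge list with explicit conservation groups, YAML
round-trippable), and a generic edge-list evaluator serves as the
independent oracle for the hand-coded right-hand sides. Every edge is
checked to conserve every declared group, which makes the conservation
laws (per-enzyme totals and substrate carbon) consequences of the data,
not just of the code.

## Normalization and units

All printed rate constants are min⁻¹, including the bimolecular ones, so
species must be dimensionless. Every species is normalized by the
process's convertible substrate mass: cellulose + hemicellulose for
pretreatment (the default composition, percent dry weight: cellulose
10.2, hemicellulose 49.54, starch 19.62, protein 19.57, fat 1.07, gives
S_cel(0) = 10.2/59.74 ≈ 0.171 and S_hem(0) ≈ 0.829), and starch for
saccharification (S(0) = 1).

Enzyme pools support two scales:

* `mass-ratio` (pretreatment default): pool = dose mass / substrate mass.
  The study's 10–30% w/w doses give order-one pools (30% → ≈ 0.50 per
  enzyme), which is the regime in which the published constants produce
  the reported yield scale (≈ 36% at 40 min for the 30% loading).
* `unit-pool` (saccharification default): pool = dose / reference dose,
  with the study's doses (α-amylase 0.0006%, glucoamylase 0.01% w/w) as
  the reference, i.e. pools of 1 at the standard design. These doses are
  quoted per unit of catalytic activity and are four to five orders of
  magnitude smaller than the substrate by mass; a literal mass ratio
  (≈ 3·10⁻⁵) would make the published order-one constants produce no
  measurable conversion within an hour, contradicting the fitted curves.
  The unit-pool scale treats the loading as absorbed into the constants,
  which is also why the fitted constants vary between loadings.

A caveat that follows from this choice: under the reversible mechanism the
55 °C saccharification constants plateau at a glucose fraction of ≈ 0.54,
not the ≈ 0.90 experimental yield, and scanning the enzyme pool over
0.1–10× shows no scale that reaches 0.90 (larger pools pull product back
through the k16 step). The dimensionless scale used in the original
fitting is not recoverable from the published tables, so cross-scale
equality with the experimental yields is not asserted anywhere;
self-consistency (parameter recovery from the model's own trajectories)
is the quantitative surface instead.

Yields are reported as percent of a configurable basis
(`total-carbohydrate` default, also `per-substrate` and `total-biomass`),
with an optional multiplicative mass-correction factor (default 1; no
hydration factor is applied inside the ODEs — stoichiometry is 1:1 on the
mass-fraction scale). Glucose in g/L undoes the normalization:
P × substrate mass / volume.

## Integration

Adaptive Dormand–Prince RK45 (`scipy.integrate.solve_ivp`) with dense
output evaluated on the experimental grid (0, 10, …, 60 min), rtol 1e-8 /
atol 1e-10 defaults. Reported values are therefore independent of the
sampling grid; tightening both tolerances tenfold moves final glucose by
< 1e-6. The constants are O(1) min⁻¹, the systems are nonstiff, and
linear conservation laws are preserved by the RK step to roundoff
(verified to ≤ 1e-8 along all trajectories). The hot path unpacks
constants into a scalar closure; the public per-model RHS functions
(validated, NaN-checked) are tested equal to both that closure and the
generic mass-action oracle.

The pseudo-steady-state reduction integrates only the slow species
(substrates and products), closing each enzyme balance through total
enzyme conservation: ES = E_tot·q/(1+q) with q = (k_bind·S +
k_rebind·P)/(k_unbind + k_cat). It is accurate when enzyme pools are small
relative to substrate and binding/unbinding is fast relative to catalysis;
in the two-enzyme cascade the complex-formation transient is relayed twice,
so agreement at the first sampled time (10 min) additionally needs that
transient (≈ 1/(k_bind·S + k_unbind + k_cat)) to be well under a minute.

## Parameter estimation

The objective is the sum of squared residuals over individual observation
points (replicates are never averaged), and the reported misfit is its
root mean square, SE = √(Σ(y_obs − y_model)²/n), on the yield-fraction
scale — consistent in magnitude with the study's printed standard errors
(0.0073–0.0495). Optimization is bounded trust-region least squares
(default bounds [0, 10] min⁻¹) from multiple seeded starts: log-uniform in
[1e-3, 10] by default, or multiplicative perturbations of a supplied
center (factor^U(−1,1)). Ties between converged starts break by objective,
then SE, then the lexicographically smaller constant vector, making
results deterministic for fixed data, starts and seed. A single
Nelder–Mead simplex run — the classical "ODE solver inside a simplex
search" workflow — is available as `method="nelder-mead"`.

Stopping tolerances (`f_tol`, `x_tol`), Jacobian-based parameter scaling
(`x_scale="jac"`) and an evaluation cap are exposed because the
glucose-only mode is practically non-identifiable: eight constants against
one observable leave flat valleys in which strict tolerances never
trigger. `identifiability_report` quantifies this: among starts whose
objective is within 1% of the best (or whose SE is within 1e-3 yield
fraction — the absolute floor makes noiseless near-perfect fits
comparable), the per-parameter relative spread is reported and spreads
above 20% are flagged. Full-state noiseless data yield spreads < 1%;
glucose-only data reliably flag at least one binding/unbinding constant.

Self-consistency is the package's quantitative acceptance surface: every
published constant set, simulated noiselessly and refit from two-fold
perturbed starts (16 for the headline checks), returns all eight
constants within 1% relative (5% for constants below 0.01 min⁻¹).

## Synthetic experiments

The generator reproduces the study design: 500 mg biomass in 100 mL,
samples every 10 min for 60 min, triplicates, and additive Gaussian noise
on the yield fraction, truncated at zero, sd 0.02 by default (the
magnitude of the printed standard errors; the study reports no noise
model). Observation files round-trip through the fitter's delimited
format with a ground-truth sidecar (constants, design, seed); generation
is bit-reproducible per seed. The linear spectrophotometric calibration
X (g/L) = 2.1086·OD + 0.0058 is modelled with exact inverse; the
wavelength is stored as a free-text label defaulting to "540 nm".

What the generator does *not* emulate: assay chemistry and its systematic
errors, glucose consumption by side reactions (the study attributes
late-time yield decline to oxidation, which the mechanism does not
contain), enzyme denaturation within a run, and pipetting-level
correlations between replicates. Passing recovery tests therefore show
that the estimation machinery is correct and calibrated under the model's
own assumptions, not that the mechanism captures every feature of real
hydrolysis data.

A note on the noise-floor calibration: with 8 parameters against 21 noisy
points, the fitted RMSE concentrates slightly below the generating sd
(mean ≈ 0.017 for sd 0.02) because the fit absorbs part of the noise —
the usual √((n−p)/n) shrinkage — and individual seeds scatter by ±0.005.
The calibration is therefore asserted on the Monte-Carlo mean over seeds;
with tenfold more replicates the per-fit SE itself settles onto the
generating sd within 15%.

## Arrhenius analysis

Ordinary least squares of ln k on 1/T (kelvin; T + 273.15), Ea =
−slope·R with R = 8.314 J/(mol·K), A = exp(intercept). With two points the
fit is exact; Ea is invariant to rescaling all k by a common factor. Above
their optimum temperature the enzymes denature and fitted constants fall,
so the `auto` subset keeps the longest initial run of strictly increasing
k (the pre-denaturation regime) and refuses series that never increase.
The published per-temperature tables are used qualitatively (orderings,
regime selection, recovery-test magnitudes such as 11.29 kJ/mol for
saccharification); the published Ea values are not reconstructible from
the published k(T) tables under any temperature subset, so no numeric
equality with them is asserted.

## Problem sizes and numerical defaults

Headline recovery checks use 16 multi-starts on 49 noiseless observations
(7 time points × 7 species); the full-table sweep uses 4 starts per row.
The noise-floor calibration runs 100 seeds with a single truth-initialized
fit each (rtol 1e-6, f_tol 1e-4 — SE needs only two significant digits);
the Arrhenius Monte-Carlo uses 1000 replicates. Degenerate inputs
(zero-enzyme or zero-substrate runs) integrate to constant states; a
perfect fit at a start point short-circuits the optimizer (whose internal
scaling is undefined at an exactly zero Jacobian); PSSA reductions refuse
constant sets with k_unbind + k_cat = 0, naming the degenerate pair.

## Known limitations

* Temperature enters only through per-temperature constant sets; there is
  no denaturation term inside the ODEs and no Eyring analysis.
* No product-inhibition variants beyond the reverse steps; no Bayesian
  posterior or global optimization beyond multi-start.
* The glucose-only inverse problem is under-determined by design of the
  assay; the package reports identifiability rather than pretending a
  unique optimum exists.
* Absolute comparability of fitted constants across normalization scales
  is not possible without knowing the original dimensionless convention
  (see the normalization caveat above).
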