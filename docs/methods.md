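# Methods

This note documents the models, conventions and numerical choices behind
`nlcopt`, and what the synthetic-data generators do and do not emulate.

## Central composite designs

A k-factor CCD consists of the 2^k factorial points (coded ±1), 2k axial
points (one factor at ±α, the rest at 0) and `n_center` replicated center
runs. The axial distance defaults to the rotatable value α = (2^k)^(1/4);
for k = 2 this is √2 ≈ 1.41421. Published tables sometimes round this to
1.41 or state 1.412; the axial levels of the packaged study
(158.6 = 300 − 1.41421·100) are only consistent with √2, so `"rotatable"`
resolves to (2^k)^(1/4) exactly and a literal numeric α is accepted for
sensitivity checks. Actual levels are stored at full precision; display
rounding to one decimal is left to the caller.

Run order is canonical (factorial, axial, center) by default. Real studies
randomize run order; a seed produces a reproducible shuffle, and `std_order`
retains the canonical index. Run order has no effect on any fit.

## Response-surface fitting

Fits are ordinary least squares **on the per-run replicate means**, not on
individual analytical replicates. This matches how CCD formulation data are
tabulated (mean ± SD of analytical triplicates) and the convention that the
design's *pure error* comes from genuinely replicated runs — the center
points — rather than from analytical replicates, which share a preparation
and underestimate experimental error.

Model classes are hierarchical polynomial families (FO, TWI, PQ, SO) with a
canonical term order (intercept, linear, interactions, quadratics). A
factor-subset restriction supports models like a straight line in one
factor only. Coefficients are estimated independently in coded and actual
units; both parameterizations span the same column space for these
hierarchical classes, so their predictions agree to numerical precision
(asserted in tests to 1e−8). The solver is the QR/SVD-based least-squares
routine; rank deficiency raises an error naming the collinear terms.

The ANOVA splits SS(residual) into lack of fit and pure error,
SS(pe) = Σ within-replicate-group squared deviations, df(pe) = n − m for m
distinct settings. The overall-model F uses the residual mean square;
lack of fit is tested against pure error. Per-term p-values are partial
(type III) t-tests; sequential (type I) sums of squares are available via
`sequential_term_ss` for comparison, since published tables rarely state
which decomposition they used.

**Selection rule.** Among candidate classes whose overall F-test is
significant (p < 0.05 by default) and whose lack-of-fit test does not
reject, the highest adjusted R² wins, with ties (to 12 decimals) broken
toward fewer terms. If no class qualifies, the best-adjusted-R² candidate
is returned flagged `"no significant model"`. On the packaged study this
flag fires for particle size and PdI — the five center runs happen to agree
so closely that pure error is tiny and lack of fit rejects every class —
yet the fallback still lands on the published classes (PQ and SO). The
published zeta-potential model (linear in surfactant only) drops a factor
mid-analysis, a step no automatic rule can reproduce, so the pipeline
applies it as an explicit override; the unrestricted fits remain available.
A caution that follows from the rule itself: when noise is large enough to
resolve adjusted-R² differences, adding spurious higher-order terms raises
adjusted R² whenever their joint F exceeds 1 (roughly 44% of the time under
a true lower-order model), so the rule is only mildly parsimonious; the
tests exercise the regime where fits tie and parsimony decides.

## Desirability optimization

Each response maps to d ∈ [0, 1] by the Derringer–Suich transforms with
anchors (low, high), shape exponent s (default 1) and weight w (default 1);
overall desirability is the weighted geometric mean, so one fully
undesirable response vetoes the product. The optimizer runs a deterministic
dense grid over the coded region — 401 points per axis for k ≤ 2 (about
1.4 mg lipid resolution), coarser for higher k — followed by a Nelder–Mead
polish from the best cell, accepted only if it improves the grid value.
The grid stage makes results bit-for-bit reproducible; the polish tightens
the last fraction of a percent. The region is the coded box [−α, α]^k by
default, with a coded-ball mode available.

**Anchor convention.** Published desirability analyses almost never state
their anchors, weights or search region, and the optimum they report cannot
be interpreted without them. The package default is the only convention
derivable from the design data itself: low/high anchors at the observed
minimum/maximum of each response, s = 1, equal weights. On the packaged
study this yields max D = 0.741 at ≈(251 mg, 366 mg), whereas the original
analysis reported D = 0.822 at (268.4, 553.4). The discrepancy is expected
and is reported, not tuned away: at the reported settings the signed
zeta-potential desirability is poor (the model predicts −9.7 mV, near the
"worst" end of the observed −16.7…−7.0 mV range when minimizing the signed
value), which suggests the original goal was closer to "minimize |ζ|"
(i.e. toward zero). Under that reading (`transform="abs"`, available but
off by default since the study states "minimize" for the signed response)
max D rises to ≈0.89 at ≈(295, 657) and D at the reported settings is 0.86
— closer, but still not 0.822 — so no derivable convention reproduces the
printed value exactly. The `GoalSpec` config overrides anchors, weights,
shapes and transforms per response for such sensitivity analyses.

Degenerate case: if every grid point has D = 0, the optimizer flags the
result and reports the point with the largest single desirability instead
of an arbitrary corner.

## Characterization

Drug loading divides the entrapped drug mass by the *lipid matrix* mass:
solid lipid plus the oil phase, the oil volume converted at a configurable
density (default 0.92 g/mL, the literature value for sesame oil). For the
packaged study's optimized composition (268.4 mg solid lipid + 50 µL oil,
100 mg and 5 mg drug loads at ≈100% entrapment) this reproduces 31.8% and
1.6% at one-decimal rounding; it is the only composition reading that does.

DSC integration subtracts a straight baseline joining the signal at the two
window endpoints (endpoint values interpolated, so windows need not land on
samples) and integrates over time by the trapezoid rule; at constant
heating rate this equals integration over temperature, and mW/mg · s gives
J/g directly. Sigmoidal baselines and peak deconvolution are out of scope.
The crystallinity index treats the lipid-phase concentration as a fraction
(2.68% → 0.0268), the only reading that puts CI on a 0–100 scale.

## Release processing and NCA

The replacement correction C′ₙ = Cₙ + (V_s/V_t)·Σ_{i<n} Cᵢ is the standard
running-sum correction for fixed-volume replacement sampling; it is exact
when each withdrawal removes a well-mixed aliquot and is replaced by fresh
medium. Cumulative percentages above 100 (plus a 0.5-point tolerance) are
flagged, never clamped — they indicate assay inconsistency that the caller
should see. With V_s → 0 the correction reduces to C·V_t/dose.

NCA is naive-pooled: with destructive sampling each time point is an
independent animal group, so the mean profile is analyzed as a single
curve; SEMs are carried for reporting but do not enter the AUC. The AUC is
the linear trapezoid over [0, t_last] with C(0) = 0 prepended by default
(appropriate for extravascular dosing where the first sample follows the
dose); no log-linear rule or extrapolation to infinity is applied, matching
how AUC(0–24) is usually reported in such studies. A known consequence,
quantified in the tests against the closed-form one-compartment integral:
on a sparse 6-point grid (0.5–24 h, k_a = 2 h⁻¹, k_e = 0.15 h⁻¹) the linear
trapezoid overestimates the true integral by ≈13%, dominated by the 8→24 h
chord over the convex exponential tail; the error falls below 5% from about
12 evenly spaced points and decreases monotonically with refinement.

## Synthetic data

The generators mirror the *statistical structure* of a small formulation
study, not its physics:

- CCD responses: true polynomial + iid Gaussian noise per analytical
  replicate (default 3 replicates). Real analytical error may be
  heteroscedastic (the packaged study's SDs grow with particle size);
  passing tests therefore demonstrate correctness of the estimators, not
  robustness to variance structure.
- Release: released fraction f(t) = b + (1−b)(1−e^{−kt}) (burst b from
  surface-associated drug, first-order matrix release) or an immediate
  profile, back-converted to the sampled concentrations that fixed-volume
  replacement sampling would record — by construction the correction
  inverts it exactly, which is what the round-trip tests verify. No
  mechanistic diffusion/partitioning model is implied.
- PK: one-compartment first-order absorption with mean-one lognormal
  between-animal factors (CV configurable, default 0.2, a typical
  small-animal value) at the study's destructive design (6 times × 3
  animals). The flip-flop limit k_a = k_e is rejected rather than handled
  by the limiting form.

Default simulation scales follow the packaged study: 13-run designs,
triplicate responses, 6-point PK grids, 200-seed Monte-Carlo checks (the
refit-bias suite runs in seconds at these sizes).

## Known limitations

- Only full-factorial-based CCDs (no fractional factorials, blocking,
  Box–Behnken or optimal designs).
- Model selection considers whole classes, not per-term stepwise deletion.
- The desirability optimizer is grid + local polish over a box or ball;
  adequate for smooth low-order polynomials in k ≤ 3, not a global
  optimizer for arbitrary response models.
- No plotting; reports are JSON/CSV and formatted text.
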