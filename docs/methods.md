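# Methods

This note documents the statistical machinery in `pelletspec`: the models
and procedures, the parameters that matter, the synthetic-data generator
the test suite runs on, and the numerical and design choices made where
the problem left them open.

## Spectral preprocessing

Raw reflectance scans arrive on the instrument's mixed grid (1.4 nm
sampling below 1050 nm, 2 nm above) with nominally three replicate scans
per pellet. The pipeline is fixed-order and recorded in a provenance
sidecar:

1. **Replicate averaging.** Pointwise mean over the sample's scans.
   Exactly three is the nominal design; any positive count is accepted
   with a logged warning, since field data vary.
2. **Resampling.** Linear interpolation onto the integer-nm grid
   350–2500. Endpoints present in the input are preserved exactly.
3. **Splice correction.** Instruments of this class switch detectors near
   1000 and 1830 nm, which can leave step offsets. For each junction a
   low-order polynomial (quadratic when the window holds ≥ 4 points, else
   a line) is fitted to the 10 nm of spectrum below the junction and
   extrapolated to the first point above it; the whole post-junction
   segment is shifted to match. Quadratic extrapolation keeps the residual
   error third-order in the local curvature (≈1e-9 on smooth spectra
   rather than ≈1e-6 for a linear fit). Junction positions and window are
   configurable.
4. **Normalization.** Standard normal variate (SNV) per spectrum —
   centering and scaling to unit sample standard deviation (ddof = 1,
   matching the chemometric `prospectr` convention). SNV removes
   multiplicative scatter and additive offsets, and is invariant to affine
   transforms of the input. `minmax` and `none` are available; a
   zero-variance spectrum under SNV is a hard error.
5. **Trimming.** The noisy margins 350–399 and 2451–2500 nm are dropped;
   on a 1 nm grid the retained window 400–2450 nm holds exactly 2051
   wavelengths.

The order (normalize before trim) means post-trim row means are close to,
but not exactly, zero; classification is unaffected because the same
transform is applied to calibration and test samples. All steps are
idempotent where meaningful (trim of trimmed data is a no-op; SNV of SNV
changes nothing beyond 1e-9).

## MARS

The regression engine is multivariate adaptive regression splines: the
model is a sum of basis functions, each a product of at most `degree`
hinges max(0, ±(x_v − t)), never two hinges on the same variable in one
product. Degree 2 ("1-way interactions") is the pipeline default; degree
1 is used in the cross-validation loops where speed matters and decision
boundaries are close to additive.

**Forward pass.** Starting from the intercept, each step adds the
reflected hinge pair (parent × both directions) that maximizes the
squared-error reduction, scored against the current orthogonalized
residual so the search over all (parent, variable, knot) candidates is a
handful of BLAS calls per parent. Candidate knots are the sorted observed
values of the variable among rows where the parent is active, thinned by a
minimum-span rule (`minspan`, default 3: keep every third value) — with
2051 wavelength columns the span rule is what keeps 600 refits at desk
scale. A `fast_k` cap (default 20) bounds the number of parent terms
searched. Ties break deterministically to the lowest variable index, then
the lowest knot. Candidates whose orthogonalized norm is negligible
(constant columns, duplicate hinges) can never be selected.

**Backward pass.** Terms are deleted one at a time, each step removing the
term whose deletion minimizes GCV = (RSS/n)/(1 − C(m)/n)² with effective
parameters C(m) = m + penalty·(m−1)/2; the returned model is the
GCV-minimum over the whole deletion trace, so pruning can never return a
model with higher GCV than the full forward model. The penalty defaults to
2 for degree 1 and 3 otherwise (Friedman's recommendation); `max_terms`
defaults to min(200, 2n/3). GCV ties prefer the smaller model, so a
constant response collapses to the intercept.

**Variable importance.** Walking the deletion trace from the selected
model down to the intercept, the RSS increase of each deletion is credited
to every variable in the deleted term; scores are rescaled so the maximum
is 100, and variables absent from the pruned basis score exactly zero.
Aggregated over cross-validation iterations, the per-wavelength count of
"importance > 0" gives the selection-frequency profile.

## Flexible discriminant analysis

FDA recasts discriminant analysis as regression via optimal scoring: the
n × K class-indicator matrix G is regressed on the spectra with one
multiresponse MARS model (shared basis), giving fitted values Ŷ = P G.
The K × K matrix Π^(−1/2) (GᵀŶ/n) Π^(−1/2) (Π = diagonal class
proportions) is symmetric positive semidefinite; after deflating the
trivial unit eigenvalue its leading eigenvectors give up to K−1 optimal
score vectors θ_l with discrimination eigenvalues λ_l ∈ (0, 1). Canonical
coordinates are z_l(x) = η(x)ᵀθ_l · (λ_l(1−λ_l))^(−1/2); with that
per-axis weighting folded in, plain Euclidean nearest-centroid distance is
the classical FDA rule. Design choices:

- the canonical dimension is min(K−1, rank) with eigenvalues below 1e-9
  treated as zero; if no direction survives (e.g. label noise prunes the
  regression to the intercept), one degenerate axis is kept so that
  prediction falls through to the deterministic tie rule;
- sign indeterminacy is fixed by making the first nonzero entry of each
  score vector positive;
- distance ties break to the first class in the model's class list
  (sorted labels by default), making prediction fully deterministic;
- eigenvalues are clipped to [1e-8, 1−1e-8] before weighting so perfectly
  separated training data yield finite coordinates;
- the classification rule is nearest canonical centroid because the
  underlying posterior rule of the original analysis is not specified.

Models serialize to JSON (basis, coefficients, scores, centroids,
training canonical ranges) and reload for calibrate-once/predict-later
use. New samples whose canonical coordinates fall outside the per-axis
training range are flagged as extrapolating — a cheap triage for the
elevated misclassification risk of out-of-population samples.

## Repeated double Monte Carlo cross-validation

Each iteration draws a stratified calibration/test split, refits the full
classifier — variable selection included — on the calibration set only,
and predicts the test set. The default design crosses test fractions
(0.05, 0.10, 0.20) with 200 iterations each: 600 fits. Strata are the
cross-classification of the configured keys (species; species × exposure
week; species × week × region); each stratum contributes
round-half-up(fraction × size), at least 1 and at most size−1, test
samples. Strata smaller than 2 go wholly into calibration with a warning
(or raise, when strict). An iteration whose calibration set would hold
fewer than two members of any class is flagged and skipped, never silently
dropped — reachable at 5% fractions with small strata.

Per-iteration seeds derive from the master seed by a counter-based rule
(SeedSequence of [seed, fraction-index, replicate]), so any single
iteration is reproducible in isolation and results are independent of
execution order. Per-class accuracy is recall (correct / true-class test
count); the test-count-weighted mean of class recalls plus the
misclassification rate equals 1 in every iteration. IPA is each sample's
mean 0/1 outcome over the iterations where it was tested; summaries are
reported both per fraction and pooled.

Regional transfer (`transfer_predict`) calibrates once on one region and
predicts all samples of each region, reporting per-region rates — the
training region's figures are resubstitution values.

## Beta regression of IPA on exposure

IPA values live on [0, 1] with endpoint mass, so they are first compressed
by (IPA·(n−1)+0.5)/n — the Smithson–Verkuilen device — with n the number
of observations entering the regression (configurable, since other
readings of n are possible). The model is Beta(μφ, (1−μ)φ) with
logit(μ) = b0 + b1·week and constant precision φ, fitted by maximum
likelihood through `statsmodels`' BetaModel; intervals come from observed
information. Regressions are fitted independently per species, without
pooling or multiplicity correction, over exposed samples (weeks 0–6 as a
numeric predictor). A random-walk Metropolis sampler over (b0, b1, log φ)
with weakly informative normal priors (sd 5 on coefficients, sd 3 around
log 10 on log φ) provides a Bayesian reading; on well-behaved data its
posterior means sit within one standard error of the ML estimates, which
the tests verify. Non-convergence is flagged on the results object, never
silent.

## Spectra–diet association

Diet read counts become relative read abundances by row normalization
(zero-total rows dropped with a report). The diet-side distance is
Bray–Curtis on RRA; the spectra-side distance is Euclidean on the
preprocessed (SNV) spectra, because Bray–Curtis is undefined for the
negative values SNV produces — both metrics are configurable. The Mantel
statistic is the Pearson correlation of the off-diagonal upper triangles,
with significance from joint row/column permutations of one matrix and
p = (#extreme + 1)/(B + 1), two-sided by default. The Procrustes test
(PROTEST) centers and unit-scales two k-dimensional principal-coordinate
configurations (k = 2 by default, matching the usual 2-D ordination
plots), finds the optimal rotation by singular decomposition, and reports
m² = 1 − (Σ singular values)² with the permutation null on row order.
PCoA is the classical double-centering eigendecomposition; axes are scaled
by √eigenvalue, requesting more axes than positive eigenvalues is an
error, and each axis is sign-fixed so its largest-magnitude coordinate is
positive. For n ≤ 6 both permutation tests agree with exhaustive
enumeration over all n! permutations, which the tests assert. The
Bayesian latent-variable ordination used in the original diet
visualization is out of scope; PCoA fills the visualization role.

## Synthetic-data generator

`simulate_dataset` composes reflectance as

    baseline(λ) + archetype_species(λ) + offset_region(λ)
    + individual(s, λ) + coupling·diet(s, λ) + saturation(week)·exposure(λ)
    + scan noise,

where the baseline is a smooth positive curve with water-band dips;
species archetypes are sums of `n_features` Gaussian absorption features
(centers 450–2400 nm, widths 25–90 nm, signed depths scaled by
`species_effect_size`, default 0.04 reflectance units); regional offsets
are broader shared Gaussian shifts (`region_offset_amp`); individual
effects are smooth low-amplitude curves (`individual_sd`, default 0.01);
diet compositions are Dirichlet draws whose per-species means interpolate
toward a common mean as `diet_overlap` → 1, optionally coupled into the
spectra through per-taxon signatures; and weathering applies
−`exposure_decline_amp` over 700–1400 nm and +`exposure_rise_amp` over
1500–2500 nm (logistic shoulders, ~15 nm), scaled by the saturating
response 1 − exp(−week/τ) with τ = `exposure_saturation` = 2 weeks — so
band means move strictly monotonically with week at a declining rate.
Defaults mirror the field design: five species, 95 pellets per species,
three replicate scans, weeks 0–6 for the exposed subset. The exposure
signature is deliberately species-independent, so weathered samples add
information rather than confounding the species signal. A seeded
configuration is bit-reproducible, and every latent component is returned
in a truth record so recovery tests never re-simulate.

**What the simulator does not emulate:** real absorption-band physics
(overtone assignments, particle-size scattering), heteroscedastic
instrument noise, drift between scanning sessions, diet–exposure
interactions, and the actual spectra of the deposited field data. Passing
tests therefore demonstrate that the statistical machinery is correct and
well calibrated under the assumed generative structure — not that any
particular accuracy level will be attained on real pellets.

**Fixtures and problem sizes.** The named fixtures
(`separable-5species`, `wf-ef-transfer`, `exposure-grid`, `null-diet`) use
a 10 nm wavelength grid (206 points after trimming) and 20–45 samples per
species, and the end-to-end checks cap MARS at ≤ 21 terms — sizes chosen
so the full suite, including a complete 600-fit cross-validation design
(on a 20 nm grid, 120 samples), runs in minutes on one CPU while
preserving the generative structure of the full-resolution study. The
same structure at 1 nm resolution is a configuration change, not a code
path.

## Known limitations

- The forward pass scores hinge pairs jointly but adds both members only
  when numerically independent; extremely collinear wavelength blocks can
  make the selected knot sensitive to the minimum-span thinning.
- GCV effective-parameter counting uses the standard per-pair penalty;
  no explicit degrees-of-freedom correction for the optimal-scoring step
  is applied (the cross-validation loop, not GCV, is the arbiter of
  generalization here).
- The beta regression assumes constant precision; IPA values from few
  test appearances are noisier than the model acknowledges (appearance
  counts are reported so users can filter).
- Mantel and Procrustes p-values are conditional on the chosen distance
  metrics; with SNV spectra a Euclidean metric is the defensible default,
  but it is not the only one.
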