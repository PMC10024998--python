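# pelletspec

Species identification of small rodents from the near-infrared reflectance
spectra of their fecal pellets (fNIRS), for ecologists building noninvasive
monitoring pipelines.

Fecal pellets are cheap to collect at scale, and their 350–2500 nm
reflectance spectra carry a taxonomic signal: dried feces of coexisting vole
and lemming species (*Lemmus lemmus*, *Myodes rufocanus*, *M. rutilus*,
*Microtus oeconomus*, *M. agrestis*) differ enough in chemistry and
structure that a calibration model can assign a single pellet to genus or
species. `pelletspec` implements the full statistical stack for building
and honestly validating such calibrations:

- **Spectral preprocessing** — replicate-scan averaging, interpolation to a
  1 nm grid, detector-junction splice correction, standard normal variate
  (SNV) normalization, and trimming to the clean 400–2450 nm window.
- **MARS** — multivariate adaptive regression splines built from scratch:
  greedy forward selection of reflected hinge pairs
  max(0, ±(x_λ − t)), products up to a configurable degree, and backward
  pruning under the generalized cross-validation score
  GCV(m) = (RSS/n) / (1 − C(m)/n)², C(m) = m + penalty·(m−1)/2.
- **Flexible discriminant analysis (FDA)** — linear discriminant analysis
  generalized through optimal scoring, with the multiresponse MARS fit
  supplying the (nonlinear) discriminant subspace; classification is
  nearest class centroid in the weighted canonical space (at most K−1
  axes for K classes).
- **rdMCCV** — repeated double Monte Carlo cross-validation: stratified
  calibration/test splits at test fractions 5%, 10% and 20%, 200
  iterations each (600 model fits), with variable selection refitted
  inside every split. Outputs misclassification-rate distributions,
  per-class accuracies, per-wavelength selection frequencies, and each
  sample's **individual prediction accuracy** (IPA) — the mean of its
  0/1 classification outcomes over the iterations in which it was held
  out.
- **Inference on IPA** — the endpoint transform
  IPA_beta = (IPA·(n−1) + 0.5)/n followed by logit-link beta regression of
  accuracy on weathering (exposure) time, by maximum likelihood with an
  optional Metropolis sampler.
- **Spectra–diet association** — relative read abundances (RRA) from diet
  metabarcoding counts, Bray–Curtis distances, Mantel and Procrustes
  permutation tests, and principal-coordinates ordination.
- **Synthetic data** — a generator that emulates the study's structure
  (species-specific absorption features, regional offsets, saturating
  weathering drift, Dirichlet diet compositions with tunable overlap), so
  every stage is testable end to end without the field dataset.

## Worked example

Fit a calibration model on the bundled well-separated five-species fixture
and cross-validate it:

```python
from pelletspec import (make_fixture, FlexibleDiscriminantAnalysis,
                        ModelSpec, SplitScheme, run_rdmccv)

ds, diet, truth = make_fixture("separable-5species")
fit = FlexibleDiscriminantAnalysis(
    ds.reflectance, ds.labels("species"), degree=2, max_terms=21
).fit()
print(fit.summary())

res = run_rdmccv(
    ds, ModelSpec(degree=1, max_terms=15),
    SplitScheme(fractions=(0.05, 0.10, 0.20), iterations_per_fraction=20,
                stratify_by=("species", "exposure_week"), rng_seed=0),
)
print(res.summary_text())
```

prints

```
Flexible discriminant analysis (MARS basis)
======================================================
classes: Llem, Magr, Moec, Mruf, Mrut
canonical dimension: 4
basis terms: 21    selected wavelengths: 8
training accuracy: 1.000
------------------------------------------------------
axis    eigenvalue       scale
   1        0.9988       29.04
   2        0.9943       13.33
   3        0.9891        9.61
   4        0.9872       8.901

Repeated double Monte Carlo cross-validation
======================================================
response: species    classifier: fda_mars    degree: 1
models fitted: 60    skipped: 0
------------------------------------------------------
fraction  0.05: misclassification 0.000 +/- 0.000  (n=20)
fraction   0.1: misclassification 0.000 +/- 0.000  (n=20)
fraction   0.2: misclassification 0.000 +/- 0.000  (n=20)
pooled        : misclassification 0.000 +/- 0.000
------------------------------------------------------
      Llem: accuracy 100.0% +/- 0.0%
      ...
```

The five classes separate on four canonical axes (eigenvalues near 1 =
near-perfect discrimination); eight wavelengths suffice, and every held-out
sample is classified correctly at all three split fractions. On harder
(noisier, more overlapping) data the misclassification densities and
per-class accuracies become informative, and `res.ipa()` pinpoints which
individual samples are fragile.

The same workflow is scriptable from a shell — `pelletspec simulate`,
`preprocess`, `calibrate`, `predict`, `crossvalidate`, `ipa-regress`,
`diet-assoc`, `report` — with CSV/JSON outputs at every stage; see
`pelletspec --help`.

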