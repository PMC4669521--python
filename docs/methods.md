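# Methods

This note documents the statistical procedures, the synthetic data the
package tests itself on, the numerical choices, and the places where the
design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Association scan

Each CpG site's beta value (fraction of methylated alleles, in [0, 1]) is
regressed on chronological age by ordinary least squares. The reported
statistics per site are the slope (beta/year), intercept, Pearson R,
R², the slope's Student t statistic t = R·√((n−2)/(1−R²)), its two-sided
p-value on n−2 degrees of freedom, and the Benjamini–Hochberg adjusted
q-value. Two selection filters are exposed: a *loose* one (p < 0.01 and
R² > 0.5) and a *strict* one (q < 0.01). All threshold comparisons are
strict inequalities, exactly as the thresholds are conventionally printed;
a site at p = 0.01 is excluded, a value with detection p = 0.01 exactly is
kept.

Numerical conventions:

* A zero-variance beta row (or age vector) yields R = 0, p = 1, slope = 0
  and a `degenerate` flag instead of NaN, so the record table stays total
  and filterable.
* A perfect fit (|R| = 1) reports p = 0 — the double-precision underflow
  convention — rather than a denormal tail value.
* The FDR procedure is Benjamini–Hochberg step-up,
  q₍ᵢ₎ = min over j ≥ i of p₍ⱼ₎·m/j, capped at 1. BH is the field default
  for array-scale methylation scans; no other FDR method is offered.
* Island enrichment is the two-sided Fisher exact test on the 2×2 table
  {selected, universe∖selected} × {island, non-island}. The selected sites
  are removed from the comparison row; an annotation covering the whole
  universe is required.

### Detection-p masking and KNN imputation

Values whose detection p exceeds 0.01 are set missing before the scan, and
missing values are imputed from the k = 10 nearest sites. Nearness between
two site rows is Euclidean distance over their mutually observed samples,
rescaled by √(n_samples/n_shared) so that rows sharing few samples are not
spuriously close — the behaviour of the widely used row-KNN imputation for
expression/methylation arrays, documented here as an approximation of that
package's exact scheme. A missing cell takes the mean of that sample's
values at the k nearest sites *observed in that sample*; distance ties
break by input row order, which makes imputation deterministic. A site
with zero observed values is an error, not a guess.

## Sequenom-style calibration and QC

The canonical stage order is **confidence filter → missingness filter →
calibration → |R| selection**, enforced by `run_qc_pipeline`:

1. **Confidence.** Mass-spectrometric quantification attaches a per-value
   confidence score (0–5); values are accepted only if the score is
   strictly above 1.9. The acceptance fraction is reported.
2. **Missingness.** Sites with > 70 % missing values are dropped first,
   then samples with > 70 % missing computed on the site-reduced matrix.
   Sites go first because a failed amplicon should not drive a sample
   exclusion. A site at exactly 70 % is retained.
3. **Calibration.** Known standard methylation (0, 10, …, 100 %) is
   regressed on measured methylation; the fitted line (slope, intercept,
   R² of fit) maps measured values to corrected ones. Corrected values are
   clipped to [0, 1]: the calibration line maps low measurements to
   negative fractions (measured 0.5 ↦ −0.0751 under the 2.285/−1.2176
   line), and beta values are fractions by definition. The clip count is
   recorded in the QC report. Whether calibration should precede site
   selection was an open choice; this pipeline calibrates first, because
   selection statistics should see values on the biological scale.
4. **Selection.** Per-site Pearson R against age on pairwise-complete
   observations (no imputation at this stage — imputation is reserved for
   the dense BeadChip scan). Sites with |R| strictly above 0.5 are kept;
   sites with fewer than three observed values are excluded with a flag
   rather than an error.

## Age models

All four families consume a samples × sites feature matrix and ages in
years, and report MAD = mean |predicted − observed| in years.

* **Linear**: OLS with intercept, solved by pivoted QR. Rank deficiency is
  an error naming the collinear columns — never a silent pseudo-inverse.
  Requires n > p + 1.
* **Quadratic**: least squares on [1, xⱼ, xⱼ²] — pure squares, no cross
  terms. A full second-order model in 11 sites needs 79 parameters, more
  than a 49-sample cohort supports; pure squares need 23. Requires
  n > 2p + 1.
* **BPNN**: one hidden layer (default 3 sigmoid units), linear output,
  full-batch gradient descent (default learning rate 0.1) on standardized
  inputs and response, run for exactly 1000 epochs unless an optional loss
  plateau stops it early; deterministic given its seed; the loss curve is
  recorded. This is an ordinary back-propagation network standing in for
  proprietary "quick-method" trainers whose internals are unpublished;
  hidden size and learning rate are configuration with stated defaults.
* **SVR**: ε-insensitive loss, RBF kernel, defaults C = 2, γ = 0.1,
  ε = 0.1. Features and response are standardized internally and
  predictions de-standardized; without scaling a single γ is meaningless
  across the beta (0–1) and age (20–80) scales, and ε lives on the
  standardized response scale. The dual QP is solved by SMO with
  maximal-violating-pair working-set selection; each iteration updates one
  (αᵢ, αⱼ) pair analytically and maintains the gradient incrementally.
  Termination at KKT gap < 10⁻⁶; exceeding 10⁵ iterations raises a
  convergence error, never a warning. Zero response variance short-circuits
  to a constant predictor without a solver call. When ε exceeds the
  response range the optimal dual is z = 0 and any bias in
  [max(y)−ε, min(y)+ε] is optimal; the midpoint is returned for
  determinism. Fitted attributes expose the dual coefficients (α−α*), the
  support set, total slack, and the minimized dual objective, which the
  test suite compares against an independent dense-QP solve.

## Leave-one-out validation and subset search

`loo_cv` refits the model n times, predicting each held-out sample;
stochastic families are reseeded per fold (base seed + fold index).
`exhaustive_subset_search` scores *every* subset of the requested sizes by
LOO MAD and also records each subset's resubstitution (training) MAD —
the training-vs-LOO contrast is the over-fitting diagnostic at the heart
of the analysis, so it is built into the search table rather than bolted
on. Ties on minimal MAD break toward the lexicographically smallest
site-id tuple. A guard refuses more than 20 features (2²⁰ subsets) without
an explicit override. `choose_final_subset` formalizes the
accuracy-vs-panel-size trade: the smallest size whose minimal LOO MAD is
within a tolerance (default 0.05 years) of the global minimum. The default
tolerance is the scale at which two panel sizes are practically
indistinguishable (a 0.01-year difference between six- and seven-site
panels should not buy a seventh marker).

## Synthetic data: what it emulates, what it does not

All tests run on generated data; the generator's defaults are the study
conditions of the analysis.

* **Cohorts.** A discovery cohort of 16 samples as 8 monozygotic twin
  pairs, ages uniform on [21, 32] with twins sharing an age exactly; a
  validation cohort of 50 unrelated adults on [20, 80]. Ages are uniform
  — no attempt to model recruitment age structure.
* **Sites.** Associated sites follow clip(b₀ + s·age + ε, 0, 1) with
  ε ~ N(0, noise_sd); background sites are flat. b₀ is the age-0
  intercept drawn uniformly from `baseline_range`. The scenario helpers
  pick sign-specific baseline windows (low baselines for gaining sites,
  high for losing sites) so planted trends are not flattened by the [0,1]
  clip; the raw `generate_betas` applies no such adjustment, which is why
  a carelessly chosen baseline/slope pair saturates — as real bounded
  fractions do.
* **Effect sizes.** Discovery slopes are 0.015–0.022 beta/yr at
  noise_sd = 0.03: over the narrow 11-year twin window this places
  planted sites at population R² ≳ 0.72, the regime in which a loose
  P/R² filter on 16 samples is expected to recall them. Validation-scale
  slopes are 0.004–0.008 beta/yr: a bounded fraction cannot sustain
  0.02/yr over six decades. With 10,000 sites and 500 planted, the
  loose-filter discovery fraction lands near the ~0.5 % of the array that
  genome-scale scans of this design report.
* **Platform artifacts.** The validation measurements are pushed through a
  linear distortion whose inverse is the calibration line y = 2.285x −
  1.2176, plus a standards series (0–100 % in 10 % steps, optional noise),
  per-value confidence scores (≈5 % below the 1.9 cutoff), value-level
  Bernoulli missingness, and deliberate heavy dropout in a few sites and
  one sample so the 70 % filters have real work.
* **Age acceleration.** The model-comparison panels add a per-sample
  offset between biological and chronological age, shared across that
  sample's sites, drawn from a heavy-tailed scaled Student-t
  (5·t₃ years, sd ≈ 8.7). Age cohorts genuinely contain individuals whose
  methylome runs ahead of or behind their birth date, and the tails are
  what separates an ε-insensitive loss from squared error: under a purely
  linear, light-tailed signal OLS is the maximum-likelihood estimator and
  no kernel method can beat it in cross-validation. Under these
  conditions the 11-site SVR shows a training MAD of about 2 years
  against a LOO MAD of about 6 — the over-fitting picture the subset
  search exists to correct — and beats linear regression's LOO MAD in a
  majority of seeded replicates (both recomputed by the acceptance
  script, not asserted as constants here).
* **Determinism.** One global integer seed fans out to named sub-streams
  (cohort, betas, mask, standards, confidence), so fixing the seed fixes
  every byte of output and each stage is independently reproducible.

What the generator does **not** model: probe hybridization chemistry,
bisulfite-conversion efficiency, batch effects, cell-type composition,
sex chromosomes, or genuinely nonlinear lifespan trajectories (pediatric
methylation drift is much faster than adult). Passing tests therefore
demonstrate that the *pipeline machinery* — masking, imputation,
regression, FDR, calibration, QC, solvers, search — behaves to
specification, and that the modelling conclusions hold under the stated
statistical structure; they do not certify accuracy on any real cohort.

## Problem sizes

The default test and acceptance workloads are desk-scale by design: scans
of 10,000 sites × 16 samples; 20-seed null panels of 2,000 sites; 20-seed
model comparisons at 49 × 11; an exhaustive SVR search over an 8-site
panel (255 subsets × 49 folds). The search machinery itself handles the
full 11-site search (2,047 subsets); it is simply more than the routine
test workload needs.

## Known discrepancies and limitations

* The analysis design this pipeline follows is sometimes reported with
  an internally inconsistent discovery count (a 2,957 headline vs an
  itemized 1,476 positive + 1,489 negative = 2,965); the itemized figure
  is treated as canonical. Neither number is recomputed here — it is a
  property of a specific cohort's data, not of the pipeline.
* The exact margins of the original island-enrichment Fisher test are
  unstated, so its printed p-value is not reproduced; the implementation
  removes selected sites from the comparison row and documents that
  choice.
* EpiTYPER confidence filtering is per value, not per amplicon; site
  labels (X21–X95) are opaque strings with no genomic coordinates.
* The BPNN is an ordinary gradient-descent network; only its cycle budget
  (1000) and topology are fixed, and it is the one stochastic family.
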