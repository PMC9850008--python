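# Methods

## Scope and data model

`finclock` implements the statistical pipeline of a species-specific
epigenetic clock study: methylation beta values on a CpG-by-sample grid
(canonical orientation rows = CpGs, the methylation-array convention),
a per-sample sheet with age, age-accuracy class and sex, and sparse
fitted models saved as coefficient tables. It deliberately does **not**
touch raw array processing: no IDAT parsing, no normalization, no probe
annotation. Inputs are assumed to be normalized beta values in [0, 1].

Missing beta values are allowed on disk and in memory; every model-facing
operation first imputes them with the per-CpG mean. A model CpG entirely
absent from a prediction matrix is an error by default; with the
`impute_missing` flag its beta is fixed at 0.5 (the midpoint — no
per-CpG mean exists for a row with no data), which is deliberately
conservative for sparse models. All floats are serialized with 17
significant digits and re-read with round-trip parsing, so
write-then-read is the identity.

## Age transform

F is logarithmic up to the adult age A and linear after, with offset
c = 1 year (units: years in, dimensionless out):

    F(a) = log((a + c)/(A + c))  for a <= A;  (a - A)/(A + c) otherwise.

F is strictly increasing, zero at A, and C¹ at the knot (one-sided
derivatives both 1/(A + c)). The inverse is exact on all reals; very
negative inputs can map below 0 years and are returned unclamped with a
warning (clamping, when wanted, is a reporting choice — the CLI's
`--clamp-zero`). A defaults to 7 years (the sexual-maturity estimate
used for the study population) and is configurable (`--adult-age`),
since observational estimates for some populations run to 10–12 years;
the value is stored in every saved clock so a coefficient file is
self-contained. Natural logarithm throughout. A pass-through identity
transform is available for testing (`--no-transform`).

## Elastic-net solver

Both families minimize, with weights normalized to Σw = 1 (so λ is
comparable across datasets and weight scalings),

    gaussian:  (1/2) Σ w_i (y_i − β0 − x_i'β)² + λ P_α(β)
    binomial:  −Σ w_i [y_i log p_i + (1−y_i) log(1−p_i)] + λ P_α(β)

with P_α(β) = α‖β‖₁ + (1−α)/2 ‖β‖₂² and p = logistic(β0 + x'β). The
intercept is unpenalized. Features are standardized internally to
weighted mean 0 / variance 1 (the penalty applies on that scale, as in
standard practice); coefficients are reported back on the original
scale. Zero-variance features are dropped with a warning.

Numerics: cyclic coordinate descent with soft-thresholding and residual
updates, an active-set strategy, and warm starts down a 100-point
log-spaced path from λ_max (the smallest penalty with an all-zero
solution, computed from the null-model gradient and given a 1e-9
relative margin so a fit at exactly λ_max is null despite rounding) to
λ_max·r with r = 1e-4 when n > p else 1e-2. Convergence is declared when
a full sweep moves no coefficient by more than `tol` (default 1e-7).
Two accelerations leave the solution unchanged: a sequential strong rule
restricts per-penalty work to candidate columns (with a full-gradient
KKT pass that admits any violator and re-solves), and an active-set
Newton "polish" solves the stationarity system exactly on the detected
support before the final certified coordinate-descent pass. The binomial
family wraps the gaussian core in iteratively reweighted least squares;
working probabilities are clamped (|η| ≤ 30, p(1−p) ≥ 1e-5) and
quasi-separation is flagged on the result. α = 0 uses the conventional
λ_max surrogate (computed at α = 0.001). Exact-equality ties in the
soft-threshold map to zero.

Penalty selection: n-fold cross-validation, by default leave-one-out
(folds are then singletons in sample order — no randomness); k < n folds
derive deterministically from a seed. The CV error is the weighted mean
squared error (gaussian) or weighted binomial deviance (held-out,
probabilities clipped at 1e-10). λ is the CV-error minimizer, ties
broken toward the larger penalty (sparser model); the one-standard-error
rule is available as a flag but is not the default, since the study's
procedure implies the plain minimizer. A binomial fold that would strip
a class from the training part triggers one reshuffle, then an error.

The test suite checks the solver against independent references:
scikit-learn's `ElasticNet`/`LogisticRegression(saga)` at matched
penalties, a closed-form univariate soft-threshold solution, weighted
OLS at λ = 0, and a direct L-BFGS-B minimization of the penalized
deviance via a split-variable reformulation.

## Clock pipeline

Training weights come from the age-accuracy class: ≤ ±1 year → 1.0,
≤ ±2 years → 0.5, coarser or unknown → excluded. (The 84-sample clock
variant of the study is this same pipeline with the ±2 class present —
a configuration, not separate code.) At least 10 weighted samples are
required (a guard, not a recommendation; real clocks want ≥ ~70).

λ is selected **once** on the full weighted training set by LOO internal
CV; the leave-one-out evaluation then refits at that fixed λ with each
sample held out, predicts its transformed age, and inverse-transforms to
years. This matches the study's stated order of operations; a
`refit_lambda` flag provides the stricter fully-nested variant. Because
LOO folds are deterministic, the whole train → evaluate path is
bit-reproducible. Reported metrics: Pearson r, median absolute error in
years, and the OLS line of predicted on observed age. Regularization
shrinks predictions toward the cohort mean, so the fitted slope is ≤ 1 —
young animals read old and old animals read young, the compression
pattern characteristic of penalized clocks. Predictions are unclamped;
an r is undefined (reported missing) when either vector is constant.

## Sex predictor

Binomial elastic net on all samples of known sex, unit weights, LOO
internal CV on deviance. No outer cross-validation: reported accuracy is
resubstitution accuracy (the library exposes everything needed to
evaluate otherwise). The decision rule is strict — probability > 0.5 is
male, exactly 0.5 is female. Samples of unknown sex are excluded from
training but predictions are produced for any array. On the default
synthetic cohort (30 sex CpGs with a 0.3 mean beta shift against 0.03
noise) the classes separate completely, with fitted probabilities near
0.99/0.01 — the degree of extremity is set by the CV-selected penalty,
not by the data noise; R's `cv.glmnet` selects the same penalty and
produces the same probabilities on identical data.

## Quality control

The screen operationalizes the visual inter-array-correlation check as a
reproducible rule. Statistic: each array's mean Pearson correlation with
all others (after per-CpG mean imputation). Rule: flag when the robust
z-score (median/MAD, scale 1.4826) is below `z_cut` (default −5) **and**
the mean correlation is below 0.5. The absolute guard exists because the
mean-correlation distribution of clean arrays has genuine structure —
arrays from animals at the age extremes track the cohort less tightly
and can reach z ≈ −8 under a pure z-rule — while true technical failures
sit near zero correlation (z ≈ −100 or lower); an array still correlated
0.9 with the cohort is never removed on a z-score alone. A zero MAD
(near-identical arrays) falls back to the absolute rule; zero-variance
arrays have undefined correlations and are always flagged. The
average-linkage merge history on distance 1 − r accompanies every report
so the classical dendrogram inspection can be replicated; flagging is
invariant to sample order and stable under deletion of a flagged array.

## Synthetic cohorts

The generator emulates the calibration data of a wild-dolphin
methylation study: by default 68 animals with ages uniform on 0–37 years
(a "cohort" preset draws instead from a truncated normal, mean 14.6,
SD 8.0), sex Bernoulli(1/2), and 2030 CpGs — 200 age-associated, 30
sex-associated, 1800 null. Age CpGs follow
beta = clip01(a_j + b_j·F(age) + ε) with baselines a_j ~ U(0.2, 0.8),
slopes b_j ~ N(0, 0.05) (both hyper- and hypomethylating sites; the
spread gives per-site effects comparable to published clock CpGs), and
ε ~ N(0, 0.03). Sex CpGs shift male means by 0.3 (baselines drawn on
[0.2, 0.5] so the shift is never clipped); null CpGs are baseline plus
noise. Clipping to [0, 1] happens after noise — beta values are
fractions — and is the one acknowledged nonlinearity: rows that touch
the boundary lose exact linearity in F(age), which the recovery tests
therefore condition on. Outlier arrays are corrupted by resampling all
their values uniformly on [0, 1], destroying inter-array correlation.
All draws flow from a single seeded generator: identical configs give
bit-identical datasets, and every simulated CpG and sample carries a
ground-truth record.

What the generator does *not* model — array chemistry, batch and chip
effects, CpG–CpG correlation beyond the shared age factor, missingness
patterns, age-dependent sampling bias — bounds what passing tests show:
they validate the statistical machinery (selection, shrinkage,
cross-validation, weighting, QC) under the assumed generative model, not
clock accuracy on real arrays, which is limited by biological variation
this simulation idealizes away. The default noise level makes the
synthetic signal considerably cleaner than real methylation data; LOOCV
r ≈ 0.999 here versus ≈ 0.86 in the field is expected, not a claim.

## Problem sizes and determinism

Default problem sizes used by the test suite and acceptance script —
n = 68 (clock), n = 165 (sex, QC), 2030 CpGs, 100-penalty paths, LOO CV
throughout — run end to end in a few minutes on one CPU; they were
chosen to mirror the study's sample sizes exactly while keeping the CpG
panel at array scale in the informative fraction. Every stochastic step
(simulation, k-fold shuffling) is driven by explicit integer seeds, and
LOO CV introduces none of its own, so identical seeds give bit-identical
pipelines.

## Known limitations

* The solver targets dense matrices; no sparse-input path.
* Gaussian and binomial families only (no multinomial/Cox).
* The QC rule's constants (z = −5, absolute 0.5) were fixed a priori as
  deliberately conservative; the original visual procedure had no
  numeric criterion to validate against beyond its reported outlier
  count.
* `impute_missing` for absent model CpGs substitutes 0.5, which biases
  predictions toward the intercept for heavily incomplete inputs.
* No replication of any published clock's coefficient values is
  attempted; `predict-age` accepts such tables if the user supplies
  them.
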