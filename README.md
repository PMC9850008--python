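# finclock

Epigenetic age clocks and methylation-based sex prediction for wild
cetacean populations.

Knowing an animal's age and sex is fundamental to population ecology, but
for free-ranging dolphins both are hard to obtain without decades of
observation or invasive sampling. DNA methylation offers a way out: the
methylation fraction (*beta value*, in [0, 1]) at certain CpG sites drifts
predictably with age, and a handful of sites differ systematically between
the sexes. `finclock` builds both estimators from methylation-array data —
a sparse **elastic-net age clock** and a **binomial elastic-net sex
classifier** — together with the supporting machinery: inter-array
quality control, leave-one-out evaluation, and a synthetic-data generator
that reproduces the statistical structure of a wild-cohort methylation
study for testing every stage without access to restricted data.

## The model

**Age clock.** Chronological age is first mapped through a log-linear
transform with a knot at the average age of sexual maturity *A* (default
7 years, offset *c* = 1), reflecting fast epigenetic change before
maturity:

```
F(a) = log((a + c) / (A + c))   if a <= A
F(a) = (a - A) / (A + c)        if a >  A
```

The transformed age is regressed on the CpG-by-sample beta matrix with a
weighted elastic net (mixing parameter α = 0.5),

```
min_{β0, β}  (1/2) Σ_i w_i (F(a_i) - β0 - x_i'β)²
             + λ [ α ‖β‖₁ + (1-α)/2 ‖β‖₂² ]
```

where the sample weights encode age-record accuracy: ages known to ±1
year weigh 1.0, ±2 years weigh 0.5, anything coarser is excluded. The
penalty λ is selected by n-fold (= leave-one-out) internal
cross-validation; the clock is then evaluated by leave-one-out
cross-validation at that fixed λ, each prediction mapped back to years via
F⁻¹. Accuracy is reported as the Pearson correlation *r* between
predicted and observed age, the median absolute error (MAE, years), and
the least-squares line of predicted on observed age.

**Sex predictor.** A binomial elastic net (α = 0.5, unit weights) on the
same beta values, sex coded 0 = female / 1 = male; a sample is called
male iff its fitted probability strictly exceeds 0.5.

**QC.** Technical outlier arrays are screened by inter-array correlation:
each array's mean Pearson correlation with all others is summarized by a
robust z-score (median/MAD), and an array is flagged when z < −5 *and* its
mean correlation falls below 0.5. An average-linkage dendrogram on 1 − r
is emitted for visual review.

The elastic-net solver (weighted gaussian and binomial families, cyclic
coordinate descent with soft-thresholding, active-set Newton polish,
strong-rule screening, warm-started regularization paths) is implemented
in the package and verified against independent reference solvers in the
test suite.

## Worked example

Simulate a 68-animal cohort with two corrupted arrays, screen them out,
and build both estimators:

```
$ finclock simulate --out-dir demo --seed 7 --n-samples 68 --n-outliers 2
simulated 2030 CpGs x 68 samples -> demo

$ finclock qc --beta demo/beta.csv --out demo/qc.json \
    --drop-outliers demo/beta_clean.csv
flagged 2 outlier array(s): ['s0035', 's0068']

$ finclock loocv --beta demo/beta_clean.csv --samples demo/samples.csv \
    --out-predictions demo/pred.csv --out-report demo/loocv.json
LOOCV on 66 samples: r=0.999, MAE=0.25 y, slope=0.986, intercept=0.244

$ finclock train-age --beta demo/beta_clean.csv --samples demo/samples.csv \
    --out demo/clock.csv
clock trained on 66 samples: 74 CpGs retained at lambda=0.0281407

$ finclock train-sex --beta demo/beta_clean.csv --samples demo/samples.csv \
    --out demo/sex.csv
sex model trained on 66 samples: 30 CpGs retained at lambda=0.0098424
```

Reading the numbers: both injected outliers (and nothing else) were
flagged; the leave-one-out clock correlates 0.999 with true age with a
median error of a quarter year on this low-noise synthetic cohort; the
predicted-on-observed slope 0.986 < 1 shows the mild compression typical
of regularized clocks (young animals overestimated, old underestimated);
the final clock keeps 74 of 2030 candidate CpGs. The saved `clock.csv`
carries the transform parameters in its header, so
`finclock predict-age --beta newdata.csv --model demo/clock.csv --out ages.csv`
is self-contained.

The same workflow is available as a library of scikit-learn-style
estimators (`ElasticNetCD`, `LogisticElasticNetCD`, `EpigeneticAgeClock`,
`MethylationSexClassifier`, `InterArrayOutlierDetector`) plus pipeline
functions (`train_clock`, `loocv_predict`, `apply_clock`, `train_sex`,
`predict_sex`, `run_qc`); see `docs/methods.md` for the modelling details.

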