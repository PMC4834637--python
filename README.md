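# fcbiomarker

Sparse functional-connectivity biomarker discovery for case–control
neuroimaging studies.

## The problem

Resting-state fMRI yields, for every participant, a vector of functional
connections (FCs): Pearson correlations between the time courses of brain
regions — 9,730 of them for a 140-region atlas. Building a diagnostic
classifier from such data faces two failure modes: *over-fitting* (far more
FCs than subjects) and *nuisance variables* (NVs — acquisition site, age,
sex, eye condition, medication) whose correlated FCs masquerade as disease
markers and destroy generalization to new cohorts. `fcbiomarker`
implements a pipeline designed for exactly this setting:

1. **Connectivity** — band-pass filtering (0.008–0.1 Hz), regression of
   tissue/global signals and six motion parameters, frame-displacement
   scrubbing (FD > 0.5 mm removes the frame, its predecessor and the two
   successors), and pairwise Pearson correlation.
2. **L1-regularized sparse CCA** between the 10-column attribute block
   `X1` (diagnosis + 9 NV columns) and the FC block `X2`: maximize
   `v1' X1' X2 v2` under `||v||₂ ≤ 1`, `||v||₁ ≤ c`. Only canonical
   components whose attribute loading is nonzero *solely on the diagnosis
   column* (the diagnostic canonical constraint) contribute FC features;
   components tied to any NV are discarded.
3. **Sparse logistic regression** with automatic relevance determination
   (ARD): per-weight Gaussian priors whose learned precisions prune
   irrelevant FCs to exactly zero; the classifier output is the weighted
   linear summation (WLS), positive → case, negative → control.
4. **Nested 9×9 feature selection + leave-one-out cross-validation** over
   the λ grid (λ1 ≤ λ2 in {0.1, …, 0.9}; 45 pairs) with stratified
   (diagnosis, sex, site) folds — the held-out subject never enters
   standardization, selection or training for its own prediction.
5. **Evaluation and characterization** — diagnostic odds ratio, AUC,
   binomial/permutation tests, KS comparisons with Benjamini–Hochberg
   correction; laterality/network composition, under/over-connectivity and
   distance statistics of an identified FC set; cross-validated clinical
   score regression with a bootstrap null.

A seeded synthetic-cohort generator (`fcbiomarker.synthetic`) plants known
diagnosis and nuisance effects so every stage is testable without access to
clinical data.

## Worked example

`examples/03_nested_loocv_classifier.py` generates a 90-subject cohort with
5 planted diagnosis FCs and 10 site-driven FCs among 60 columns, runs the
nested protocol and applies the final classifier to a fresh cohort:

```
LOOCV accuracy:    0.84
LOOCV sensitivity: 0.85  specificity: 0.84
LOOCV AUC:         0.94
mean FCs used per iteration: 3.7
final classifier uses 7 FCs; 5 of 5 planted FCs among them
accuracy on an untouched validation cohort (no retuning): 0.90
```

The classifier recovers the planted diagnosis FCs, excludes the
site-driven ones, and holds its accuracy on a validation cohort it never
saw — the point of the NV-controlled selection. The other examples cover
FC extraction from ROI time series (`01`), the sparse-CCA selection step in
isolation (`02`), the composition statistics of the packaged 16-FC
classifier annotation table (`04`), and evaluation plus clinical-score
prediction with a bootstrap null (`05`).

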