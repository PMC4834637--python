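# Methods

## Connectivity extraction

Per subject the pipeline is: band-pass filter → nuisance regression →
scrubbing-masked Pearson correlation, in that fixed order. Filtering always
sees the full series; frames are excluded only at the correlation stage,
because censoring before filtering would distort the spectrum of the
retained frames.

* **Band-pass filter.** Second-order Butterworth with transmission range
  0.008–0.1 Hz, applied forward and backward (`filtfilt`). The
  forward–backward pass squares the magnitude response (effective 4th
  order) and zeroes the phase, so filtered series are not shifted in time
  relative to one another — essential when the downstream statistic is a
  correlation. Only the transmission range is externally specified; the
  filter family and order are this package's choices.
* **Nuisance regression.** The white-matter, CSF and whole-brain signals
  plus the six rigid-body motion parameters are band-passed with the same
  filter before being regressed out (unfiltered regressors would reinject
  out-of-band fluctuations). The whole-brain (global) signal is included by
  default; `include_global_signal=False` drops it.
* **Frame displacement.** FD(t) is the sum over the six motion parameters
  of |Δ parameter|. Rotations (radians) are converted to millimetres as arc
  length on a 50 mm sphere before summation — the convention of the
  scrubbing literature; pass `rotation_radius_mm=None` to sum raw radians.
  Scrubbing removes any frame with FD > 0.5 mm together with the previous
  and the two subsequent frames.
* **Degenerate pairs.** A region constant over the retained frames has an
  undefined correlation; it is stored as 0 with a warning so the FC vector
  keeps its fixed length R(R−1)/2. FC order is the row-major strict lower
  triangle, (1,0), (2,0), (2,1), …, 0-based.

## L1-regularized sparse CCA and the diagnostic constraint

For standardized blocks `X1` (n × 10 attributes) and `X2` (n × p FCs) the
method maximizes `v1' X1' X2 v2` subject to unit L2 and bounded L1 norms on
each projection vector. Implementation choices:

* **L1 bound.** `c_j = max(1, λ_j √p_j)` with λ ∈ (0, 1]. λ → 0 forces a
  single nonzero coordinate; λ = 1 leaves the unit-L2 solution
  unconstrained. The literature states only that λ controls sparseness;
  this parameterization makes the 0.1–0.9 grid interpolate between those
  extremes and is declared here so results are reproducible.
* **Solver.** Per component, alternating constrained projections
  `v1 ← P(S v2, c1)`, `v2 ← P(S' v1, c2)` on the cross-product matrix
  `S = X1' X2`, where `P(a, c)` soft-thresholds `a` with the smallest
  threshold (bisection, 100 halvings) that brings the normalized vector's
  L1 norm under `c`, then rescales to unit L2. Initialization: leading
  right singular direction of S estimated by 20 factored power steps, sign
  fixed so the largest-magnitude entry is positive. Convergence: objective
  change < 1e-6·max(1, |objective|) (relative, because bisection
  quantization leaves absolute jitter on objectives of magnitude ~10²), cap
  200 alternations; non-convergence keeps the last iterate and is recorded
  in `SccaResult.converged`. After each component the rank-1 term
  `d_k v1 v2'` is deflated from S; the multi-component scheme is not
  specified upstream and rank-1 deflation is this package's choice.
* **Diagnostic canonical constraint.** A component is *diagnostic* when its
  attribute loading `v1[:, k]` is nonzero exactly on the diagnosis row and
  zero elsewhere ("nonzero" means exactly nonzero — soft-thresholding
  produces exact zeros, no epsilon). The selection weight vector ξ sums
  |v2| over diagnostic components and across fits; the selected FC set is
  the support of ξ. Magnitudes are kept for reporting, only the support
  drives the projection.
* **Constant columns** (e.g. a site flag in single-site training rows) get
  SD set to 1 at standardization, making them inert, and are flagged.
* **Behaviour to be aware of.** After the dominant diagnostic component is
  deflated, later components whose attribute loading again lands on the
  diagnosis row capture residual (noise-level) covariance, and at dense λ2
  the soft threshold admits most columns; the ξ-support union over the full
  grid is therefore broad at moderate p, and excluding nuisance-linked FCs
  is accomplished by the *combination* of the diagnostic constraint and the
  downstream ARD pruning, not by the union alone. The acceptance experiment
  measures exactly this: site-linked FCs reach the final classifier at a
  rate of zero-to-chance, while planted diagnosis FCs survive.

## ARD sparse logistic regression

Binary logistic regression with an independent Gaussian prior N(0, 1/α_i)
per weight. Fitting alternates a Laplace approximation around the
penalized-likelihood mode (damped Newton; solved in the n-dimensional dual
space via the Woodbury identity whenever there are more active features
than samples) with MacKay evidence updates
`α_i ← (1 − α_i Σ_ii) / μ_i²`. Defaults: α initialized to 1; bias on a
fixed broad prior (α = 1e-6) and exempt from pruning; weights with
α > 1e8 pruned to exactly zero; convergence when the maximum relative α
change falls below 1e-4, cap 500 iterations (the flag in `fit_log` records
non-convergence; borderline precisions can oscillate indefinitely without
affecting the mode). Features are standardized internally with training
statistics stored in the model, so external subjects are scored without
touching their data at training time.

A property of this joint MacKay fixed point worth stating plainly: on pure
noise it retains the columns whose data alignment exceeds its null
expectation (roughly the χ²₁ > 1 tail, ~30% at n=200/m=50 — sklearn's ARD
regression behaves the same), with small weights. Pruning is therefore
*bulk*, not total, at moderate dimension; in the m ≫ n regime and in the
presence of real signal the retained set is far smaller. The tests assert
the measured contract.

## Nested 9×9 feature selection + LOOCV

* Folds are stratified by (diagnosis, sex, site): each stratum is dealt
  round-robin after a seeded shuffle, starting at an offset that rotates
  with cumulative stratum size so small strata spread across folds; per-
  stratum fold counts differ by ≤ 1. The remainder rule is this package's
  decision.
* For each outer fold (testing pool), the other 8 folds are re-partitioned
  into 9 inner folds; dropping each inner fold in turn, sparse CCA runs for
  all 45 λ pairs on rows standardized over the retained subjects only, and
  diagnostic features accumulate by summed ξ. λ pairs yielding no
  diagnostic component contribute nothing.
* Every subject in the pool is then predicted by an ARD classifier trained
  on all N−1 remaining subjects restricted to the pool's feature set.
  Implementation note: each per-subject fit is warm-started (α, w) from a
  *pool-reference* fit trained on the 8 outer training folds. The reference
  excludes every pool subject, and the per-subject fit still trains on all
  N−1 rows, so no information about the held-out subject enters its own
  prediction; the warm start reuses admissible data only and skips the
  expensive high-dimensional pruning phase of each of the N fits.
* The final classifier trains on the whole cohort restricted to the union
  of the nine outer-fold feature sets, and is applied to external cohorts
  with stored standardization statistics and no refitting of any kind.

## Synthetic cohorts

The generator emulates a multi-site case–control resting-state study; it
is the package's test bed, not a physiological simulation.

* **Attributes** (10 columns): diagnosis, one-hot site (3 columns,
  default proportions 0.4/0.4/0.2), age uniform 20–45 y, sex
  Bernoulli(0.7 male), eye condition Bernoulli(0.5), three medication flags
  (default Bernoulli(0.4) among cases, 0 among controls — mirroring
  clinical cohorts; set equal rates for independence). A site can be
  declared control-only. `exact_balance=True` fixes the case count to
  round(n/2) by seeded permutation — the designed-experiment convention
  used for the null-calibration cohorts, where the chance level must be
  exactly 0.5 (with Bernoulli draws a noise cohort can be ~55/45 and LOOCV
  accuracy then reflects the majority rate, not miscalibration).
* **FC matrix.** Latent Gaussian per column: baseline N(0, 0.2) + planted
  diagnosis effect (effect_size × noise_sd for cases) + nuisance
  contributions (per-unit effect × raw binary value, or z-scored age) +
  N(0, noise_sd = 0.1) noise, squashed through tanh to stay in (−1, 1)
  without changing rank order; at these scales the map is near-linear and
  standardized effects survive. Baselines are drawn from the ground
  truth's own seed, not the cohort seed, so independently sampled cohorts
  from one ground truth share their baseline profile the way real cohorts
  share biology — this is what makes train-on-one-cohort /
  validate-on-another meaningful.
* **Time series.** Multivariate normal with a requested PSD unit-diagonal
  correlation; motion is white jitter (rotational jitter scaled to the
  same arc-length displacement as the translational jitter) plus
  persistent translation jumps at spike frames; tissue signals are
  low-pass filtered noise — plausible nuisance regressors only.
* **What passing does not show.** No hemodynamics, scanner drift,
  autocorrelated BOLD noise, spatial structure, or realistic FC
  covariance; recovery results demonstrate the algorithmic claim (planted
  effects found, nuisance-linked columns excluded), not performance on
  real fMRI.

## Evaluation statistics

DOR = (TP·TN)/(FN·FP), with the Haldane–Anscombe +0.5 correction and a
flag when a cell is zero. AUC is the rank-based (Mann–Whitney) estimator
with half credit for ties. Binomial tails are exact (regularized
incomplete beta). The permutation test permutes diagnosis labels once per
replicate and reruns the *entire* selection + training pipeline
(conservative); `freeze_features=True` reuses the observed feature sets
and only retrains — faster and explicitly anticonservative. Two-sample KS
uses the exact small-sample distribution below 25 per group, asymptotic
otherwise; Benjamini–Hochberg adjustment across datasets. Clinical-score
prediction uses leave-one-out OLS computed through the exact hat-matrix
deletion identity (algebraically identical to refitting per subject); the
bootstrap null redraws 16 FCs from the never-selected pool, predicts all
domains, and pools the per-repetition maximum correlation.

## Characterization conventions

Laterality: both terminals L → left-intra, both R → right-intra, anything
else (including a medial terminal) → inter-hemispheric — the only rule
consistent with the published 69%/31%/0 split. Network enrichment counts
terminals with duplicates (2 per FC) against the atlas fraction of that
network's regions. The under/over χ² test excludes ties (reported
separately) and the distance t-test uses the pooled variance (df matches
the published t₁₄). The null proportion for the absence-of-left-intra
binomial test is not stated upstream; `laterality_binomial_test` accepts
an explicit null fraction or derives one from the left/right/medial region
counts of the atlas, and labels which was used.

## Problem sizes in the shipped experiments

The acceptance experiment uses 360 subjects × 2,000 FC columns with 15
planted diagnosis FCs (d = 1.0) and 50 site-linked FCs, the full 45-pair
grid and 9×9 folds; null calibration uses two exactly balanced 180-subject
cohorts with 300 FC columns each, pooled into one binomial band. These
sizes keep a full run in the minutes range on a single CPU while leaving
the protocol itself unreduced.

## Known limitations

* No NIfTI/image-space path: inputs are extracted ROI series or FC
  matrices (delimited text); atlas construction and MRI preprocessing are
  out of scope.
* Two-block CCA only; no permutation-based λ selection (the method's point
  is to avoid per-λ tuning by pooling over the grid).
* The ARD variant is Laplace + MacKay; a variational-Bayes alternative is
  an extension point, not implemented.
* Binary diagnosis only.
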