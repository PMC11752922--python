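# Methods

This note records the statistical model behind the synthetic cohort
generator, the architecture and training conventions, the evaluation
protocol, and the design choices made where more than one reasonable
reading existed. It documents what the code does and why; every number
quoted as an outcome here is computed by the test suite or
`scripts/acceptance.py`, not asserted from memory.

## 1. Cohort schema and preprocessing

A cohort is a rectangular table of 16 input features (age, sex, BMI,
lactate, AF, SBP, DBP, MBP, P/F ratio, GCS; VASO, MV, 24-h urine output,
platelets, bilirubin, creatinine) plus the target, ICU LOS in days. Sex,
AF, VASO and MV are 0/1 binaries (yes/male → 1); GCS is an integer score
on 3–15. Validation rejects missing cells outright rather than imputing,
mirroring how the reference cohort was assembled.

Preprocessing:

- **Outlier filtering** removes rows whose LOS falls outside the Tukey
  fences Q1 − 1.5·IQR, Q3 + 1.5·IQR, computed on the whole dataset
  before splitting (the reference pipeline excluded LOS outliers at
  cohort construction). Quartiles use linear interpolation between order
  statistics ("type 7"), the default of mainstream numeric stacks; a
  brute-force quantile oracle pins the convention in the tests. Applying
  the filter before the split technically leaks target-distribution
  information into the test set; this mirrors the original protocol and
  is confined to two scalar bounds.
- **Standardization** z-scores numeric/integer input columns with mean
  and sample SD (n−1). Binaries and the target are never standardized —
  the model regresses raw days so MAE/RMSE read directly in days. By
  default the standardizer is fitted on training rows only and applied
  to validation/test (no leakage); `pooled_standardize` fits on all rows to
  mimic the original single-pass standardization.
- **Splitting** holds out round(0.2·n) rows as a common test set and
  partitions the remainder into k = 4 folds of near-equal size (differ
  by ≤ 1), uniformly at random without stratification, fully determined
  by a seed.

## 2. Synthetic cohort generator

The real cohort is private, so the generator reproduces its published
statistical skeleton: per-feature means, SDs and ranges, binary
prevalences, and each feature's correlation with LOS.

**Construction.** Single-factor Gaussian copula. Draw z0 ~ N(0,1); the
target is F⁻¹_LOS(Φ(z0)). Each feature's latent is
z_i = ρ_i·z0 + √(1−ρ_i²)·ε_i with independent ε_i ~ N(0,1), mapped
through its marginal's probability-integral transform. Features are
therefore conditionally independent given z0, and feature–feature
correlations are implied (corr ≈ ρ_i·ρ_j after attenuation) rather than
matched — the published table does not report them, and the generator
does not pretend to know them.

**Marginal families and calibration.**

- Continuous vitals/labs: truncated normal on the published (min, max);
  the parent's (μ, σ) are found by least squares on the closed-form
  truncated moments so the post-truncation mean/SD hit the published
  values within 0.5 % relative error, then verified by Monte Carlo on
  fresh draws. Heavily skewed labs can push the solution deep into the
  parent's tail (lactate calibrates to μ ≈ −337, σ ≈ 30 — effectively an
  exponential-like decreasing density on (0, 29)), which is handled by
  multi-start optimization and far-tail-safe truncated-normal routines.
- ICU LOS: truncated lognormal on (1.01, 16.47) — the published LOS
  distribution is strongly right-skewed and the post-filter range is
  hard — moment-calibrated the same way via closed-form truncated
  lognormal partial expectations.
- GCS: a plain-normal parent, rounded to integers and clipped to
  [3, 15]. The clipping (not pre-rounding truncation) matters: with
  truncation before rounding the family's dispersion at mean 11.08 caps
  at sd ≈ 3.40, below the published 3.55, whereas edge-clipping lets the
  boundary scores absorb the tails and matches both moments exactly
  (calibrated μ ≈ 11.63, σ ≈ 4.53).
- Binaries: threshold the latent at the prevalence quantile, so the
  expected prevalence is exact by construction.

Two published dispersion targets are infeasible for a truncated normal:
bilirubin (mean 1.31, SD 2.09 on (0.09, 22.58)) and creatinine (2.14,
2.20 on (0.11, 16.60)) have SD > mean − min, beyond the family's
exponential-limit ceiling for a left-edge mean. These two keep their
best-achieved parameters, are flagged uncalibrated, and sit outside all
fidelity checks; their real-world heavy right tails are a documented
simplification. The published urine-output range (max 1,250 below the
mean 1,803.52) is internally inconsistent — presumably a typo — so its
support is widened to (0, mean + 4·SD) and UR is excluded from
calibration targets.

**Correlation calibration.** Marginal transforms attenuate latent
correlations (most visibly for binaries: hitting a realized
point-biserial of 0.43 for MV at prevalence 0.33 needs a latent loading
≈ 0.55). Loadings are calibrated by the fixed-point iteration
ρ_i ← clip(ρ_i + (r_target − r_realized), −0.99, 0.99), with realized
correlations measured on 2×10⁵ fresh samples per iteration, tolerance
0.01, at most 50 iterations (converges in well under 10). Statistically
insignificant published correlations are still calibrated to their point
estimates by default; a flag zeroes them.

**Fidelity, as verified by the acceptance checks:** at n = 2×10⁵,
calibrated moments within 0.5 % relative (LOS mean/SD, GCS mean within
±0.06), prevalences within ±0.5 points, and GCS/MV/PF–LOS correlations
within ±0.02 of the published coefficients.

**Mechanistic mode.** For model testing, features are drawn with zero
loadings and the target is computed from a known formula: intercept +
Σ w_i·x̃_i + Σ w_ij·x̃_i·x̃_j + N(0, noise_sd²), clipped to the LOS
support, with x̃ standardized by the marginal's own target moments. Two
stock settings:

- the *strong-signal* fixture (additive GCS/PF/lactate weights, two
  interactions, noise_sd = 0.5 days) for learnability floors;
- `study_mechanism()` — additive weights proportional to the published
  strongest feature–LOS correlations (GCS, MV, PF, lactate), two
  interactions, noise_sd = 2.7 days (the published RMSE scale) and
  intercept 5.24 days, so the planted signal explains ≈ 0.3–0.4 of the
  target variance and the target SD lands near the published 3.57 days.

What the generator does *not* emulate: feature–feature dependence beyond
the single factor, heavy lab tails (above), time-series structure, and
site effects. Passing tests on synthetic cohorts therefore demonstrate
pipeline and architecture correctness and calibration fidelity — not
clinical performance on real data.

## 3. Model

Input (B, 16) standardized features → batch norm → per-feature affine
embedding into d = 40 dimensional tokens plus a trainable CLS vector at
position 0 (zero-initialized; equivalent to embedding a zero scalar with
a trainable bias) → one encoder block → post-encoder batch norm → fusion
head.

Design choices where the architecture description is open:

- **Tokenizer.** The embedding maps each scalar through its own d-vector
  weight and bias (feature-tokenizer convention), keeping features
  unmixed before attention. The alternative — one dense layer from the
  concatenated 17-vector to 17×d — would entangle features prior to
  attention and defeat the "feature-wise token" reading; a
  `shared_tokenizer` switch exposes a single shared 1→d map instead.
- **Encoder.** Standard multi-head self-attention, 5 heads (d_k = 8),
  softmax(QKᵀ/√d_k)V, concatenated and projected, then a 2-layer FFN
  with ReLU and hidden width 4·d. Residual connections with **post**
  layer-norm wrap both sublayers (pre-vs-post is unstated in the
  description; post-norm is the classic encoder contract). One block by
  default; configurable.
- **Normalization.** Batch norm on the raw input and on the flattened
  encoder output, treating each of the 17·d activations as a channel;
  layer norm only inside the encoder. Running statistics (momentum 0.9,
  eps 1e-5) make evaluation-mode predictions independent of batch
  composition.
- **Head.** The normalized output splits into CLS (global) and the 16
  feature tokens (local); f = Dense(Flatten(f′)) ∈ R^d;
  t_sc = Dense(CLS + f); prediction = Dense_1(t_sc). Modes:
  `both` (default), `global_only` (t_sc from CLS alone), `local_only`
  (from f alone) — zeroing the fusion map reduces `both` to
  `global_only` exactly, which the tests exploit as a sanity identity.
- d = 40 (divisible by 5 heads), no dropout, no positional encodings
  (feature identity lives in the per-position embeddings).

The whole network runs on a ~300-line reverse-mode autodiff engine over
float64 numpy (elementwise ops, batched matmul, reductions, softmax,
layer norm); every primitive's gradient is checked against central
finite differences, and the composed model passes an end-to-end gradient
check. Single-threaded float64 makes training bit-reproducible.

## 4. Training

Adam (β = 0.9/0.999, eps 1e-8), initial learning rate 1e-3, batch size
32, MSE loss on raw-day targets, seeded per-epoch shuffling. The
learning rate follows a staircase: lr = 1e-3 · 0.96^floor(step/10).
"Step" defaults to the **epoch** counter: at ~13 optimizer steps per
epoch for a 417-row training pool, per-optimizer-step decay would shrink
the rate by 0.96^130 ≈ 0.005 within 100 epochs and stall training;
`decay_unit="optimizer_step"` is available for the literal reading.
Stopping: max 300 epochs (package default; smaller in the CLI and test
harness), early stop after 30 epochs without validation-MAE improvement,
best weights restored. Initialization is Glorot-uniform, seeded; biases,
CLS, and BN offsets start at zero.

## 5. Evaluation protocol

R² = 1 − SS_res/SS_tot (negative when worse than the mean predictor),
MAE, RMSE. The RMSE applies the square root to the mean squared error —
the metric's verbal definition — and the suite verifies rmse² = MSE and
rmse ≥ mae.

Cross-validation: the 20 % test set is held out first; each of the 4
folds serves once as validation while the other three train a model;
all 4 models are scored on the common test set; summaries are
across-fold mean ± sample SD. The per-fold validation-vs-test ambiguity
is resolved toward the common test set, matching the protocol's "test
set held out before folding" wording. Per-fold model and shuffle seeds
derive deterministically from the configured seeds plus the fold index.
A mean-predictor baseline (predict the training-pool mean) anchors
sanity checks at R² ≤ 0.

The ablation suite reruns the protocol for the three head modes on
shared splits. On the `study_mechanism()` cohort (n = 2,000, 5 seeds,
30 epochs) the three modes land within ~0.05 days of median test MAE of
one another — inside seed-level noise — with `global_only` marginally
ahead; the fused head's advantage reported on the real cohort does not
re-express on this synthetic family, where either single path already
sits near the attainable optimum (both paths see all tokens through
attention). The corresponding acceptance test asserts the fused-head
ordering and is expected to fail until a harder synthetic family
separates the modes; it is left failing deliberately rather than
weakened.

The correlation report computes Pearson r of each feature against the
target (point-biserial for binaries under 0/1 coding) with two-sided
p-values from the exact t-transform (n−2 df); values below 0.01 print
as "< 0.01".

## 6. Shapley interpretation

Marginal-expectation value function: v(S) = mean model prediction over a
background sample (≤ 64 seeded training rows) with features in S taken
from the explained patient. Exact estimator enumerates all 2^m
coalitions (usable as a slow oracle up to the full 16 features); the
default estimator averages marginal contributions over seeded random
permutations — each permutation telescopes exactly, so efficiency
(base + Σφ = prediction) holds to float precision for both estimators.
Attributions act on raw-day predictions, so φ is in days; the base value
is the background-mean prediction. Explanations default to test-set
patients. Verified properties: linear-model closed form
φ_i = w_i(x_i − mean background_i) to 1e-9, symmetry, dummy-feature
zeroing, and monotone convergence of the sampled estimator to the
oracle over {10, 100, 1000} permutations.

## 7. Problem sizes and numerical conventions

Calibration Monte-Carlo sizes: 2×10⁵ per latent iteration and for
verification (tests calibrate at 5×10⁴ and verify at 2×10⁵); fidelity
cohorts 2×10⁵ rows. Harness experiments use n = 2,000 mechanistic
cohorts at 30 training epochs, and n = 521 copula cohorts for
protocol checks — sizes chosen so the full suite runs on a laptop-class
single CPU in minutes. Degenerate inputs error early and descriptively:
< 4 values for IQR, zero-variance standardization columns, constant
targets in R², empty train/val sets, non-finite losses, n < k+1 splits.
Batch norm in training mode requires ≥ 2 rows per batch; trailing
1-row batches are skipped by the loop.

## 8. Known limitations

- Synthetic fidelity is to published *marginal* and *bivariate-with-
  target* statistics only; joint structure is a modeling assumption.
- Bil/Cr dispersions are unreachable under the chosen family (flagged
  uncalibrated); lactate/Bil tail shapes are simplified.
- The fused-head ablation advantage observed on the real cohort is not
  reproduced on synthetic cohorts (see §5).
- No GPU path, no dropout, no hyperparameter search; the training loop
  is deliberately small and deterministic rather than fast.
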