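# Methods

This note documents the models, numerical choices and assumptions behind
`pepquant`, and what the synthetic-data tests do and do not demonstrate.

## Data model

Intensities are handled as a peptides × runs matrix of log2 ion intensities
with an explicit missingness mask (empty TSV cell / NaN). Missing is never
zero — zero is a valid log2 intensity — and no stage ever imputes: transforms
preserve the mask exactly, and the only operations that change it are
whole-peptide filtering and replicate collapsing. A tuple of state flags
(`raw → log2 → calibrated → drift_corrected → filtered → collapsed`) is
carried with the matrix and each stage refuses input in the wrong state, so
the pipeline order is machine-enforced.

The design table lists one run per row: run order (a permutation of 1..N),
run id, sample id, the three two-level factors (age ed12/ed17, sex M/F,
treatment C/E), block, and a reference-replicate flag. Reference runs are
repeated injections of one biological sample; all share a single sample id.
Group labels (8 = 2×2×2) are always derived from the factors, never stored,
so they cannot drift out of sync.

## Normalization

**Calibration.** The reference run is the per-peptide median over runs,
restricted to peptides observed in *strictly more than* half of all runs (the
strict inequality is deliberate; a peptide observed in exactly 50 % of runs
is excluded). Each run's observed values are regressed on the reference over
their shared peptides (OLS, minimum 3 shared peptides, slope |b| ≥ 1e-6), and
every observed value v in the run is replaced by (v − a)/b. Whether the
original procedure regressed run-on-reference or reference-on-run is not
recoverable; the committed contract is the testable outcome: after
calibration each run re-regresses on the reference with slope 1 and intercept
0 (to 1e-8), and a run that is an exact affine image of the reference is
restored exactly. Re-calibrating against the same reference is the identity.

**Drift correction.** Per peptide, a locally weighted linear regression of
intensity on run order: at each observed run the nearest ⌈span · n_obs⌉
observed runs (span 0.5 by default, interpreted as a fraction of that
peptide's observed runs) enter a weighted least-squares line with tricube
weights w = (1 − (d/h)³)³, h being the largest neighbour distance; no
robustness iterations. These are the classical lowess defaults, pinned by a
per-point weighted-OLS oracle in the tests so the choice is explicit. The
corrected value is observed − fitted + mean(fitted over observed runs).
Adding back the mean of the *fitted* curve (rather than of the raw values)
makes mean preservation exact while still reducing to the textbook behaviour:
a peptide following a pure line c + β·order becomes the constant
c + β·mean(order). Peptides with fewer than 4 observations are left
uncorrected and flagged. Local linear regression only removes drift whose
period is long relative to the window; the sinusoidal-drift test therefore
uses a window of ~1/6 of the drift period.

**Outlier flagging.** Runs whose median observed intensity falls more than k
(default 3) normal-scaled MADs below the median of run medians are flagged —
advisory only; removal is an explicit caller decision, exposed as two drop
points (before normalization, and after PCA inspection) because that is how
outliers are handled in practice. The second historical criterion (visual
detection of increased degradation) has no algorithmic definition and is not
implemented; such runs are handled via the pre-normalization drop list.

**Filtering and collapsing.** A peptide is retained iff every group has at
most one missing run (configurable). Reference replicates are collapsed to a
per-peptide median pseudo-run, present wherever at least one replicate
observed the peptide.

## Multivariate models

Variables (peptides) are mean-centered and by default scaled to unit variance
(ddof 1) — the convention of the chemometric software of the era; a
`scale=False` flag documents the uncertainty. Zero-variance variables are an
error under scaling, named in the message.

**PCA** is computed by SVD of the preprocessed matrix, equivalent to
sequential extraction of variance-maximizing components; per-component sign
is fixed by making the largest-magnitude loading positive. R²X_a is the
component sum of squares over the total; eigenvalues are reported as the
component sum of squares ((n−1) × score variance). Q² uses row-wise K-fold
cross-validation (default 7 folds, deterministic round-robin assignment): per
fold the model is refit on training rows, held-out rows are projected
component by component, and Q²_a = 1 − PRESS_a/SS_{a−1} with SS_{a−1} the
full-fit residual SS after a−1 components; the cumulative Q² is
1 − Π PRESS_a/SS_{a−1}. Row-wise (whole-observation) CV was chosen over
element-wise CV as the simplest defensible reading; fold counts are
configurable.

**Diagnostics.** Hotelling T²_i = Σ_a t²_ia/s²_a with the F-referenced 95 %
tolerance limit A(n−1)/(n−A) · F_{0.95}(A, n−A); DModX_i is the
residual-row distance s_i normalized by the pooled residual scale s0, with
the chi-squared-referenced critical limit sqrt(χ²_{0.95}(p−A)/(p−A)) at
significance 0.05. When the model fits exactly (s0 ≈ 0) the absolute
residual distance (zero) is reported instead of the indeterminate ratio.

**PLS-DA.** The response is the K-column class-indicator matrix, centered;
components come from the iterative two-block NIPALS algorithm (convergence
1e-10 on the score vector or 500 iterations; the weight vector converges to
the dominant eigenvector of X'YY'X), deflating both blocks by the score
rank-1 update. Predicted class is the argmax over predicted dummy columns.
R²Y and Q² are computed on the Y block analogously to PCA. VIP uses the
explained-Y-variance-weighted squared normalized weights; its mean-square
is identically 1, which the tests assert to 1e-10. Jackknife confidence
intervals are the standard-error form: leave-one-observation-out refits give
SE² = (n−1)/n Σ (VIP_i − mean)², interval = point ± t_{0.975, n−1}·SE
(not percentile-based; df = n−1).

**Descriptive tools.** The group-median transform is X_class − X_tot per
peptide (group median minus overall median over the included runs).
Hierarchical clustering is complete-linkage on Euclidean distances (scipy),
applied to rows and/or columns; trees are exported as Newick.

## Factorial differential analysis

The full 2×2×2 fixed-effects model is fit per peptide by least squares on a
±1 sum-to-zero design matrix (high levels ed17, F, E), complete-case over
that peptide's observed runs. Blocks are not modelled (the model is fixed
effects only, by design). Marginal (Type III) SS per term is the residual-SS
increase from deleting that term's column from the full model — verified
against statsmodels' Type III ANOVA on unbalanced toys to 1e-8, and equal to
sequential SS on balanced designs. The overall F tests the full model against
the intercept; its p-values are Benjamini–Hochberg adjusted across peptides
(Benjamini–Yekutieli available). The joint interaction test is the
full-versus-main-effects comparison F, which coincides with the Wald F for
those four coefficients under OLS (asserted against statsmodels'
`compare_f_test`). Fold changes are least-squares-mean differences
(ed17−ed12, F−M, E−C), equal to raw group-mean contrasts on balanced designs.
Least-squares means are averages of predicted cell means and are reported for
main effects significant at the chosen level. Pairwise t-tests between the 8
group means use the model residual variance with df = residual df; by
default only within-factor contrasts (pairs differing in exactly one factor,
12 pairs) are reported, with an all-pairs (28) flag, since the original
choice is not recoverable. Degenerate cases (constant response, zero residual
df, single-level factor) keep their estimates and carry explicit flags
instead of statistics.

## Synthetic data

The generator emulates what the analysis assumes, with defaults mirroring
the study: 8 groups sized 5,5,5,4,4,4,4,5 (36 samples), 5 blocks, 6
reference injections (one opening the sequence, one closing each block), 204
peptides. Per peptide and run:

    value = baseline_p + group effects + slope_r·(baseline_p − mean baseline)
            + intercept_r + drift(order_r) + ε,  ε ~ N(0, noise_sd²)

- baselines ~ N(17, 2²) log2 units (typical ion-trap log2 intensities span
  roughly 12–19);
- effects are level-mean differences; 40 % of peptides carry an age effect
  ~ N(+1.5, 0.8²) (age dominates, mostly up at the older stage), 5 % a sex
  effect ~ N(0, 0.6²), 10 % a treatment effect ~ N(0, 0.6²), 5 % each
  interaction ~ N(0, 0.5²);
- drift is sinusoidal with amplitude 0.5 log2 units (one cycle over the
  sequence; linear and random-spline shapes available), per-run scale
  distortion has slope SD 0.05 and intercept SD 0.3, noise SD 0.5;
- missingness is logistic in the realized intensity:
  p(miss) = floor + (1−floor)·sigmoid(−steepness·(x − midpoint)), defaults
  midpoint 13, steepness 1.5, floor 0.01 — intensity-dependent (MNAR), as
  label-free dropout is; steepness 0 degrades to MCAR, steepness ∞ to a hard
  detection threshold.

Drift amplitude and missingness rates are assumptions, not measurements —
the study did not quantify them. Everything is driven by one seed;
identical seeds give bit-identical output, and ground truth (true effects,
run distortions, dropout probabilities) is returned alongside the matrix.

What passing tests show: the pipeline recovers planted effects without bias,
controls the FDR under the null, removes the distortions it models, and its
oracles (SVD, brute-force LOO, O(n³) linkage, model-comparison SS) agree to
tight tolerances. What they do not show: behaviour under peak-matching
errors, retention-time misalignment, non-Gaussian noise, or drift shapes
outside the configured family — none of which the generator emulates. The
original study's real-data headline numbers depend on raw LC-MS files that
are no longer retrievable and are not reproduced here; the bundled peptide
catalog and run schedule are transcriptions of the published tables (64 of
the 65 catalog rows are recoverable from the available text; the
substance-P row's sequence is restored from the differential-expression
table, and the two printed variants of the GnIH-RP2 sequence are noted in
the catalog comment). Several printed MH+ values differ from theoretical
monoisotopic masses by 0.1–0.8 Da (low-resolution observed masses); only
rows verified to match theory within 0.01 Da serve as mass goldens.

## Problem sizes

Default test and acceptance runs use the study-scale 204 × 42 matrix for
end-to-end checks (a single run completes in a few seconds), 200-peptide /
32-run factorials for the stochastic recovery and null-FDR experiments
(3–50 seeds), and 5–40-point sets for the brute-force oracles — sizes chosen
to make the statistical assertions stable while keeping the whole suite
fast on a single CPU.

## Known limitations

- No imputation, retention-time alignment or peak re-integration; upstream
  peak detection/matching is out of scope and emulated by the generator.
- PCA/PLS-DA require complete rows; peptides with any residual missingness
  after filtering are excluded from the multivariate models (the original
  software tolerated missing values via NIPALS; this implementation trades
  that for exact, testable linear algebra).
- The printed eigenvalues/R²/Q² of the original models are not reproducible
  without the raw data and are not targets.
- Mixed/random-effects variants (block as a random effect) and
  empirical-Bayes variance moderation are deliberately out of scope.
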