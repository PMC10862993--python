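# Methods

## The predictive framework

`cpmkit` implements the two-stage connectome predictive modeling (CPM)
procedure and its vertexwise anatomical analogue (APM). The input is a
subject × feature matrix — Fisher-z connectivity edges unwrapped from the
strict upper triangle of a node × node correlation matrix, or per-vertex
cortical measurements — plus a phenotype table with a bounded integer
outcome score (0–25, modeled on a clinician-rated anxiety scale), age, sex,
optional scanner, and motion summaries.

**Stage one (feature screening).** Each feature is correlated with the
outcome; the two-sided p-value comes from the t transform
t = r·√(df/(1−r²)) with df = n−2. When covariates participate, the
screening statistic is the partial correlation of feature and outcome given
the covariates (both residualized on an intercept plus covariates,
df = n−2−k). Features with p < α (default 0.01) are kept, split by
association sign into disjoint positive and negative masks.

**Stage two (summary regression).** Selected feature values are summed per
subject (one column for positive or negative mode, two for both; optionally
each feature weighted by its training correlation) and the outcome is
regressed on the summaries by OLS. Covariates can be

- ignored (`covariate_role="none"`),
- entered as predictors in both stages (`"predictors"`), or
- treated as nuisance (`"nuisance"`): their coefficients are estimated on
  the training set, outcome and summaries are residualized before the
  stage-two fit, held-out summaries are residualized with coefficients from
  the training set (leave-one-out) or re-estimated from the test set
  (external validation, where many test subjects are available), and the
  nuisance-predicted outcome component is added back so predictions stay on
  the original 0–25 scale. The outcome add-back always uses the
  training-set coefficients, since predicting a new subject cannot use that
  subject's observed outcome. Fitted and evaluated on the same data, this
  scheme coincides with the predictors scheme by the Frisch–Waugh–Lovell
  theorem — a property the test suite asserts to 1e-8.

Evaluation is leave-one-out cross-validation (selection and fitting redone
in every fold; per-fold masks retained so recurrent features can be
tabulated at a fraction threshold, default 50%) or a single external
validation fit. Folds whose selection is empty fall back to a
covariate-only (or intercept-only) model and are flagged. Metrics are MAE,
Pearson r, and the cross-validated R² = 1 − SSE/SST with SST around the
mean of the evaluated observed outcomes — negative whenever predictions are
worse than that mean. 95% intervals resample (observed, predicted) pairs
with replacement (default 1000 replicates); degenerate replicates with a
constant resampled outcome are redrawn (up to 100 attempts) so the
replicate count stays fixed.

A permutation check (`motion_check`) verifies that mean framewise
displacement does not itself predict the outcome: two-tailed p over
Monte-Carlo permutations with the identity included,
p = (1 + #{|r_perm| ≥ |r_obs|})/(n_perm + 1), or an exact proportion over
all n! permutations when feasible. Motion QC excludes a scan when mean
FD > 0.25 mm or more than 50% of frames exceed 0.25 mm; both inequalities
are strict, so boundary values are kept.

## Connectivity features

Full connectivity is pairwise Pearson correlation of node timecourses;
partial connectivity is the correlation of each pair after regressing out
all remaining nodes, computed from the precision matrix
(pr_ab = −P_ab/√(P_aa·P_bb), pseudo-inverse fallback when the covariance is
singular) — algebraically identical to the regression phrasing and far
cheaper. Correlations are clipped to ±(1−1e-12) before z = arctanh(r) so a
numerically perfect correlation stays finite. Edge order is fixed as the
row-major strict upper triangle; a 216-node parcellation (200 cortical +
16 subcortical) yields 23,220 edges. Confound removal is plain
least-squares residualization on an intercept plus the supplied confound
timecourses, with rank checking that names redundant columns.

Surface smoothing for anatomical features is iterated neighbor averaging;
the iteration count k for a requested kernel is calibrated by the diffusion
approximation FWHM ≈ edge_len·√(8·ln2·k/3), a standard coarse equivalence
between repeated local averaging and a Gaussian kernel. The global mean is
restored exactly after smoothing; isolated vertices are left unchanged with
a warning.

## Fingerprinting

Each subject's session vectors are centered and scaled to unit norm, so
cross-session similarity r_ij is a dot product and decomposes per feature
as r_ij = Σ_e φ_ij(e) with φ_ij(e) = x̃ᵢᵇ(e)·x̃ⱼᶠ(e). Identification is
argmax with replacement in both directions; k correct of n is tested
against the upper tail of Binomial(n, 1/n), evaluated via a log-space sum
of log-pmfs so tails far below 1e-300-per-term rounding remain exact.

The chance probability that feature e's self-match contribution for
subject i is exceeded is estimated by the rank statistic

P̂ᵢ(e) = [Σⱼ I(φ_ij(e) ≥ φ_ii(e)) + Σⱼ I(φ_ji(e) ≥ φ_ii(e)) − 1]/(2n−1),

bounded in [1/(2n−1), 1], and Fisher-combined into the differential power
DP(e) = −2·Σᵢ ln P̂ᵢ(e), referred to a χ² distribution with 2n degrees of
freedom. The φ tensor is O(n²·M) and is processed feature-blockwise;
results are independent of the block size (asserted in tests).

**Calibration caveat.** The χ²(2n) reference assumes each P̂ᵢ(e) is
uniform under the null. It is not: φ has product structure
(φ_ij = aᵢ·bⱼ), so the count inside P̂ is the sum of a row-rank and a
column-rank statistic rather than a single uniform rank. Simulation with
no subject-stable component gives E[−2·ln P̂] ≈ 1.81 rather than 2 and a
count variance between the uniform and triangular values, so DP is
stochastically smaller than χ²(2n) and its p-values are conservative
(mean ≈ 0.84 under the null; empirical rejection at α = 0.05 stays below
0.05, which the suite asserts). DP-based feature selection therefore never
over-selects under the null, but its nominal level overstates the true
false-positive rate. The statistic is computed exactly as defined above;
no recalibration is applied.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, not
imaging physics. Feature values are

x[i,s,e] = μ(e) + σ_subject·S[i,e] + σ_session·E[i,s,e]

with μ, S, E standard normal; S is drawn once per subject (the stable
fingerprint shared by both sessions), E independently per session. A
sparse set of signal features drives the post-treatment outcome:

y_post = intercept + β_signal·mean(baseline signal features)
         + β_age·age + β_sex·sex + β_baseline·y_base + N(0, σ_outcome),

rounded and clipped to 0–25. Baseline severity is N(14.6, 2.8) rounded and
clipped (matching a treatment-seeking pediatric sample with a clinical
cut-off of 9), age is uniform on 8–17 years, sex Bernoulli(0.5), and
motion summaries are drawn near FD ≈ 0.11 ± 0.05 mm. Defaults are a
54-subject, 216-node (23,220-edge) cohort with σ_subject = σ_session = 1,
200 signal features (about two orders of magnitude fewer than the feature
count), β_signal = 3, β_age = 0.2, β_sex = 1, β_baseline = 0.5,
σ_outcome = 3 — chosen so outcomes land in a realistic range (post ≈ 9)
and identification succeeds well above chance without being trivial.
A latent-factor timecourse generator (node loadings = common + subject
perturbation, factor scores redrawn per session) feeds the connectivity
pipeline when raw timecourses are wanted.

What the generator does **not** emulate: BOLD autocorrelation, motion
artifacts, scanner or site effects, spatial structure on the cortex, or
feature-feature correlation beyond the shared subject component. Passing
tests therefore demonstrate correctness of the statistical machinery under
the assumed generative structure, not performance on real imaging data.

Test regimes are fixed instantiations of this generator:

- *signal regime* — n = 60, 150 vertex features, 4 signal features,
  β_signal = 5, σ_outcome = 0.5, no covariate effects. A power analysis at
  design time (per-feature correlation ≈ 1/√4 scaled by the outcome
  signal-to-noise) puts per-feature detection power at α = 0.01 near 0.9,
  so mean truth recovery ≥ 80% and held-out r > 0.5 are expected with
  margin. The noiseless variant concentrates the signal in 2 features so
  every fold retains both.
- *null regime* — no signal features, no covariate effects; used for
  chance-identification, permuted-outcome R², and DP calibration checks.

## Numerical choices and edge cases

- OLS via `numpy.linalg.lstsq` with explicit rank checks that name the
  redundant columns; duplicated covariates are an error, not a silent drop.
- Selection masks are disjoint by construction (sign split of one test).
- Argmax ties in identification break toward the lowest index with a
  logged warning (probability ~0 on real-valued data).
- `r_weighted` summaries multiply each selected feature by its
  training-set correlation before summing; weights are per-mask, so a
  positive mask only ever carries positive weights.
- Change-score outcome is post − baseline (negative = improvement).
- Scanner enters as dummy-coded categorical, first level dropped.
- Leave-one-out requires n ≥ 4 (stage one needs 3 training subjects plus
  residual degrees of freedom) and warns below n = 10.
- Bootstrap with n < 5 pairs warns; intervals are indicative only.
- Cohort comparisons use pooled-variance t-tests (Welch available by flag)
  and Yates-corrected 2×2 chi-squared for binary variables — the
  combination that reproduces published descriptive-table statistics from
  their printed counts.

## Problem sizes

Default test and example problem sizes (tens of subjects, 45–150 features,
a few hundred replicates for calibration checks) are chosen so every
statistical assertion has adequate Monte-Carlo resolution while the whole
suite stays interactive; all statistical tests are seeded and
deterministic.

## Known limitations

- Only leave-one-out cross-validation and single-split external validation;
  no k-fold, no nested selection of α.
- The second stage is OLS only; no regularization, which matters when both
  summary columns are retained with few subjects.
- The DP χ²(2n) p-values are conservative (see above).
- Percentile bootstrap only; no BCa or refitting bootstrap, so intervals
  ignore selection uncertainty.
- Surface smoothing is a graph-diffusion approximation, not a geodesic
  Gaussian kernel.
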