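# Methods

## The causal model

`mrpipe` implements two-sample Mendelian randomization (MR) for GWAS
summary statistics.  Each genetic instrument *i* contributes an
estimated effect on the exposure, `beta_exp_i` with standard error
`se_exp_i`, from one study, and an estimated effect on the outcome,
`beta_out_i (se_out_i)`, from a second, non-overlapping study.  Under
the instrumental-variable assumptions (relevance, independence from
confounders, and exclusion restriction) every valid instrument
identifies the same causal effect θ through its Wald ratio

    r_i = beta_out_i / beta_exp_i,     se(r_i) ≈ se_out_i / |beta_exp_i|,

the first-order delta-method SE that ignores uncertainty in
`beta_exp` (the usual convention; second-order terms are out of
scope).  When the outcome is binary and its GWAS is on the log-odds
scale, θ and all confidence bounds are also reported exponentiated as
odds ratios.

## Estimators

* **IVW** (`ivw`): the inverse-variance-weighted mean
  Σ w_i r_i / Σ w_i with w_i = beta_exp_i²/se_out_i².  The default is
  the *fixed-effect* SE (Σ w_i)^(−1/2); a multiplicative
  random-effects variant inflates it by max(1, √(Q/(k−1))).  The
  fixed-effect default is deliberate: the packaged example's published
  interval back-solves to the fixed-effect SE.
* **MR-Egger** (`egger`): weighted least squares of `beta_out` on
  `beta_exp` with a free intercept, weights 1/se_out², after orienting
  every exposure beta positive (the fit is not invariant to allele
  coding).  The intercept estimates the average directional
  pleiotropy; the slope is the pleiotropy-adjusted effect.  The
  residual scale is floored at 1 (never shrunk below homoscedastic)
  and inference is t-based with k−2 df — standard MR-Egger
  conventions.  The fit itself runs through `statsmodels.WLS`.
* **Weighted median** (`weighted_median`): ratios sorted ascending
  (ties broken by snp_id for determinism), standardized cumulative
  weights p_j = (S_j − w_j/2)/S_total, linear interpolation at
  p = 0.5.  Consistent when ≥50% of the total weight comes from valid
  instruments.  SE by seeded parametric bootstrap (both betas redrawn
  from their sampling normals; default 1000 draws).
* **Simple / weighted mode** (`mode_estimate`): argmax over a 512-point
  grid of a normal-kernel density of the ratios, bandwidth
  h = φ·0.9·min(sd, MAD)·k^(−1/5) with normal-consistent MAD and
  φ = 1 by default.  Weights are uniform (simple) or IVW (weighted).
  Mode estimates are bandwidth-convention sensitive; treat them as a
  robustness check, not a precision instrument.  If all ratios
  coincide the common value is returned directly.

## Diagnostics

* **Cochran's Q**: Σ w_i (r_i − β_IVW)², df = k−1, upper-tail χ².
  df is always computed as k−1 from the instruments actually used,
  never trusted from input metadata.
* **Egger intercept test**: intercept significantly different from 0
  (t, k−2 df) indicates directional horizontal pleiotropy; the verdict
  string uses the conventional 0.05 threshold.
* **MR-PRESSO** (`mr_presso`): each SNP's observed residual is
  (beta_out_i − β₋ᵢ·beta_exp_i)²/se_out_i² with β₋ᵢ the leave-one-out
  IVW estimate.  The global test compares the residual sum against
  `n_sim` parametric simulations under the no-pleiotropy model
  (beta_out*ᵢ ~ N(β₋ᵢ·beta_exp_i, se_out_i),
  beta_exp*ᵢ ~ N(beta_exp_i, se_exp_i)); per-SNP outlier p-values come
  from the same simulations, Bonferroni-adjusted by k, and are
  evaluated when the global test is significant.  The distortion test
  compares the shift caused by removing the flagged set with shifts
  from removing random same-sized subsets.  All empirical p-values use
  add-one smoothing, (1 + #exceedances)/(n_sim + 1), so they are never
  exactly zero and are reproducible bit-for-bit given the seed.
  Defaults: n_sim = 1000, outlier α = 0.05 — conventional published
  values; the seed is a mandatory config field wherever simulation is
  involved.
* **Leave-one-out**: fixed-effect IVW excluding each instrument in
  turn, plus the all-SNP row (k+1 rows total); an exclusion is flagged
  when the estimate changes sign or its p-value crosses 0.05 relative
  to the full fit.  Funnel/forest output is emitted as plot-ready
  tables (ratio, SE, precision = 1/SE per SNP plus one row per
  method); funnel symmetry is left to visual assessment, not
  formalized into a test.

## Instrument strength

Two F conventions coexist in applied MR and both are exposed,
explicitly labelled.  Per-SNP F is the squared Wald statistic
(beta/se)² — the convention instrument tables print.  Combined F over
K instruments is (N−K−1)/K · R²/(1−R²) with R² the sum of per-SNP
variance explained 2·EAF·(1−EAF)·beta² (standardized-trait form).  For
panels beyond ~10 SNPs `large_panel_r2` provides the ratio form
2pq·beta²/(2pq·beta² + 2pq·n·se²); it is not used on the packaged
≤10-SNP sets.  F > 10 is the conventional weak-instrument rule.

## Harmonization choices

Alleles are matched exactly, then (for non-palindromic pairs) on the
complementary strand; swapped pairs flip the outcome beta and replace
eaf with 1−eaf.  Palindromic pairs (A/T, C/G) skip complement matching
— it is uninformative for them — and are dropped as ambiguous when the
allele frequency is missing on either side or both frequencies lie
within `eaf_window` of 0.5.  The default window 0.08 (ambiguous when
both EAF ∈ [0.42, 0.58]) is common practice; the packaged datasets
contain no palindromic instruments, so their results do not depend on
it.  LD clumping against a genotype panel is out of scope: instruments
are assumed pre-clumped unless the caller supplies a pairwise r²
matrix, in which case a greedy smallest-p-first pruning applies the
r² ≥ threshold rule within a same-chromosome window (default
r² = 0.01, 10 000 kb).  Records with unknown coordinates are pruned on
r² alone (conservative).

## The packaged example

Two fixture tables ship with the package: five instruments for morning
plasma cortisol (CORNET consortium GWAS, n = 12 597, effects in SD
units of log cortisol) and seven for ADHD (PGC GWAS, n = 55 347,
log-odds scale).  Default instrument p-value thresholds mirror their
sources: 5×10⁻⁶ for the cortisol panel (a relaxed threshold, only one
SNP reaches 5×10⁻⁸), 5×10⁻⁸ for the ADHD panel; both are
config-exposed.  The cortisol→ADHD table carries outcome SEs and
p-values but no outcome betas (its source prints none), so in that
direction the pipeline computes only SE-based quantities — notably the
fixed-effect IVW SE, which needs only beta_exp and se_out — and labels
point estimates unavailable rather than inventing effect signs from
p-values.

## Synthetic data

`generate_two_sample` emulates the statistical structure the
estimators assume: per-SNP EAF ~ Uniform(eaf_range); true exposure
effect sized so 2p(1−p)b² equals `exposure_h2_per_snp` with random
sign; GWAS standard errors via the standardized-trait approximation
(2p(1−p)n)^(−1/2); observed betas drawn from normals around the truth;
true outcome effect θ·b plus an optional pleiotropy term
α ~ N(mean, sd) present with probability `pleiotropy_frac`.  The
pleiotropy term is applied on the *exposure-increasing allele
orientation* (α·sign(b)): directional pleiotropy is defined in the
same orientation in which the Egger intercept is interpreted, so a
positive `pleiotropy_mean` produces a positive expected intercept.
Planted outliers displace the implied ratio by a fixed 10 combined
SEs.  P-values are the exact two-sided normal transform of beta/se.
A single integer seed drives one RNG stream; no global state.

What the generator does **not** model: LD between instruments, sample
overlap between the two studies, winner's curse, and binary-trait
attenuation (outcome betas are treated as exact log-odds).  Passing
calibration tests therefore demonstrate correctness of the estimators
under their own assumptions, not robustness to those real-data
complications.

`paper_like_config` returns conditions matched to the fixtures'
scale: forward k = 5, n_exp = 12 597, per-SNP h² 0.005 (the cortisol
panel's mean per-SNP R² ≈ 0.52%); reverse k = 7, n_exp = 55 347,
per-SNP h² 0.003.

## Numerical and calibration notes

* Empirical p-values never reach 0 (add-one smoothing); analytic
  p-values are clipped to (tiny, 1].
* Degenerate inputs: zero exposure beta → explicit undefined-ratio
  error; all-identical ratios → zero Q, p = 1, and modes return the
  common value; zero bootstrap spread yields SE 0 rather than NaN.
* Bootstrap and PRESSO results are bit-for-bit reproducible given
  (n_boot/n_sim, seed).
* Calibration checks run at the following problem sizes, chosen to
  keep Monte-Carlo error well below the tested margins: PRESSO global
  type-I error over 200 null replicates at n_sim = 300 (3 MC-SE band
  ±0.046 around 0.05); planted-outlier detection over 100 replicates;
  IVW 95% CI coverage over 500 replicates at k = 50 strong
  instruments (3 MC-SE band ±0.029).

## Known limitations

* No Steiger directionality filtering, radial MR, conditional F, or
  multivariable MR.
* Confounder screening of instruments (database lookup) is a manual
  step outside the package.
* The weighted-median and mode SEs depend on the bootstrap model's
  normality assumption; with very weak instruments (beta_exp near 0)
  resampled ratios can be heavy-tailed, inflating those SEs.
* Odds-ratio language for the continuous cortisol outcome follows the
  source studies' reporting convention (exp of an SD-scale effect),
  not a true odds.
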