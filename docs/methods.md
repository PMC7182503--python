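# Methods

## The problem and the model

`summr` implements two-sample Mendelian randomization (MR) from GWAS
summary statistics. A set of J genetic variants (instruments) robustly
associated with an exposure is used to estimate the causal effect θ of
that exposure on an outcome, using only per-SNP association estimates from
two separate GWAS samples: the SNP–exposure effects γ̂ⱼ (SE σ_xj) and the
SNP–outcome effects Γ̂ⱼ (SE σ_yj). Under the instrumental-variable
assumptions each Wald ratio θ̂ⱼ = Γ̂ⱼ/γ̂ⱼ estimates θ; the package's
estimators combine the ratios under different assumptions about horizontal
pleiotropy (direct SNP→outcome effects αⱼ that bypass the exposure, the
main threat to validity):

* **IVW**: θ̂ = Σ wⱼ γ̂ⱼ Γ̂ⱼ / Σ wⱼ γ̂ⱼ², wⱼ = σ_yj⁻² — weighted least
  squares of Γ̂ on γ̂ through the origin. Unbiased only when all
  instruments are valid. The fixed-effect SE (Σ wⱼ γ̂ⱼ²)^(−1/2) is
  multiplied by max(1, √(Q/(J−1))) — a multiplicative random-effects model
  floored at 1, so heterogeneity can widen but never narrow the interval.
  The floor makes the test mildly conservative under the null (observed
  type-I error ≈ 0.025–0.05 at α = 0.05 in the validation runs).
* **MR-Egger**: the same weighted regression with a free intercept. Under
  InSIDE (instrument strength independent of direct effects) the slope is
  a pleiotropy-adjusted estimate of θ and the intercept estimates the
  average direct effect per instrument. SEs use a multiplicative residual
  scale max(1, σ̂) with J−2 degrees of freedom; p-values and CI use
  t(J−2). Requires exposure effects oriented non-negative
  (`orient_positive_exposure`), since the intercept's sign is only
  meaningful relative to the exposure-increasing allele.
* **Weighted median**: the weight-interpolated median of the ratios
  (weights wⱼ = γ̂ⱼ²/σ_yj², Sⱼ = cumsum(wⱼ′) − wⱼ′/2, linear
  interpolation at S = 0.5). Consistent while valid instruments hold
  > 50% of the weight. SE by parametric bootstrap (γ̂ⱼ*, Γ̂ⱼ* redrawn from
  their sampling normals; default 1000 resamples, seeded).
* **Weighted mode**: argmax of a weighted normal-kernel density of the
  ratios, bandwidth h = φ·0.9·min(sd, MAD/0.6745)·J^(−1/5), evaluated on a
  512-point grid spanning the ratio range padded by 3h; ties take the
  smallest grid point; φ defaults to 1. Consistent when the largest
  homogeneous cluster of instruments is valid. SE by the same bootstrap.

Wald-ratio SEs use the first-order delta method (σ_yj/|γ̂ⱼ|). Binary
outcomes are analyzed throughout on the log-odds scale and converted with
`to_odds_ratio` (OR = exp θ̂, CI transformed endpoint-wise).

## Diagnostics and reporting rules

* **Cochran's Q** over the Wald ratios (weights γ̂ⱼ²/σ_yj²) against the
  fixed-effect IVW estimate; df J−1, upper-tail χ².
* **Egger intercept test**: two-sided t(J−2) on the intercept; directional
  pleiotropy is flagged at p < 0.01.
* **PRESSO** (pleiotropy residual sum and outlier test): the observed
  statistic is RSS = Σⱼ σ_yj⁻²(Γ̂ⱼ − θ̂₋ⱼ γ̂ⱼ)² with leave-one-out IVW
  slopes θ̂₋ⱼ; the null distribution is simulated by redrawing
  γ̂ⱼ* ~ N(γ̂ⱼ, σ_xj²) and Γ̂ⱼ* ~ N(θ̂₋ⱼ γ̂ⱼ, σ_yj²), recomputing the
  leave-one-out slopes per replicate. Empirical p-values carry the +1
  correction and are never exactly zero. Per-SNP p-values compare each
  SNP's residual term with its simulated distribution and are
  Bonferroni-scaled by J; SNPs below 0.10 are outliers. **Resolution
  constraint**: the scaled per-SNP p floors at J/(n_sim+1), so n_sim must
  exceed ~J/α for outliers to be detectable at all (defaults n_sim = 1000,
  J ≈ 50, floor ≈ 0.05). Minimum J = 4. The distortion test (outlier-
  corrected IVW vs. random same-size subsets) is computed but optional in
  reporting.
* **Steiger directionality**: per-SNP variance explained
  r² = t²/(t² + n − 2) summed per side; the hypothesized direction is
  supported when R²_exposure > R²_outcome, with a Fisher-z comparison
  using the *median* per-SNP sample size per side (per-SNP n may vary but
  the z denominator needs one number). For binary outcomes r² is computed
  on the observed log-odds scale with no liability correction, and the
  result is flagged accordingly.

The pipeline runs: harmonize → orient → estimate (4 methods) → diagnose →
remove PRESSO outliers (one round, no iteration) → re-estimate and
recompute Q and the Egger intercept. The PRESSO global p retained in the
flags refers to the raw instrument set: outlier removal corrects the
estimate but does not erase the evidence that pleiotropy was present.
Reporting flags: IVW p < 0.01; sign concordance across IVW/median/mode
(Egger's sign recorded but non-blocking, since a wide, non-significant
Egger estimate of opposite sign should not veto concordant robust
estimators); overlapping 95% CIs between IVW and median/mode as a
non-blocking magnitude sub-flag; PRESSO global and Egger intercept
p > 0.01; Steiger p < 0.01 with the right direction; and a
Bonferroni-corrected IVW threshold α/m with caller-supplied m (e.g. 20 for
a family of UK-Biobank outcomes, 1 for a single dependence outcome;
0.05/20 = 0.0025). When J < 4 PRESSO cannot run and the horizontal-
pleiotropy flag is `None` rather than a silent pass.

## Harmonization

Effects are aligned to the exposure's effect allele. Non-palindromic SNPs
are resolved by exact match, swap (negate Γ̂, mirror the frequency),
strand complement, or complement+swap; irreconcilable allele sets get
status `removed_incompatible_alleles`; SNPs absent from the outcome get
`removed_missing`. Palindromic SNPs (A/T, G/C) carry no strand information
in their labels and are resolved from allele frequencies: labels are first
aligned assuming the same strand, then a disagreement in frequency side
(< 0.5 vs > 0.5) flips the orientation. When either frequency is missing
or falls inside the intermediate window **[0.42, 0.58]** the SNP is
removed (`removed_palindromic_intermediate`): the window is a common
convention in summary-data MR tooling and is configurable; removing
missing-frequency palindromes is the conservative choice. Harmonization is
idempotent on aligned data and never changes Wald ratios (both betas flip
together).

## Instrument construction

Selection keeps SNPs with exposure p < 5×10⁻⁸ (configurable). Clumping is
greedy: repeatedly keep the smallest-p remaining SNP (ties broken by
lexicographic snp_id for deterministic reruns) and discard remaining SNPs
with r² > 0.001 to it within ±10,000 kb on the same chromosome; when
positions are absent the window is ignored (LD-only clumping), and SNPs
missing from the LD matrix are kept with a warning — the permissive
behavior is explicit because real clumping runs against an external
reference panel this package does not ship. Proxy substitution replaces an
instrument missing from the outcome data by its highest-r² proxy with
r² ≥ 0.8 ("high LD" quantified as a configurable default). Secondary-trait
filtering removes instruments associated with, e.g., household income at
α/J (0.05/53 ≈ 0.00094). `overlap_fraction` reports shared-cohort overlap
relative to the larger study (11,096/293,723 ≈ 3.8%), the quantity
relevant to weak-instrument bias from overlapping samples.

## The synthetic-data generator

`simulate_two_sample` emulates exactly the data structure the method
consumes — paired summary statistics with known truth — not individual-
level genotypes. Per SNP: eaf ~ U(0.1, 0.9); γⱼ ~ N(0, γ_sd²);
αⱼ = 0 with probability 1−frac, else N(μ_α, σ_α²) applied on the
*observed* exposure-increasing allele (the orientation in which published
instrument sets report effects; planting on the true-γ orientation would
let sign-flips of weak instruments contaminate the Egger intercept
estimand); Γⱼ = θγⱼ + αⱼ; sampling SEs follow the standardized-trait
approximation σ = 1/√(2p(1−p)n) and observed effects add the matching
normal noise. Binary outcomes reuse the same machinery on the log-odds
scale. Encoding corruptions (swaps, strand flips, palindromes planted with
eaf ∈ (0.44, 0.56)) are applied to the outcome table with the truth
recorded, so harmonization can be tested for *exact* recovery. One PCG64
stream per SNP, seeded (root_seed, snp_index), makes studies exactly
reproducible and extensible without perturbing earlier draws.

Frozen scenario conditions (J = 50, n = 100,000 per side, θ = 0.2 or 0):

| scenario | pleiotropy |
|---|---|
| `null` / `causal` | none |
| `balanced_pleiotropy` | 30% of SNPs, αⱼ ~ N(0, 0.01²) |
| `directional_pleiotropy` | 30% of SNPs, αⱼ ~ N(0.02, 0.01²) |
| `single_outlier` | one SNP with α = 10·σ_y |
| `reverse_causal` | none; causal roles swapped |

`gamma_sd = 0.2` puts the instruments in a deliberately strong regime
(mean F ≈ 1600, total exposure R² ≈ 0.8 — far stronger than real
polygenic instruments). This is a validation-suite design choice: it makes
weak-instrument attenuation of IVW (≈ θσ_x²/γ_sd² ≈ 1×10⁻⁴) negligible at
the Monte-Carlo resolution of the recovery checks, so those checks test
estimator correctness, not weak-instrument behavior. Consequences for
interpretation: passing tests demonstrate correct implementation and
calibration under ideal instrument strength; they say nothing about
weak-instrument bias, winner's curse in instrument selection, LD between
instruments, or sample overlap, none of which the generator models.

Under `directional_pleiotropy` the Egger intercept estimates the average
direct effect per instrument, frac·μ_α = 0.006 (not μ_α itself); the
validation suite asserts exactly that, and recovers μ_α = 0.02 in a
separate check with frac = 1.

## Numerical and degenerate-input choices

* 95% CIs use the exact normal quantile 1.95996 (t(J−2) for Egger).
* Two-sided p-values are floored at 1e-300 in the generator so serialized
  tables round-trip through the (0, 1] validity check.
* Zero exposure effects are excluded from ratio-based methods with a
  warning (strict |γ̂| > 0; continuous noise never produces exact zeros).
* All-equal ratios: Q = 0, random-effects scale 1, mode bandwidth 0 →
  the common ratio is returned directly.
* Bootstrap and simulation p-values are exactly reproducible given
  (seed, n_boot/n_sim); empirical p-values use the +1 correction.
* Tables serialize as TSV with 12 significant digits (round-trips preserve
  estimates beyond reporting precision); row-level validation drops and
  counts invalid rows per reason (rows_read = rows_kept + Σ dropped).
* Minimum instruments: 2 (IVW, Q), 3 (Egger, median, mode, leave-one-out,
  pipeline), 4 (PRESSO).

## Design notes

* The package is a library (importable API + `examples/` scripts), not a
  shell tool: like its R-ecosystem counterparts it is driven from analysis
  code, so the functions are the interface and no console entry point is
  installed.
* `statsmodels` is used in the test suite as an independent oracle for the
  weighted regressions; the estimators themselves are closed-form
  numpy/scipy implementations, so the dual-route check stays meaningful.
* One round of outlier removal (no iteration until clean): matches the
  reporting convention of presenting "outlier-corrected" estimates without
  an iteration count.
* Problem sizes in the validation suite (500 replicates for recovery and
  intercept calibration, 1000 for type-I error, 200 for detection and
  directionality rates, 100 for harmonization recovery) were chosen so
  Monte-Carlo error is small relative to the assertions' bands.

## Known limitations

* No LD computation from genotypes and no reference-panel handling; the
  LD matrix is an input.
* No weak-instrument diagnostics (I²_GX), no MR-RAPS/multivariable MR, no
  liability-scale correction for binary-outcome Steiger r².
* The generator draws independent instruments; clumping correctness is
  therefore tested against explicit LD matrices, not emergent LD.
* Real GWAS inputs require a column map; no automatic header inference.
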