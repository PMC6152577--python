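# Methods

## Model

Two-sample MR treats each instrument j as a natural experiment. With
SNP-exposure association γⱼ (standard error σ_γⱼ) from one GWAS and
SNP-outcome association Γⱼ (σ_Γⱼ) from an independent GWAS, a valid
instrument satisfies Γⱼ = θγⱼ, so the Wald ratio Γⱼ/γⱼ estimates the causal
effect θ. Violations enter as horizontal pleiotropy αⱼ:

    Γⱼ = θ·γⱼ + αⱼ + εⱼ,   εⱼ ~ N(0, σ_Γⱼ²)

The three estimators make different assumptions about the αⱼ:

- **IVW** assumes αⱼ = 0 for all j. It is the inverse-variance-weighted
  mean of the Wald ratios with weights γⱼ²/σ_Γⱼ², identical to weighted
  least squares of Γ on γ through the origin with weights 1/σ_Γⱼ². The
  fixed-effect standard error is (Σγⱼ²/σ_Γⱼ²)^(-1/2); an optional
  multiplicative random-effects variant inflates it by √(Q/df) when
  Cochran's Q exceeds its degrees of freedom (off by default — both are
  exposed because consortium reports rarely state which was used).
- **MR-Egger** frees the intercept: consistent for θ when the αⱼ are
  independent of the γⱼ (InSIDE), even if every instrument is pleiotropic.
  The intercept estimates the mean directional pleiotropy. Instruments are
  first oriented so all γⱼ ≥ 0 (the regression is not invariant to the
  arbitrary effect-allele sign; Wald ratios, IVW and Q are unaffected by
  this orientation, which the test suite verifies numerically). SEs use the
  fixed-effect WLS covariance (XᵀWX)⁻¹, mirroring the IVW default; a
  dispersion inflation √(max(1, Q_e/(J−2))) and a t(J−2) inference option
  exist but are off by default.
- **Weighted median** orders the Wald ratios βⱼ ascending with weights
  wⱼ = γⱼ²/σ_Γⱼ², places βⱼ at percentile pⱼ = 100(Sⱼ − wⱼ/2)/S_total
  (Sⱼ the running weight sum) and interpolates linearly at the 50th
  percentile. It is consistent when valid instruments carry at least half
  the total weight. Its SE comes from a parametric bootstrap resampling
  Γⱼ ~ N(Γⱼ, σ_Γⱼ²) and γⱼ ~ N(γⱼ, σ_γⱼ²) (default 1000 replicates, seeded
  — the one place exposure-side uncertainty enters).

Heterogeneity: Q = Σ(Γⱼ − β̂γⱼ)²/σ_Γⱼ² from the fixed-effect IVW fit, df =
J − 1, and I² = max(0, (Q − df)/Q)·100. A single instrument has Q = 0 by
construction. Wald-ratio SEs use the first-order delta method σ_Γ/|γ|,
ignoring exposure uncertainty — standard practice; the induced CI
undercoverage is negligible at the operating point below (the γⱼ/σ_γⱼ
ratios are ≈ 9, and simulation coverage stays within [93%, 97%]).

All CIs and p-values are normal-theory (estimate ± 1.96·SE; two-sided Φ),
chosen for cross-method consistency. Minimum instrument counts: 1 for IVW,
3 for MR-Egger and the weighted median (a two-parameter weighted fit needs
a residual degree of freedom); with 1–2 surviving instruments the pipeline
reports IVW only, with an explicit notice. Binary outcomes are analyzed on
the log-odds scale and reported as odds ratios by exponentiating the point
estimate and CI bounds; SE and p stay on the log scale.

## Instrument selection and proxies

Selection keeps SNPs with p strictly below the threshold (defaults follow
common practice: 5×10⁻⁸ genome-wide, 5×10⁻⁵ suggestive), preserving input
order; LD pruning is assumed done upstream by the source GWAS ("independent
SNPs"). An instrument absent from the outcome GWAS is replaced by its
highest-r² proxy with r² ≥ 0.9 present in the outcome table (ties: smallest
distance, then lexicographic ID, for deterministic output); the proxy
carries the instrument's exposure statistics under its own ID. Allele
correspondence between query and proxy is **not** remapped — proxy tables
do not reliably carry phased allele pairings — so a proxy whose outcome
record is reported on the opposite allele is handled (or dropped) by the
downstream harmonization step like any other variant. Instruments with no
qualifying proxy are dropped and logged, never fatal.

## Harmonization

The exposure dataset is the reference frame and is never modified.
Non-palindromic variants are resolved from allele labels alone: identical
pair → unchanged; swapped pair → Γ sign-flipped (and outcome EAF
complemented); complementary pair → strand-flipped and re-compared.
Palindromic variants (A/T, C/G) are label-uninformative — a strand flip
reproduces the swapped labels — so orientation uses allele frequency
directly: both EAFs on the same side of 0.5 means both GWAS measured the
same physical allele; opposite sides flip the sign. When either EAF is
missing or inside the ambiguous window (0.42, 0.58) (half-width 0.08,
common two-sample MR practice), the SNP is dropped under the default
policy; a policy switch instead aligns by labels assuming a shared strand,
since the original analysis's palindrome handling is typically unstated.
Irreconcilable allele sets drop with reason `allele_mismatch`. The
accounting identity `selected = analyzed + dropped(proxy stage) +
dropped(harmonization)` holds for every run; proxied instruments are
analyzed and counted separately.

## Power

Analytic post-hoc power follows the normal-approximation non-centrality
scheme of the standard online MR calculators. The IVW SE is approximately
1/√(n·R²) (continuous outcome) or 1/√(n·R²·K(1−K)) (binary outcome on the
log-odds scale, K the case fraction), giving

    power = Φ( √(n·R²·[K(1−K)]) · |b| − z₀.₉₇₅ )

with b the causal beta or log odds ratio. At b = 0 this returns exactly
α/2 (one-sided accounting of a two-sided test). For the motivating designs:
n = 74,053, R² = 1%, β = 0.1 gives 0.777 → 78%, matching the published 77%
to rounding. For n = 74,053, R² = 2%, K = 28%, OR = 1.2 the formula gives
0.883 → 88%, whereas 73% was published for that design; no standard
variant of the normal-approximation formula we are aware of reproduces 73%
from those inputs (scaling the non-centrality by K(1−K) instead of its
square root gives 29%, farther still), and we report the formula's value
rather than tune constants toward the published figure.

## Synthetic data generator

`simulate_pair` draws true effects γⱼ ~ N(0.06, 0.015²), observed exposure
betas γⱼ + N(0, σ_γ²), pleiotropy αⱼ = μ_α + σ_α·z (+ c·γⱼ under deliberate
InSIDE violation) on a configurable invalid fraction, and outcome betas
θγⱼ + αⱼ + N(0, σ_Γ²); p-values are recomputed from the observed betas and
SEs, and are uniform under the null (KS-checked). Defaults emulate a
consortium-scale externalizing-on-smoking design: J = 14 instruments
jointly explaining ≈ 2% of exposure variance against an exposure GWAS of
n ≈ 55k (σ_γ = 0.0066 ≈ 1/√(2p̄q̄·n) at p̄ ≈ 0.3) and a binary outcome GWAS
of n ≈ 74k with 28% cases (σ_Γ = 0.0126 on the log-odds scale). EAFs are
uniform on (0.05, 0.95). A configurable fraction of variants receives a
consistent palindromic allele pair at generation time (palindromicity is a
property of the variant, not of one dataset), and `corrupt_alleles`
re-expresses a fraction of outcome records under a swapped or
strand-flipped reading — both effect-preserving, so a correct harmonization
pass inverts every corruption except frequency-ambiguous palindromes. In
the noise-free limit (σ = 0) stored SEs are floored at 1e-12 and p-values
at 1e-300 so record invariants hold while betas stay exact.

What the generator does **not** emulate: LD between instruments (beyond the
proxy-table abstraction), winner's-curse inflation of selected exposure
effects, sample overlap between the two GWAS, allele-frequency differences
between cohorts, and non-normal effect distributions. Passing tests
therefore certify the estimators and the harmonization algebra at the
stated operating point, not robustness to those real-data features.

## Validation design

The simulation studies (in `tests/test_acceptance.py`) use 1000 replicates
at J = 15 instruments, a scale at which each study runs in seconds:
parameter recovery and CI coverage at θ = 0.2; type-I error at θ = 0; the
directional-pleiotropy study uses μ_α = 0.05, σ_α = 0.01 on 100% invalid
instruments under InSIDE with a **null** causal effect — the canonical
demonstration where IVW reports a large spurious effect while the Egger
intercept is an unbiased estimate of μ_α (with θ ≠ 0, exposure measurement
noise attenuates the Egger slope and leaks θ(1−λ)γ̄ into the intercept — a
known property of MR-Egger, not an implementation artifact); the
majority-valid study uses 40% invalid instruments at θ = 0.2, where the
weighted median's bias is far below IVW's. Estimator point estimates are
cross-checked against statsmodels WLS fits and an independently coded
cumulative-weight interpolation to ≥ 10 significant digits on 100 random
datasets.

## Limitations

- Published headline estimates of the motivating analyses (e.g. an ADHD →
  initiation OR_IVW of 1.23) cannot be recomputed here: they require the
  non-public per-SNP outcome associations. Validation is property-based.
- No MR-PRESSO, mode-based, multivariable or Steiger-filtered variants.
- Proxy substitution assumes the proxy tags the query's effect direction;
  with r² ≥ 0.9 this is usually but not always true.
- Normal-theory inference is anti-conservative at very small J; the t
  option for MR-Egger mitigates this but is off by default.
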