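# Methods

## Model and assumptions

Two-sample Mendelian randomization treats SNPs as instrumental variables
for an exposure. Validity requires, per SNP: association with the exposure
(relevance), no association with confounders of the exposure–outcome
relationship (independence), and no effect on the outcome except through
the exposure (exclusion restriction). The exposure here is a standardized
quantitative trait (natural-log 25(OH)D, SD = 1); the outcome is binary,
so all causal effects are log odds ratios per unit exposure. The two
studies are assumed non-overlapping (overlap biases estimates toward the
observational association) and drawn from comparable populations, checked
loosely via effect-allele-frequency agreement.

Everything operates on summary statistics only. Per-SNP effects are taken
as independent across SNPs (inputs are assumed LD-clumped; the package
performs no clumping, which needs an external LD reference).

## Harmonization policy

Outcome records are aligned to the exposure study's effect allele by
letter matching, allowing allele-order swap (negate beta, complement EAF)
and strand complementation. Palindromic SNPs (A/T, C/G) are oriented by
EAF agreement and require both EAFs farther than `palindromic_maf_limit`
(default 0.08, i.e. outside [0.42, 0.58]) from 0.5; otherwise they are
dropped with a logged reason. Harmonized pairs whose EAFs differ by more
than `eaf_tolerance` (default 0.2) are kept but flagged and warned about,
not dropped — the frequencies in two well-matched European-ancestry
meta-GWAS rarely disagree that much, so a flag usually indicates a
mismapped variant worth inspecting. These thresholds are conventional
choices; the defaults matter only for borderline palindromic SNPs. A
zero exposure beta drops the SNP (no Wald ratio exists) rather than
aborting a batch run.

## Estimators: numerical conventions

- Wald ratio SEs are first-order (`se_out/|beta_exp|`) throughout; the
  second-order delta-method term is available on `wald_ratio` but off by
  default. With every instrument at F > 10 the difference is negligible,
  and first-order SEs are the convention the published two-sample MR
  toolchain uses.
- IVW is computed in closed form; a weighted regression through the
  origin is kept as an independent oracle in the tests (agreement 1e-10).
  Random-effects is multiplicative with the scale floored at 1, so
  under-dispersion can never make the random-effects interval *narrower*
  than the fixed-effect one. IVW p-values use the normal reference.
- MR-Egger orients all SNPs to positive exposure beta, fits WLS with
  weights 1/se_out², floors the residual scale at 1, and uses t(L−2) for
  p-values. All 95% CIs, including Egger's, use the normal 1.96 quantile;
  only p-values switch to t. This asymmetry mirrors common reporting
  practice for these methods.
- The median family sorts Wald ratios (stable sort; ties broken by input
  order), builds standardized cumulative weight positions
  p_j = (cum_j − w_j/2)/Σw, and interpolates linearly at p = 0.5,
  clamping to the end ratios if 0.5 falls outside [p_1, p_L]. Weights are
  beta_exp²/se_out² (the inverse Wald-ratio variance) or 1/L for the
  simple median. The penalized variant multiplies each weight by
  min(1, 20·q_j), q_j the upper-tail χ²(1) probability of the SNP's
  heterogeneity contribution about the unpenalized weighted median; the
  factor 20 leaves weights untouched unless a SNP's one-degree Q
  contribution is individually significant below p = 0.05.
- Median SEs come from a parametric bootstrap (default n_boot = 1000):
  betas in both studies redrawn from normal(beta, se), weights and
  penalties recomputed per replicate, SE = SD of the replicate estimates.
  The seed is mandatory. Bootstrapping parameters rather than resampling
  SNPs is the standard choice for these estimators and is stable at
  small L.

## Diagnostics

Cochran's Q uses ratio-scale weights beta_exp²/se_out² about the
fixed-effect IVW estimate by default; its per-SNP contributions sum to Q
exactly and feed the random-effects scale.

The pleiotropy residual-sum-of-squares test computes, per SNP, the
leave-one-out IVW slope b₋ⱼ and standardized residual
r_j = (beta_out,j − b₋ⱼ·beta_exp,j)/se_out,j; the observed statistic is
Σr_j². The null distribution redraws beta_exp* from
normal(beta_exp, se_exp) and beta_out* from normal(b₋ⱼ·beta_exp*, se_out)
and recomputes the statistic identically (default n_sim = 5000, floor
100). The global p uses the add-one empirical formula
(1 + #{RSS* ≥ RSS_obs})/(n_sim + 1), never exactly zero. Per-SNP outlier
p-values are the empirical tails of r_j², Bonferroni-multiplied by L and
flagged at 0.05. At n_sim = 5000 the Monte-Carlo SE of a global p near
0.3 is about 0.007. When outliers are found the report directs the user
to remove them and re-run; an automatic outlier-corrected ("distortion")
comparison is not implemented.

## Power

The binary-outcome approximation power = Φ(|ln OR|·√(N·R²·K(1−K)) −
z_{1−α/2}) with case fraction K is the single supported model; the
detectable OR at target power inverts it in closed form, making the two
operations exact inverses. The second tail of the two-sided test is
omitted; it contributes below 1e-5 power anywhere near conventional
operating points, and omitting it keeps the inversion exact. At the null
(OR = 1) the formula therefore returns α/2. R² is always an explicit
input: for the packaged study the six instruments' per-SNP R² sum to
0.464%, while the published power statement uses 2.84%; the package never
substitutes one for the other.

## Synthetic-data generator

The generator emulates the assumed causal structure at summary level:
EAFs uniform on `eaf_range` (default 0.1–0.9), per-SNP exposure R²
uniform on `r2_range` (default 0.02%–0.32%, the span of the packaged
instruments), exposure effects ±√(R²/2p(1−p)) with random sign, analytic
SEs 1/√(2p(1−p)·N_exp) and 1/√(2p(1−p)·N_out·K(1−K)), observed betas =
truth + normal noise at those SEs. Default study sizes (N_exp 79,366;
N_out 1,030,836; K 0.0588) match the packaged study. Direct (pleiotropic)
effects α_j ~ normal(pleiotropy_mean, pleiotropy_sd²) are applied
relative to the exposure-raising allele, so a non-zero mean is genuinely
*directional* and recoverable by the Egger intercept regardless of how
alleles were coded. `scramble_alleles` randomly swaps allele order and/or
strand-relabels outcome records, exercising harmonization; allele pairs
are non-palindromic by default (`allow_palindromic` opts in) so the
scramble→harmonize round-trip is exact rather than subject to EAF-based
drops.

What the generator does **not** emulate: LD between instruments, weak or
winner's-curse-biased instruments, population stratification, sample
overlap, EAF drift between studies, or non-linear exposure–outcome
relationships. Tests passing on this generator therefore validate the
estimators' arithmetic and first-order statistical calibration, not
robustness to those real-data pathologies.

## Problem sizes used in the shipped tests

Calibration tests use 50-SNP scenarios with 1000 replicates for type-I
error, 500 for effect recovery and 200 for pleiotropy-intercept recovery;
the pleiotropy simulation uses n_sim = 5000 and the median bootstrap
n_boot = 1000 on the six-SNP set. These sizes give Monte-Carlo error
comfortably inside the asserted tolerances while keeping the whole suite
under a minute.

## Known limitations

- No LD clumping or proxy-SNP lookup; inputs must be independent SNPs.
- Biallelic SNPs only; indels and multi-allelic sites are rejected.
- The published per-SNP F statistics for two of the six packaged
  instruments (rs10745742, rs8018720) are not reproducible from their own
  printed R² and N under the stated formula; the package reports the
  formula value (8.5 for rs8018720, below the conventional F > 10 bar)
  rather than the printed one.
- Mode-based estimators, multivariable MR, Steiger filtering and radial
  MR are out of scope.
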