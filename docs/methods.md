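# Methods

This note documents the statistical model behind `mr2s`, the defaults and
the reasoning behind them, what the synthetic generator does and does not
emulate, and the numerical choices that matter for reproducibility.

## The two-sample MR model

Summary statistics from two non-overlapping studies provide, per SNP j,
the exposure association γ̂ⱼ ~ N(γⱼ, σ²_Xj) and the outcome association
Γ̂ⱼ ~ N(θγⱼ + αⱼ, σ²_Yj), both on the log-odds scale. θ is the causal
effect of interest; αⱼ is a direct (pleiotropic) effect that violates the
exclusion restriction when nonzero. All estimators consume a harmonized
set — per-SNP (γ̂ⱼ, σ_Xj, Γ̂ⱼ, σ_Yj) expressed for a common effect
allele — and all p-values are two-sided from the normal (estimates) or
chi-square (Q statistics); the 95 % multiplier is fixed at 1.959964.
Because the inputs are case/control GWAS, the package standardizes on
log-OR betas throughout; odds-ratio columns are exponentiated transforms.

## Instrument selection

Selection keeps SNPs with p strictly below 5 × 10⁻⁸ (strict inequality:
a SNP at exactly the threshold is excluded), then clumps greedily: the
smallest-p remaining SNP becomes an index, and every remaining SNP on the
same chromosome within 1000 kb with r² ≥ 0.01 against it is discarded.
Ties in p break by rsid, so the output is independent of input row order.
LD is an explicit input (three-column TSV); pairs absent from it are
treated as unlinked, since no reference panel is bundled. Per-SNP
instrument strength is F = (β/σ)², the squared Wald z — the standard
summary-data approximation — with F ≤ 10 flagged as weak. Fewer than
`min_instruments` (default 3) survivors is an error, not a degraded
analysis.

## Harmonization

Outcome records are re-expressed for the exposure's effect allele by
swapping allele labels (negating the outcome beta and complementing its
EAF), complementing the strand (A↔T, C↔G), or both. Palindromic SNPs
(A/T, C/G) are strand-ambiguous and are oriented by minor/major-allele
agreement between the two studies; when the effect-allele frequency is
inside the intermediate band — default [0.42, 0.58], configurable,
symmetric about 0.5 — or missing in either study, the SNP is excluded as
unresolvable. Palindromes with informative frequencies are kept and
frequency-aligned rather than dropped. One uniform rule is applied to all
exposures. Instruments absent from the outcome are excluded with their own
reason; no proxy-SNP search is attempted. The accounting is exact and
asserted at run time: pairs plus exclusions partition the instrument list.

## Estimators

**IVW.** Weighted mean of Wald ratios with first-order weights
wⱼ = γ̂ⱼ²/σ²_Yj (exposure-side noise ignored in the weights), equivalent
to weighted zero-intercept regression of Γ̂ on γ̂. The SE is
√(1/Σwⱼ) · max(1, √(Q/(J−1))) — multiplicative random effects, floored at
1 so homogeneous data cannot deflate the fixed-effect SE. IVW on a single
pair is defined as the Wald ratio (SE σ_Yj/|γ̂ⱼ|, first order).

**MR-Egger.** Pairs are oriented so γ̂ⱼ ≥ 0 (both signs flipped
otherwise), then weighted least squares with free intercept and weights
1/σ²_Yj (via statsmodels WLS). Slope and intercept SEs carry the
analogous inflation max(1, √(Q′/(J−2))) from the regression's residual
Cochran statistic. The intercept test is the directional-pleiotropy
diagnostic.

**Weighted median.** Ratio estimates sorted ascending with normalized
inverse-variance weights; the estimate interpolates the piecewise-linear
cumulative-midpoint curve sⱼ = Σ_{k≤j}w_k − wⱼ/2 at 0.5 (clamped at the
extremes). The SE is a parametric bootstrap — γ̂ⱼ, Γ̂ⱼ resampled from
normal(observed, SE), 1000 draws by default, explicit seed — because no
closed form is standard.

**MR.RAPS.** With standardized residuals
tⱼ(θ, τ²) = (Γ̂ⱼ − θγ̂ⱼ)/√(σ²_Yj + θ²σ²_Xj + τ²), θ solves the robust
profile score Σⱼ ψ(tⱼ)(γ̂ⱼ/sⱼ + tⱼθσ²_Xj/s²ⱼ) = 0 and the overdispersion
τ² ≥ 0 solves Σⱼ[ψ(tⱼ)tⱼ − E ψ(Z)Z] = 0 (Z standard normal; the constant
is 2Φ(c)−1 for the Huber ψ). Defaults are Huber influence with c = 1.345
and overdispersion on; `l2` without overdispersion recovers the plain
profile likelihood and is used in oracle tests, where it agrees with IVW
and the Egger slope to 10⁻⁶ on noiseless collinear data. The two
equations are solved by alternating bracketed Brent root-finding from the
IVW start; non-convergence raises with diagnostics rather than returning
a value. The SE is the sandwich estimate √B/|A| (B the summed squared
score contributions, A the numerical score derivative). Because the score
models exposure-side noise explicitly, RAPS shows less regression-dilution
bias than IVW when instruments are weak (mean F ≈ 15), which the test
suite verifies by direct Monte-Carlo comparison.

**MR-PRESSO.** The observed residual sum of squares is
Σⱼ wⱼ(Γ̂ⱼ − θ̂₋ⱼγ̂ⱼ)² with leave-one-out IVW predictions θ̂₋ⱼ
(fixed-effect weights inside PRESSO, for speed and determinism). The null
distribution comes from parametric simulation — γ*ⱼ ~ N(γ̂ⱼ, σ_Xj),
Γ*ⱼ ~ N(θ̂₋ⱼγ̂ⱼ, σ_Yj), 1000 draws by default — and empirical p-values
use the add-one rule, so the attainable floor is 1/(n_sim+1). Per-SNP
outlier p-values are Bonferroni-adjusted by J and flagged below 0.05;
note the floor means n_sim must exceed J/0.05 for any SNP to be
flaggable. The distortion test compares (θ̂_raw − θ̂_corr)/θ̂_corr against
random same-sized removals. Global and outlier tests share one simulation
set inside `run_presso`; all three tests are deterministic given the seed.

## Meta-analysis

DerSimonian–Laird was chosen as "the" random-effects model because it is
the default moment estimator in the standard meta-analysis packages; no
REML/Paule–Mandel variants are offered. Q uses fixed-effect weights,
τ² = max(0, (Q−df)/(S₁−S₂/S₁)), pooling uses 1/(se²+τ²), and
I² = max(0, (Q−df)/Q)·100. Pooling happens on the log-OR scale. When a
stage is only available as a printed OR with CI, `se_from_ci` recovers
se = (ln hi − ln lo)/(2z); two-decimal printed CIs carry rounding noise of
about ±0.01 on the recovered bounds, so pooled point estimates are robust
but pooled CI digits may differ slightly from a source's. The
implementation was cross-checked once against an independent reference
fit (R metafor, DL method) and those values are frozen in the test suite.

## The pipeline

Per stage and exposure: select → clump → F → harmonize → {IVW, Egger,
weighted median, RAPS} → both Q flavors → PRESSO when J ≥ 4. The primary
significance decision compares the IVW p-value with the Bonferroni
threshold α/m (default m = 3 exposures, displayed as 0.0167 but carried
at full precision); the other estimators are reported as sensitivity
analyses. Failures (e.g. too few instruments) are isolated per exposure.
With ≥ 2 stages, per-exposure IVW log-ORs are pooled by DL; heterogeneity
between stages is flagged at p < 0.05. Every seed derives
deterministically from the master seed and the stage/exposure labels, so
reruns produce byte-identical TSV reports.

## The synthetic generator

`simulate_two_sample` draws maf ~ U(0.05, 0.5), sets
σ = 1/√(2np(1−p)) — the standardized-trait approximation, adequate
because only the SE structure matters, though the emulated traits are
binary — and draws γⱼ = σ_Xj√F with F ~ U(72, 200) for strong instruments
(√72 sits ≈ 3 SDs above the genome-wide z cutoff, so a post-selection
instrument list stays significant after sampling noise) and
F ~ U(4, 9) for the deliberately weak fraction. Effect alleles are coded
exposure-increasing (γⱼ > 0), the convention under which directional
pleiotropy αⱼ ~ N(μ_α, τ_α²) is defined; sign variety in emitted tables
comes from allele re-coding, which ~30 % of outcome rows receive so
harmonization is genuinely exercised. Default study sizes (n_exp 30k,
n_out 20k) and the `uc`/`cd`/`ibd` presets (J = 26/46/54 against a
3026-sample outcome) echo consortium-scale designs. A master seed spawns
named substreams (truth, exposure, outcome, replication, alleles, LD), so
`simulate_harmonized` — the fast path that skips table plumbing — carries
exactly the same effect draws as the full table route, which is asserted
in the tests.

What the generator does **not** emulate: real LD (blocks are synthetic
uniform r², not panel-derived), binary-trait likelihoods (normal summary
approximation only), sample overlap between studies, allele-frequency
differences between cohorts, population stratification, or winner's-curse
inflation of the discovery effect sizes. Passing tests therefore show the
estimators are correct under the stated summary-level model, not that any
real-data finding is right.

## Monte-Carlo scenarios and problem sizes

Calibration and recovery checks run at: IVW type-I error, 2000 null
replicates at J = 50 (band [0.03, 0.07]); IVW bias < 5 % of θ = 0.2 over
500 replicates; Egger intercept recovery of μ_α = 0.03 within 0.01 over
200 replicates at J = 100 with InSIDE holding; weighted median within
0.05 of θ = 0.2 with 30 % invalid instruments over 500 replicates;
PRESSO sensitivity ≥ 0.9 to a planted 10× outlier over 500 replicates at
J = 20 with n_sim = 799 (chosen so the Bonferroni-adjusted empirical
floor 20/800 = 0.025 can clear 0.05). The weighted-median scenario uses a
biobank-scale outcome (n_out = 200k, the replication-stage design): with
a small outcome study the weighted median's finite-noise quantile shift
under one-sided contamination is itself ≈ 0.06, and the check would
measure noise rather than the 50 %-validity consistency property it is
meant to exercise. These sizes keep the whole suite and the acceptance
script within a few minutes on one CPU while leaving comfortable margins
on every band.

## Known limitations

* Clumping quality is only as good as the supplied LD table; with no
  table, everything is treated as unlinked.
* RAPS assumes the overdispersion model's residuals are approximately
  normal; heavy contamination beyond what the Huber influence absorbs can
  still bias it.
* The distortion test's reference distribution (random same-sized
  removals) is the conventional one but is conservative when outliers are
  few and extreme.
* Back-transforming printed ORs propagates their rounding; pooled point
  estimates are stable, final CI digits may not be.
* No multivariable MR, mode-based estimators, Steiger filtering, proxy
  SNPs, or confounder lookups against external services.
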