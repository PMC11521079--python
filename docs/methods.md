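# Methods

## Setting and assumptions

`tsmr` implements two-sample summary-statistics Mendelian randomization: the
SNP→exposure associations (γ̂ⱼ, σ_γⱼ) and SNP→outcome associations (Γ̂ⱼ, σ_Γⱼ)
come from non-overlapping GWAS cohorts and are combined per SNP. Causal
interpretation rests on the three instrumental-variable conditions —
relevance (the SNP is robustly associated with the exposure), independence
(no association with exposure–outcome confounders) and exclusion restriction
(no effect on the outcome except through the exposure). The package enforces
relevance with a p-value screen, supports independence via a confounder
deny-list, and probes exclusion-restriction violations with the Egger
intercept and MR-PRESSO rather than assuming them away.

Instruments are assumed independent (pre-clumped). LD clumping is *not*
recomputed: it needs a genotype reference panel, and the supported workflows
consume published pre-clumped instrument lists. Estimates for a binary
outcome are on the log-odds scale and reported as odds ratios per exposure SD.

## Harmonization

Exposure and outcome tables are intersected on rsid (exposure order is
preserved) and aligned to the exposure's effect allele: identical allele
pairs pass through, swapped pairs negate the outcome beta and complement its
frequency, and anything else is excluded as `allele_mismatch` unless the
opt-in strand-complement retry resolves it. Exclusion, not silent repair, is
the default because strand guessing is the classic source of sign errors.

Palindromic variants (A/T, C/G; indels are never palindromic) are handled by
policy: `drop_all`, `drop_ambiguous` (default — dropped when the
effect-allele frequency lies in a window around 0.5, default [0.42, 0.58],
*or is unknown*), or `keep`. `keep` exists because already-screened published
instrument sets — including the packaged one, which prints no frequencies —
were strand-checked upstream; re-dropping their palindromes would silently
change a published instrument count. Every removal is logged as
`(rsid, reason)`, and |intersection| = |instruments| + |exclusions| is an
enforced invariant.

The default exposure significance threshold is 5 × 10⁻⁹, the discovery
threshold of the LST GWAS behind the packaged dataset; it is configuration,
not a constant.

## Estimators and conventions

Point estimates follow the standard summary-data formulas (README). The
conventions that matter for matching published analyses:

- **IVW dispersion.** Default is multiplicative random effects: SE_fixed ×
  max(1, √(Q/(L−1))), with Q always computed about the *fixed-effect* IVW
  estimate using first-order ratio weights (σ_Γⱼ/|γ̂ⱼ|)⁻². The floor at 1
  means random-effects SEs never undercut fixed-effect SEs. IVW and
  weighted-median p-values and CIs are normal-based (z = 1.96).
- **MR-Egger orientation.** The fit is preceded by negating (γ̂ⱼ, Γ̂ⱼ) wherever
  γ̂ⱼ < 0. The slope is orientation-invariant but the intercept's sign is
  not; the convention is recorded in every report. Inference is t-based with
  L − 2 df, and in random-effects mode both coefficient SEs are scaled by
  max(1, √(Q′/(L−2))) where Q′ is the weighted residual sum of squares.
- **Weighted median.** Ratios are sorted; the weighted empirical CDF through
  the cumulative midpoint percentiles pₖ = Σᵢ≤ₖwᵢ − wₖ/2 is linearly
  interpolated and inverted at 0.5. The point estimate is deterministic. The
  SE is a parametric bootstrap: each ratio is redrawn N(β̂ⱼ, σ_Γⱼ/|γ̂ⱼ|) with
  the weights held fixed — the simplest published variant — and the seed is a
  required argument, recorded in the report.
- **MR-PRESSO.** Observed statistic: RSS = Σⱼ wⱼ(Γ̂ⱼ − β̂₍₋ⱼ₎γ̂ⱼ)² with
  wⱼ = σ_Γⱼ⁻² and β̂₍₋ⱼ₎ the fixed-effect IVW without SNP j. The null draws
  Γ*ⱼ ~ N(β̂₍₋ⱼ₎γ̂ⱼ, σ_Γⱼ) and γ*ⱼ ~ N(γ̂ⱼ, σ_γⱼ) and recomputes RSS
  identically. All p-values use the add-one estimator (never below
  1/(n_sim+1)); per-SNP outlier p-values are Bonferroni-adjusted across the
  L instruments at a configurable significance (default 0.05); the distortion
  test references the change in IVW after outlier removal against n_sim
  random same-size removals. A configuration error is raised when n_sim
  cannot resolve the requested significance.

Degenerate inputs: a zero exposure effect makes the ratio undefined
(analysis error); collinear oriented exposure effects make Egger singular
(analysis error); a single instrument is allowed only for the Wald ratio and
fixed-effect IVW.

## Instrument strength and power

The overall F statistic uses F = (N−k−1)/k · R²/(1−R²), with R² an explicit
input — a joint R² is not derivable from printed per-SNP betas, so it is
never back-computed. Per-SNP strength is reported as (β/se)², explicitly
labeled approximate: for the packaged dataset this does *not* reproduce the
published per-SNP F column (e.g. 45.6 vs a printed 252.33 for the strongest
discrepancy), whose derivation would require unpublished per-SNP R² values;
the published column is stored verbatim and kept separate.

Power uses the normal approximation Φ(√(n·R²·K(1−K))·|ln OR| − z_{1−α/2})
for a binary outcome with case fraction K. Every input (which n, which OR)
is explicit; nothing is defaulted silently. At the packaged outcome's
dimensions (n = 319,046, K = 0.0326, R² = 0.019, α = 0.05, OR = 1.22) the
formula gives 0.786.

## The simulator: what it emulates and what it does not

`simulate_pair` draws true exposure effects, adds direct effects
αⱼ ~ N(α_mean, α_sd) to a chosen fraction of instruments (InSIDE holds by
construction: α is drawn independently of γ), and adds per-study Gaussian
noise with σ = 1/√(2p(1−p)·n_eff), where n_eff = n·K(1−K) for a binary
outcome. It emulates: realistic SE magnitudes, genome-wide-significant
instrument strength, palindromic-allele shares, and the valid/invalid
instrument mixture. It does **not** emulate LD between instruments, winner's
curse in instrument discovery, sample overlap between studies,
allele-frequency-dependent effect sizes, or non-Gaussian effect
distributions — so passing recovery tests demonstrate estimator correctness
under the stated model, not robustness to those real-data features.

The `lst_dr_scenario` preset mirrors the packaged study's dimensions: L = 63,
exposure n = 703,901, outcome 10,413 cases / 308,633 controls, effect
magnitudes N(0.028, 0.006) with the negative sign convention of the
published table, and MAF ~ Uniform(0.02, 0.10). The MAF range is a deliberate
calibration: under σ = 1/√(2p(1−p)n) at the full meta-analysis n, only
low-frequency instruments give the published exposure-SE scale (~0.004). The
published exposure and outcome SE columns imply mutually inconsistent
2p(1−p) under this one-parameter noise model; the scenario matches the
exposure side. A consequence worth knowing: simulated outcome SEs run ~2×
the published ones, so per-SNP ratio noise is somewhat larger than in the
real dataset.

## Simulation studies wired into the tests

Problem sizes were chosen to give informative Monte-Carlo error at desk
scale: estimator recovery and CI coverage use 500 replicates of the 63-SNP
scenario (θ = 0.2); the type-I-error study uses 1000 replicates at θ = 0.
Recovery simulations harmonize with the significance filter disabled: the
generator's instruments are truly associated by construction, and leaving
the filter on would entangle estimator bias with winner's-curse selection,
which the generator does not model.

The directional-pleiotropy study places α ~ N(0.15, 0.02) on 30% of
instruments — direct effects about five outcome SEs, i.e. unambiguous,
detectable pleiotropy. The magnitude matters: the weighted median's
finite-sample contamination bias saturates near the shifted quantile of the
valid-ratio distribution, while IVW bias grows linearly in the pleiotropy
mean, so the robustness contrast between the two is an identifiable property
only when direct effects are well separated from per-SNP ratio sampling
noise. The Egger intercept is compared against the true mean direct effect
in the γ ≥ 0 orientation.

## Known limitations

- No LD-aware modeling: correlated instruments would understate SEs.
- First-order Wald-ratio SEs throughout (the convention of the analyses this
  package reproduces); second-order weights are not offered.
- MR-Egger is fragile under weak instruments and InSIDE violations; the
  simulator can demonstrate the former but only models the latter via its
  correlation-free construction.
- The power formula is an asymptotic normal approximation; it ignores
  weak-instrument bias and case-control ascertainment subtleties.
- Harmonization trusts rsids; no positional (chr:pos) matching.
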