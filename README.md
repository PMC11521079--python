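# tsmr — two-sample Mendelian randomization from GWAS summary statistics

`tsmr` estimates the causal effect of an exposure on an outcome using genetic
variants as instrumental variables, working entirely from published GWAS
summary statistics (one `beta ± se` pair per SNP per trait — no
individual-level genotypes). It is written for epidemiologists and statistical
geneticists who want a reproducible, scriptable MR workflow: explicit
harmonization with a full exclusion log, seeded resampling, and
machine-readable reports.

The package ships a worked, fully reproducible analysis: the effect of
**leisure screen time (LST**, in SD units; 1 SD ≈ 2.2 h/day**)** on
**diabetic retinopathy (DR)**, using a published set of 63 independent SNPs
from a 703,901-person LST GWAS meta-analysis paired with a FinnGen DR
case-control GWAS (10,413 cases / 308,633 controls).

## The model

For instrument *j*, let γ̂ⱼ (SE σ_γⱼ) be the SNP→exposure association and
Γ̂ⱼ (SE σ_Γⱼ) the SNP→outcome association on the same effect allele. A valid
instrument satisfies Γⱼ = θγⱼ, and θ (log-odds of outcome per SD of
exposure) is estimated by:

- **Wald ratio** — β̂ⱼ = Γ̂ⱼ/γ̂ⱼ, SE σ_Γⱼ/|γ̂ⱼ|.
- **IVW** — β̂ = Σwⱼγ̂ⱼΓ̂ⱼ / Σwⱼγ̂ⱼ², wⱼ = σ_Γⱼ⁻²; the inverse-variance-weighted
  average of the ratios. Default mode is multiplicative random effects: the
  fixed-effect SE is inflated by max(1, √(Q/(L−1))).
- **Weighted median** — the inverse-variance-weighted median of the ratios
  (interpolated); consistent when instruments carrying ≥50% of weight are
  valid. SE by seeded parametric bootstrap.
- **MR-Egger** — weighted regression of Γ̂ on γ̂ *with an intercept*, after
  orienting all γ̂ⱼ ≥ 0; the intercept estimates the mean directional
  pleiotropic effect, the slope the causal effect (t-based inference, L−2 df).

Diagnostics: Cochran **Q** (heterogeneity of ratios about the fixed-effect
IVW, χ²_{L−1}), Rücker **Q′** for the Egger model, the Egger **intercept
test**, **MR-PRESSO** (seeded parametric resampling of the leave-one-out
residual sum of squares: global heterogeneity p, Bonferroni-adjusted per-SNP
outlier p, distortion test), **leave-one-out** IVW, and plot-ready
single-SNP/funnel tables. Instrument strength is summarized by
F = (N−k−1)/k · R²/(1−R²) plus per-SNP (β/se)², and statistical power for a
binary outcome by Φ(√(n·R²·K(1−K))·|ln OR| − z_{1−α/2}).

A simulator (`tsmr.simulate`) generates paired summary statistics under
Γⱼ = θγⱼ + αⱼ with known ground truth — configurable invalid-instrument
fraction, directional or balanced pleiotropy, palindromic-allele share — so
every estimator and diagnostic is testable without downloading anything.

## Worked example

The packaged instrument set is pre-screened (genome-wide significant,
LD-clumped, confounder-checked), so palindromic variants are kept:

```bash
tsmr fixture --out demo --analyze --seed 7
```

prints the forest-table summary:

```
method           nSNP  OR      CI_low  CI_high  p
ivw_mre          63    1.2107  1.0317  1.4207   0.0192
weighted_median  63    1.2840  1.0421  1.5821   0.0189
egger            63    0.6622  0.3181  1.3786   0.265
```

Reading: each SD of genetically proxied leisure screen time raises the odds
of diabetic retinopathy by ~21% (IVW) to ~28% (weighted median), both
significant at the 5% level; the MR-Egger slope is imprecise and
non-significant, and its intercept (0.0178, SE 0.0106, p = 0.097) does not
indicate significant directional pleiotropy. Heterogeneity is unremarkable
(Q = 75.51 on 62 df, p = 0.116), MR-PRESSO finds no outliers (global
p ≈ 0.10), and no single SNP flips the odds ratio across 1 in leave-one-out.
The same run writes `report.json` (full precision, byte-reproducible for a
given seed) plus TSV tables for forest/scatter/funnel/leave-one-out plotting.

Power at the outcome GWAS's size:

```bash
tsmr power --n-total 319046 --case-fraction 0.032640 --r2 0.019 --or-alt 1.22
# power = 0.786 (n=319046, K=0.0326, R2=0.019, alpha=0.05, OR=1.22)
```

The same workflow runs on any pair of summary-stat files via
`tsmr run --exposure ... --outcome ...`, and `tsmr simulate` writes synthetic
pairs with their ground truth.

## Layout

- `tsmr.datamodel`, `tsmr.io`, `tsmr.fixtures` — domain types, delimited-table
  readers/writers, packaged instrument set
- `tsmr.harmonize` — allele alignment and screening filters
- `tsmr.estimators`, `tsmr.diagnostics`, `tsmr.strength` — the statistics
- `tsmr.simulate` — ground-truth generator
- `tsmr.pipeline`, `tsmr.cli` — orchestration and the `tsmr` command
- `docs/methods.md` — modeling assumptions, conventions, and design choices
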