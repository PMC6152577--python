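# tsmr — two-sample Mendelian randomization from GWAS summary statistics

`tsmr` estimates the causal effect of an exposure on an outcome using
genetic variants as instrumental variables, working entirely from published
GWAS summary statistics (two-sample MR). It was built for analyses of the
kind that ask whether externalizing phenotypes (childhood aggression, ADHD
liability) causally influence tobacco use, where the exposure and outcome
associations come from separate large consortium GWAS — but it applies to
any exposure/outcome summary-statistic pair.

## What it does

Given per-SNP association tables for an exposure and an outcome, the
pipeline:

1. **selects instruments** by p-value threshold in the exposure GWAS
   (`P < 5×10⁻⁸` genome-wide, or a suggestive threshold such as `5×10⁻⁵`);
2. **substitutes LD proxies** (`r² ≥ 0.9` by default, from a local proxy
   table) for instruments absent from the outcome GWAS;
3. **harmonizes alleles** — the outcome effect Γⱼ is re-oriented to the
   exposure's effect allele, resolving label swaps, strand flips and
   palindromic (A/T, C/G) SNPs via allele frequency, dropping ambiguous
   palindromes by default;
4. **estimates the causal effect** three ways, each with SE, 95% CI and
   p-value, plus Cochran's Q / I² heterogeneity:
   - **IVW**: β̂ = Σwⱼγⱼ Γⱼ / Σwⱼγⱼ², wⱼ = 1/σ_Γⱼ² — weighted regression of
     Γ on γ through the origin (all instruments assumed valid);
   - **MR-Egger**: the same weighted regression with a free intercept; the
     intercept estimates mean directional pleiotropy, the slope is the
     pleiotropy-adjusted effect under the InSIDE assumption;
   - **weighted median**: the weight-interpolated 50th percentile of the
     Wald ratios Γⱼ/γⱼ (weights γⱼ²/σ_Γⱼ²), consistent when ≥ 50% of the
     weight comes from valid instruments; SE by parametric bootstrap;
5. **reports** a per-method table (odds-ratio scale for binary outcomes)
   with instrument accounting, and writes a harmonization report and run log.

It also provides an **analytic power calculator** for two-sample MR designs
and a **synthetic summary-statistic generator** (`Γⱼ = θγⱼ + αⱼ + εⱼ` with
controllable pleiotropy, InSIDE violation and allele corruption) used to
validate every stage without any data download.

## Worked example

Simulate a 14-instrument binary-outcome dataset with a true causal effect
θ = 0.2 (odds ratio e^0.2 ≈ 1.22) and realistic allele-metadata corruption,
then run the full pipeline:

```bash
tsmr simulate --n-snps 14 --theta 0.2 --frac-palindromic 0.2 \
  --frac-strand-flipped 0.2 --frac-allele-swapped 0.2 --seed 7 --out demo
tsmr run --exposure demo/exposure.tsv --outcome demo/outcome.tsv \
  --p-threshold 0.99 --seed 7
```

```
| Method             | OR    | 95% CI       | P value  |
|--------------------|-------|--------------|----------|
| IVW                | 1.239 | 1.102, 1.393 | 0.000351 |
| Weighted median    | 1.198 | 1.025, 1.399 | 0.0228   |
| MR-Egger slope     | 1.364 | 0.755, 2.466 | 0.304    |
| MR-Egger intercept | 0.994 | 0.961, 1.029 | 0.745    |

Heterogeneity I2 = 0% (Q = 6.788, df = 12); instruments: 14 selected, 0 proxied, 1 dropped, 13 analyzed
```

All three estimators bracket the true OR of 1.22; the Egger intercept is
consistent with no directional pleiotropy (OR-scale intercept ≈ 1, p =
0.745); one instrument — an ambiguous palindromic SNP — was dropped during
harmonization, and I² = 0% indicates no excess heterogeneity. The power
subcommand reproduces an analytic design calculation:

```bash
tsmr power --n 74053 --r2 0.01 --effect 0.1 --scale continuous
# 78%
```

The same functionality is available as a library (`tsmr.run_analysis`,
`tsmr.ivw_estimate`, `tsmr.simulate_pair`, ...); see `docs/methods.md` for
the statistical model, parameter defaults and limitations.

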