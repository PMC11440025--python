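# neuromr

Two-sample Mendelian randomization (MR) for GWAS summary statistics, built
for screens of the "several exposures × many disorders" shape: univariable
estimation, pleiotropy diagnostics, multivariable MR, and two-step mediation
with the proportion mediated — plus a synthetic GWAS generator with known
causal truth so every stage can be validated without downloading any
consortium data.

## Who this is for

Genetic epidemiologists asking whether a heritable exposure (say, a
neuroticism item cluster measured in a few hundred thousand individuals)
causally raises the risk of a binary outcome (say, a psychiatric disorder
from a case–control GWAS), using only published per-SNP association
statistics from two non-overlapping samples.

## The model

Each genetic instrument *j* contributes an exposure effect estimate
(β̂ₓⱼ, seₓⱼ) and an outcome effect estimate (β̂ᵧⱼ, seᵧⱼ). Under the
instrumental-variable assumptions the per-SNP Wald ratio β̂ᵧⱼ/β̂ₓⱼ estimates
the causal effect θ, and the estimators combine them:

* **IVW (multiplicative random effects)** — weighted regression of β̂ᵧ on
  β̂ₓ through the origin with weights 1/seᵧ²; θ̂ = Σwβ̂ₓβ̂ᵧ / Σwβ̂ₓ²; the SE is
  inflated by max(1, √(Q/(J−1))) with Q Cochran's heterogeneity statistic.
  This is the primary estimator.
* **MR-Egger** — the same regression with an intercept α; α ≠ 0 indicates
  directional horizontal pleiotropy, and the slope remains consistent under
  the InSIDE assumption. Inference is t-based with J−2 df.
* **Weighted median** — the interpolated weighted median of Wald ratios
  (weights = inverse ratio variance), consistent when ≥50% of weight comes
  from valid instruments; SE by seeded parametric bootstrap.
* **MR-PRESSO** — simulation-based residual-sum-of-squares test for
  horizontal pleiotropy with per-SNP outlier calls and outlier-corrected
  re-estimation.
* **MVMR** — weighted multiple regression of β̂ᵧ on several exposures'
  effect matrices jointly, giving each exposure's direct effect.
* **Two-step mediation** — β_indirect = β_EM·β_MO (product of
  coefficients), proportion mediated PM = β_indirect/β_total, delta-method
  SE, Monte-Carlo CI.

Instruments are selected at p < 5×10⁻⁸ (mediators fall back to 5×10⁻⁶ when
fewer than three survive), greedily LD-clumped to r² < 0.001 within
±10,000 kb, and filtered to per-SNP F = β²/se² > 10. Harmonization aligns
all datasets to a common effect allele, resolving swaps and strand flips and
eliminating palindromic SNPs with intermediate allele frequencies
(default band 0.42–0.58).

## Worked example

```sh
python examples/univariable_mr.py
```

generates a synthetic exposure GWAS (350k individuals) and binary outcome
GWAS (200k) with a true log-odds causal effect of 0.3, then prints:

```
instrument selection: {'input': 250, 'removed_pvalue': 224, 'removed_clump': 0, 'removed_weak': 0, 'retained': 26}
harmonized 23 SNPs (3 dropped, 5 sign-flipped)
ivw_mre          beta=+0.346 se=0.030 OR=1.41 (1.33,1.50) p=8.22e-31
egger            beta=+0.424 se=0.089 OR=1.53 (1.27,1.84) p=1.04e-04
weighted_median  beta=+0.377 se=0.045 OR=1.46 (1.34,1.59) p=5.03e-17
Cochran Q=21.5 (df=22, p=0.490)
Egger intercept=-0.0021 p=0.359
MR-PRESSO global p=0.6154, outliers=[]
dismissed by pleiotropy rule: False
```

All three estimators agree in sign and their CIs cover the true θ = 0.3
(odds ratio 1.35); the diagnostics show no heterogeneity, a null Egger
intercept, and no outliers — a clean instrument set. The other examples
cover mediation (`mediation_analysis.py`, planted proportion mediated 10%),
a full 3 × 10 study grid with Bonferroni tiers, MVMR and mediation
(`full_study.py`), and dialect-mapped file input (`reading_sumstats.py`).

There is also a thin CLI: `neuromr run --config study.yaml`,
`neuromr simulate`, `neuromr select`, `neuromr uvmr`.

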