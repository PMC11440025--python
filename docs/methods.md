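# Methods

## Scope and data model

The package operates entirely on GWAS summary statistics: one row per SNP
with identifier, chromosome/position, effect and other allele, effect-allele
frequency, effect size, standard error, p-value and sample size. Binary
traits are held on the log-odds scale internally; odds ratios appear only at
the reporting boundary (`or_ci_to_beta_se` inverts a published OR and CI
back to log-odds). Column mapping on read is explicit and config-driven —
header dialects vary across consortia and silent mis-mapping is the dominant
failure mode, so nothing is sniffed. Non-ACGT alleles and rows violating the
record invariants (se ≤ 0, p outside (0,1], duplicate ids, …) are dropped
with counted reasons.

## Instrument selection

`build_instruments` applies, in order: a strict p < threshold screen
(default 5×10⁻⁸; the selection uses strict inequality so a p equal to the
threshold is excluded), greedy LD clumping, and the per-SNP strength filter
F = β²/se² > 10. Clumping ranks by ascending p (ties broken by snp_id so the
result is independent of input row order), takes the best remaining SNP as
index, and removes all remaining SNPs on the same chromosome within
±window_kb (default 10,000 kb) whose r² with the index is ≥ r2_max (default
0.001). SNPs absent from the LD table are treated as uncorrelated, which
mirrors reference-panel dropout. The variance explained by one SNP uses the
one-parameter relation R² = F/(F + N − 2), the algebraic inverse of
F = R²(N−2)/(1−R²).

Mediator traits often lack three genome-wide-significant instruments;
`build_instruments_relaxed` retries at 5×10⁻⁶ in that case and records the
threshold actually used.

## Harmonization

All estimators consume vectors aligned to a common effect allele.
Non-palindromic SNPs are aligned by letters: identical pair → keep; swapped
pair → negate the outcome beta and reflect its frequency; complementary
letters → remap the strand first. Irreconcilable pairs are dropped and
logged, never silently kept. Palindromic SNPs (A/T, C/G) carry no strand
information in their letters, so they are oriented by allele frequency:
dropped when either dataset's frequency lies in the open ambiguity band
(default 0.42–0.58, the de-facto convention; set the band to (0,1) to drop
all palindromes) or is missing, and otherwise aligned so both frequencies
fall on the same side of 0.5. Multi-exposure harmonization keeps a SNP only
when it is alignable in every exposure and the outcome, and expresses all
exposure effects on the first exposure's allele.

## Estimators

Weights are always 1/seᵧ² (first-order: exposure-side uncertainty is
ignored in weighting, the dominant convention; a second-order Wald-ratio SE
is available). The IVW multiplicative random-effects scale factor
√(Q/(J−1)) is truncated below at 1 — underdispersion never shrinks the SE —
and the same truncation applies to the Egger and MVMR residual-SD
inflation. CIs and p-values are normal for IVW, weighted median and MVMR,
and t with J−2 df for Egger; published analyses rarely state their CI
method, and these are the conventional choices. Egger orients every SNP so
β̂ₓ ≥ 0 (flipping both betas leaves Wald ratios unchanged), which makes the
intercept interpretable as the mean pleiotropic effect on the
exposure-increasing allele. The weighted-median bootstrap redraws both
betas from normals with the observed SEs under a caller-supplied seed
recorded in the result.

With one SNP, IVW degrades to the Wald ratio; with two, Egger and the
weighted median are omitted rather than forced.

## Sensitivity analysis

Cochran's Q is computed at the fitted IVW (df J−1) and Egger (df J−2)
models. Leave-one-out re-estimates IVW-MRE excluding each SNP (computed
from subset sums, so it is exact and O(J)). Funnel data are per-SNP (ratio,
1/ratio-SE) pairs for symmetry inspection.

The residual-sum-and-outlier (MR-PRESSO) procedure scores each SNP by its
inverse-variance-weighted squared residual around the leave-one-out IVW
prediction and simulates the null by redrawing β̂ₓ ~ N(β̂ₓⱼ, seₓⱼ) and
β̂ᵧ ~ N(β₍₋ⱼ₎β̂ₓⱼ, seᵧⱼ). The global p uses the add-one estimator
(1 + #exceed)/(n_sim + 1), so it is never exactly zero and its floor is
1/(n_sim+1). The per-SNP outlier p deliberately uses the raw exceedance
proportion instead: an add-one floor would bound the Bonferroni-adjusted p
below by J/(n_sim+1) ≈ 0.06 at J = 30, n_sim = 500, making even a gross
outlier formally undetectable at α = 0.05. The simulation count defaults to
1000. No distortion test is reported; instead the uncorrected and
outlier-corrected IVW estimates are presented side by side.

A pair is *dismissed* when the global pleiotropy p < 0.05; the Egger
intercept test is recorded alongside as a secondary flag but does not drive
dismissal on its own.

## Multiplicity, MVMR triggering, mediation

The family-wise threshold is 0.05/m with m defaulting to the number of
exposure × outcome pairs (0.05/30 ≈ 0.0017 for a 3 × 10 grid); p < 0.05
below that is "nominal". MVMR runs on every outcome with at least two
nominally significant, non-dismissed exposures, over the union of the
per-exposure instruments re-clumped jointly with the smallest cross-exposure
p as ranking key. Mediation triples (exposure, mediator, final outcome)
require all three IVW links significant at 0.05 and none dismissed; the
mediator → outcome link is estimated by univariable IVW on the mediator's
own instruments (relaxed threshold fallback), not adjusted for the exposure
— consistent with reporting conventions for two-step MR; an MVMR-adjusted
variant can be assembled from the same pieces. The proportion-mediated CI
comes from Monte-Carlo propagation of the three link estimates rather than
a second delta step, because the ratio's distribution is skewed when the
total effect is imprecise. The direct effect is reported as
total − indirect ("difference-derived").

## Synthetic data generator

The generator emulates the statistical structure two-sample MR assumes, not
individual-level genetics. Per instrument: allele frequency
p ~ Uniform(0.05, 0.95); sampling SEs follow the per-allele form
1/√(2Np(1−p)) with the exposure and outcome sample sizes (defaults 350,000
and 200,000, the scale of UK-Biobank-style exposure GWAS and a large
psychiatric case–control GWAS; mediator default 50,000); true effects
γⱼ ~ N(0, (F*−1)·seₓ²) so the expected per-SNP F equals the target F*
(default 80, inside the 20–170 range seen in practice); observed effects
are the truth plus sampling noise. Binary outcomes reuse the same SE form
on the log-odds scale — adequate for method testing, but it is *not* a
case-control likelihood simulation and encodes no winner's curse beyond
what selection induces.

Horizontal pleiotropy adds αⱼ to the outcome effect for a fraction of SNPs,
αⱼ = sign(γⱼ)·N(μ, σ²): alignment to the exposure-increasing allele is what
makes μ ≠ 0 *directional* — allele labels are arbitrary, and a label-fixed
shift would cancel over random label choices instead of biasing IVW.
μ = 0 gives balanced pleiotropy. LD blocks add near-duplicate tag SNPs
(effects scaled by √r²) within 10 kb of an index instrument and record the
r² entries; a palindrome fraction assigns A/T or C/G letters with
frequencies near 0.5; the outcome file reports every SNP in a random allele
orientation so harmonization is exercised end to end. Mediation scenarios
add a mediator dataset with its own instruments and compose the outcome as
θ_direct·γ + θ_MO·(mediator path). Exposure and outcome draws are
independent streams per dataset — the two-sample, non-overlap assumption
holds by construction. All generation is driven by one recorded seed.

`generate_grid_study` assembles a study-shaped collection — 3 exposures ×
10 outcomes sharing one SNP universe, five non-null effects, and one
planted chain (EM 0.4, MO 0.25, direct 0.9 ⇒ PM = 10%) — used by the
end-to-end tests and the reproduction script.

## What passing tests do and do not show

Replicate studies run at desk scale: 1000 replicates for calibration and
the global pleiotropy test's size, 500 for weighted-median robustness, 200
for outlier power and mediation recovery, with J = 30–50 instruments and
n_sim = 500 for the residual-sum test — sizes chosen so the whole battery
completes in minutes while leaving Monte-Carlo error well inside the
asserted bands. They establish that the estimators are implemented
correctly and behave as the theory predicts *under the generator's
assumptions* (independent instruments, normal sampling error, known SEs,
non-overlapping samples). They do not establish robustness to real-data
pathologies the generator omits: sample overlap, winner's curse from
discovery-and-use of the same GWAS, fine-scale LD misspecification,
population stratification, or allele-frequency mismatch between cohorts.

## Numerical notes and known limitations

- Estimator linear algebra is closed-form (normal equations); MVMR solves a
  K×K system and rejects rank-deficient exposure matrices.
- Cochran's Q is slightly overdispersed when the causal effect is strong,
  because exposure-side measurement error enters the residuals (the
  familiar NOME deviation); with ~30 instruments this can push a few
  percent of clean strong pairs past the 0.05 dismissal rule. The
  residual-sum global test simulates exposure noise explicitly and is
  calibrated (measured size ≈ 4–5%).
- The Egger intercept recovers the mean directional pleiotropy only when
  instruments are strong; sign flips of weak instruments attenuate it
  (≈ 0.041 recovered from a true 0.05 at the default F target).
- Empirical p-values: global test never exactly 0 (add-one); per-SNP
  outlier p raw (see above).
- Per-SNP Wald p-values in generated tables are clamped to ≥ 1e-300 to
  respect the p ∈ (0,1] invariant.
- Reported tables round-trip bit-exactly (floats written as %.17g, read
  with round-trip parsing).
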