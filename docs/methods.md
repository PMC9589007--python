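# Methods

This note documents the statistical models behind `tissueprot`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real data.

## Synthetic cohorts

The generator emulates a cross-sectional multi-organ donor cohort: three
glycemic groups (CTRL/PD/T2D, default sizes 17/14/12), five tissues (islets,
liver, muscle, VAT, serum), and subject-level covariates and traits. Per
protein *p*, subject *i*, tissue *t*, the log2 abundance is

    y_pit = mu_p + b_pi + delta_p·1[group_i affected]
            + sum_c beta_pc (x_ci − mean x_c) + eps_pit

* `mu_p ~ Uniform(18, 30)` — spans the log2 dynamic range of label-free
  tissue proteomics so the censoring curve is exercised across its support.
* `b_pi ~ N(0, 0.3)` — a subject-level deviation shared across tissues
  (subjects carry their proteome between organs); within a single tissue it
  simply adds to the residual.
* `eps ~ N(0, 0.8)` — residual log2 SD; 0.8 reflects the combined biological
  and technical within-group variability typical of human tissue LFQ cohorts.
* Group effects `delta_p` are planted set-wise: each planted gene set names a
  per-protein log2 shift and the affected group, and the exact truth (shifts,
  covariate slopes, planted sets) is recorded for recovery tests.
* Covariate defaults: BMI slope 0.03 per kg/m² and age slope 0.012 per year,
  random sign per protein, on all proteins — strong enough that the 1%
  explained-variance screen selects them, as the screen does on real cohorts.
* Traits are group-conditional: HbA1c rises (5.3 → 6.0 → 7.6%) and GSIS falls
  (20 → 14 → 8) along CTRL → PD → T2D, so trait correlations and group
  contrasts respond to the same underlying signal.

**Missingness** is probit left-censoring around a per-sample detection
threshold: `P(missing | v) = Φ(s·(T_sample − v)) + mcar` clipped to [0, 1],
with `T_sample` the `censor_quantile` quantile (default 0.15) of the sample's
complete values and `s` the probit slope (default 2 per log2 unit; `inf`
gives a hard limit; `censor_quantile = 0` disables MNAR censoring entirely).
This reproduces the strong low-abundance bias of real missingness with two
interpretable knobs.

What the generator does **not** emulate: peptide-level quantification and
razor-protein inference, inter-protein correlation (pathway co-regulation),
serum's dynamic-range compression, batch structure, and heavy-tailed
residuals. Passing tests therefore demonstrate correctness and calibration of
the statistical machinery under a clean generative model, not robustness to
every artefact of real MS data.

## QC conventions

* **Outlier samples**: score `d_s = (median_s − M) / SD_(−s)` with M the
  median of the per-sample medians and the SD computed leave-one-out. A plain
  SD lets a single extreme sample inflate the yardstick it is judged against
  (with six samples, one median 10 and five near 0, the plain-SD score is
  2.4 and the outlier escapes a 3-SD rule); the leave-one-out scale flags it
  while leaving degenerate equal-median batches untouched. A subject is
  recommended for exclusion only when flagged in *every* tissue where it has
  a sample — "consistent" deviation is declared as this all-tissues rule.
* **Presence filter** is ≥ 80% observed per tissue, boundary inclusive, and
  is applied after outlier-sample removal.
* **Gene aggregation** averages observed values only; a cell is missing iff
  all contributing proteins are missing. Averaging precedes imputation so the
  mean never includes fabricated values.

## QRILC imputation

Left-censoring means the observed values of a sample are the upper quantiles
of its latent intensity distribution. With fraction *f* missing and *m*
observed values, the i-th sorted observed value receives the shifted Blom
plotting position `p_i = f + (1−f)(i−0.375)/(m+0.25)`; ordinary least squares
of observed values on Φ⁻¹(p_i) gives the latent mean (intercept) and SD
(slope). Missing cells are drawn from N(μ̂, (tune_sigma·σ̂)²) truncated above
at the latent f-quantile `Q = μ̂ + σ̂·Φ⁻¹(f)`, so imputations populate the
censored lower tail. Imputation is per sample column (each sample has its own
detection limit); `tune_sigma` defaults to 1. A degenerate fit (σ̂ ≤ 0) falls
back to half-minimum imputation (minimum − 1 on the log2 scale) with a logged
warning. Fits on a 20%-censored N(20, 2) sample of 5000 recover μ within 0.1
and σ within 5% (tested).

## Covariate screening and trait correlations

Explained variance is marginal (one covariate at a time): per protein, the R²
of the single-covariate least-squares fit (group-means model for categorical
covariates), summarized by the median across proteins; a covariate is selected
at median R² ≥ 1% in at least one tissue, with islet purity eligible only in
islets. Note the null behaviour: at n samples the null R² has median on the
1/(n−1) scale (≈ 2.4% at n = 43), so the 1% floor is permissive at cohort
size — it screens out only covariates with essentially no marginal signal.

Trait correlations are Spearman on pairwise-complete cases with BH q-values.
Partial correlations take ranks first, then residualize both protein and
trait on the covariates by least squares and correlate the residuals
(whether the original analysis used Pearson or Spearman partials is
unstated; rank-based is declared here for uniformity with the marginal
correlations). A trait fully explained by the covariates yields r = 0 by
convention. The with/without-BMI comparison at the |Δr| = 0.4 threshold
classifies BMI-driven associations.

## Moderated differential analysis

Per-protein OLS on the imputed matrix with columns [intercept, group
indicator, centered continuous covariates, categorical dummies]. Merged-group
contrasts pool their groups into one indicator. Variance moderation follows
the closed-form empirical-Bayes scheme for a scaled-inverse-χ² prior:
with `e_g = log s²_g − ψ(d/2) + log(d/2)` (ψ the digamma function),
`trigamma(d₀/2) = Var(e) − trigamma(d/2)` determines the prior df d₀ (solved
by bracketed root finding; no excess dispersion ⇒ d₀ = ∞ and complete
shrinkage), and `s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2))`. Note that the
bias correction means "all s² exactly equal" yields a common posterior
variance slightly above that shared value — the estimator treats the
observed s² as χ²-distributed draws. Moderated t uses d₀ + d df (normal when
d₀ = ∞). q-values are BH by default with an optional Storey variant (fixed
λ = 0.5). The ranking statistic is π = logFC × (−log10 q); q = 0 is clamped
to the smallest positive float with a warning. ICU days are modeled
continuous.

## Enrichment

* **Competitive parametric test** (camera-style, preranked): for a set of
  size m among G ranked statistics, `Δ = mean(set) − mean(rest)` with pooled
  variance on G−2 df and the set's variance share inflated by
  `VIF = 1 + (m−1)ρ`; ρ defaults to 0.01, the standard preranked default when
  genewise statistics rather than expression are supplied, and is exposed as
  a flag. At ρ = 0 the test is exactly the pooled two-sample t-test.
* **Preranked GSEA**: weighted running sum (hits add `|stat|^w / Σ_set|stat|^w`
  with w = 1, misses subtract 1/(G−m)); ES is the signed maximum deviation,
  with exact ± ties broken toward the positive excursion so float noise
  cannot flip the sign. The null is n_perm random same-size gene sets scored
  against the same ranked list; null distributions are cached per set size
  within a call (the estimator is identical for all sets of one size).
  p = (1 + #{same-sign |ES_perm| ≥ |ES|}) / (1 + #{same-sign ES_perm}),
  NES = ES / mean(same-sign |ES_perm|). The default n_perm = 10,000 trades
  Monte-Carlo precision against runtime; the estimator is unchanged at higher
  counts (p saturates at 1/(n_same_sign+1)). The leading edge is the members
  at or before the extremum for positive ES and at or after it for negative
  ES. Sets are restricted to 5–300 members after intersection with the
  ranked list.
* **Consensus**: q-values are computed per method across its own sets (a
  joint correction is equally defensible; per-method is declared here), and
  a set is consensus-enriched iff both q < α (default 0.05) and the
  directions agree.
* **ORA**: hypergeometric upper tail P(X ≥ k) with the set intersected with
  the background before the 5–300 size filter; the background is the union
  of tissue proteomes for tissue-shared queries and the tissue's own proteome
  for tissue-specific queries.
* **Enrichment graph**: nodes are consensus sets with both q < 0.01; edge
  weight is the overlap coefficient |A∩B| / min(|A|, |B|) kept at ≥ 0.5 —
  the published networks state only "high similarity", so both the metric
  and the cutoff are conventions exposed in the config.

### Known limitation: GSEA power on spiked π rankings

When a cohort contains a small number of strongly shifted proteins and
everything else is exactly null, the π statistic is near zero for almost all
genes and large for the shifted ones. The weighted running sum then saturates:
a *random* null set that happens to contain one strong gene already reaches
|ES| ≈ 0.9, close to the ≈ 0.96 of a fully planted set, so the permutation
p of true sets flattens around 10⁻²–10⁻³ and cannot survive FDR correction
across a large collection. This is a property of the weighted-KS statistic on
spiked rankings, not of the implementation (the same implementation
reproduces the classic null ES scale, mean |ES| ≈ 0.31 at G = 3000, m = 20,
on Gaussian statistics, and recovers planted sets reliably when the
collection under test is the planted family). Real cohort signal is diffuse
across many proteins, which keeps the ranking smooth and GSEA informative;
the competitive parametric test does not share the saturation and flags
planted sets at q < 10⁻¹⁶ in either regime.

## Calibration checks

Null-cohort checks (no planted effects) use the moderated t statistic as the
genewise input to the competitive test at ρ = 0: the generator's genes are
independent and near-normal, which is exactly the test's parametric null
(the spiked shape of π under the null violates it, and π is a ranking device,
not a test statistic). Measured on 2000 proteins / 500 random sets: moderated
p-values KS-uniform, competitive rejection rate within the binomial band
around 5%, and zero consensus sets at q < 0.05.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen as the
smallest sizes at which the binomial/KS bands are informative: null cohorts
of 2000 proteins × 500 sets, recovery cohorts of 3000 proteins with five
20-gene planted sets over 10–20 independent seeds, GSEA at 1,000–10,000
permutations, QRILC recovery at m = 5000. All randomness flows from explicit
seeds; identical configs reproduce byte-identical outputs.
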