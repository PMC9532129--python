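# Methods

This note documents the statistical models, the defaults and why they were
chosen, the synthetic-data model that underpins the tests, and the
package's known limitations.

## Effect-size meta-analysis

Each cohort contributes a standardized mean difference of log2 expression
between cancer and control. The estimator is **Hedges' g**: Cohen's d on
the pooled (n−1) standard deviation times the small-sample correction
J = 1 − 3/(4·df − 1), df = n1 + n0 − 2, with the usual large-sample
variance (n1+n0)/(n1·n0) + g²/(2(n1+n0)). Group SDs use the n−1
denominator throughout, the convention for published group summaries. The
degenerate case of a zero pooled SD returns g = 0 when the means are also
equal and raises an error otherwise (the effect is unbounded).

Pooling is **DerSimonian–Laird** random effects: Q on fixed inverse-variance
weights, τ² = max(0, (Q − df)/C) with C = Σw − Σw²/Σw, re-weighting by
1/(vᵢ + τ²), and a 95% CI using the normal multiplier 1.96. No
Knapp–Hartung adjustment and no REML: the DL method of moments is
deterministic, requires no optimizer, and matches the CI widths of the
standard meta-analysis toolchains this workflow emulates. I² =
max(0, (Q − df)/Q). With a single study all heterogeneity statistics are
zero and the CI is g ± 1.96√v.

On the built-in nine-cohort fixture this machinery is validated by the test
suite; choosing Cohen's d instead of g shifts the pooled value and
heterogeneity away from the reference values the tests pin, which is the
empirical reason g is the default and only estimator.

**Begg's test** correlates the variance-standardized deviates
tᵢ = (gᵢ − ĝ_fixed)/√(vᵢ − 1/Σw) with the sampling variances via Kendall's
τ_b. For k ≤ 10 studies without ties the two-sided p is exact, computed
from the full permutation null of Kendall's S via the inversion-count
generating function ∏ᵢ(1 + x + … + x^{i−1}); otherwise a normal
approximation with continuity correction and tie-corrected variance is
used. Note that for small k the exact p-value is *discrete*: at k = 9 the
gaps between achievable p-values reach ≈ 0.16, so the p-value distribution
under the null is a conservative step function rather than uniform. The
test suite therefore checks uniformity at k = 20 (where the approximation
branch makes the distribution nearly continuous) and checks
P(p ≤ α) ≤ α at k = 9.

**Fisher-Z pooling of correlations** reuses the identical DL machinery on
zᵢ = atanh(rᵢ) with se = 1/√(nᵢ − 3), back-transforming the pooled value
and CI bounds with tanh. Studies need n ≥ 4 for a finite standard error;
|r| = 1 is rejected as an unbounded effect.

## Diagnostic meta-analysis

Per cohort the AUC is the Mann–Whitney probability P(case > control) +
½P(tie), computed from ranks. Orientation is fixed (higher in cases =
positive); a marker lower in cases shows AUC < 0.5 visibly rather than
being silently flipped. Discrimination bands: weak < 0.7 ≤ moderate ≤ 0.9 <
strong.

Continuous expression is dichotomized at the **Youden-optimal cutoff**
(max sens + spec − 1, smallest threshold on ties; a sample is positive when
strictly above the cutoff). Zero cells in the resulting 2×2 table receive
the standard 0.5 continuity correction on all four cells. The original
workflow's dichotomization rule is not recoverable from group summaries, so
reproduction of published pooled sensitivity/specificity on real data is
not claimed — only the arithmetic built on such values (likelihood ratios,
Fagan updates) is.

Sensitivity and specificity are pooled separately on the logit scale by DL
random effects with per-study variances 1/tp + 1/fn and 1/tn + 1/fp. The
summary ROC is the **Moses–Littenberg** linear model D = a + b·S, D =
logit(TPR) − logit(FPR) (log diagnostic odds ratio), S = logit(TPR) +
logit(FPR) (threshold proxy), fit by OLS; the curve is traced over FPR ∈
(0.005, 0.995) in 200 steps, closed at (0,0) and (1,1), and integrated by
the trapezoid rule. If all S coincide the regression is degenerate and a
symmetric SROC (b = 0) is used with a warning. The bivariate/HSROC
hierarchical models are deliberately out of scope: Moses–Littenberg is
deterministic and adequate for a screening pipeline.

Fagan's update: posttest odds = pretest odds × LR, with LR⁺ = sens/(1−spec)
and LR⁻ = (1−sens)/spec. The default pre-test probability is 0.20.

## Batch adjustment

`batch_adjust` is a parametric empirical-Bayes location/scale adjustment
(ComBat semantics): per-gene OLS with batch indicators plus the group
covariate, standardization by the pooled residual SD, EB shrinkage of
per-batch means (normal prior) and variances (inverse-gamma prior) toward
their across-gene moments via the standard fixed-point iteration, then
de-batching and restoration of the group-preserving mean. The group label
is always in the design so biological signal is protected; a batch
perfectly confounded with the group partition is refused.

The implementation is cross-checked in the test suite against Bioconductor
`sva::ComBat` on the same input (agreement to the oracle's convergence
tolerance). One behavioral consequence worth stating: EB *shrinkage means
batch means are not exactly equalized per gene* — genes whose estimated
batch effect deviates from the across-gene average retain a small residue.
This matches `sva::ComBat` exactly and is tested as such; plain per-batch
mean-centering would zero the residue but is not what ComBat-family tools
do.

## Differential expression and the screen

The moderated t-statistic shrinks per-gene pooled variances toward the
across-gene **median** with a fixed prior weight of 4 df:
s²_mod = (4·s²_median + df·s²_gene)/(4 + df), with p-values on df + 4
degrees of freedom and Benjamini–Hochberg adjustment within each cohort.
This is a deliberate, deterministic simplification of the limma-style
empirical-Bayes fit: the screening thresholds (|log2 FC| > 1, adjusted
p < 0.05) dominate behavior, not the exact prior estimate. BH adjustment is
verified against `statsmodels.multipletests`.

Cross-cohort reconciliation: a gene is "up" if called up in ≥ 1 cohort and
never down (and symmetrically); genes significant in both directions are
dropped with a warning. Survivors must additionally pass the per-gene SMD
meta-filter — pooled 95% CI excluding zero with sign matching the call.
Co-expressed genes (CEGs) require |r| ≥ 0.3 at p < 0.05 in ≥ 2 cohorts;
genes recurrent in both directions are assigned to neither set and logged.
Correlations default to cancer samples only (mixing groups inflates r
through the group-mean difference); a flag selects all samples. CEG
p-values are deliberately not multiplicity-adjusted — recurrence across
independent cohorts is the false-positive control at this stage — while
DEG calling uses BH.

The final screen intersects up-DEGs ∩ positive CEGs ∩ ChIP targets (score
> 0; duplicate genes keep the maximum score) and the mirrored down/negative
set, with a per-gene audit trail of which filters passed. The auxiliary
`promoter_overlap` reports genes whose ±2 kb TSS window (symmetric, so
strand only selects the annotated coordinate) overlaps any peak, all
arithmetic 0-based half-open.

## Synthetic-data model

The generator emulates the structure the pipeline assumes: K cohorts of
Gaussian log2-scale expression with shared baselines μ_g ~ N(7, 1.5²),
additive per-cohort batch offsets ~ N(0, batch_sd²), i.i.d. noise
(noise_sd, default 1), an anchor gene shifted by δ·noise_sd in cases, a
correlated block sharing the anchor's standardized noise as a latent factor
(loading ρ, residual SD √(1−ρ²)), and planted DEGs (±log2 FC added to
cases). Defaults mirror the published study conditions: the nine published
(n_case, n_control) pairs, δ = 1.8 (the reported pooled SMD), ρ = 0.4,
log2 FC = 2. Up-DEGs live inside the positively correlated block and
down-DEGs carry loading −ρ, so both sets carry the full triple evidence and
serve as ground truth for the end-to-end screen.

What the generator does *not* model — and hence what passing tests do not
establish about real data: probe-level array artifacts, count noise and
mean–variance trends of RNA-seq, heavy tails and outlier samples,
correlated gene–gene background structure beyond the single latent factor,
non-additive batch effects, and annotation/identifier mismatches.

## Numerical choices and problem sizes

Log2 conversion triggers when a matrix maximum exceeds 30 (log2 expression
essentially never does) and applies log2(x+1). Gene matching is exact and
case-sensitive. Writers use fixed 6-decimal formatting so round-trips are
reproducible byte for byte. The 95% multiplier is Φ⁻¹(0.975) to machine
precision. Simulation-based tests use 100–200 replicates with a few genes
per collection and cohorts at the published sample sizes — large enough to
pin the calibration properties they assert (CI coverage, recovery
envelopes, FDR level) while keeping the whole suite under a minute; the
end-to-end screen test uses 600 genes with 25 + 25 planted regulated genes.

## Known limitations

- Only the DL estimator of τ²; no REML, Knapp–Hartung, trim-and-fill, or
  meta-regression.
- Moses–Littenberg SROC ignores within-study correlation of sens/spec;
  no confidence bands.
- The moderated-t prior is fixed rather than estimated from the data.
- No probe-to-gene collapsing, identifier aliasing, or quantile
  normalization; inputs are assumed gene-level matrices.
- Exact Begg p-values are conservative (discrete) for small study counts.
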