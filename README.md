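# metamarker

Multi-cohort expression meta-analysis and anchor-gene marker screening.

`metamarker` implements the statistical workflow used to nominate a single
gene (the *anchor*, e.g. a transcription factor such as ARNT2 in
nasopharyngeal carcinoma) as a disease marker from many independent
expression cohorts, and to screen for genes it may regulate. No downloads
are required: the package ships a built-in fixture of published per-cohort
group summaries and a fully seeded synthetic-cohort generator with known
ground truth, so every stage is testable end to end.

## What it computes

**Effect-size meta-analysis.** Per cohort, the standardized mean difference
of log2 expression between cancer and control is Hedges' g,

    d = (m1 - m0) / s_p,   s_p^2 = ((n1-1)s1^2 + (n0-1)s0^2) / (n1+n0-2),
    g = J d,               J = 1 - 3 / (4(n1+n0-2) - 1),
    var(g) = (n1+n0)/(n1 n0) + g^2 / (2(n1+n0)).

Cohorts are pooled by DerSimonian–Laird random effects: Cochran's Q on
inverse-variance weights gives tau^2 = max(0, (Q - df)/C), studies are
re-weighted by 1/(v_i + tau^2), and heterogeneity is reported as
I^2 = max(0, (Q - df)/Q). Leave-one-out sensitivity analysis and Begg's
rank-correlation test (exact permutation null for small study counts)
assess stability and publication bias. The same machinery pools Fisher-Z
transformed correlations (z = atanh r, se = 1/sqrt(n-3)).

**Diagnostic meta-analysis.** Per cohort: Mann–Whitney AUC and the
Youden-optimal cutoff; the resulting 2×2 tables are pooled on the logit
scale and summarized by a Moses–Littenberg SROC curve
(D = a + bS with D = logit TPR − logit FPR, S = logit TPR + logit FPR).
Fagan's nomogram arithmetic converts a pre-test probability and the pooled
likelihood ratios into post-test probabilities.

**Marker screen.** Candidate regulated genes must pass three independent
filters in consistent directions: differential expression (moderated t,
|log2 FC| > 1, BH-adjusted p < 0.05, pooled-SMD 95% CI excluding zero),
recurrent co-expression with the anchor (|r| ≥ 0.3, p < 0.05, in ≥ 2
cohorts), and ChIP-seq target evidence (regulatory-potential score > 0).

## Worked example

```sh
python examples/anchor_meta_analysis.py
```

pools the nine built-in cohort summaries (308 cancer, 66 control samples)
and prints:

```
pooled SMD 1.80 (95% CI 1.17 to 2.43); I2 = 63.0%, tau2 = 0.516, Q = 21.65 (p = 0.0056)
...
Begg's test: Kendall tau = 0.111, p = 0.761
```

A pooled SMD of 1.80 with a CI excluding zero means anchor-gene expression
is consistently about 1.8 pooled standard deviations higher in cancer
tissue; I^2 = 63% flags substantial between-cohort heterogeneity (hence the
random-effects model), and Begg's p = 0.76 gives no evidence of
publication bias. The other examples cover diagnostic meta-analysis
(`diagnostic_meta_analysis.py`), co-expression screening and correlation
pooling (`coexpression_pooling.py`), and the complete screen
(`full_screen_pipeline.py`). A thin CLI mirrors the library, e.g.

```sh
metamarker fagan --pretest 0.20 --sens 0.93 --spec 0.89   # -> 0.68 / 0.02
metamarker meta-smd --fixture table1 --out forest.tsv
metamarker run --config config.yaml --json
```

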