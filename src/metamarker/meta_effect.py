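"""Standardized-mean-difference meta-analysis.

Per-cohort effect sizes are Hedges' g — Cohen's d times the small-sample
correction J = 1 - 3/(4*df - 1) — with the usual large-sample variance

    var(g) = (n1 + n0) / (n1 * n0) + g^2 / (2 * (n1 + n0)).

Cohorts are pooled by DerSimonian-Laird random effects: Cochran's Q on
inverse-variance weights gives the method-of-moments between-study variance
tau^2 = max(0, (Q - df) / C), effects are re-weighted by 1/(v_i + tau^2),
and the 95% CI uses the normal multiplier 1.96 (no Knapp-Hartung).
Heterogeneity is summarised by I^2 = max(0, (Q - df)/Q).

Also provided: leave-one-out sensitivity analysis, Begg's rank-correlation
publication-bias test (exact permutation null for small k), and the
per-gene SMD screen that keeps a gene only when its pooled 95% CI excludes
zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .cohort_io import GroupSummary, StudyCollection, summarize_gene
from .exceptions import InfiniteEffectError, InsufficientDataError, ValidationError

Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass(frozen=True)
class EffectSize:
    """Hedges' g for one cohort with its sampling variance."""

    dataset_id: str
    g: float
    variance: float
    df: int

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValidationError(f"{self.dataset_id}: nonpositive variance {self.variance}")
        if self.df < 1:
            raise ValidationError(f"{self.dataset_id}: df {self.df} < 1")


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate with heterogeneity statistics and per-study weights."""

    model: Literal["fixed", "random"]
    pooled: float
    se: float
    ci_low: float
    ci_high: float
    Q: float
    df_Q: int
    p_Q: float
    I2: float
    tau2: float
    weights: dict[str, float]  # normalised, sum to 1


@dataclass(frozen=True)
class BeggResult:
    kendall_tau: float
    p: float
    n_studies: int


def hedges_g(s: GroupSummary) -> EffectSize:
    """Hedges' g (bias-corrected SMD) from a group summary.

    Zero pooled SD with equal means returns g = 0 by convention; with
    unequal means the effect is unbounded and an error is raised.
    """
    n1, n0 = s.n_case, s.n_control
    df = n1 + n0 - 2
    sp2 = ((n1 - 1) * s.sd_case**2 + (n0 - 1) * s.sd_control**2) / df
    diff = s.mean_case - s.mean_control
    if sp2 == 0:
        if diff != 0:
            raise InfiniteEffectError(
                f"{s.dataset_id}: zero pooled SD with unequal means — effect is infinite"
            )
        g = 0.0
    else:
        d = diff / math.sqrt(sp2)
        J = 1.0 - 3.0 / (4.0 * df - 1.0)
        g = J * d
    n = n1 + n0
    variance = n / (n1 * n0) + g**2 / (2.0 * n)
    return EffectSize(dataset_id=s.dataset_id, g=g, variance=variance, df=df)


def pool_dl(
    effects: Sequence[EffectSize], model: Literal["fixed", "random"] = "random"
) -> MetaResult:
    """DerSimonian-Laird pooling of effect sizes.

    With a single study the pooled estimate is that study's effect and all
    heterogeneity statistics are zero.
    """
    if len(effects) == 0:
        raise InsufficientDataError("pool_dl needs at least one effect size")
    g = np.array([e.g for e in effects], dtype=float)
    v = np.array([e.variance for e in effects], dtype=float)
    k = len(g)
    w = 1.0 / v
    sw = w.sum()
    df_Q = k - 1
    if k == 1:
        Q, tau2, I2, p_Q = 0.0, 0.0, 0.0, 1.0
    else:
        Q = float(w @ g**2 - (w @ g) ** 2 / sw)
        C = sw - (w**2).sum() / sw
        tau2 = max(0.0, (Q - df_Q) / C) if C > 0 else 0.0
        I2 = max(0.0, (Q - df_Q) / Q) if Q > 0 else 0.0
        p_Q = float(stats.chi2.sf(Q, df_Q))
    if model == "fixed":
        tau2 = 0.0
    w_star = 1.0 / (v + tau2)
    pooled = float(w_star @ g / w_star.sum())
    se = float(w_star.sum() ** -0.5)
    return MetaResult(
        model=model,
        pooled=pooled,
        se=se,
        ci_low=pooled - Z95 * se,
        ci_high=pooled + Z95 * se,
        Q=Q,
        df_Q=df_Q,
        p_Q=p_Q,
        I2=I2,
        tau2=tau2,
        weights={e.dataset_id: float(ws / w_star.sum()) for e, ws in zip(effects, w_star)},
    )


def leave_one_out(
    effects: Sequence[EffectSize], model: Literal["fixed", "random"] = "random"
) -> list[tuple[str, MetaResult]]:
    """Re-pool k times, each omitting one study (sensitivity analysis)."""
    if len(effects) < 3:
        raise InsufficientDataError("leave_one_out needs >= 3 effects")
    out = []
    for i, e in enumerate(effects):
        rest = [x for j, x in enumerate(effects) if j != i]
        out.append((e.dataset_id, pool_dl(rest, model=model)))
    return out


def _kendall_s_null_pmf(n: int) -> dict[int, float]:
    """Exact null pmf of Kendall's S for n untied observations.

    The number of permutations with m inversions has generating function
    prod_{i=1..n} (1 + x + ... + x^{i-1}); S = C(n,2) - 2m.
    """
    coeffs = np.array([1.0])
    for i in range(2, n + 1):
        coeffs = np.convolve(coeffs, np.ones(i))
    coeffs /= coeffs.sum()
    m_max = n * (n - 1) // 2
    return {m_max - 2 * m: float(p) for m, p in enumerate(coeffs)}


def _tau_b(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Tie-corrected Kendall tau_b plus S and its tie-corrected null variance."""
    n = len(x)
    S = 0
    for i in range(n):
        for j in range(i + 1, n):
            S += int(np.sign(x[j] - x[i]) * np.sign(y[j] - y[i]))

    def tie_sizes(v: np.ndarray) -> np.ndarray:
        _, counts = np.unique(v, return_counts=True)
        return counts[counts > 1]

    tx, ty = tie_sizes(x), tie_sizes(y)
    n0 = n * (n - 1) / 2
    n1 = sum(t * (t - 1) / 2 for t in tx)
    n2 = sum(t * (t - 1) / 2 for t in ty)
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    tau = S / denom if denom > 0 else 0.0
    v0 = n * (n - 1) * (2 * n + 5)
    vt = sum(t * (t - 1) * (2 * t + 5) for t in tx)
    vu = sum(t * (t - 1) * (2 * t + 5) for t in ty)
    var_S = (v0 - vt - vu) / 18.0
    var_S += (
        sum(t * (t - 1) * (t - 2) for t in tx) * sum(t * (t - 1) * (t - 2) for t in ty)
    ) / (9.0 * n * (n - 1) * (n - 2)) if n > 2 else 0.0
    var_S += (
        sum(t * (t - 1) for t in tx) * sum(t * (t - 1) for t in ty)
    ) / (2.0 * n * (n - 1))
    return tau, float(S), var_S


def begg_test(effects: Sequence[EffectSize]) -> BeggResult:
    """Begg's rank correlation test for publication bias.

    Correlates the variance-standardized deviates
    t_i = (g_i - pooled_fixed) / sqrt(v_i - 1/sum w) with the sampling
    variances v_i using Kendall's tau_b.  The two-sided p-value is exact
    (full permutation null of S) for k <= 10 without ties, otherwise a
    normal approximation with continuity correction.
    """
    if len(effects) < 3:
        raise InsufficientDataError("begg_test needs >= 3 effects")
    g = np.array([e.g for e in effects], dtype=float)
    v = np.array([e.variance for e in effects], dtype=float)
    w = 1.0 / v
    pooled_fixed = float(w @ g / w.sum())
    cond_var = v - 1.0 / w.sum()
    cond_var = np.maximum(cond_var, 1e-300)
    t = (g - pooled_fixed) / np.sqrt(cond_var)

    tau, S, var_S = _tau_b(t, v)
    k = len(effects)
    has_ties = len(np.unique(t)) < k or len(np.unique(v)) < k
    if k <= 10 and not has_ties:
        pmf = _kendall_s_null_pmf(k)
        p = sum(prob for s_val, prob in pmf.items() if abs(s_val) >= abs(S))
    else:
        if var_S <= 0:
            p = 1.0
        else:
            z = (abs(S) - 1.0) / math.sqrt(var_S) if abs(S) >= 1 else 0.0
            p = 2.0 * float(stats.norm.sf(z))
    return BeggResult(kendall_tau=float(tau), p=min(1.0, float(p)), n_studies=k)


def begg_p_by_enumeration(effects: Sequence[EffectSize]) -> float:
    """Brute-force permutation p-value for Begg's test (oracle, k <= ~8).

    Enumerates all k! pairings of the deviates with the variances and counts
    orderings with |S| at least as extreme as observed.
    """
    g = np.array([e.g for e in effects], dtype=float)
    v = np.array([e.variance for e in effects], dtype=float)
    w = 1.0 / v
    pooled_fixed = float(w @ g / w.sum())
    t = (g - pooled_fixed) / np.sqrt(v - 1.0 / w.sum())

    def s_stat(a: np.ndarray, b: np.ndarray) -> int:
        s = 0
        for i in range(len(a)):
            for j in range(i + 1, len(a)):
                s += int(np.sign(a[j] - a[i]) * np.sign(b[j] - b[i]))
        return s

    s_obs = abs(s_stat(t, v))
    count = 0
    total = 0
    for perm in permutations(range(len(t))):
        total += 1
        if abs(s_stat(t[list(perm)], v)) >= s_obs:
            count += 1
    return count / total


def gene_smd_screen(
    collection: StudyCollection, gene: str, model: Literal["fixed", "random"] = "random"
) -> tuple[MetaResult, bool]:
    """Pool one gene's SMD across cohorts; keep it iff the 95% CI excludes 0."""
    summaries = []
    for cohort in collection:
        if gene in cohort.matrix.index:
            summaries.append(summarize_gene(cohort, gene))
    if len(summaries) < 2:
        raise InsufficientDataError(
            f"gene {gene!r} present in {len(summaries)} cohort(s); >= 2 required"
        )
    result = pool_dl([hedges_g(s) for s in summaries], model=model)
    keep = result.ci_low > 0 or result.ci_high < 0
    return result, keep


def write_forest_tsv(effects: Sequence[EffectSize], result: MetaResult, path) -> None:
    """Forest-plot data: one row per study plus a POOLED summary row."""
    import pandas as pd

    rows = [
        {
            "dataset_id": e.dataset_id,
            "g": e.g,
            "ci_low": e.g - Z95 * math.sqrt(e.variance),
            "ci_high": e.g + Z95 * math.sqrt(e.variance),
            "weight_pct": 100.0 * result.weights[e.dataset_id],
        }
        for e in effects
    ]
    rows.append(
        {
            "dataset_id": "POOLED",
            "g": result.pooled,
            "ci_low": result.ci_low,
            "ci_high": result.ci_high,
            "weight_pct": 100.0,
        }
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")
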