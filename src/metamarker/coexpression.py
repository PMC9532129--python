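"""Anchor-gene co-expression screening and Fisher-Z correlation pooling.

Within each cohort every gene is correlated (Pearson) against the anchor
gene; genes passing |r| >= 0.3 at p < 0.05 in at least two datasets are
co-expressed genes (CEGs), split by sign.  For a single gene, per-cohort
correlations are combined on the Fisher-Z scale (z = atanh r,
se = 1/sqrt(n-3)) with DerSimonian-Laird random effects and back-transformed
by tanh — the same pooling machinery used for standardized mean differences,
applied to z.

Correlations default to cancer samples only; co-expression in tumours is the
signal of interest and mixing groups inflates r through the group effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .cohort_io import GROUP_CASE, ExpressionCohort
from .exceptions import DomainError, InfiniteEffectError, InsufficientDataError, LookupError_
from .meta_effect import EffectSize, pool_dl

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationRecord:
    dataset_id: str
    gene: str
    r: float
    p: float
    n: int
    constant: bool = False  # gene had zero variance; r recorded as 0, p = 1


@dataclass
class CEGSet:
    """Anchor-coexpressed genes split by direction, with per-gene support.

    A gene meeting the criteria positively in some datasets and negatively
    in others is assigned to neither set and listed in ``conflicts``.
    """

    positive: set[str]
    negative: set[str]
    support: dict[str, int]
    conflicts: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class PooledCorrelation:
    r_pooled: float
    ci_low: float
    ci_high: float
    z_pooled: float
    k: int


def correlate_anchor(
    cohort: ExpressionCohort,
    anchor: str,
    subset: Literal["all", "cancer_only"] = "cancer_only",
) -> list[CorrelationRecord]:
    """Pearson correlation of every other gene against the anchor.

    p-values from t = r * sqrt((n-2)/(1-r^2)) on n-2 df.  Constant genes get
    r = 0, p = 1 and a ``constant`` flag; a constant anchor is an error.
    """
    if anchor not in cohort.matrix.index:
        raise LookupError_(f"anchor {anchor!r} absent from cohort {cohort.dataset_id}")
    if subset == "cancer_only":
        cols = cohort.group_mask(GROUP_CASE)
    else:
        cols = np.ones(cohort.n_samples, dtype=bool)
    X = cohort.matrix.to_numpy(dtype=float)[:, cols]
    n = X.shape[1]
    if n < 4:
        raise InsufficientDataError(
            f"{cohort.dataset_id}: subset {subset!r} has {n} samples; >= 4 required"
        )
    genes = cohort.matrix.index.to_numpy()
    a = X[genes == anchor][0]
    a_c = a - a.mean()
    a_ss = float(a_c @ a_c)
    if a_ss == 0.0:
        raise DomainError(f"anchor {anchor!r} is constant in cohort {cohort.dataset_id}")

    Xc = X - X.mean(axis=1, keepdims=True)
    ss = (Xc**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ a_c) / np.sqrt(ss * a_ss)
    const = ss == 0.0
    r = np.clip(np.where(const, 0.0, r), -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(const, 1.0, p)

    out = []
    for i, gene in enumerate(genes):
        if gene == anchor:
            continue
        out.append(
            CorrelationRecord(
                dataset_id=cohort.dataset_id,
                gene=str(gene),
                r=float(r[i]),
                p=float(p[i]),
                n=n,
                constant=bool(const[i]),
            )
        )
    return out


def screen_cegs(
    records: Sequence[CorrelationRecord],
    r_min: float = 0.3,
    p_max: float = 0.05,
    min_support: int = 2,
) -> CEGSet:
    """Recurrence screen: a gene is a positive CEG if r >= r_min with
    p < p_max in >= min_support datasets (negative mirrored at -r_min)."""
    datasets = {rec.dataset_id for rec in records}
    if len(datasets) < 2:
        raise InsufficientDataError("screen_cegs needs records from >= 2 datasets")
    pos_count: dict[str, int] = {}
    neg_count: dict[str, int] = {}
    for rec in records:
        if rec.p < p_max:
            if rec.r >= r_min:
                pos_count[rec.gene] = pos_count.get(rec.gene, 0) + 1
            elif rec.r <= -r_min:
                neg_count[rec.gene] = neg_count.get(rec.gene, 0) + 1
    positive = {g for g, c in pos_count.items() if c >= min_support}
    negative = {g for g, c in neg_count.items() if c >= min_support}
    conflicts = sorted(positive & negative)
    if conflicts:
        logger.warning("gene(s) recurrent in both directions excluded: %s", conflicts)
        positive -= set(conflicts)
        negative -= set(conflicts)
    support = {}
    for g in positive:
        support[g] = pos_count[g]
    for g in negative:
        support[g] = neg_count[g]
    return CEGSet(positive=positive, negative=negative, support=support, conflicts=conflicts)


def fisher_z_pool(records: Sequence[CorrelationRecord]) -> PooledCorrelation:
    """Random-effects pooling of correlations on the Fisher-Z scale."""
    if len(records) < 2:
        raise InsufficientDataError("fisher_z_pool needs >= 2 studies")
    for rec in records:
        if rec.n < 4:
            raise InsufficientDataError(f"{rec.dataset_id}: n = {rec.n} < 4 for gene {rec.gene}")
        if abs(rec.r) >= 1.0:
            raise InfiniteEffectError(f"{rec.dataset_id}: |r| = 1 gives infinite Fisher z")
    effects = [
        EffectSize(
            dataset_id=rec.dataset_id,
            g=math.atanh(rec.r),
            variance=1.0 / (rec.n - 3),
            df=rec.n - 2,
        )
        for rec in records
    ]
    res = pool_dl(effects, model="random")
    return PooledCorrelation(
        r_pooled=math.tanh(res.pooled),
        ci_low=math.tanh(res.ci_low),
        ci_high=math.tanh(res.ci_high),
        z_pooled=res.pooled,
        k=len(records),
    )


def write_cegs(cegs: CEGSet, records: Sequence[CorrelationRecord], path) -> None:
    """CEG table: gene, direction, support, median r across qualifying datasets."""
    import pandas as pd

    by_gene: dict[str, list[float]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene, []).append(rec.r)
    rows = []
    for direction, genes in (("positive", cegs.positive), ("negative", cegs.negative)):
        for g in sorted(genes):
            rows.append(
                {
                    "gene": g,
                    "direction": direction,
                    "support": cegs.support[g],
                    "median_r": float(np.median(by_gene.get(g, [np.nan]))),
                }
            )
    pd.DataFrame(rows, columns=["gene", "direction", "support", "median_r"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )
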