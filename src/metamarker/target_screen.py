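"""Differential expression, ChIP-target handling, and the triple intersection.

The candidate-gene screen combines three independent lines of evidence:

1. differential expression — per merged cohort, a moderated t-test on log2
   data (|log2 FC| > 1, BH-adjusted p < 0.05), reconciled across cohorts
   (up if called up in >= 1 cohort and never down), then confirmed by a
   cross-cohort SMD meta-analysis whose 95% CI must exclude zero with the
   matching sign;
2. co-expression with the anchor gene (a :class:`~metamarker.coexpression.CEGSet`);
3. membership in a ChIP-seq target list (regulatory-potential score > 0).

Genes passing all three filters in consistent directions form the
``up + positive + target`` and ``down + negative + target`` result sets;
an audit trail records which filters each candidate passed.

The moderated t shrinks gene-wise variances toward the across-gene median
with a fixed prior weight of 4 degrees of freedom — a deterministic
simplification of the empirical-Bayes fit used by limma-style tools:
s2_mod = (4 * s2_median + df * s2_gene) / (4 + df), tested against
t on df + 4 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import GROUP_CASE, GROUP_CONTROL, ExpressionCohort, StudyCollection
from .exceptions import FormatError, InsufficientDataError
from .meta_effect import MetaResult, gene_smd_screen

logger = logging.getLogger(__name__)

PRIOR_DF = 4.0  # weight of the median-variance shrinkage target


@dataclass(frozen=True)
class DEGRecord:
    dataset_id: str
    gene: str
    log_fc: float
    t_stat: float
    p: float
    p_adj: float

    @property
    def direction(self) -> Literal["up", "down"] | None:
        if self.log_fc > 0:
            return "up"
        if self.log_fc < 0:
            return "down"
        return None


@dataclass(frozen=True)
class TargetGene:
    gene: str
    score: float


@dataclass
class ScreenResult:
    up_pos_target: set[str]
    down_neg_target: set[str]
    audit: pd.DataFrame  # per candidate gene: which filters passed


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def differential_expression(cohort: ExpressionCohort) -> list[DEGRecord]:
    """Moderated t-test of cancer vs control for every gene in one cohort.

    log FC is the group mean difference (data are log2, so a difference is
    a log fold change); p-values are BH-adjusted within the cohort.
    """
    case_mask = cohort.group_mask(GROUP_CASE)
    ctrl_mask = cohort.group_mask(GROUP_CONTROL)
    n1, n0 = int(case_mask.sum()), int(ctrl_mask.sum())
    if n1 < 3 or n0 < 3:
        raise InsufficientDataError(
            f"{cohort.dataset_id}: both groups need >= 3 samples (got {n1}/{n0})"
        )
    X = cohort.matrix.to_numpy(dtype=float)
    xc, x0 = X[:, case_mask], X[:, ctrl_mask]
    log_fc = xc.mean(axis=1) - x0.mean(axis=1)
    df = n1 + n0 - 2
    s2 = ((xc.var(axis=1, ddof=1) * (n1 - 1)) + (x0.var(axis=1, ddof=1) * (n0 - 1))) / df
    s2_med = float(np.median(s2))
    s2_mod = (PRIOR_DF * s2_med + df * s2) / (PRIOR_DF + df)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log_fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=df + PRIOR_DF)
    p_adj = _bh_adjust(p)
    return [
        DEGRecord(
            dataset_id=cohort.dataset_id,
            gene=str(g),
            log_fc=float(log_fc[i]),
            t_stat=float(t[i]),
            p=float(p[i]),
            p_adj=float(p_adj[i]),
        )
        for i, g in enumerate(cohort.matrix.index)
    ]


def call_degs(
    records: Sequence[DEGRecord], logfc_min: float = 1.0, p_adj_max: float = 0.05
) -> tuple[set[str], set[str]]:
    """Reconcile per-cohort DEG calls across cohorts.

    A gene is 'up' if it passes |logFC| > logfc_min and p_adj < p_adj_max in
    the up direction in >= 1 cohort and never passes in the down direction
    (and symmetrically for 'down'); genes significant both ways are dropped.
    """
    up_any: set[str] = set()
    down_any: set[str] = set()
    for rec in records:
        if abs(rec.log_fc) > logfc_min and rec.p_adj < p_adj_max:
            (up_any if rec.log_fc > 0 else down_any).add(rec.gene)
    both = up_any & down_any
    if both:
        logger.warning("gene(s) significant in both directions dropped: %s", sorted(both))
    return up_any - both, down_any - both


def deg_meta_filter(
    collection: StudyCollection, candidates: dict[str, Literal["up", "down"]]
) -> tuple[dict[str, MetaResult], list[dict]]:
    """Keep candidate DEGs whose pooled SMD 95% CI excludes zero with a sign
    matching the called direction.  Returns survivors and a per-gene audit."""
    survivors: dict[str, MetaResult] = {}
    audit: list[dict] = []
    for gene, direction in candidates.items():
        try:
            result, keep = gene_smd_screen(collection, gene)
        except InsufficientDataError:
            audit.append({"gene": gene, "status": "insufficient replication"})
            continue
        sign_ok = (direction == "up" and result.pooled > 0) or (
            direction == "down" and result.pooled < 0
        )
        if keep and sign_ok:
            survivors[gene] = result
            audit.append({"gene": gene, "status": "kept", "pooled_smd": result.pooled})
        else:
            reason = "CI crosses 0" if not keep else "pooled sign contradicts call"
            audit.append({"gene": gene, "status": reason, "pooled_smd": result.pooled})
    return survivors, audit


def read_target_scores(path: str | Path) -> list[TargetGene]:
    """Read a (gene, score) TSV; keep score > 0, dedup by maximum score."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for col in ("gene", "score"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    bad = pd.to_numeric(df["score"], errors="coerce").isna() & df["score"].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise FormatError(f"{path}: non-numeric score at line {line}")
    df["score"] = pd.to_numeric(df["score"])
    df = df.dropna(subset=["score"])
    df = df[df["score"] > 0].groupby("gene", as_index=False)["score"].max()
    return [TargetGene(gene=row.gene, score=float(row.score)) for row in df.itertuples()]


def triple_intersect(
    degs_up: set[str],
    degs_down: set[str],
    cegs,
    targets: Sequence[TargetGene] | set[str],
) -> ScreenResult:
    """Intersect DEGs, CEGs and ChIP targets in matching directions."""
    target_set = {t.gene for t in targets} if targets and not isinstance(targets, set) else set(targets)
    up_result = degs_up & cegs.positive & target_set
    down_result = degs_down & cegs.negative & target_set
    all_genes = sorted(degs_up | degs_down | cegs.positive | cegs.negative | target_set)
    audit = pd.DataFrame(
        {
            "gene": all_genes,
            "deg_up": [g in degs_up for g in all_genes],
            "deg_down": [g in degs_down for g in all_genes],
            "ceg_positive": [g in cegs.positive for g in all_genes],
            "ceg_negative": [g in cegs.negative for g in all_genes],
            "chip_target": [g in target_set for g in all_genes],
            "selected": [g in up_result or g in down_result for g in all_genes],
        }
    )
    return ScreenResult(up_pos_target=up_result, down_neg_target=down_result, audit=audit)


def promoter_overlap(
    peaks: str | Path | Sequence[tuple[str, int, int]],
    tss: pd.DataFrame,
    window: int = 2000,
) -> set[str]:
    """Genes whose promoter window (TSS +/- window bp) overlaps any peak.

    ``peaks`` is a BED path (0-based half-open) or an iterable of
    (chrom, start, end).  ``tss`` has columns gene, chrom, tss_1based,
    strand; the window is symmetric, so strand only matters through which
    coordinate was annotated as the TSS.  All arithmetic is done 0-based
    half-open.
    """
    if isinstance(peaks, (str, Path)):
        intervals = []
        with open(peaks) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise FormatError(f"{peaks}: line {lineno}: fewer than 3 BED fields")
                try:
                    intervals.append((parts[0], int(parts[1]), int(parts[2])))
                except ValueError as exc:
                    raise FormatError(f"{peaks}: line {lineno}: non-integer coordinate") from exc
    else:
        intervals = list(peaks)

    for col in ("gene", "chrom", "tss_1based"):
        if col not in tss.columns:
            raise FormatError(f"TSS table missing column {col!r}")

    hits: set[str] = set()
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    for row in tss.itertuples():
        tss0 = int(row.tss_1based) - 1  # to 0-based
        win_start = max(0, tss0 - window)
        win_end = tss0 + window + 1  # half-open
        for start, end in by_chrom.get(row.chrom, ()):
            if start < win_end and end > win_start:
                hits.add(row.gene)
                break
    return hits


def write_screen_tsv(
    result: ScreenResult,
    smd_results: dict[str, MetaResult],
    deg_support: dict[str, int],
    target_scores: dict[str, float],
    path,
) -> None:
    """Screen output: gene, direction, cohort support, pooled SMD + CI, score."""
    rows = []
    for direction, genes in (("up", result.up_pos_target), ("down", result.down_neg_target)):
        for g in sorted(genes):
            mr = smd_results.get(g)
            rows.append(
                {
                    "gene": g,
                    "direction": direction,
                    "n_cohorts_deg": deg_support.get(g, 0),
                    "pooled_smd": mr.pooled if mr else np.nan,
                    "ci_low": mr.ci_low if mr else np.nan,
                    "ci_high": mr.ci_high if mr else np.nan,
                    "target_score": target_scores.get(g, np.nan),
                }
            )
    cols = ["gene", "direction", "n_cohorts_deg", "pooled_smd", "ci_low", "ci_high", "target_score"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, float_format="%.6f")
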