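"""Diagnostic-accuracy analysis: per-cohort ROC, SROC meta-analysis, Fagan.

Each cohort's continuous marker is summarised by the Mann-Whitney AUC
(P(case > control) + P(tie)/2) and dichotomised at the Youden-optimal
cutoff (max sens + spec - 1, smallest threshold on ties).  The resulting
2x2 tables are pooled: sensitivity and specificity separately on the logit
scale by DerSimonian-Laird random effects, and a summary ROC by the
Moses-Littenberg linear model

    D = a + b * S,   D = logit(TPR) - logit(FPR),  S = logit(TPR) + logit(FPR),

where D is the log diagnostic odds ratio and S a proxy for threshold.
Fagan's nomogram arithmetic turns a pre-test probability and the pooled
likelihood ratios into post-test probabilities.

Orientation is fixed as higher-in-case = positive; a marker that is lower
in cases shows up as AUC < 0.5 rather than being silently flipped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .exceptions import DomainError, InsufficientDataError
from .meta_effect import EffectSize, pool_dl

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RocResult:
    dataset_id: str
    auc: float
    n_case: int
    n_control: int
    youden_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float

    @property
    def band(self) -> Literal["weak", "moderate", "strong"]:
        """Discrimination band: <0.7 weak, 0.7-0.9 moderate, >0.9 strong."""
        if self.auc < 0.7:
            return "weak"
        if self.auc <= 0.9:
            return "moderate"
        return "strong"


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts at a cutoff; cells are real-valued after the 0.5 continuity
    correction applied when any raw cell is zero."""

    dataset_id: str
    tp: float
    fp: float
    fn: float
    tn: float
    corrected: bool = False

    @property
    def sens(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def spec(self) -> float:
        return self.tn / (self.tn + self.fp)


@dataclass(frozen=True)
class DiagMetaResult:
    pooled_sens: float
    sens_ci: tuple[float, float]
    pooled_spec: float
    spec_ci: tuple[float, float]
    lr_pos: float
    lr_neg: float
    sroc_points: list[tuple[float, float]]
    sroc_auc: float
    moses_intercept: float
    moses_slope: float


@dataclass(frozen=True)
class FaganResult:
    pretest: float
    posttest_pos: float
    posttest_neg: float


def roc_auc(
    case_values: Sequence[float], control_values: Sequence[float], dataset_id: str = ""
) -> RocResult:
    """Mann-Whitney AUC and Youden-optimal cutoff for one cohort.

    A sample is called positive when its value is strictly greater than the
    cutoff; candidate cutoffs are the observed values (plus one below the
    minimum so 'everything positive' is reachable).
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if len(case) == 0 or len(control) == 0:
        raise InsufficientDataError("both groups must be non-empty")
    # rank-based Mann-Whitney probability with tie handling
    combined = np.concatenate([case, control])
    ranks = stats.rankdata(combined)
    r_case = ranks[: len(case)].sum()
    auc = (r_case - len(case) * (len(case) + 1) / 2) / (len(case) * len(control))

    candidates = np.unique(combined)
    candidates = np.concatenate([[candidates[0] - 1.0], candidates])
    best_j, best_cut, best_sens, best_spec = -np.inf, candidates[0], 1.0, 0.0
    for cut in candidates:
        sens = float((case > cut).mean())
        spec = float((control <= cut).mean())
        j = sens + spec - 1.0
        if j > best_j + 1e-12:  # strict improvement: ties keep smallest threshold
            best_j, best_cut, best_sens, best_spec = j, float(cut), sens, spec
    return RocResult(
        dataset_id=dataset_id,
        auc=float(auc),
        n_case=len(case),
        n_control=len(control),
        youden_cutoff=best_cut,
        sens_at_cutoff=best_sens,
        spec_at_cutoff=best_spec,
    )


def auc_by_enumeration(case_values: Sequence[float], control_values: Sequence[float]) -> float:
    """Brute-force AUC: average over all (case, control) pairs of
    1[case > control] + 0.5 * 1[tie] (oracle for small inputs)."""
    total = 0.0
    case = list(case_values)
    control = list(control_values)
    for a in case:
        for b in control:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(case) * len(control))


def confusion_at_cutoff(
    case_values: Sequence[float],
    control_values: Sequence[float],
    cutoff: float,
    dataset_id: str = "",
) -> ConfusionTable:
    """2x2 table at a cutoff (positive = value > cutoff); if any cell is
    zero, 0.5 is added to all four cells and the table is flagged."""
    if not math.isfinite(cutoff):
        raise DomainError("cutoff must be finite")
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    tp = float((case > cutoff).sum())
    fn = float((case <= cutoff).sum())
    fp = float((control > cutoff).sum())
    tn = float((control <= cutoff).sum())
    corrected = min(tp, fp, fn, tn) == 0
    if corrected:
        tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
    return ConfusionTable(dataset_id=dataset_id, tp=tp, fp=fp, fn=fn, tn=tn, corrected=corrected)


def _pool_logit(values: list[float], variances: list[float], ids: list[str]):
    effects = [
        EffectSize(dataset_id=i, g=v, variance=var, df=1)
        for i, v, var in zip(ids, values, variances)
    ]
    return pool_dl(effects, model="random")


def pool_diagnostics(tables: Sequence[ConfusionTable]) -> DiagMetaResult:
    """Pool 2x2 tables: logit sens/spec by DL random effects plus a
    Moses-Littenberg SROC curve and its trapezoid AUC.

    The SROC is traced over FPR in (0.005, 0.995) in 200 steps and closed
    at (0,0) and (1,1) for the area computation.  If all S values coincide
    the regression is degenerate and a symmetric SROC (slope 0) is used.
    """
    if len(tables) < 3:
        raise InsufficientDataError("pool_diagnostics needs >= 3 tables")
    ids = [t.dataset_id or str(i) for i, t in enumerate(tables)]
    logit_sens = [float(logit(t.sens)) for t in tables]
    var_sens = [1.0 / t.tp + 1.0 / t.fn for t in tables]
    logit_spec = [float(logit(t.spec)) for t in tables]
    var_spec = [1.0 / t.tn + 1.0 / t.fp for t in tables]

    ms = _pool_logit(logit_sens, var_sens, ids)
    sp = _pool_logit(logit_spec, var_spec, ids)
    pooled_sens = float(expit(ms.pooled))
    pooled_spec = float(expit(sp.pooled))

    tpr = np.array([t.sens for t in tables])
    fpr = np.array([1.0 - t.spec for t in tables])
    D = logit(tpr) - logit(fpr)  # log diagnostic odds ratio
    S = logit(tpr) + logit(fpr)  # threshold proxy
    if np.ptp(S) < 1e-10:
        logger.warning("all S values equal; falling back to symmetric SROC (slope 0)")
        a, b = float(np.mean(D)), 0.0
    else:
        b, a = np.polyfit(S, D, 1)
        a, b = float(a), float(b)

    fpr_grid = np.linspace(0.005, 0.995, 200)
    u = logit(fpr_grid)
    if abs(1.0 - b) < 1e-10:
        tpr_grid = np.full_like(fpr_grid, np.nan)
    else:
        tpr_grid = expit((a + (1.0 + b) * u) / (1.0 - b))
    tpr_grid = np.clip(tpr_grid, 0.0, 1.0)
    points = list(zip(fpr_grid.tolist(), tpr_grid.tolist()))
    x = np.concatenate([[0.0], fpr_grid, [1.0]])
    y = np.concatenate([[0.0], tpr_grid, [1.0]])
    sroc_auc = float(np.trapezoid(y, x))

    return DiagMetaResult(
        pooled_sens=pooled_sens,
        sens_ci=(float(expit(ms.ci_low)), float(expit(ms.ci_high))),
        pooled_spec=pooled_spec,
        spec_ci=(float(expit(sp.ci_low)), float(expit(sp.ci_high))),
        lr_pos=pooled_sens / (1.0 - pooled_spec),
        lr_neg=(1.0 - pooled_sens) / pooled_spec,
        sroc_points=points,
        sroc_auc=sroc_auc,
        moses_intercept=a,
        moses_slope=b,
    )


def fagan(pretest: float, sens: float, spec: float) -> FaganResult:
    """Bayes update of a pre-test probability through the likelihood ratios.

    posttest = odds * LR / (1 + odds * LR) with odds = p/(1-p),
    LR+ = sens/(1-spec) and LR- = (1-sens)/spec.
    """
    for name, p in (("pretest", pretest), ("sens", sens), ("spec", spec)):
        if not 0.0 < p < 1.0:
            raise DomainError(f"{name} must lie strictly inside (0, 1), got {p}")
    odds = pretest / (1.0 - pretest)
    lr_pos = sens / (1.0 - spec)
    lr_neg = (1.0 - sens) / spec
    post_pos = odds * lr_pos / (1.0 + odds * lr_pos)
    post_neg = odds * lr_neg / (1.0 + odds * lr_neg)
    return FaganResult(pretest=pretest, posttest_pos=post_pos, posttest_neg=post_neg)


def write_sroc(result: DiagMetaResult, tsv_path, json_path) -> None:
    """SROC curve as (fpr, tpr) TSV plus a JSON summary of pooled indices."""
    import json

    import pandas as pd

    pd.DataFrame(result.sroc_points, columns=["fpr", "tpr"]).to_csv(
        tsv_path, sep="\t", index=False, float_format="%.6f"
    )
    with open(json_path, "w") as fh:
        json.dump(
            {
                "pooled_sens": result.pooled_sens,
                "pooled_spec": result.pooled_spec,
                "lr_pos": result.lr_pos,
                "lr_neg": result.lr_neg,
                "sroc_auc": result.sroc_auc,
            },
            fh,
            indent=2,
        )
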