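"""Reading, normalising, merging and batch-adjusting expression cohorts.

A *cohort* is one gene-expression matrix (genes x samples, log2 scale after
normalisation) together with a sample sheet assigning every sample to a
``cancer`` or ``control`` group, a dataset and a platform.  Cohorts measured
on the same platform can be merged into one matrix (gene intersection,
sample concatenation) with the original dataset retained as a batch label,
and batch effects removed by a parametric empirical-Bayes location/scale
adjustment that protects the group signal.

File dialects
-------------
Expression matrix: TSV, UTF-8, first column header ``gene_id``, remaining
headers sample ids.  Sample sheet: TSV with columns ``sample_id``, ``group``
(``cancer``/``control``), ``dataset_id``, ``platform_id``.  Writers emit the
same dialects with fixed 6-decimal formatting so round-trips are
bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfoundingError,
    DomainError,
    DuplicateGeneError,
    EmptyJoinError,
    FormatError,
    InsufficientDataError,
    LookupError_,
    ValidationError,
)

logger = logging.getLogger(__name__)

GROUP_CASE = "cancer"
GROUP_CONTROL = "control"
SHEET_COLUMNS = ("sample_id", "group", "dataset_id", "platform_id")

#: Matrices whose maximum exceeds this are treated as unlogged raw intensities.
#: Log2 expression essentially never exceeds 30; a common GEO heuristic.
LOG2_TRIGGER = 30.0


@dataclass(frozen=True)
class GroupSummary:
    """Per-group sample size, mean and SD of one gene in one cohort.

    SDs use the n-1 denominator, the convention for published group
    summaries.
    """

    dataset_id: str
    n_case: int
    mean_case: float
    sd_case: float
    n_control: int
    mean_control: float
    sd_control: float

    def __post_init__(self) -> None:
        if self.n_case < 3 or self.n_control < 3:
            raise ValidationError(
                f"{self.dataset_id}: each group needs >= 3 samples "
                f"(got {self.n_case} case / {self.n_control} control)"
            )
        if self.sd_case < 0 or self.sd_control < 0:
            raise ValidationError(f"{self.dataset_id}: negative SD")


@dataclass
class ExpressionCohort:
    """One expression matrix plus its sample sheet.

    ``matrix`` is a genes x samples DataFrame indexed by gene id; ``samples``
    holds one row per matrix column, in column order.  ``batch`` optionally
    labels sub-batches inside a merged cohort (the original dataset ids).
    """

    dataset_id: str
    platform_id: str
    matrix: pd.DataFrame
    samples: pd.DataFrame
    batch: pd.Series | None = None
    log2_transformed: bool = False

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            dupes = self.matrix.index[self.matrix.index.duplicated()].unique()
            raise DuplicateGeneError(f"duplicate gene id(s): {', '.join(map(str, dupes))}")
        if self.matrix.shape[1] != len(self.samples):
            raise ValidationError(
                f"{self.dataset_id}: matrix has {self.matrix.shape[1]} columns "
                f"but sheet lists {len(self.samples)} samples"
            )
        if not (self.matrix.columns == self.samples["sample_id"].to_numpy()).all():
            raise ValidationError(f"{self.dataset_id}: column order disagrees with sheet order")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def group_mask(self, group: str) -> np.ndarray:
        return (self.samples["group"] == group).to_numpy()

    def values_for(self, gene: str, group: str | None = None) -> np.ndarray:
        """Expression values of one gene, optionally restricted to a group."""
        if gene not in self.matrix.index:
            raise LookupError_(f"gene {gene!r} not present in cohort {self.dataset_id}")
        row = self.matrix.loc[gene].to_numpy(dtype=float)
        if group is None:
            return row
        return row[self.group_mask(group)]


@dataclass
class StudyCollection:
    """The unit of the whole pipeline: several cohorts plus the anchor gene."""

    cohorts: list[ExpressionCohort]
    anchor_gene: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.dataset_id for c in self.cohorts]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate dataset ids: {ids}")
        missing = [c.dataset_id for c in self.cohorts if self.anchor_gene not in c.matrix.index]
        if missing:
            raise ValidationError(
                f"anchor gene {self.anchor_gene!r} absent from cohort(s): {', '.join(missing)}"
            )

    def __iter__(self):
        return iter(self.cohorts)

    def __len__(self) -> int:
        return len(self.cohorts)


def _validate_sheet(sheet: pd.DataFrame, path: str | Path = "<sheet>") -> pd.DataFrame:
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing column(s) {missing}")
    bad = set(sheet["group"].unique()) - {GROUP_CASE, GROUP_CONTROL}
    if bad:
        raise FormatError(f"{path}: unknown group label(s) {sorted(bad)}")
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample id(s) {dupes}")
    return sheet


def read_cohort(expression_path: str | Path, sheet_path: str | Path) -> ExpressionCohort:
    """Read a cohort from an expression TSV and a sample-sheet TSV.

    Samples are restricted to the intersection of the two files, in sheet
    order; sheet rows with no matrix column are dropped with a warning.
    """
    expression_path, sheet_path = Path(expression_path), Path(sheet_path)
    mat = pd.read_csv(expression_path, sep="\t", dtype={0: str})
    if mat.columns[0] != "gene_id":
        raise FormatError(f"{expression_path}: first column header must be 'gene_id', got {mat.columns[0]!r}")
    mat = mat.set_index("gene_id")
    if mat.index.has_duplicates:
        dupes = mat.index[mat.index.duplicated()].unique()
        raise DuplicateGeneError(f"{expression_path}: duplicate gene id(s): {', '.join(dupes)}")

    sheet = _validate_sheet(pd.read_csv(sheet_path, sep="\t", dtype=str), sheet_path)

    in_matrix = sheet["sample_id"].isin(mat.columns)
    if not in_matrix.any():
        raise EmptyJoinError(f"no sample id shared between {expression_path} and {sheet_path}")
    dropped = sheet.loc[~in_matrix, "sample_id"].tolist()
    if dropped:
        logger.warning("dropping %d sheet sample(s) absent from matrix: %s", len(dropped), dropped)
    sheet = sheet.loc[in_matrix].reset_index(drop=True)
    mat = mat[sheet["sample_id"].tolist()].astype(float)

    dataset_ids = sheet["dataset_id"].unique()
    platform_ids = sheet["platform_id"].unique()
    return ExpressionCohort(
        dataset_id=dataset_ids[0] if len(dataset_ids) == 1 else expression_path.stem,
        platform_id=platform_ids[0] if len(platform_ids) == 1 else "mixed",
        matrix=mat,
        samples=sheet,
        batch=pd.Series(sheet["dataset_id"].to_numpy(), name="batch") if len(dataset_ids) > 1 else None,
    )


def write_cohort(cohort: ExpressionCohort, expression_path: str | Path, sheet_path: str | Path) -> None:
    """Write the matrix (6-decimal fixed format) and the sheet as TSV."""
    cohort.matrix.to_csv(expression_path, sep="\t", float_format="%.6f", index_label="gene_id")
    cohort.samples[list(SHEET_COLUMNS)].to_csv(sheet_path, sep="\t", index=False)


def ensure_log2(cohort: ExpressionCohort, threshold: float = LOG2_TRIGGER) -> ExpressionCohort:
    """Log2-transform a matrix that looks like raw intensities.

    If the matrix maximum exceeds ``threshold`` every value x becomes
    log2(x + 1) (the pseudocount avoids log 0) and the transform is flagged;
    otherwise the cohort is returned unchanged.  Idempotent: a transformed
    matrix falls below the trigger.
    """
    mx = float(cohort.matrix.to_numpy().max())
    if mx <= threshold:
        return cohort
    if (cohort.matrix.to_numpy() < 0).any():
        raise DomainError(
            f"{cohort.dataset_id}: matrix max {mx:.3g} triggers log2 conversion "
            "but negative values are present"
        )
    return replace(cohort, matrix=np.log2(cohort.matrix + 1.0), log2_transformed=True)


def merge_platform(cohorts: Sequence[ExpressionCohort]) -> ExpressionCohort:
    """Merge >= 2 same-platform cohorts into one matrix.

    Genes are intersected (order of the first cohort), samples concatenated;
    the merged cohort is named after the platform and keeps each sample's
    original dataset id as a batch label.
    """
    if len(cohorts) < 2:
        raise InsufficientDataError("merge_platform needs at least 2 cohorts")
    platforms = {c.platform_id for c in cohorts}
    if len(platforms) > 1:
        raise ValidationError(f"cannot merge across platforms: {sorted(platforms)}")
    common = cohorts[0].matrix.index
    for c in cohorts[1:]:
        common = common.intersection(c.matrix.index, sort=False)
    if len(common) == 0:
        raise EmptyJoinError("gene intersection across cohorts is empty")

    mats, sheets, batches = [], [], []
    for c in cohorts:
        mats.append(c.matrix.loc[common])
        sheets.append(c.samples)
        batches.append(np.repeat(c.dataset_id, c.n_samples))
    platform = cohorts[0].platform_id
    return ExpressionCohort(
        dataset_id=platform,
        platform_id=platform,
        matrix=pd.concat(mats, axis=1),
        samples=pd.concat(sheets, ignore_index=True),
        batch=pd.Series(np.concatenate(batches), name="batch"),
    )


def _combat_parametric(X: np.ndarray, batch_codes: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Parametric empirical-Bayes location/scale adjustment (ComBat-style).

    X is genes x samples.  ``design`` carries the biological covariates
    (group indicator) whose effect must survive the adjustment.  Per-batch
    location (gamma) and scale (delta) parameters are shrunk toward their
    across-gene moments under a normal / inverse-gamma prior, solved by the
    standard fixed-point iteration.
    """
    n_genes, n_samples = X.shape
    batches = np.unique(batch_codes)
    n_batch = len(batches)
    # full design: batch indicators + biological covariates
    B = np.zeros((n_samples, n_batch))
    for j, b in enumerate(batches):
        B[batch_codes == b, j] = 1.0
    n_per_batch = B.sum(axis=0)
    design_full = np.hstack([B, design])

    # per-gene OLS for batch means + covariate effects
    beta, *_ = np.linalg.lstsq(design_full, X.T, rcond=None)  # (n_batch+p) x genes
    grand_mean = (n_per_batch / n_samples) @ beta[:n_batch]  # genes
    cov_effect = (design @ beta[n_batch:]).T  # genes x samples

    resid = X - (design_full @ beta).T
    pooled_var = (resid**2).mean(axis=1)  # genes
    pooled_sd = np.sqrt(np.maximum(pooled_var, 1e-12))

    stand_mean = grand_mean[:, None] + cov_effect
    Z = (X - stand_mean) / pooled_sd[:, None]

    # batch effect estimates on the standardized scale
    gamma_hat = np.stack([(Z[:, batch_codes == b]).mean(axis=1) for b in batches])  # batch x genes
    delta_hat = np.stack(
        [(Z[:, batch_codes == b]).var(axis=1, ddof=1) for b in batches]
    )
    delta_hat = np.maximum(delta_hat, 1e-12)

    # hyperpriors from across-gene moments
    gamma_bar = gamma_hat.mean(axis=1)
    tau2_bar = gamma_hat.var(axis=1, ddof=1)
    v = delta_hat.mean(axis=1)
    s2 = delta_hat.var(axis=1, ddof=1)
    a_prior = (2 * s2 + v**2) / np.maximum(s2, 1e-12)
    b_prior = (v * s2 + v**3) / np.maximum(s2, 1e-12)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for j, b in enumerate(batches):
        nj = int(n_per_batch[j])
        Zj = Z[:, batch_codes == b]
        g_old = gamma_hat[j].copy()
        d_old = delta_hat[j].copy()
        for _ in range(100):
            g_new = (tau2_bar[j] * nj * gamma_hat[j] + d_old * gamma_bar[j]) / (
                tau2_bar[j] * nj + d_old
            )
            ssq = ((Zj - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * ssq + b_prior[j]) / (nj / 2 + a_prior[j] - 1)
            if np.max(np.abs(g_new - g_old)) < 1e-8 and np.max(np.abs(d_new - d_old)) < 1e-8:
                g_old, d_old = g_new, d_new
                break
            g_old, d_old = g_new, d_new
        gamma_star[j] = g_old
        delta_star[j] = np.maximum(d_old, 1e-12)

    Z_adj = Z.copy()
    for j, b in enumerate(batches):
        sel = batch_codes == b
        Z_adj[:, sel] = (Z[:, sel] - gamma_star[j][:, None]) / np.sqrt(delta_star[j])[:, None]
    return Z_adj * pooled_sd[:, None] + stand_mean


def batch_adjust(
    cohort: ExpressionCohort,
    batch: Sequence[str] | None = None,
    group: Sequence[str] | None = None,
) -> ExpressionCohort:
    """Remove additive/multiplicative batch effects, preserving group signal.

    ``batch`` defaults to the cohort's stored batch labels, ``group`` to its
    sheet groups.  A single batch is a no-op.  Each batch needs >= 2 samples
    and must not coincide 1:1 with the group partition (the adjustment would
    silently erase the biology).
    """
    if batch is None:
        if cohort.batch is None:
            return cohort
        batch = cohort.batch.to_numpy()
    batch = np.asarray(batch)
    if group is None:
        group = cohort.samples["group"].to_numpy()
    group = np.asarray(group)
    if len(batch) != cohort.n_samples or len(group) != cohort.n_samples:
        raise ValidationError("batch/group label length must equal sample count")

    levels = np.unique(batch)
    if len(levels) < 2:
        return cohort
    counts = {b: int((batch == b).sum()) for b in levels}
    small = [b for b, n in counts.items() if n < 2]
    if small:
        raise InsufficientDataError(f"batch(es) with < 2 samples: {small}")
    # confounding: every batch contains a single group level
    per_batch_groups = [set(group[batch == b]) for b in levels]
    if all(len(s) == 1 for s in per_batch_groups) and len(set(group)) > 1:
        raise ConfoundingError("batch labels are perfectly confounded with the group partition")

    design = (group == GROUP_CASE).astype(float)[:, None]
    codes = np.searchsorted(levels, batch)
    adjusted = _combat_parametric(cohort.matrix.to_numpy(dtype=float), codes, design)
    return replace(
        cohort,
        matrix=pd.DataFrame(adjusted, index=cohort.matrix.index, columns=cohort.matrix.columns),
    )


def summarize_gene(cohort: ExpressionCohort, gene: str) -> GroupSummary:
    """Group sample sizes, means and SDs (n-1 denominator) for one gene."""
    case = cohort.values_for(gene, GROUP_CASE)
    control = cohort.values_for(gene, GROUP_CONTROL)
    if len(case) == 0 or len(control) == 0:
        raise InsufficientDataError(f"{cohort.dataset_id}: a group is empty for gene {gene!r}")
    return GroupSummary(
        dataset_id=cohort.dataset_id,
        n_case=len(case),
        mean_case=float(np.mean(case)),
        sd_case=float(np.std(case, ddof=1)),
        n_control=len(control),
        mean_control=float(np.mean(control)),
        sd_control=float(np.std(control, ddof=1)),
    )
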