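"""End-to-end orchestration of the marker screen.

``run_pipeline`` wires the stages together — cohort loading/merging →
anchor-gene SMD meta-analysis → diagnostic meta-analysis → co-expression
screen → DEG/target triple intersection — writes all stage outputs
(forest TSV, SROC TSV+JSON, CEG/DEG/screen TSVs) and returns a
machine-readable :class:`Report`.  Every number in the report is
reproducible by calling the corresponding module function directly; the
pipeline adds no computation of its own.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .cohort_io import (
    ExpressionCohort,
    StudyCollection,
    batch_adjust,
    ensure_log2,
    merge_platform,
    read_cohort,
    summarize_gene,
)
from .coexpression import correlate_anchor, fisher_z_pool, screen_cegs, write_cegs
from .exceptions import InsufficientDataError, MetamarkerError, ValidationError
from .meta_diagnostic import (
    confusion_at_cutoff,
    fagan,
    pool_diagnostics,
    roc_auc,
    write_sroc,
)
from .meta_effect import begg_test, hedges_g, leave_one_out, pool_dl, write_forest_tsv
from .synthetic_data import SimConfig, generate_collection, table1_fixture
from .target_screen import (
    call_degs,
    deg_meta_filter,
    differential_expression,
    read_target_scores,
    triple_intersect,
    write_screen_tsv,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with the published default thresholds."""

    anchor_gene: str = "ARNT2"
    cohorts: list[dict[str, str]] = field(default_factory=list)  # expression/sheet paths
    synthetic: SimConfig | None = None
    fixture: str | None = None  # "table1" -> summary-only mode
    target_scores: str | None = None
    r_min: float = 0.3
    p_max: float = 0.05
    min_support: int = 2
    logfc_min: float = 1.0
    p_adj_max: float = 0.05
    target_score_min: float = 0.0
    pretest: float = 0.20
    promoter_window: int = 2000
    random_effects: bool = True
    coexpression_subset: str = "cancer_only"
    diagnostic_sens: float | None = None  # summary-only mode only
    diagnostic_spec: float | None = None
    seed: int = 0
    out_dir: str = "metamarker_out"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_min <= 1.0:
            raise ValidationError(f"r_min = {self.r_min} outside [0, 1]")
        for name, v in (("p_max", self.p_max), ("p_adj_max", self.p_adj_max)):
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} = {v} outside (0, 1]")
        if not 0.0 < self.pretest < 1.0:
            raise ValidationError(f"pretest = {self.pretest} outside (0, 1)")
        if self.min_support < 1:
            raise ValidationError("min_support must be >= 1")
        if self.logfc_min < 0:
            raise ValidationError("logfc_min must be >= 0")
        if self.promoter_window < 0:
            raise ValidationError("promoter_window must be >= 0")
        if self.coexpression_subset not in ("all", "cancer_only"):
            raise ValidationError(f"unknown coexpression subset {self.coexpression_subset!r}")
        if not self.cohorts and self.synthetic is None and self.fixture is None:
            raise ValidationError("config must provide cohorts, synthetic, or fixture")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SimConfig(**raw["synthetic"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


@dataclass
class Report:
    """Machine-readable record of one pipeline run."""

    version: str
    seed: int
    config: dict
    anchor_meta: dict | None = None
    begg: dict | None = None
    leave_one_out: list | None = None
    roc_table: list | None = None
    diag_meta: dict | None = None
    fagan: dict | None = None
    ceg_counts: dict | None = None
    deg_counts: dict | None = None
    screen_sizes: dict | None = None
    files: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_cohorts(config: PipelineConfig) -> StudyCollection:
    """Load, log2-normalise, merge same-platform cohorts and batch-adjust."""
    if config.synthetic is not None:
        collection, _ = generate_collection(config.synthetic)
        return collection
    raw = [ensure_log2(read_cohort(c["expression"], c["sheet"])) for c in config.cohorts]
    by_platform: dict[str, list[ExpressionCohort]] = {}
    for c in raw:
        by_platform.setdefault(c.platform_id, []).append(c)
    cohorts = []
    for platform, members in by_platform.items():
        if len(members) == 1:
            cohorts.append(members[0])
        else:
            merged = merge_platform(members)
            logger.info("merged %d cohorts into %s; removing batch effects", len(members), platform)
            cohorts.append(batch_adjust(merged))
    return StudyCollection(cohorts=cohorts, anchor_gene=config.anchor_gene)


def run_pipeline(config: PipelineConfig) -> Report:
    """Execute all stages; on any stage error remove partial outputs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report = Report(version=__version__, seed=config.seed, config=_config_echo(config))
    try:
        if config.fixture == "table1":
            _stage_summary_only(config, report, out_dir, written)
        else:
            truth = None
            if config.synthetic is not None:
                collection, truth = _stage("load", generate_collection, config.synthetic)
            else:
                collection = _stage("load", load_cohorts, config)
            _stage_anchor_meta(collection, report, out_dir, written)
            _stage_diagnostics(collection, config, report, out_dir, written)
            _stage_coexpression(collection, config, report, out_dir, written)
            _stage_screen(collection, config, report, out_dir, written, truth=truth)
        report_path = out_dir / "report.json"
        with open(report_path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        report.files["report"] = str(report_path)
        return report
    except MetamarkerError:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _stage(name: str, fn, *args):
    try:
        return fn(*args)
    except MetamarkerError as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc


def _config_echo(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("synthetic") is not None:
        d["synthetic"]["cohort_sizes"] = [list(x) for x in d["synthetic"]["cohort_sizes"]]
    return d


def _meta_to_dict(mr) -> dict:
    return {
        "model": mr.model,
        "pooled": mr.pooled,
        "se": mr.se,
        "ci_low": mr.ci_low,
        "ci_high": mr.ci_high,
        "Q": mr.Q,
        "df_Q": mr.df_Q,
        "p_Q": mr.p_Q,
        "I2": mr.I2,
        "tau2": mr.tau2,
        "weights": mr.weights,
    }


def _stage_summary_only(config, report, out_dir, written) -> None:
    """Meta-analysis from the built-in group summaries only (no matrices)."""
    summaries = table1_fixture()
    effects = [hedges_g(s) for s in summaries]
    model = "random" if config.random_effects else "fixed"
    result = _stage("meta_effect", pool_dl, effects, model)
    report.anchor_meta = _meta_to_dict(result)
    b = begg_test(effects)
    report.begg = {"kendall_tau": b.kendall_tau, "p": b.p, "n_studies": b.n_studies}
    report.leave_one_out = [
        {"omitted": ds, "pooled": mr.pooled, "ci_low": mr.ci_low, "ci_high": mr.ci_high}
        for ds, mr in leave_one_out(effects, model=model)
    ]
    forest = out_dir / "forest.tsv"
    write_forest_tsv(effects, result, forest)
    written.append(forest)
    report.files["forest"] = str(forest)
    if config.diagnostic_sens is not None and config.diagnostic_spec is not None:
        fr = fagan(config.pretest, config.diagnostic_sens, config.diagnostic_spec)
        report.fagan = {
            "pretest": fr.pretest,
            "posttest_pos": fr.posttest_pos,
            "posttest_neg": fr.posttest_neg,
        }


def _stage_anchor_meta(collection, report, out_dir, written) -> None:
    summaries = [summarize_gene(c, collection.anchor_gene) for c in collection]
    effects = [hedges_g(s) for s in summaries]
    result = _stage("meta_effect", pool_dl, effects, "random")
    report.anchor_meta = _meta_to_dict(result)
    b = begg_test(effects)
    report.begg = {"kendall_tau": b.kendall_tau, "p": b.p, "n_studies": b.n_studies}
    report.leave_one_out = [
        {"omitted": ds, "pooled": mr.pooled, "ci_low": mr.ci_low, "ci_high": mr.ci_high}
        for ds, mr in leave_one_out(effects)
    ]
    forest = out_dir / "forest.tsv"
    write_forest_tsv(effects, result, forest)
    written.append(forest)
    report.files["forest"] = str(forest)


def _stage_diagnostics(collection, config, report, out_dir, written) -> None:
    rocs, tables = [], []
    for cohort in collection:
        case = cohort.values_for(collection.anchor_gene, "cancer")
        control = cohort.values_for(collection.anchor_gene, "control")
        rr = roc_auc(case, control, dataset_id=cohort.dataset_id)
        rocs.append(rr)
        tables.append(
            confusion_at_cutoff(case, control, rr.youden_cutoff, dataset_id=cohort.dataset_id)
        )
    report.roc_table = [
        {
            "dataset_id": r.dataset_id,
            "auc": r.auc,
            "band": r.band,
            "youden_cutoff": r.youden_cutoff,
            "sens": r.sens_at_cutoff,
            "spec": r.spec_at_cutoff,
        }
        for r in rocs
    ]
    dm = _stage("meta_diagnostic", pool_diagnostics, tables)
    report.diag_meta = {
        "pooled_sens": dm.pooled_sens,
        "sens_ci": list(dm.sens_ci),
        "pooled_spec": dm.pooled_spec,
        "spec_ci": list(dm.spec_ci),
        "lr_pos": dm.lr_pos,
        "lr_neg": dm.lr_neg,
        "sroc_auc": dm.sroc_auc,
    }
    fr = fagan(config.pretest, dm.pooled_sens, dm.pooled_spec)
    report.fagan = {
        "pretest": fr.pretest,
        "posttest_pos": fr.posttest_pos,
        "posttest_neg": fr.posttest_neg,
    }
    sroc_tsv, sroc_json = out_dir / "sroc.tsv", out_dir / "sroc_summary.json"
    write_sroc(dm, sroc_tsv, sroc_json)
    written += [sroc_tsv, sroc_json]
    report.files["sroc"] = str(sroc_tsv)
    report.files["sroc_summary"] = str(sroc_json)


def _stage_coexpression(collection, config, report, out_dir, written) -> None:
    records = []
    for cohort in collection:
        try:
            records.extend(
                correlate_anchor(cohort, collection.anchor_gene, subset=config.coexpression_subset)
            )
        except InsufficientDataError as exc:
            logger.warning("skipping cohort in co-expression stage: %s", exc)
    cegs = _stage(
        "coexpression", screen_cegs, records, config.r_min, config.p_max, config.min_support
    )
    report.ceg_counts = {
        "positive": len(cegs.positive),
        "negative": len(cegs.negative),
        "conflicts": len(cegs.conflicts),
    }
    path = out_dir / "cegs.tsv"
    write_cegs(cegs, records, path)
    written.append(path)
    report.files["cegs"] = str(path)
    report._cegs = cegs  # stage handoff, not serialized
    report._correlations = records


def _stage_screen(collection, config, report, out_dir, written, truth=None) -> None:
    import pandas as pd

    deg_records = []
    for cohort in collection:
        deg_records.extend(differential_expression(cohort))
    up, down = call_degs(deg_records, logfc_min=config.logfc_min, p_adj_max=config.p_adj_max)
    candidates = {g: "up" for g in up} | {g: "down" for g in down}
    survivors, audit = _stage("deg_meta_filter", deg_meta_filter, collection, candidates)
    up_final = {g for g in up if g in survivors}
    down_final = {g for g in down if g in survivors}
    report.deg_counts = {
        "up_called": len(up),
        "down_called": len(down),
        "up_after_smd_filter": len(up_final),
        "down_after_smd_filter": len(down_final),
    }
    deg_path = out_dir / "degs.tsv"
    pd.DataFrame(audit).to_csv(deg_path, sep="\t", index=False)
    written.append(deg_path)
    report.files["degs"] = str(deg_path)

    if config.target_scores is not None:
        targets = read_target_scores(config.target_scores)
        targets = [t for t in targets if t.score > config.target_score_min]
    elif truth is not None:
        # synthetic run without an external target table: use the generator's
        # own ChIP-target evidence so the screen remains end-to-end
        from .synthetic_data import target_table_from_truth
        from .target_screen import TargetGene

        tt = target_table_from_truth(truth, collection.cohorts[0].gene_ids, seed=config.seed)
        targets = [
            TargetGene(gene=row.gene, score=float(row.score))
            for row in tt.itertuples()
            if row.score > config.target_score_min
        ]
    else:
        targets = []
    cegs = getattr(report, "_cegs")
    screen = triple_intersect(up_final, down_final, cegs, targets)
    report.screen_sizes = {
        "up_pos_target": len(screen.up_pos_target),
        "down_neg_target": len(screen.down_neg_target),
    }
    deg_support: dict[str, int] = {}
    for rec in deg_records:
        if abs(rec.log_fc) > config.logfc_min and rec.p_adj < config.p_adj_max:
            deg_support[rec.gene] = deg_support.get(rec.gene, 0) + 1
    screen_path = out_dir / "screen.tsv"
    write_screen_tsv(
        screen,
        survivors,
        deg_support,
        {t.gene: t.score for t in targets},
        screen_path,
    )
    written.append(screen_path)
    report.files["screen"] = str(screen_path)


def pooled_anchor_correlation(collection: StudyCollection, gene: str, subset: str = "cancer_only"):
    """Pool the anchor-vs-gene correlation across all cohorts (Fisher Z).

    Cohorts whose selected subset is too small for a finite Fisher-Z
    standard error (n < 4) are skipped with a warning.
    """
    records = []
    for cohort in collection:
        try:
            for rec in correlate_anchor(cohort, collection.anchor_gene, subset=subset):
                if rec.gene == gene:
                    records.append(rec)
        except InsufficientDataError as exc:
            logger.warning("skipping cohort in correlation pooling: %s", exc)
    return fisher_z_pool(records)
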