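"""Synthetic multi-cohort expression data with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
K independent cohorts of approximately Gaussian log2-scale expression with

* shared per-gene baseline means mu_g ~ Normal(7, 1.5^2),
* an additive per-cohort batch offset ~ Normal(0, batch_sd^2),
* an *anchor* gene shifted by delta * noise_sd in cancer samples (so the
  planted effect equals delta on the SMD scale),
* a block of genes correlated with the anchor at a target Pearson rho via a
  shared per-sample latent factor (loading rho, residual SD
  sqrt(1 - rho^2), both scaled by noise_sd),
* planted differentially expressed genes with a specified log2 fold change
  added to cancer samples.

Up-regulated DEGs are placed inside the positively-correlated block (a
transcription-factor target that responds to the factor is also
co-expressed with it); down-regulated DEGs carry a negative loading of the
same magnitude.  Both sets are the "regulated" ground truth for the
end-to-end screen.  Generation is fully reproducible from the seed.

Also ships the built-in nine-row fixture of published per-cohort group
summaries (n / mean / SD for cancer and control) used throughout the
worked examples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import ExpressionCohort, GroupSummary, StudyCollection
from .exceptions import ValidationError

#: (dataset_id, n_case, mean_case, sd_case, n_control, mean_control, sd_control)
#: Published per-cohort anchor-gene (ARNT2) group summaries: nine cohorts,
#: 308 nasopharyngeal-carcinoma and 66 control samples in total.  Merged
#: cohorts are named by platform (GPL570 = GSE64634+GSE34573+GSE12452,
#: GPL11154 = GSE68799+GSE63381+GSE102349).
_TABLE1_ROWS = (
    ("GPL570", 58, 7.83, 1.02, 17, 6.41, 0.91),
    ("GPL11154", 159, 3.50, 0.72, 4, 2.24, 1.25),
    ("GSE13597", 25, 6.18, 1.03, 3, 4.54, 1.08),
    ("GSE39826", 3, 6.89, 0.04, 3, 4.11, 0.53),
    ("GSE40290", 25, 1.38, 0.96, 8, -0.70, 0.72),
    ("GSE53819", 18, 12.79, 0.92, 18, 11.40, 0.42),
    ("GSE61218", 10, 7.56, 0.56, 6, 4.98, 0.74),
    ("GSE118719", 7, 5.40, 1.61, 4, 3.12, 0.96),
    ("GSE126683", 3, 6.95, 0.14, 3, 7.06, 0.14),
)

#: Default per-cohort (n_case, n_control) pairs: the nine published sizes.
TABLE1_SIZES: tuple[tuple[int, int], ...] = tuple((r[1], r[4]) for r in _TABLE1_ROWS)

ANCHOR_ID = "ANCHOR"


def table1_fixture() -> list[GroupSummary]:
    """The nine published per-cohort group summaries of the anchor gene."""
    return [
        GroupSummary(
            dataset_id=d,
            n_case=n1,
            mean_case=m1,
            sd_case=s1,
            n_control=n0,
            mean_control=m0,
            sd_control=s0,
        )
        for d, n1, m1, s1, n0, m0, s0 in _TABLE1_ROWS
    ]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the published study conditions: nine cohorts with the
    published sample sizes, an anchor effect of 1.8 SD units (the reported
    pooled SMD), anchor-target correlation 0.4, and DEG log2 fold change 2
    (comfortably past the |logFC| > 1 screening threshold).
    """

    n_cohorts: int = 9
    cohort_sizes: tuple[tuple[int, int], ...] | None = None  # defaults to TABLE1_SIZES
    n_genes: int = 1000
    anchor_delta: float = 1.8
    target_block_size: int = 50
    target_rho: float = 0.4
    n_deg_up: int = 50
    n_deg_down: int = 50
    deg_logfc: float = 2.0
    batch_sd: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort_sizes is None:
            sizes = tuple(TABLE1_SIZES[i % len(TABLE1_SIZES)] for i in range(self.n_cohorts))
            self.cohort_sizes = sizes
        if len(self.cohort_sizes) != self.n_cohorts:
            raise ValidationError(
                f"cohort_sizes has {len(self.cohort_sizes)} entries for {self.n_cohorts} cohorts"
            )
        if not abs(self.target_rho) < 1.0:
            raise ValidationError(f"|target_rho| must be < 1, got {self.target_rho}")
        for n1, n0 in self.cohort_sizes:
            if n1 < 3 or n0 < 3:
                raise ValidationError(f"each group needs >= 3 samples, got ({n1}, {n0})")
        for name in ("n_genes", "target_block_size", "n_deg_up", "n_deg_down"):
            if getattr(self, name) < 0 or (name == "n_genes" and self.n_genes < 1):
                raise ValidationError(f"{name} must be positive")
        needed = 1 + max(self.target_block_size, self.n_deg_up) + self.n_deg_down
        if self.n_genes < needed:
            raise ValidationError(f"n_genes = {self.n_genes} too small for planted structure ({needed})")
        if self.noise_sd <= 0 or self.batch_sd < 0:
            raise ValidationError("noise_sd must be > 0 and batch_sd >= 0")


@dataclass
class SimTruth:
    """Ground truth of a generated collection."""

    anchor: str
    true_delta: float
    target_rho: dict[str, float]  # gene -> signed latent-factor loading
    deg_logfc: dict[str, float]  # gene -> signed planted log2 FC
    batch_offsets: dict[str, float]  # dataset_id -> additive offset
    regulated_up: set[str] = field(default_factory=set)
    regulated_down: set[str] = field(default_factory=set)

    @property
    def regulated(self) -> set[str]:
        return self.regulated_up | self.regulated_down


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [ANCHOR_ID] + [f"G{i:0{width}d}" for i in range(1, n)]


def generate_collection(config: SimConfig) -> tuple[StudyCollection, SimTruth]:
    """Generate a reproducible multi-cohort collection with planted truth."""
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    genes = _gene_ids(n_genes)

    B, U, D = config.target_block_size, config.n_deg_up, config.n_deg_down
    block_idx = np.arange(1, 1 + B)
    up_idx = np.arange(1, 1 + U)  # overlaps the block where possible
    down_start = 1 + max(B, U)
    down_idx = np.arange(down_start, down_start + D)

    loading = np.zeros(n_genes)
    loading[block_idx] = config.target_rho
    loading[down_idx] = -config.target_rho
    shift = np.zeros(n_genes)
    shift[up_idx] = config.deg_logfc
    shift[down_idx] = -config.deg_logfc

    mu = rng.normal(7.0, 1.5, size=n_genes)  # shared baselines
    batch_offsets = rng.normal(0.0, config.batch_sd, size=config.n_cohorts)

    cohorts = []
    for c, (n1, n0) in enumerate(config.cohort_sizes):
        ds = f"SIM{c + 1}"
        n = n1 + n0
        case = np.zeros(n)
        case[:n1] = 1.0
        f = rng.normal(size=n)  # latent factor = anchor's standardized noise
        eps = rng.normal(size=(n_genes, n))

        X = mu[:, None] + batch_offsets[c] + config.noise_sd * (
            loading[:, None] * f[None, :]
            + np.sqrt(1.0 - loading[:, None] ** 2) * eps
        )
        # the anchor IS the latent factor (loading 1, no residual)
        X[0] = mu[0] + batch_offsets[c] + config.noise_sd * f
        X[0] += config.anchor_delta * config.noise_sd * case
        X += shift[:, None] * case[None, :]

        sample_ids = [f"{ds}_S{i:03d}" for i in range(n)]
        sheet = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": ["cancer"] * n1 + ["control"] * n0,
                "dataset_id": ds,
                "platform_id": f"PL{c + 1}",
            }
        )
        cohorts.append(
            ExpressionCohort(
                dataset_id=ds,
                platform_id=f"PL{c + 1}",
                matrix=pd.DataFrame(X, index=pd.Index(genes, name="gene_id"), columns=sample_ids),
                samples=sheet,
                log2_transformed=True,
            )
        )

    garr = np.asarray(genes)
    truth = SimTruth(
        anchor=ANCHOR_ID,
        true_delta=config.anchor_delta,
        target_rho={genes[i]: float(loading[i]) for i in np.flatnonzero(loading)},
        deg_logfc={genes[i]: float(shift[i]) for i in np.flatnonzero(shift)},
        batch_offsets={f"SIM{c + 1}": float(b) for c, b in enumerate(batch_offsets)},
        regulated_up=set(garr[np.intersect1d(block_idx, up_idx)]) if B and U else set(),
        regulated_down=set(garr[down_idx]) if D else set(),
    )
    return StudyCollection(cohorts=cohorts, anchor_gene=ANCHOR_ID), truth


def target_table_from_truth(
    truth: SimTruth, all_genes: list[str], n_decoys: int = 100, seed: int = 0
) -> pd.DataFrame:
    """A synthetic ChIP-target score table: every regulated gene scores > 0;
    decoys drawn from the remaining genes get scores straddling zero (those
    with score <= 0 must be filtered out downstream)."""
    rng = np.random.default_rng(seed)
    regulated = sorted(truth.regulated)
    others = [g for g in all_genes if g not in truth.regulated and g != truth.anchor]
    decoys = list(rng.choice(others, size=min(n_decoys, len(others)), replace=False))
    rows = [(g, float(rng.uniform(0.5, 5.0))) for g in regulated]
    rows += [(g, float(rng.uniform(-1.0, 2.0))) for g in decoys]
    return pd.DataFrame(rows, columns=["gene", "score"])


def write_collection(
    collection: StudyCollection, truth: SimTruth, out_dir: str | Path
) -> list[Path]:
    """Write each cohort in the standard TSV dialect plus the truth as JSON."""
    from .cohort_io import write_cohort

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for cohort in collection:
        ep = out_dir / f"{cohort.dataset_id}_expression.tsv"
        sp = out_dir / f"{cohort.dataset_id}_samples.tsv"
        write_cohort(cohort, ep, sp)
        paths += [ep, sp]
    tp = out_dir / "truth.json"
    with open(tp, "w") as fh:
        json.dump(
            {
                "anchor": truth.anchor,
                "true_delta": truth.true_delta,
                "target_rho": truth.target_rho,
                "deg_logfc": truth.deg_logfc,
                "batch_offsets": truth.batch_offsets,
                "regulated_up": sorted(truth.regulated_up),
                "regulated_down": sorted(truth.regulated_down),
            },
            fh,
            indent=2,
        )
    paths.append(tp)
    return paths
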