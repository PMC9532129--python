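import numpy as np
import pandas as pd
import pytest

from metamarker.cohort_io import ExpressionCohort


def make_cohort(
    values: np.ndarray,
    genes: list[str],
    groups: list[str],
    dataset_id: str = "DS1",
    platform_id: str = "PL1",
) -> ExpressionCohort:
    """Build a cohort from a genes x samples array and group labels."""
    values = np.asarray(values, dtype=float)
    sample_ids = [f"{dataset_id}_S{i}" for i in range(values.shape[1])]
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": groups,
            "dataset_id": dataset_id,
            "platform_id": platform_id,
        }
    )
    return ExpressionCohort(
        dataset_id=dataset_id,
        platform_id=platform_id,
        matrix=pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sample_ids),
        samples=sheet,
    )


@pytest.fixture
def small_cohort() -> ExpressionCohort:
    """3 genes x 6 samples, 3 cancer + 3 control."""
    rng = np.random.default_rng(0)
    return make_cohort(
        rng.normal(7, 1, size=(3, 6)),
        genes=["GA", "GB", "GC"],
        groups=["cancer"] * 3 + ["control"] * 3,
    )
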