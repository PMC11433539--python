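"""Shared fixtures: tiny hand-written matrices plus generated cohorts.

Everything is built programmatically at test time; the generated cohorts
are session-scoped because several test modules probe different aspects of
the same planted structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coexpath import (
    CountMatrix,
    ExpressionMatrix,
    SampleAnnotations,
    synthetic_data,
)


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes × 4 samples with simple round numbers."""
    df = pd.DataFrame(
        [[10, 20, 10, 12], [0, 0, 1, 0], [100, 90, 110, 95]],
        index=["GENE_A", "GENE_B", "GENE_C"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return CountMatrix(df)


@pytest.fixture
def tiny_annotations() -> SampleAnnotations:
    df = pd.DataFrame(
        {
            "group": ["lesional", "lesional", "healthy", "healthy"],
            "easi": [22.5, 30.0, np.nan, np.nan],
            "scorad": [48.0, 55.0, np.nan, np.nan],
        },
        index=["S1", "S2", "S3", "S4"],
    )
    return SampleAnnotations(df)


@pytest.fixture(scope="session")
def planted_cohort():
    """Default-structure cohort at reduced gene count: 3 associated modules
    of 100 genes, planted DE genes, 27/27/38 samples."""
    counts, ann, truth = synthetic_data.generate_cohort(n_genes=1500, seed=42)
    return counts, ann, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Global null: no modules, no DE genes, no association."""
    counts, ann, truth = synthetic_data.generate_cohort(
        n_genes=1500, n_modules=0, de_fraction=0.0, assoc_shift=0.0, seed=43
    )
    return counts, ann, truth


def random_expression(n_genes: int, n_samples: int, seed: int) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.normal(5.0, 1.0, size=(n_genes, n_samples)),
        index=[f"G{i}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(df, "test")
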