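"""Shared fixtures: small synthetic cohorts and hand-built toy matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from necsig.io import ExpressionMatrix, SampleAnnotation, SampleSheet
from necsig.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def full_sheet() -> SampleSheet:
    """Complete 7-pair x 2-condition x 3-period design (42 runs)."""
    return SampleSheet(
        SampleAnnotation(
            sample_id=f"{prefix}{pair}{period}",
            condition=cond,
            pair_id=pair,
            period=period,
        )
        for pair in range(1, 8)
        for cond, prefix in (("NEC", "N"), ("control", "C"))
        for period in "ABC"
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced synthetic cohort with a strong planted effect (fast to screen)."""
    config = CohortConfig(
        n_proteins=200,
        n_up_markers=12,
        n_down_markers=12,
        effect_fold=4.0,
        seed=11,
    )
    return generate_cohort(config)


def make_matrix(values: np.ndarray, mask: np.ndarray | None = None,
                sample_ids: list[str] | None = None,
                genes: list[str] | None = None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a dense array for toy tests."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if mask is None:
        mask = np.isnan(values)
    if sample_ids is None:
        sample_ids = [f"S{j}" for j in range(m)]
    ids = [f"P{i:03d}" for i in range(n)]
    if genes is None:
        genes = [f"G{i:03d}" for i in range(n)]
    return ExpressionMatrix(
        protein_ids=np.array(ids, dtype=object),
        gene_symbols=np.array(genes, dtype=object),
        sample_ids=sample_ids,
        values=values,
        missing_mask=np.asarray(mask, dtype=bool),
    )
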