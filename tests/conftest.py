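"""Shared fixtures: handcrafted genotype matrices and a null dataset."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gwasrank.genotype_io import GenotypeMatrix
from gwasrank.synthetic_data import SimulationConfig, simulate_dataset


def make_gm(
    calls,
    phenotype=None,
    chromosome=None,
    position=None,
    covariates: dict | None = None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a markers x samples call array."""
    calls = np.asarray(calls, dtype=np.int8)
    m, n = calls.shape
    markers = pd.DataFrame({
        "marker_id": [f"m{j}" for j in range(m)],
        "chromosome": chromosome if chromosome is not None else ["1"] * m,
        "position_bp": position if position is not None else
        [1000 * (j + 1) for j in range(m)],
        "allele_ref": ["A"] * m,
        "allele_alt": ["G"] * m,
    })
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "phenotype": phenotype if phenotype is not None else [-9] * n,
    })
    if covariates:
        for name, values in covariates.items():
            samples[name] = values
    return GenotypeMatrix(markers, samples, calls)


@pytest.fixture(scope="session")
def null_dataset() -> GenotypeMatrix:
    """No-effect case-control dataset: 500 markers, 600 samples, fixed seed."""
    config = SimulationConfig(
        n_cases=300, n_controls=300, n_markers=500, seed=11, missing_rate=0.0
    )
    return simulate_dataset(config)


def ranking_from_order(order: list[str]) -> pd.Series:
    """Ranking series (marker -> rank, 1 = best) from a best-first order."""
    return pd.Series(range(1, len(order) + 1), index=order, dtype=int)


def random_ranking(rng: np.random.Generator, n: int) -> pd.Series:
    ids = [f"snp{i}" for i in range(n)]
    return pd.Series(rng.permutation(n) + 1, index=ids)
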