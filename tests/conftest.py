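"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import trafficsem as ts


@pytest.fixture(scope="session")
def small_dataset() -> ts.SyntheticDataset:
    """~310 visits over two years; default generative truth."""
    cfg = ts.CohortConfig(
        n_participants=150,
        study_start="2004-01-01",
        study_end="2005-12-31",
        seed=42,
    )
    return ts.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_big_dataset() -> ts.SyntheticDataset:
    """~10,000 visits with no traffic effect on either outcome."""
    truth = ts.GenerativeTruth(gamma_traffic=0.0, delta_traffic=0.0)
    cfg = ts.CohortConfig(
        n_participants=4800,
        study_start="2002-01-01",
        study_end="2006-12-31",
        seed=7,
        truth=truth,
    )
    return ts.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_design(small_dataset) -> "pd.DataFrame":  # noqa: F821
    return small_dataset.model_design()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
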