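"""Shared fixtures: reduced-scale synthetic cohorts and feature tables.

Simulation studies in the suite use paper-sized groups but shortened
recordings (3 resting epochs, 10 pulses, 500 Hz) so that many cohorts can
be generated; the light preprocessing chain skips ICA because these cohorts
carry no injected artifacts.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tmseegdx.cohort import generate_cohort
from tmseegdx.config import reduced_cohort
from tmseegdx.experiment import build_feature_table
from tmseegdx.features import FeatureTable
from tmseegdx.preprocess import PreprocConfig

LIGHT_CFG = PreprocConfig(run_ica=False)


@pytest.fixture(scope="session")
def light_cfg() -> PreprocConfig:
    return LIGHT_CFG


@pytest.fixture(scope="session")
def planted_tables() -> list[FeatureTable]:
    """Feature tables of ten planted cohorts (n=60/60, five effects, d=1.2)."""
    return [
        build_feature_table(generate_cohort(reduced_cohort(seed=s)), LIGHT_CFG)
        for s in range(10)
    ]


@pytest.fixture(scope="session")
def null_tables_30() -> list[FeatureTable]:
    """Four 30/30 cohorts with empty effect tables (null calibration)."""
    return [
        build_feature_table(
            generate_cohort(reduced_cohort(seed=s, n_per_group=30,
                                           effect_table=())), LIGHT_CFG)
        for s in (100, 101, 102, 103)
    ]


@pytest.fixture(scope="session")
def null_table_30(null_tables_30) -> FeatureTable:
    return null_tables_30[0]


@pytest.fixture(scope="session")
def fast_null_table() -> FeatureTable:
    """A 12/12 null cohort for permuted-label cross-validation checks."""
    spec = reduced_cohort(seed=200, n_per_group=12, effect_table=())
    return build_feature_table(generate_cohort(spec), LIGHT_CFG)


def synthetic_table(n_per_group: int = 15, n_noise: int = 20, seed: int = 0,
                    extra: dict | None = None) -> FeatureTable:
    """A FeatureTable of Gaussian noise features plus optional named columns."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    ids = [f"S{i:03d}" for i in range(n)]
    labels = pd.Series(["MDD"] * n_per_group + ["HC"] * n_per_group, index=ids)
    data = {f"RST_power_N{i}_alpha": rng.standard_normal(n) for i in range(n_noise)}
    if extra:
        data.update(extra)
    values = pd.DataFrame(data, index=ids)
    covs = pd.DataFrame({
        "age": rng.uniform(20, 60, n), "MADRS": rng.uniform(0, 40, n),
        "STAI_state": rng.uniform(20, 70, n), "STAI_trait": rng.uniform(20, 70, n),
        "MMSE": rng.uniform(25, 30, n),
    }, index=ids)
    return FeatureTable(values, labels, covs)


@pytest.fixture
def make_table():
    return synthetic_table
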