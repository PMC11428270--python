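from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cafscreen import ExpressionMatrix
from cafscreen.simulate import (
    ANCHOR_PROBE,
    HOUSEKEEPING_PROBE,
    SimulationParams,
    simulate_cohort,
    write_fixture_suite,
)


def make_matrix(values, probes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples))


def paired_annotation(n_tumors: int, subtypes=None) -> pd.DataFrame:
    rows = []
    for i in range(n_tumors):
        tid = f"T{i + 1:02d}"
        sub = subtypes[i] if subtypes else "unknown"
        rows.append((f"{tid}_str", tid, "stroma", sub))
        rows.append((f"{tid}_epi", tid, "epithelium", sub))
    return pd.DataFrame(rows, columns=["sample_id", "tumor_id", "compartment", "subtype"])


@pytest.fixture(scope="session")
def small_cohort():
    """50-probe stochastic cohort used for oracle-equivalence checks."""
    params = SimulationParams(
        n_tumors=10,
        n_background_genes=35,
        n_block_genes=8,
        n_subtype_block_genes=5,
        n_subtype_tumors=4,
        noise_sigma_log2=0.25,
        seed=101,
    )
    return params, simulate_cohort(params)


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return write_fixture_suite(out)


@pytest.fixture
def anchor_probe():
    return ANCHOR_PROBE


@pytest.fixture
def hk_probe():
    return HOUSEKEEPING_PROBE
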