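import numpy as np
import pandas as pd
import pytest

from itx.deg_stats import ContrastSpec, call_degs
from itx.normalization import (
    compute_cpm,
    filter_low_expression,
    log2_transform,
    quantile_normalize,
)
from itx.synthetic_data import DesignSpec, make_oracle_fixture, simulate_experiment


def normalize_full(cm, filter_low=True):
    """cpm -> (filter) -> log2 -> quantile, the standard stage order."""
    m = compute_cpm(cm)
    if filter_low:
        m = filter_low_expression(m)
    return quantile_normalize(log2_transform(m))


@pytest.fixture(scope="session")
def oracle_fixture():
    """The deterministic 6x6 (3 vs 3) matrix plus its frozen statistics."""
    return make_oracle_fixture()


@pytest.fixture(scope="session")
def oracle_normalized(oracle_fixture):
    cm, _ = oracle_fixture
    return normalize_full(cm, filter_low=False)


@pytest.fixture(scope="session")
def oracle_result(oracle_fixture, oracle_normalized):
    cm, _ = oracle_fixture
    contrast = ContrastSpec.from_groups(cm.groups, "grpA", "grpB", seed=7)
    return call_degs(oracle_normalized, contrast)


@pytest.fixture(scope="session")
def small_experiment():
    """One modest simulated experiment with planted signal, shared
    read-only across tests."""
    spec = DesignSpec(
        n_genes=500,
        group_sizes={"ctrl": 4, "treat": 4},
        de_fraction=0.05,
        de_log2fc=2.0,
        dispersion=0.1,
        seed=11,
    )
    cm, truth = simulate_experiment(spec)
    return spec, cm, truth


@pytest.fixture(scope="session")
def small_result(small_experiment):
    _, cm, truth = small_experiment
    m = normalize_full(cm)
    contrast = ContrastSpec.from_groups(cm.groups, "treat", "ctrl", seed=11)
    return call_degs(m, contrast), truth
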