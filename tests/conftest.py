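"""Shared fixtures: synthetic endpoints and trained conformal models.

The heavier simulations are session-scoped so the imbalanced benchmark
endpoint (n=2000, 4 % active) is cross-validated only once for the
whole suite.
"""

import numpy as np
import pytest

from cpqsar.chemistry import AssayDataset
from cpqsar.conformal import MondrianICP
from cpqsar.protocols import run_cp_protocol, run_protocol_comparison, train_forest
from cpqsar.synthetic import GeneratorConfig, make_endpoint_dataset


def make_labeled_dataset(n_active: int, n_inactive: int, name: str = "toy") -> AssayDataset:
    """Minimal dataset with an exact active count (features are noise)."""
    n = n_active + n_inactive
    rng = np.random.default_rng(0)
    y = np.concatenate([np.ones(n_active, int), np.zeros(n_inactive, int)])
    return AssayDataset(
        endpoint_name=name,
        compound_ids=[f"c{i}" for i in range(n)],
        X=rng.normal(size=(n, 3)),
        y=y,
        descriptor_names=["d0", "d1", "d2"],
    )


@pytest.fixture(scope="session")
def benchmark_run():
    """5-fold, 10-iteration Mondrian CP on the default imbalanced endpoint.

    Study conditions: n=2000 compounds, 4 % active, class separation at
    the generator default (forest AUC near 0.9), 200-tree forests.
    """
    dataset = make_endpoint_dataset(GeneratorConfig(seed=7), "benchmark")
    return run_cp_protocol(dataset, seed=7)


@pytest.fixture(scope="session")
def single_icp():
    """One forest + one Mondrian calibration on balanced exchangeable data.

    1000 training, 1000 calibration and 1000 test compounds (about 500
    per class in the test split) for the distribution-free coverage and
    uniformity checks.
    """
    dataset = make_endpoint_dataset(
        GeneratorConfig(n_compounds=3000, active_fraction=0.5, seed=13),
        "balanced",
    )
    act = np.flatnonzero(dataset.y == 1)
    inact = np.flatnonzero(dataset.y == 0)
    train = np.concatenate([act[:500], inact[:500]])
    calib = np.concatenate([act[500:1000], inact[500:1000]])
    test = np.concatenate([act[1000:], inact[1000:]])
    forest = train_forest(dataset.X[train], dataset.y[train], seed=13)
    icp = MondrianICP.calibrate(forest, dataset.X[calib], dataset.y[calib])
    return icp, dataset.X[test], dataset.y[test]


@pytest.fixture(scope="session")
def imbalance_comparison():
    """Naive vs under-sampling forests on a 4 %-active synthetic endpoint."""
    dataset = make_endpoint_dataset(
        GeneratorConfig(n_compounds=1500, active_fraction=0.04, seed=29),
        "imbalanced",
    )
    table = run_protocol_comparison(
        dataset, ["naive", "undersample"], seed=29
    )
    return table.set_index("protocol")


@pytest.fixture(scope="session")
def quick_cp_run():
    """Small, fast CP run for schema/determinism-level checks."""
    dataset = make_endpoint_dataset(
        GeneratorConfig(n_compounds=400, active_fraction=0.1, seed=3),
        "quick",
    )
    return dataset, run_cp_protocol(
        dataset, n_iterations=3, n_trees=50, seed=3
    )
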