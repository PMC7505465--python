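import warnings

import numpy as np
import pandas as pd
import pytest

from tempotraj import (
    ClusterTable,
    ExpressionMatrix,
    PathwayCollection,
    SimulationSpec,
    simulate,
)


@pytest.fixture(autouse=True)
def _quiet_small_sample_warnings():
    """The toy fixtures are deliberately tiny; silence the coarse-estimate
    warnings the library correctly emits for them."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*coarse.*")
        warnings.filterwarnings("ignore", message=".*clusters.*")
        warnings.filterwarnings("ignore", message=".*trivial.*")
        yield


@pytest.fixture
def toy_expression():
    values = np.array(
        [
            [1.0, 3.0, 2.0, 4.0],
            [5.0, 1.0, 6.0, 2.0],
            [0.5, 0.5, 1.5, 1.5],
        ]
    )
    return ExpressionMatrix(values, ["g1", "g2", "g3"], ["c1", "c2", "c3", "c4"])


@pytest.fixture
def toy_labels():
    return ClusterTable(
        cell_to_cluster={"c1": "A", "c2": "A", "c3": "B", "c4": "B"},
        cell_to_timepoint={"c1": 1, "c2": 1, "c3": 2, "c4": 2},
        timepoint_labels=["t0", "t24"],
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default planted-lineage draw, shared across tests."""
    return simulate(SimulationSpec(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """A lighter draw for pipeline-level tests."""
    spec = SimulationSpec(
        seed=3,
        modules={
            "STEM": ([1.0, 0.60, 0.22, 0.08, 0.30, 0.12], 40),
            "PROG": ([0.30, 1.0, 0.55, 0.20, 0.42, 0.18], 40),
            "BRANCHA": ([0.0, 0.22, 0.72, 1.0, 0.04, 0.01], 40),
            "BRANCHB": ([0.06, 0.42, 0.10, 0.03, 0.68, 1.0], 40),
        },
        cells_per_cluster=30,
        background_genes=100,
        n_decoy_sets=5,
    )
    return simulate(spec)


def write_gmt_text(path, sets):
    lines = [f"{name}\tna\t" + "\t".join(genes) for name, genes in sets.items()]
    path.write_text("\n".join(lines) + "\n")
    return path
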