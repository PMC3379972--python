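import numpy as np
import pytest

from rangeflow import dec, geosse, simulate
from rangeflow.trees import parse_newick


@pytest.fixture(scope="session")
def two_area_space():
    return dec.build_state_space(tuple("AB"), 2)


@pytest.fixture(scope="session")
def eight_area_space():
    return dec.build_state_space(tuple("ABCDEFGH"), 3)


@pytest.fixture
def four_tip_chronogram():
    return parse_newick(
        "((t1:0.4,t2:0.4):0.8,(t3:0.9,t4:0.9):0.3):0.0;", mode="chronogram")


@pytest.fixture(scope="session")
def small_oracle_trees():
    """Every binary tree shape with 2-4 tips (one labeling per shape)."""
    shapes = [
        "(t1:1.0,t2:1.0):0.0;",
        "((t1:0.5,t2:0.5):0.7,t3:1.2):0.0;",
        "((t1:0.4,t2:0.4):0.8,(t3:0.9,t4:0.9):0.3):0.0;",
        "(((t1:0.3,t2:0.3):0.4,t3:0.7):0.5,t4:1.2):0.0;",
    ]
    return [parse_newick(s, mode="chronogram") for s in shapes]


@pytest.fixture(scope="session", autouse=True)
def _warm_numba():
    """Compile the ODE/PL kernels once so per-test timings are honest."""
    tree = parse_newick("(t1:1.0,t2:1.0):0.0;", mode="chronogram")
    geosse.geosse_loglik(tree, {"t1": "A", "t2": "A"},
                         geosse.GeoSSEParams(0.2, 0.1, 0.0, 0.05, 0.05,
                                             0.01, 0.01))
    from rangeflow import pldating
    phylo = parse_newick("(t1:0.01,t2:0.01):0.0;", mode="phylogram")
    pldating.fit_pl(phylo, pldating.PLConfig(smoothing=1.0,
                                             calibration_age=1.0, sites=100))
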