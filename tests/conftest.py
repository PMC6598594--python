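import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from phenoflow.network import AND, MAJ, BooleanNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path_net():
    """A -> B -> C plus isolated D."""
    net = BooleanNetwork()
    for n in "ABCD":
        net.add_node(n, MAJ)
    net.add_edge("A", "B", 1)
    net.add_edge("B", "C", 1)
    net.validate()
    return net


@pytest.fixture
def and_net():
    """A and B feed complex C (AND); C activates D."""
    net = BooleanNetwork()
    net.add_node("A", MAJ)
    net.add_node("B", MAJ)
    net.add_node("C", AND)
    net.add_node("D", MAJ)
    net.add_edge("A", "C", 1)
    net.add_edge("B", "C", 1)
    net.add_edge("C", "D", 1)
    net.validate()
    return net


@pytest.fixture
def mutual_activation():
    """Two MAJ nodes activating each other (bistable)."""
    net = BooleanNetwork()
    net.add_node("A", MAJ)
    net.add_node("B", MAJ)
    net.add_edge("A", "B", 1)
    net.add_edge("B", "A", 1)
    net.validate()
    return net
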