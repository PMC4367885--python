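import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mtbkit import InteractionNetwork, MinerParams


@pytest.fixture
def matrix_a() -> InteractionNetwork:
    """Five mRNAs x four miRNAs with one isolated 2x2 exact module."""
    edges = [("m1", "g1"), ("m2", "g1"), ("m1", "g2"), ("m2", "g2"),
             ("m3", "g3"), ("m3", "g4"), ("m4", "g4"), ("m4", "g5")]
    return InteractionNetwork.from_edges(edges)


@pytest.fixture
def matrix_b() -> InteractionNetwork:
    """Seven rows whose signatures run through all non-empty subsets of
    three columns — the extremal construction where every column pair is a
    distinct maximal biclique."""
    sigs = ["001", "010", "011", "100", "101", "110", "111"]
    edges = [(f"m{j + 1}", f"g{i + 1}")
             for i, sig in enumerate(sigs)
             for j, bit in enumerate(sig) if bit == "1"]
    return InteractionNetwork.from_edges(edges)


@pytest.fixture
def matrix_c() -> InteractionNetwork:
    """Three columns over four rows: m1, m2 target g1-g3; m3 targets g1-g4."""
    edges = [("m1", "g1"), ("m1", "g2"), ("m1", "g3"),
             ("m2", "g1"), ("m2", "g2"), ("m2", "g3"),
             ("m3", "g1"), ("m3", "g2"), ("m3", "g3"), ("m3", "g4")]
    return InteractionNetwork.from_edges(edges)


@pytest.fixture
def params() -> MinerParams:
    return MinerParams()


def ids_of(mtb, network):
    """(mRNA ids, miRNA ids) of a module, sorted, for readable assertions."""
    return (tuple(sorted(network.mrna_ids[i] for i in mtb.rows)),
            tuple(sorted(network.mirna_ids[j] for j in mtb.cols)))


@pytest.fixture
def as_ids():
    return ids_of
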