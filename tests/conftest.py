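import numpy as np
import pandas as pd
import pytest

from leafstem import phylo_core as pc
from leafstem import synthetic_data as sd


@pytest.fixture
def three_tip_tree():
    return pc.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip_tree():
    return pc.read_newick("((A:0.5,B:1.2):0.7,(C:0.3,D:0.9):1.1);")


@pytest.fixture
def six_tip_tree():
    return pc.read_newick(
        "(((A:0.2,B:0.4):0.3,(C:0.5,D:0.1):0.2):0.6,(E:0.7,F:0.3):0.5);"
    )


@pytest.fixture
def two_tip_tree():
    return pc.read_newick("(A:1,B:1);")


@pytest.fixture
def yule60():
    return sd.sim_tree(60, seed=7)


def star_tree(n: int, depth: float = 1.0) -> pc.PhyloTree:
    parent = [n] * n + [-1]
    edge = [depth] * n + [0.0]
    labels = [f"t{i}" for i in range(n)]
    return pc.PhyloTree(parent, edge, labels)


@pytest.fixture
def star20():
    return star_tree(20)
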