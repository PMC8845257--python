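import numpy as np
import pytest

from ecomorph import io_formats as iof


@pytest.fixture
def rng():
    return np.random.default_rng(20220214)


@pytest.fixture
def cherry_tree():
    """((A,B),C); with Grafen branch lengths (depth 1)."""
    return iof.grafen_branch_lengths(iof.read_newick("((A,B),C);"))


@pytest.fixture
def cherry_cov(cherry_tree):
    return iof.phylo_vcv(cherry_tree)


def write_csv(path, text):
    path.write_text(text, encoding="utf-8")
    return str(path)


@pytest.fixture
def trait_csv(tmp_path):
    return write_csv(
        tmp_path / "traits.csv",
        "species,v1,v2\nA,1.0,2.0\nB,3.0,4.0\nC,5.0,6.0\n",
    )


@pytest.fixture
def habitat_csv(tmp_path):
    return write_csv(
        tmp_path / "habitat.csv",
        "species,d1,d2,d3\nA,1,0,1\nB,0,1,0\n",
    )
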