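import numpy as np
import pytest

from phylocv.alignment import Alignment
from phylocv.tree import Phylogeny, tree_from_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def three_taxon_tree():
    return tree_from_newick("((A:0.1,B:0.1):0.05,C:0.2);")


@pytest.fixture
def four_taxon_tree():
    return tree_from_newick("((A:0.12,B:0.08):0.1,C:0.25,D:0.15);")


@pytest.fixture
def tiny_alignment():
    return Alignment.from_sequences([
        ("A", "ACGTAC"),
        ("B", "ACGTTC"),
        ("C", "ACGAAC"),
    ])


def one_leaf_tree(name: str = "A") -> Phylogeny:
    """A degenerate single-taxon 'tree' for base-case likelihood checks."""
    return Phylogeny(parent=np.array([-1]), children=[[]],
                     lengths=np.array([0.0]), names=[name], root=0)
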