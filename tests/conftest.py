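import numpy as np
import pytest

from gcbias.codon import CodonAlignment, Tree

SMALL_TREE = "((sp1:0.1,sp2:0.1)anc12:0.05,sp3:0.15)root;"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tree():
    return Tree.from_newick(SMALL_TREE)


def make_alignment(gene_id="g1", tree=None, **rows):
    """Build a CodonAlignment from keyword rows; node names starting with
    'anc'/'root' become ancestors."""
    sequences = {k: v for k, v in rows.items() if not k.startswith(("anc", "root"))}
    ancestors = {k: v for k, v in rows.items() if k.startswith(("anc", "root"))}
    return CodonAlignment(gene_id, sequences, ancestors, tree)


@pytest.fixture
def trio_alignment(small_tree):
    # sp1 differs from its ancestor anc12 by one synonymous change (GGG->GGA)
    return make_alignment(
        tree=small_tree,
        sp1="GGAAAATTT",
        sp2="GGGAAATTT",
        sp3="GGGAAATTT",
        anc12="GGGAAATTT",
        root="GGGAAATTT",
    )
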