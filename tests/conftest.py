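import numpy as np
import pytest

from netcoal import parse_network, simulate_gene_tree

# Inputs used throughout: a hybridization network with a symbolic hybrid tag
# (inheritance probability supplied separately) ...
HYBRID_SYMBOLIC = "((((B,C)s1)h1#H1,A)s2,(h1#H1,D)s3)r;"
# ... the same topology with branch lengths making it ultrametric ...
HYBRID_SYMBOLIC_LENGTHS = (
    "((((B:1,C:1)s1:1)h1#H1:1,A:3)s2:1,(h1#H1:1,D:3)s3:1)r;"
)
# ... and a 7-tip network with an inline inheritance probability after '#'.
HYBRID_INLINE = (
    "(((((((6:.1,7:.1)s_6:.4,2:.5)s_1:1.1,3:1.6)s_2:3.3,4:4.9)s_3:2)"
    "h_2#.5:1.41,5:8.31)s_4:0.1,(1:7.2,h_2#.5:.3)s_5:1.21)r;"
)


@pytest.fixture
def rng():
    return np.random.default_rng(20150915)


@pytest.fixture
def hybrid_net():
    return parse_network(HYBRID_SYMBOLIC, inheritance_probs={"h1": 0.6})


@pytest.fixture
def hybrid_net_with_lengths():
    return parse_network(HYBRID_SYMBOLIC_LENGTHS, inheritance_probs={"h1": 0.6})


@pytest.fixture
def inline_net():
    return parse_network(HYBRID_INLINE)


@pytest.fixture
def random_gene_trees(rng):
    """Factory: Kingman genealogies of random size from one population."""
    single = parse_network("A;")

    def make(count, min_tips=2, max_tips=8):
        trees = []
        for _ in range(count):
            n = int(rng.integers(min_tips, max_tips + 1))
            trees.append(simulate_gene_tree(single, n, rng))
        return trees

    return make
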