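import dendropy
import numpy as np
import pytest

from traitniche import SymmetricDistanceMatrix


def random_symmetric(n, rng, labels=None):
    """Random non-negative symmetric distance matrix (not additive)."""
    a = rng.random((n, n))
    a = 0.5 * (a + a.T)
    np.fill_diagonal(a, 0.0)
    labels = labels or [f"s{i:02d}" for i in range(1, n + 1)]
    return SymmetricDistanceMatrix(a, labels)


def caterpillar_tree(n=13, inner=0.5, tip=1.0):
    """Fixed fully imbalanced (ladder) tree with n leaves.

    Deterministic: leaf t01 hangs off the root, each subsequent leaf one
    internal node deeper — the most unbalanced shape possible, giving
    strongly structured expected trait covariance under Brownian motion.
    """
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    node = tree.seed_node
    for i in range(1, n):
        leaf = dendropy.Node(taxon=ns.require_taxon(f"t{i:02d}"))
        leaf.edge.length = tip + (n - i) * inner
        node.add_child(leaf)
        if i < n - 1:
            nxt = dendropy.Node()
            nxt.edge.length = inner
            node.add_child(nxt)
            node = nxt
        else:
            last = dendropy.Node(taxon=ns.require_taxon(f"t{n:02d}"))
            last.edge.length = tip + inner
            node.add_child(last)
    tree.is_rooted = True
    return tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
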