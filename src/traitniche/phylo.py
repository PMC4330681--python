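"""Distance-based phylogeny: pairwise sequence distances, neighbor-joining,
bootstrap support and patristic distances.

The tree container is a :class:`dendropy.Tree`; FASTA parsing goes through
Biopython. The neighbor-joining agglomeration itself is implemented here so
that tie-breaking is deterministic (lowest (row, column) index pair wins in
the Q-criterion) and negative branch-length estimates are clamped to zero
with the deficit logged — both needed for reproducible tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np
from Bio import SeqIO

from .distances import SymmetricDistanceMatrix
from .errors import ValidationError

__all__ = [
    "Alignment",
    "pairwise_distance",
    "neighbor_joining",
    "nj_bootstrap",
    "patristic_matrix",
    "tree_splits",
    "read_newick",
    "write_newick",
]

logger = logging.getLogger(__name__)

_ALPHABET = set("ACGTN-")
_CODE = {c: i for i, c in enumerate("ACGT")}  # A=0 G... transitions A<->G, C<->T


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment over {A, C, G, T, -, N}."""

    taxa: tuple
    sequences: tuple

    def __post_init__(self):
        taxa = tuple(str(t) for t in self.taxa)
        seqs = tuple(str(s).upper() for s in self.sequences)
        object.__setattr__(self, "taxa", taxa)
        object.__setattr__(self, "sequences", seqs)
        if len(taxa) != len(seqs):
            raise ValidationError("one sequence per taxon required")
        if len(set(taxa)) != len(taxa):
            raise ValidationError("duplicate taxon labels")
        if len(taxa) < 3:
            raise ValidationError("alignment needs at least 3 taxa")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValidationError("sequences must all have the same length")
        if lengths == {0}:
            raise ValidationError("empty alignment")
        bad = set("".join(seqs)) - _ALPHABET
        if bad:
            raise ValidationError(f"invalid characters in alignment: {sorted(bad)}")

    @property
    def n_taxa(self):
        return len(self.taxa)

    @property
    def n_sites(self):
        return len(self.sequences[0])

    @classmethod
    def from_fasta(cls, path):
        """Read a (possibly line-wrapped, mixed-case) FASTA alignment."""
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls(tuple(r.id for r in records), tuple(str(r.seq) for r in records))

    def resample_sites(self, rng):
        """Bootstrap replicate: columns resampled with replacement."""
        cols = rng.integers(0, self.n_sites, size=self.n_sites)
        mat = np.array([list(s) for s in self.sequences])
        return Alignment(self.taxa, tuple("".join(row) for row in mat[:, cols]))


def _encode(aln: Alignment):
    """Integer-encode sequences; -1 marks gap/N (excluded pairwise)."""
    out = np.full((aln.n_taxa, aln.n_sites), -1, dtype=np.int8)
    for i, s in enumerate(aln.sequences):
        for j, c in enumerate(s):
            out[i, j] = _CODE.get(c, -1)
    return out


def pairwise_distance(aln: Alignment, model="p-distance") -> SymmetricDistanceMatrix:
    """Pairwise genetic distances under p-distance or Kimura 2-parameter.

    Columns with a gap or N in either sequence of a pair are deleted for
    that pair. K2P uses d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)) with P, Q the
    transition and transversion proportions.
    """
    if model not in ("p-distance", "K2P"):
        raise ValueError(f"unknown distance model: {model!r}")
    enc = _encode(aln)
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = enc[i], enc[j]
            ok = (a >= 0) & (b >= 0)
            m = int(ok.sum())
            if m == 0:
                raise ValidationError(
                    f"no comparable sites between {aln.taxa[i]} and {aln.taxa[j]}"
                )
            diff = a[ok] != b[ok]
            if model == "p-distance":
                d[i, j] = d[j, i] = diff.sum() / m
            else:
                # transitions are A<->G (codes 0, 2) and C<->T (codes 1, 3)
                ts = int((diff & ((a[ok] % 2) == (b[ok] % 2))).sum())
                tv = int(diff.sum()) - ts
                p_, q_ = ts / m, tv / m
                arg1, arg2 = 1.0 - 2.0 * p_ - q_, 1.0 - 2.0 * q_
                if arg1 <= 0 or arg2 <= 0:
                    raise ValidationError(
                        f"K2P undefined for {aln.taxa[i]} vs {aln.taxa[j]} "
                        "(too divergent); consider p-distance"
                    )
                d[i, j] = d[j, i] = -0.5 * math.log(arg1 * math.sqrt(arg2))
    return SymmetricDistanceMatrix(d, list(aln.taxa))


def _clamp(x, what):
    if x < 0:
        logger.info("clamped negative branch length %.3g on %s to 0", x, what)
        return 0.0
    return x


def neighbor_joining(d: SymmetricDistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Returns an unrooted :class:`dendropy.Tree` whose patristic distances
    reproduce the input exactly (up to float error) whenever the input is
    additive. Ties in the Q-criterion are broken toward the lowest
    (row, column) pair; negative branch-length estimates are clamped to 0.
    """
    if d.n_species < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    if np.isnan(d.values).any():
        raise ValidationError("distance matrix contains NA entries")
    D = d.values.copy()
    ns = dendropy.TaxonNamespace(list(d.species))
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for label in d.species:
        node = dendropy.Node(taxon=ns.get_taxon(label))
        nodes.append(node)

    while len(nodes) > 2:
        r = len(nodes)
        row_sums = D.sum(axis=1)
        q = (r - 2) * D - row_sums[:, None] - row_sums[None, :]
        iu = np.triu_indices(r, k=1)
        flat = np.full((r, r), np.inf)
        flat[iu] = q[iu]
        i, j = np.unravel_index(np.argmin(flat), flat.shape)  # row-major first min
        li = 0.5 * D[i, j] + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = _clamp(li, "join")
        nodes[j].edge.length = _clamp(lj, "join")
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        D[i, :] = d_new
        D[:, i] = d_new
        D[i, i] = 0.0
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        nodes[i] = parent
        del nodes[j]

    a, b = nodes
    if a.is_leaf():  # keep the internal node as the seed so leaves stay leaves
        a, b = b, a
    a.add_child(b)
    b.edge.length = _clamp(D[0, 1], "final edge")
    tree.seed_node = a
    tree.is_rooted = False
    return tree


def patristic_matrix(tree: dendropy.Tree) -> SymmetricDistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distance matrix of a tree."""
    leaves = [lf for lf in tree.leaf_node_iter()]
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            name = node.taxon.label if node.taxon else "internal node"
            raise ValidationError(f"missing branch length on edge above {name}")
    labels = [lf.taxon.label for lf in leaves]
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(
                leaves[i].taxon, leaves[j].taxon
            )
    return SymmetricDistanceMatrix(out, labels)


def tree_splits(tree: dendropy.Tree):
    """Non-trivial bipartitions of the leaf set, as canonical frozensets.

    Each internal edge splits the leaves in two; the side *not* containing
    the lexicographically smallest leaf label is used as the canonical
    representative, making the set comparable across differently rooted
    representations of the same unrooted topology.
    """
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(all_leaves)
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = all_leaves - below if ref in below else below
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.add(side)
    return splits


def nj_bootstrap(aln: Alignment, n_reps=100, seed=None,
                 model="p-distance") -> dendropy.Tree:
    """Point-estimate NJ tree with bootstrap support on internal nodes.

    Sites are resampled with replacement per replicate; support is the
    percentage of replicate NJ trees containing each internal split of the
    point-estimate tree. Replicates where a pair has no comparable sites
    are dropped (and logged). Supports are stored as node labels.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = neighbor_joining(pairwise_distance(aln, model))
    rng = np.random.default_rng(seed)
    counts = {s: 0 for s in tree_splits(tree)}
    n_ok = 0
    for _ in range(n_reps):
        rep = aln.resample_sites(rng)
        try:
            rep_tree = neighbor_joining(pairwise_distance(rep, model))
        except ValidationError as exc:
            logger.warning("bootstrap replicate dropped: %s", exc)
            continue
        n_ok += 1
        rep_splits = tree_splits(rep_tree)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    if n_ok == 0:
        raise ValidationError("all bootstrap replicates failed")

    all_leaves = frozenset(aln.taxa)
    ref = min(all_leaves)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = all_leaves - below if ref in below else below
        if side in counts:
            node.label = f"{100.0 * counts[side] / n_ok:g}"
    return tree


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path):
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)
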