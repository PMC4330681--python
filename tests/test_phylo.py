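import itertools
import math

import numpy as np
import pytest

from traitniche import (
    Alignment,
    SymmetricDistanceMatrix,
    ValidationError,
    neighbor_joining,
    nj_bootstrap,
    pairwise_distance,
    patristic_matrix,
    simulate_tree,
)
from traitniche.phylo import read_newick, tree_splits, write_newick


def aln(**named):
    taxa, seqs = zip(*named.items())
    return Alignment(taxa, seqs)


class TestPairwiseDistance:
    def test_identical_sequences(self):
        a = aln(a="ACGT", b="ACGT", c="ACGT")
        assert np.all(pairwise_distance(a).values == 0)

    def test_single_mismatch_p_distance(self):
        a = aln(a="AAAA", b="AAAT", c="AAAA")
        d = pairwise_distance(a).to_frame()
        assert d.loc["a", "b"] == pytest.approx(0.25)

    def test_k2p_against_hand_formula(self):
        # 10 sites: 2 transitions (A<->G, C<->T), 1 transversion (A<->C)
        a = aln(x="AACAAAAAAA", y="GATCAAAAAA", z="AACAAAAAAA")
        p_, q_ = 2 / 10, 1 / 10
        expected = -0.5 * math.log((1 - 2 * p_ - q_) * math.sqrt(1 - 2 * q_))
        d = pairwise_distance(a, model="K2P").to_frame()
        assert d.loc["x", "y"] == pytest.approx(expected, abs=1e-12)

    def test_gapped_columns_deleted_pairwise(self):
        a = aln(a="AC-T", b="ACNT", c="ACGT")
        d = pairwise_distance(a).to_frame()
        assert d.loc["a", "b"] == 0.0  # 3 comparable identical sites

    def test_no_comparable_sites_names_the_pair(self):
        a = aln(a="A---", b="-CCC", c="ACCC")
        with pytest.raises(ValidationError, match="a.*b|b.*a"):
            pairwise_distance(a)

    def test_permutation_equivariance(self, rng):
        seqs = {f"t{i}": "".join(rng.choice(list("ACGT"), 30)) for i in range(5)}
        d1 = pairwise_distance(aln(**seqs)).to_frame()
        order = list(seqs)[::-1]
        d2 = pairwise_distance(
            Alignment(order, [seqs[k] for k in order])).to_frame()
        assert np.allclose(d1.loc[order, order], d2)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = SymmetricDistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                                    ["A", "B", "C"])
        tree = neighbor_joining(d)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_four_taxon_additive_matrix(self):
        # split AB|CD, leaf branches 1,2,3,4, internal branch 1
        d = SymmetricDistanceMatrix(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            ["A", "B", "C", "D"])
        tree = neighbor_joining(d)
        assert tree_splits(tree) == {frozenset({"C", "D"})}
        recon = patristic_matrix(tree).reindex(d.species)
        assert np.allclose(recon.values, d.values, atol=1e-9)

    def test_recovers_random_synthetic_topologies(self):
        for seed in range(15):
            tree = simulate_tree(5 + seed, seed=seed)
            d = patristic_matrix(tree)
            nj = neighbor_joining(d)
            assert tree_splits(nj) == tree_splits(tree)
            recon = patristic_matrix(nj).reindex(d.species)
            assert np.allclose(recon.values, d.values, atol=1e-9)

    def test_matches_scikit_bio_topology(self, rng):
        skbio_tree = pytest.importorskip("skbio.tree")
        from skbio import DistanceMatrix

        tree = simulate_tree(8, seed=3)
        d = patristic_matrix(tree)
        ours = neighbor_joining(d)
        theirs = skbio_tree.nj(DistanceMatrix(d.values, d.species))
        their_splits = set()
        labels = frozenset(d.species)
        ref = min(labels)
        for node in theirs.non_tips(include_self=False):
            below = frozenset(t.name for t in node.tips())
            side = labels - below if ref in below else below
            if 2 <= len(side) <= len(labels) - 2:
                their_splits.add(side)
        assert tree_splits(ours) == their_splits

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            neighbor_joining(SymmetricDistanceMatrix([[0, 1], [1, 0]], ["a", "b"]))


class TestPatristic:
    def test_path_sums_on_known_tree(self):
        d = SymmetricDistanceMatrix(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            ["A", "B", "C", "D"])
        tree = neighbor_joining(d)
        m = patristic_matrix(tree).to_frame()
        assert m.loc["A", "C"] == pytest.approx(5.0)  # 1 + 1 + 3
        assert m.loc["A", "A"] == 0.0

    def test_brute_force_path_sum_oracle(self):
        """Patristic distances equal summed edge lengths along node paths."""
        tree = simulate_tree(7, seed=9)
        # oracle: distance to root for every node, then d(i,j) via the MRCA
        depth = {tree.seed_node: 0.0}
        for node in tree.preorder_node_iter():
            if node is not tree.seed_node:
                depth[node] = depth[node.parent_node] + node.edge.length
        leaves = list(tree.leaf_node_iter())
        m = patristic_matrix(tree).to_frame()
        for a, b in itertools.combinations(leaves, 2):
            mrca = tree.mrca(taxa=[a.taxon, b.taxon])
            expected = depth[a] + depth[b] - 2 * depth[mrca]
            assert m.loc[a.taxon.label, b.taxon.label] == pytest.approx(expected)

    def test_four_point_condition_and_metric_axioms(self):
        tree = simulate_tree(8, seed=5)
        m = patristic_matrix(tree)
        v, labels = m.values, m.species
        assert np.all(v >= 0) and np.allclose(v, v.T)
        for i, j, k in itertools.combinations(range(len(labels)), 3):
            assert v[i, j] <= v[i, k] + v[k, j] + 1e-9
        for q in itertools.combinations(range(len(labels)), 4):
            i, j, k, l = q
            sums = sorted([v[i, j] + v[k, l], v[i, k] + v[j, l],
                           v[i, l] + v[j, k]])
            assert sums[1] == pytest.approx(sums[2], abs=1e-9)

    def test_missing_branch_length_reported(self):
        tree = simulate_tree(5, seed=1)
        next(tree.leaf_node_iter()).edge.length = None
        with pytest.raises(ValidationError, match="branch length"):
            patristic_matrix(tree)


class TestBootstrap:
    def test_pure_repeated_pattern_gives_full_support(self):
        # one informative pattern repeated: resampling cannot change it
        a = Alignment(("a", "b", "c", "d"),
                      ("AAAAAAAAAA", "AAAAAAAAAA", "CCCCCCCCCC", "CCCCCCCCCC"))
        tree = nj_bootstrap(a, n_reps=20, seed=0)
        supports = [n.label for n in tree.preorder_node_iter()
                    if n.label is not None and not n.is_leaf()]
        assert supports and all(s == "100" for s in supports)

    def test_single_replicate_supports_are_binary(self, rng):
        seqs = {f"t{i}": "".join(rng.choice(list("ACGT"), 40)) for i in range(6)}
        tree = nj_bootstrap(Alignment(tuple(seqs), tuple(seqs.values())),
                            n_reps=1, seed=4)
        supports = {float(n.label) for n in tree.preorder_node_iter()
                    if n.label is not None and not n.is_leaf()}
        assert supports <= {0.0, 100.0}

    def test_fixed_seed_identical_supports(self, rng):
        seqs = {f"t{i}": "".join(rng.choice(list("ACGT"), 60)) for i in range(6)}
        a = Alignment(tuple(seqs), tuple(seqs.values()))
        t1 = nj_bootstrap(a, n_reps=25, seed=9)
        t2 = nj_bootstrap(a, n_reps=25, seed=9)
        lab = lambda t: sorted(n.label for n in t.preorder_node_iter()
                               if n.label is not None and not n.is_leaf())
        assert lab(t1) == lab(t2)


class TestIO:
    def test_fasta_wrapped_and_case_insensitive(self, tmp_path):
        fa = tmp_path / "a.fasta"
        fa.write_text(">a\nacgt\nACGT\n>b\nACGTAC\nGT\n>c\nACGTACGT\n")
        a = Alignment.from_fasta(fa)
        assert a.n_taxa == 3 and a.n_sites == 8
        assert a.sequences[0] == "ACGTACGT"

    def test_newick_round_trip_preserves_patristic(self, tmp_path):
        tree = simulate_tree(6, seed=2)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        m1 = patristic_matrix(tree)
        m2 = patristic_matrix(back).reindex(m1.species)
        assert np.allclose(m1.values, m2.values)
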