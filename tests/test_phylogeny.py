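import numpy as np
import pandas as pd
import pytest

from ifnscan.phylogeny import (
    Node,
    PhyloTree,
    assign_clade,
    bootstrap_support,
    neighbor_joining,
    parse_newick,
    trim_intracellular,
)


def random_additive_tree(rng, n_leaves):
    """Random binary tree with positive branch lengths; returns (tree, labels)."""
    nodes = [Node(name=f"L{i}", length=float(rng.uniform(0.1, 2.0))) for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=float(rng.uniform(0.1, 2.0)))
        parent.children = [nodes[i], nodes[j]]
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    root.children = nodes
    return PhyloTree(root)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = pd.DataFrame(
            [[0, 2, 4], [2, 0, 6], [4, 6, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = neighbor_joining(d)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == {"A": 0.0, "B": 2.0, "C": 4.0}

    def test_four_taxon_additive_matrix(self):
        # path lengths of ((A:1,B:2):1,(C:3,D:4))
        labels = list("ABCD")
        d = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=labels, columns=labels, dtype=float,
        )
        tree = neighbor_joining(d)
        assert frozenset({"A", "B"}) in {bp for bp in tree.bipartitions()} or \
               frozenset({"C", "D"}) in {bp for bp in tree.bipartitions()}
        pat = tree.patristic()
        assert np.allclose(pat.loc[labels, labels].to_numpy(), d.to_numpy(), atol=1e-9)

    def test_recovers_random_additive_matrices(self):
        rng = np.random.default_rng(101)
        for _ in range(500):
            n = int(rng.integers(4, 9))
            true_tree = random_additive_tree(rng, n)
            d = true_tree.patristic()
            nj = neighbor_joining(d)
            assert np.allclose(nj.patristic().to_numpy(), d.to_numpy(), atol=1e-9)
            assert nj.bipartitions() == true_tree.bipartitions()

    def test_agrees_with_external_nj_on_topology(self):
        # independent cross-check against scikit-bio's NJ implementation
        import skbio

        rng = np.random.default_rng(7)
        true_tree = random_additive_tree(rng, 7)
        d = true_tree.patristic()
        mine = neighbor_joining(d)
        dm = skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        theirs = skbio.tree.nj(dm)
        their_bps = set()
        names = set(d.index)
        anchor = min(names)
        for node in theirs.non_tips():
            side = {t.name for t in node.tips()}
            if 2 <= len(side) <= len(names) - 2:
                their_bps.add(frozenset(names - side if anchor in side else side))
        assert mine.bipartitions() == their_bps

    def test_non_symmetric_matrix_is_error(self):
        d = pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(d)

    def test_fewer_than_three_taxa_is_error(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"), columns=list("AB"), dtype=float)
        with pytest.raises(ValueError):
            neighbor_joining(d)

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = 5
            m = rng.uniform(0.1, 2.0, size=(n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            labels = [f"T{i}" for i in range(n)]
            tree = neighbor_joining(pd.DataFrame(m, index=labels, columns=labels))

            def walk(node):
                assert node.length >= 0
                for c in node.children:
                    walk(c)

            for c in tree.root.children:
                walk(c)


class TestBootstrap:
    # two invariant column patterns separating AB from CD
    MSA = {
        "A": "AAAAAAAAAAAAAAAAAAAAAAAAAWWWWWWWWWWWWWWWWWWWWWWWWW",
        "B": "AAAAAAAAAAAAAAAAAAAAAAAAAWWWWWWWWWWWWWWWWWWWWWWWWW",
        "C": "CCCCCCCCCCCCCCCCCCCCCCCCCDDDDDDDDDDDDDDDDDDDDDDDDD",
        "D": "CCCCCCCCCCCCCCCCCCCCCCCCCHHHHHHHHHHHHHHHHHHHHHHHHH",
    }

    def test_separated_clades_get_full_support(self):
        tree = bootstrap_support(self.MSA, n_reps=100, seed=5)
        supports = [n.support for n in self._internal_nodes(tree)]
        assert supports == [100]

    def test_same_seed_identical(self):
        t1 = bootstrap_support(self.MSA, n_reps=50, seed=9)
        t2 = bootstrap_support(self.MSA, n_reps=50, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_single_replicate_support_is_zero_or_hundred(self):
        tree = bootstrap_support(self.MSA, n_reps=1, seed=2)
        for node in self._internal_nodes(tree):
            assert node.support in (0, 100)

    def test_supports_invariant_under_label_order(self):
        shuffled = {k: self.MSA[k] for k in ["D", "B", "A", "C"]}
        t1 = bootstrap_support(self.MSA, n_reps=40, seed=3)
        t2 = bootstrap_support(shuffled, n_reps=40, seed=3)
        assert {n.support for n in self._internal_nodes(t1)} == {
            n.support for n in self._internal_nodes(t2)
        }

    def test_too_few_columns_is_error(self):
        with pytest.raises(ValueError):
            bootstrap_support({"A": "A", "B": "A", "C": "C"}, n_reps=5, seed=1)

    @staticmethod
    def _internal_nodes(tree):
        out = []

        def walk(node, is_root):
            if node.children and not is_root:
                out.append(node)
            for c in node.children:
                walk(c, False)

        walk(tree.root, True)
        return out


class TestNewick:
    def test_round_trip(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            tree = random_additive_tree(rng, int(rng.integers(4, 8)))
            # attach supports
            def decorate(node):
                for c in node.children:
                    if c.children:
                        c.support = int(rng.integers(0, 101))
                    decorate(c)
            decorate(tree.root)
            back = parse_newick(tree.to_newick())
            assert back.to_newick() == tree.to_newick()
            assert back.bipartitions() == tree.bipartitions()
            assert np.allclose(back.patristic().to_numpy(), tree.patristic().to_numpy(), atol=1e-9)


class TestTrimIntracellular:
    def test_receptor_like_construct(self):
        # 40-residue ectodomain + 20-residue poly-L TM + 30-residue tail
        ecto, tm, tail = "S" * 40, "L" * 20, "S" * 30
        trimmed, warned = trim_intracellular(ecto + tm + tail)
        assert not warned
        assert trimmed == ecto + tm
        assert len(trimmed) == 60

    def test_no_tm_returns_unchanged_with_warning(self):
        protein = "SQNTKDE" * 10
        trimmed, warned = trim_intracellular(protein)
        assert warned and trimmed == protein

    def test_tm_at_c_terminus_unchanged_length(self):
        protein = "S" * 40 + "L" * 20
        trimmed, warned = trim_intracellular(protein)
        assert not warned
        assert trimmed == protein


class TestAssignClade:
    def build_tree(self):
        # ((q:0.1,a1:0.1):1.0,(b1:0.1,b2:0.1):1.0,a2:0.5);
        return parse_newick("((q:0.1,a1:0.1)90:1.0,(b1:0.1,b2:0.1)95:1.0,a2:0.5);")

    def test_query_joins_nearest_group(self):
        tree = self.build_tree()
        groups = {"A": {"a1", "a2"}, "B": {"b1", "b2"}}
        assert assign_clade(tree, "q", groups) == "A"

    def test_single_group(self):
        tree = self.build_tree()
        assert assign_clade(tree, "q", {"only": {"b1"}}) == "only"

    def test_tie_broken_alphabetically(self):
        tree = parse_newick("((q:1,x:1):1,(y1:1,y2:1):1,z:1);")
        groups = {"beta": {"y1"}, "alpha": {"y2"}}
        d = tree.patristic()
        assert d.loc["q", "y1"] == d.loc["q", "y2"]
        assert assign_clade(tree, "q", groups) == "alpha"

    def test_unknown_leaf_is_error(self):
        with pytest.raises(ValueError, match="unknown"):
            assign_clade(self.build_tree(), "nope", {"A": {"a1"}})
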