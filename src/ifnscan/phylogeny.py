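"""Neighbor-joining phylogenetics with bootstrap supports.

Implements the Saitou–Nei neighbor-joining algorithm (consistent on additive
matrices), non-parametric bootstrap over alignment columns, automated
trimming of receptor intracellular tails (everything C-terminal of the last
transmembrane segment is removed before tree building, as is conventional
for class II cytokine receptor phylogenies), and clade assignment of query
leaves to labelled reference groups by mean patristic distance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import distance_matrix
from .protein_features import FeatureParams, find_tm_segments


@dataclass
class Node:
    """A node of an (un)rooted phylogenetic tree."""

    name: str = ""
    length: float = 0.0          # branch length to parent
    support: int | None = None   # bootstrap support of the edge to parent
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]


@dataclass
class PhyloTree:
    """Unrooted NJ tree: a root node with three (or more) children.

    Branch lengths are clamped to be non-negative; bootstrap supports, when
    present, sit on internal edges as integers in [0, 100].
    """

    root: Node

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    # -- bipartitions ------------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each encoded by the side not containing
        the lexicographically smallest leaf (a canonical form)."""
        all_leaves = set(self.leaf_names())
        anchor = min(all_leaves)
        parts: set[frozenset[str]] = set()
        def walk(node: Node) -> set[str]:
            if node.is_leaf:
                return {node.name}
            below = set()
            for c in node.children:
                side = walk(c)
                if 2 <= len(side) <= len(all_leaves) - 2:
                    canon = all_leaves - side if anchor in side else side
                    parts.add(frozenset(canon))
                below |= side
            return below
        walk(self.root)
        return parts

    def _bipartition_nodes(self) -> dict[frozenset[str], Node]:
        all_leaves = set(self.leaf_names())
        anchor = min(all_leaves)
        out: dict[frozenset[str], Node] = {}
        def walk(node: Node) -> set[str]:
            below = set()
            for c in node.children:
                side = walk(c)
                if 2 <= len(side) <= len(all_leaves) - 2:
                    canon = all_leaves - side if anchor in side else side
                    out[frozenset(canon)] = c
                below |= side
            if node.is_leaf:
                return {node.name}
            return below
        walk(self.root)
        return out

    # -- patristic distances ----------------------------------------------
    def patristic(self) -> pd.DataFrame:
        names = sorted(self.leaf_names())
        idx = {n: i for i, n in enumerate(names)}
        D = np.zeros((len(names), len(names)))
        def walk(node: Node) -> dict[int, float]:
            if node.is_leaf:
                return {idx[node.name]: 0.0}
            acc: dict[int, float] = {}
            for c in node.children:
                sub = {k: v + c.length for k, v in walk(c).items()}
                for k1, d1 in acc.items():
                    for k2, d2 in sub.items():
                        D[k1, k2] = D[k2, k1] = d1 + d2
                acc.update(sub)
            return acc
        walk(self.root)
        return pd.DataFrame(D, index=names, columns=names)

    # -- newick ------------------------------------------------------------
    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else str(node.support)
            return f"({inner}){label}:{node.length:.6f}"
        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string with branch lengths and integer internal labels."""
    text = text.strip().rstrip(";")
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if text[pos] == ",":
                    pos += 1
                else:
                    break
            assert text[pos] == ")", f"expected ')' at {pos}"
            pos += 1
        # label
        start = pos
        while pos < len(text) and text[pos] not in ":,()":
            pos += 1
        label = text[start:pos]
        if label:
            if node.children:
                node.support = int(label)
            else:
                node.name = label
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",()":
                pos += 1
            node.length = float(text[start:pos])
        return node

    root = parse_node()
    return PhyloTree(root)


def neighbor_joining(d: pd.DataFrame) -> PhyloTree:
    """Saitou–Nei neighbor joining on a symmetric distance matrix.

    Iteratively joins the pair (i, j) minimizing
    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k),
    with branch lengths from the standard two-point formulas (negative
    lengths clamped to 0). Ties are broken by the lexicographically smallest
    (label_i, label_j) pair, where a merged cluster carries the smallest
    leaf label it contains.
    """
    labels = list(d.index)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = d.to_numpy(dtype=float).copy()
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    nodes = [Node(name=lab) for lab in labels]
    tags = list(labels)  # tie-break label per active cluster

    active = list(range(len(labels)))
    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        best = None
        for a in range(n):
            for b in range(a + 1, n):
                q = (n - 2) * sub[a, b] - R[a] - R[b]
                ta, tb = sorted((tags[active[a]], tags[active[b]]))
                key = (q, ta, tb)
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = D[i, j]
        li = 0.5 * dij + (R[a] - R[b]) / (2 * (n - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = li, lj
        parent.children = [ni, nj]
        # distances from the new node u to every other k
        new_row = 0.5 * (D[i] + D[j] - dij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        u = D.shape[0] - 1
        nodes.append(parent)
        tags.append(min(tags[i], tags[j]))
        active = [k for k in active if k not in (i, j)] + [u]

    # terminal three-cluster star: three-point formulas
    i, j, k = active
    a = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    b = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    c = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = Node()
    for node, ln in zip((nodes[i], nodes[j], nodes[k]), (a, b, c)):
        node.length = max(ln, 0.0)
        root.children.append(node)
    return PhyloTree(root)


def bootstrap_support(
    msa: dict[str, str],
    n_reps: int = 1000,
    seed: int = 0,
    correction: str = "p",
) -> PhyloTree:
    """NJ tree from the full MSA, with bootstrap supports on internal edges.

    Each replicate resamples alignment columns with replacement (seeded),
    recomputes the distance matrix and NJ tree; the support of an internal
    edge is the percentage of replicates whose tree contains the same leaf
    bipartition. Deterministic given (msa, n_reps, seed).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels = sorted(msa)
    L = len(next(iter(msa.values())))
    if L < 2:
        raise ValueError("alignment must have at least 2 columns")
    tree = neighbor_joining(distance_matrix({k: msa[k] for k in labels}, correction))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        resampled = {lab: "".join(msa[lab][c] for c in cols) for lab in labels}
        try:
            rep_tree = neighbor_joining(distance_matrix(resampled, correction))
        except ValueError:  # e.g. saturated poisson distance in a replicate
            continue
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    for bp, node in tree._bipartition_nodes().items():
        node.support = round(100 * counts.get(bp, 0) / n_reps)
    return tree


def trim_intracellular(
    protein: str, params: FeatureParams = FeatureParams()
) -> tuple[str, bool]:
    """Remove the intracellular tail of a receptor-like protein.

    Truncates immediately after the end of the last predicted transmembrane
    segment. Returns (sequence, warning): when no TM segment is found the
    input is returned unchanged with warning=True.
    """
    segments = find_tm_segments(protein, params)
    if not segments:
        return protein, True
    return protein[: segments[-1][1]], False


def assign_clade(
    tree: PhyloTree, query_leaf: str, reference_groups: dict[str, set[str]]
) -> str:
    """Group with minimal mean patristic distance to the query leaf.

    Ties are broken alphabetically by group name.
    """
    pat = tree.patristic()
    if query_leaf not in pat.index:
        raise ValueError(f"unknown leaf {query_leaf!r}")
    best: tuple[float, str] | None = None
    for group in sorted(reference_groups):
        members = reference_groups[group]
        missing = members - set(pat.index)
        if missing:
            raise ValueError(f"unknown reference leaves in group {group!r}: {sorted(missing)}")
        mean_d = float(np.mean([pat.loc[query_leaf, m] for m in members]))
        if best is None or mean_d < best[0] - 1e-12:
            best = (mean_d, group)
    assert best is not None
    return best[1]
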