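"""Shared unrooted-tree utilities built on dendropy.

Trees throughout the package are dendropy :class:`~dendropy.Tree` objects
treated as unrooted; helpers here extract nontrivial bipartitions (as
frozensets of leaf labels or as bitmasks), produce canonical topology
strings for deterministic tie-breaking, enumerate all unrooted binary
topologies for small taxon counts, and resolve induced quartet topologies.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Iterator, Sequence

import dendropy


def read_newick(source) -> dendropy.Tree:
    """Parse a newick string or a path to a newick file."""
    import os

    data = str(source)
    if not data.lstrip().startswith("(") and os.path.exists(data):
        with open(data) as fh:
            data = fh.read()
    tree = dendropy.Tree.get(data=data, schema="newick")
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
    ).strip()


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def _below_sets(tree: dendropy.Tree) -> dict:
    """Map each non-seed node to the frozenset of leaf labels below it."""
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(
                *(below[c] for c in node.child_nodes())
            )
    return below


def nontrivial_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions of the unrooted tree.

    Each split is represented by the side that does *not* contain the
    lexicographically smallest leaf label, so split sets from trees on the
    same leaf set are directly comparable.
    """
    labels = leaf_labels(tree)
    ref = min(labels)
    n = len(labels)
    below = _below_sets(tree)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = below[node]
        if 2 <= len(side) <= n - 2:
            if ref in side:
                side = labels - side
            splits.add(frozenset(side))
    return splits


def split_edge_map(tree: dendropy.Tree) -> dict[frozenset[str], object]:
    """Map each nontrivial split to one representing internal edge."""
    labels = leaf_labels(tree)
    ref = min(labels)
    n = len(labels)
    below = _below_sets(tree)
    out: dict[frozenset[str], object] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = below[node]
        if 2 <= len(side) <= n - 2:
            key = frozenset(labels - side) if ref in side else frozenset(side)
            out.setdefault(key, node.edge)
    return out


def split_masks(
    tree: dendropy.Tree, index: dict[str, int]
) -> list[int]:
    """Nontrivial splits as bitmasks under a caller-supplied label->bit map.

    Masks are normalized so bit 0 of the *tree's own* smallest-index leaf is
    cleared; the caller's index may cover a superset of the tree's taxa.
    """
    present = sorted(index[l] for l in leaf_labels(tree))
    full = 0
    for b in present:
        full |= 1 << b
    ref_bit = 1 << present[0]
    below = _below_sets(tree)
    masks: set[int] = set()
    n = len(present)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = below[node]
        if 2 <= len(side) <= n - 2:
            m = 0
            for label in side:
                m |= 1 << index[label]
            if m & ref_bit:
                m = full & ~m
            masks.add(m)
    return sorted(masks)


def canonical_topology(tree: dendropy.Tree) -> str:
    """Canonical label-only newick for the unrooted topology.

    Two trees yield the same string iff they have the same unrooted
    topology.  The tree is conceptually rooted at its smallest leaf and
    sibling subtrees are sorted by their string representation.
    """
    adj: dict = {}
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        adj.setdefault(edge.tail_node, []).append(edge.head_node)
        adj.setdefault(edge.head_node, []).append(edge.tail_node)
    leaves = {n: n.taxon.label for n in tree.leaf_node_iter()}
    start = min(leaves, key=lambda n: leaves[n])

    def rec(node, parent) -> str:
        kids = [k for k in adj.get(node, []) if k is not parent]
        if not kids:
            return leaves[node]
        if len(kids) == 1:
            # degree-2 node (rooted-representation artifact): pass through
            return rec(kids[0], node)
        parts = sorted(rec(k, node) for k in kids)
        return "(" + ",".join(parts) + ")"

    return f"({leaves[start]},{rec(adj[start][0], start)});"


# ---------------------------------------------------------------------------
# Quartets
# ---------------------------------------------------------------------------

def resolve_quartet(masks: Sequence[int], quartet: Sequence[int]) -> int | None:
    """Induced pairing of a 4-taxon subset given a tree's split masks.

    *quartet* is four bit positions in ascending order.  Returns 0, 1, or 2
    when the smallest taxon pairs with the second, third, or fourth taxon
    respectively, or None when no split resolves the quartet.
    """
    i, j, k, l = quartet
    qmask = (1 << i) | (1 << j) | (1 << k) | (1 << l)
    for m in masks:
        x = m & qmask
        if bin(x).count("1") != 2:
            continue
        if not x & (1 << i):
            x = qmask & ~x
        if x & (1 << j):
            return 0
        if x & (1 << k):
            return 1
        return 2
    return None


# ---------------------------------------------------------------------------
# Topology enumeration (small n)
# ---------------------------------------------------------------------------

def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! for n >= 3."""
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


class _EnumTree:
    """Mutable unrooted tree over integer leaf ids, for stepwise addition."""

    __slots__ = ("edges", "next_node")

    def __init__(self, edges: list[tuple[int, int]], next_node: int):
        self.edges = edges
        self.next_node = next_node

    def copy_with_leaf(self, edge_idx: int, leaf: int) -> "_EnumTree":
        a, b = self.edges[edge_idx]
        mid = self.next_node
        edges = list(self.edges)
        edges[edge_idx] = (a, mid)
        edges.append((mid, b))
        edges.append((mid, leaf))
        return _EnumTree(edges, mid + 1)


def enumerate_topologies(labels: Sequence[str]) -> Iterator[tuple[list[int], str]]:
    """Yield every unrooted binary topology on *labels*.

    For each topology yields ``(masks, canonical)``: the nontrivial split
    bitmasks (bits ordered by the sorted label list) and the canonical
    label-only newick string.  Intended for n <= 8 or so; the count grows as
    (2n-5)!!.
    """
    labels = sorted(labels)
    n = len(labels)
    if n < 4:
        raise ValueError("need >= 4 taxa to enumerate unrooted topologies")
    # leaves are nodes 0..n-1; internal nodes numbered from n upward
    base = _EnumTree([(0, n), (1, n), (2, n)], n + 1)
    stack = [(base, 3)]
    while stack:
        tree, next_leaf = stack.pop()
        if next_leaf == n:
            yield _enum_masks(tree, n), _enum_canonical(tree, labels, n)
            continue
        for ei in range(len(tree.edges)):
            stack.append((tree.copy_with_leaf(ei, next_leaf), next_leaf + 1))


def _enum_adj(tree: _EnumTree) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {}
    for a, b in tree.edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    return adj


def _enum_masks(tree: _EnumTree, n: int) -> list[int]:
    adj = _enum_adj(tree)
    full = (1 << n) - 1
    masks: set[int] = set()

    def below(node: int, parent: int) -> int:
        if node < n:
            return 1 << node
        m = 0
        for nb in adj[node]:
            if nb != parent:
                m |= below(nb, node)
        return m

    for a, b in tree.edges:
        if a < n or b < n:
            continue
        m = below(a, b)
        if m & 1:
            m = full & ~m
        masks.add(m)
    return sorted(masks)


def _enum_canonical(tree: _EnumTree, labels: Sequence[str], n: int) -> str:
    adj = _enum_adj(tree)

    def rec(node: int, parent: int) -> str:
        if node < n:
            return labels[node]
        parts = sorted(rec(nb, node) for nb in adj[node] if nb != parent)
        return "(" + ",".join(parts) + ")"

    return f"({labels[0]},{rec(adj[0][0], 0)});"


def tree_from_masks(
    masks: Iterable[int], labels: Sequence[str]
) -> dendropy.Tree:
    """Build a dendropy tree (no branch lengths) from compatible split masks.

    Bits follow the sorted order of *labels*.  The splits must form a
    laminar family once normalized away from bit 0; incompatible splits
    raise ValueError.
    """
    labels = sorted(labels)
    n = len(labels)
    full = (1 << n) - 1
    clusters = []
    for m in masks:
        if m & 1:
            m = full & ~m
        clusters.append(m)
    clusters = sorted(set(clusters), key=lambda m: (-bin(m).count("1"), m))
    for a, b in combinations(clusters, 2):
        inter = a & b
        if inter and inter != a and inter != b:
            raise ValueError("incompatible splits")

    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    node_for: dict[int, dendropy.Node] = {}

    def place(mask: int) -> dendropy.Node:
        # smallest enclosing cluster strictly containing `mask`
        parent = root
        best = None
        for c in clusters:
            if c == mask:
                continue
            if (c & mask) == mask:
                if best is None or bin(c).count("1") < bin(best).count("1"):
                    best = c
        if best is not None:
            parent = node_for[best]
        return parent

    for c in clusters:  # largest first, so parents exist before children
        node = dendropy.Node()
        place(c).add_child(node)
        node_for[c] = node
    for b, label in enumerate(labels):
        leaf = dendropy.Node(taxon=tns.get_taxon(label))
        place(1 << b).add_child(leaf)
    tree.is_rooted = False
    return tree


def random_binary_tree(
    labels: Sequence[str], rng, with_lengths: bool = True
) -> dendropy.Tree:
    """Uniform random unrooted binary topology via random stepwise addition."""
    labels = list(labels)
    order = list(range(len(labels)))
    rng.shuffle(order)
    tree = _EnumTree([(0, len(labels)), (1, len(labels)), (2, len(labels))],
                     len(labels) + 1)
    # insert in index order but with shuffled labels for uniformity on labels
    for leaf in range(3, len(labels)):
        ei = rng.randrange(len(tree.edges))
        tree = tree.copy_with_leaf(ei, leaf)
    shuffled = [labels[i] for i in order]
    newick = _enum_canonical(tree, shuffled, len(labels))
    out = dendropy.Tree.get(data=newick, schema="newick")
    if with_lengths:
        for edge in out.preorder_edge_iter():
            if edge.tail_node is not None:
                edge.length = 0.1 + rng.random()
    out.is_rooted = False
    return out
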