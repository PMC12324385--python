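"""Per-marker gene trees and treeness/RCV marker ranking.

Each trimmed marker alignment is converted to corrected pairwise distances
(Jukes-Cantor for nucleotides, the analogous 20-state Poisson correction
for amino acids), a neighbor-joining gene tree is built, and the marker is
scored by treeness (internal branch length fraction) over relative
composition variability (RCV).  High treeness/RCV indicates strong
hierarchical signal and homogeneous composition, the properties that make a
marker informative for species-tree inference; markers are ranked by this
score and the top n retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .msa import Alphabet, Msa, TrimmedMsa

#: Cap applied where the distance correction diverges (saturated pairs).
MAX_DISTANCE = 10.0


class GeneFilterError(ValueError):
    """Invalid input to the gene-filtering stage."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances with ordered taxa."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise GeneFilterError(f"distance matrix shape {v.shape} != ({n},{n})")
        if not np.isfinite(v).all():
            raise GeneFilterError("distance matrix has non-finite entries")
        if not np.allclose(v, v.T, atol=1e-12):
            raise GeneFilterError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise GeneFilterError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise GeneFilterError("distances must be >= 0")

    def permuted(self, order: Sequence[str]) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in order]
        return DistanceMatrix(tuple(order), self.values[np.ix_(idx, idx)])


@dataclass(frozen=True)
class ScoredMarker:
    """Treeness, RCV, and their ratio for one marker."""

    marker_id: str
    treeness: float
    rcv: float

    @property
    def score(self) -> float:
        """treeness/RCV; +inf when RCV is exactly 0 (degenerate but total)."""
        if self.rcv == 0.0:
            return math.inf
        return self.treeness / self.rcv


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _corrected_distance(p: float, k: int) -> float:
    """Correct a p-distance under a k-state uniform-exchange model.

    d = -((k-1)/k) * ln(1 - k*p/(k-1)); p at or beyond the domain boundary
    (k-1)/k is capped at :data:`MAX_DISTANCE`.
    """
    boundary = (k - 1) / k
    if p >= boundary:
        return MAX_DISTANCE
    d = -boundary * math.log(1.0 - p / boundary)
    return min(d, MAX_DISTANCE)


def distance_matrix(
    msa: Msa | TrimmedMsa, constant_pad: int = 0
) -> DistanceMatrix:
    """Corrected pairwise distances over shared non-gap columns.

    Nucleotide alignments use the JC69 correction, amino-acid alignments the
    20-state Poisson analogue.  A pair of rows with no shared non-gap column
    is an error (no information to estimate a distance).

    An alignment trimmed to parsimony-informative sites overstates every
    p-distance: the discarded columns are (nearly all) constant, and the
    log corrections amplify the distortion non-uniformly, which is enough
    to mislead neighbor joining.  When the input is a :class:`TrimmedMsa`
    that knows its source length -- or when *constant_pad* is given -- the
    removed columns are restored to the denominator as shared invariant
    sites, recovering distances on the scale of the untrimmed alignment.
    """
    if isinstance(msa, TrimmedMsa):
        constant_pad += msa.n_removed
        msa = msa.msa
    if msa.length < 1 and constant_pad == 0:
        raise GeneFilterError("cannot compute distances on an empty alignment")
    arr = msa.to_array()
    states = set(msa.alphabet.states)
    valid = np.isin(arr, list(states))
    k = msa.alphabet.size
    n = msa.n_rows
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = valid[i] & valid[j]
            m = int(shared.sum()) + constant_pad
            if m == 0:
                raise GeneFilterError(
                    f"taxa {msa.taxa[i]!r} and {msa.taxa[j]!r} share no "
                    f"non-gap columns"
                )
            p = float((arr[i, shared] != arr[j, shared]).sum()) / m
            D[i, j] = D[j, i] = _corrected_distance(p, k)
    return DistanceMatrix(msa.taxa, D)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbor joining with the Q-criterion.

    Ties in the Q-criterion are broken by the lexicographically smallest
    label pair, so the unrooted topology is invariant to taxon input order.
    Negative branch-length estimates are clamped to zero.  On additive
    matrices the generating topology and branch lengths are recovered
    exactly.  Returns an unrooted tree with a basal trifurcation.
    """
    n = len(dm.taxa)
    if n < 4:
        raise GeneFilterError(f"neighbor joining needs >= 4 taxa, got {n}")
    tns = dendropy.TaxonNamespace(sorted(dm.taxa))
    nodes: list[dendropy.Node] = []
    keys: list[str] = []
    for label in dm.taxa:
        nd = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(nd)
        keys.append(label)
    D = dm.values.astype(float).copy()
    active = list(range(n))

    def pair_key(i: int, j: int) -> tuple[str, str]:
        a, b = keys[i], keys[j]
        return (a, b) if a <= b else (b, a)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            ((a, b) for a, b in cand if a < b),
            key=lambda ab: pair_key(active[ab[0]], active[ab[1]]),
        )
        ai, bi = int(best[0]), int(best[1])
        gi, gj = active[ai], active[bi]
        dij = sub[ai, bi]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(0.0, li), max(0.0, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[gi])
        nodes[gi].edge.length = li
        parent.add_child(nodes[gj])
        nodes[gj].edge.length = lj
        new_key = min(keys[gi], keys[gj])
        # distances from the new node to every other active node
        newd = np.zeros(D.shape[0] + 1)
        for other in active:
            if other in (gi, gj):
                continue
            newd[other] = 0.5 * (D[gi, other] + D[gj, other] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newd[:-1]
        D[:-1, -1] = newd[:-1]
        nodes.append(parent)
        keys.append(new_key)
        active = [a for a in active if a not in (gi, gj)] + [len(nodes) - 1]

    # connect the last three nodes through a central (seed) vertex
    a, b, c = active
    root = dendropy.Node()
    for x, y, z in ((a, b, c), (b, a, c), (c, a, b)):
        lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
        root.add_child(nodes[x])
        nodes[x].edge.length = max(0.0, lx)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Treeness and RCV
# ---------------------------------------------------------------------------

def treeness(tree: dendropy.Tree) -> float:
    """Fraction of total branch length on internal branches, in [0, 1].

    An internal branch is one whose bipartition has at least two leaves on
    each side.  A bifurcating root is treated as an artifact of rooted
    representation: its two child edges represent a single branch.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    n = len(leaves)
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = 1
        else:
            below[node] = sum(below[c] for c in node.child_nodes())
    total = 0.0
    internal = 0.0
    seed = tree.seed_node
    seed_children = seed.child_nodes()
    bifurcating_root = len(seed_children) == 2
    counted_root_branch = False
    for node in tree.preorder_node_iter():
        if node is seed:
            continue
        length = node.edge.length or 0.0
        size = below[node]
        if bifurcating_root and node in seed_children:
            # merge the two root-adjacent edges into one branch
            if counted_root_branch:
                sib_size = n - size
                total += length
                if 2 <= size <= n - 2 and 2 <= sib_size <= n - 2:
                    internal += length
                continue
            counted_root_branch = True
        total += length
        if 2 <= size <= n - 2:
            internal += length
    if total <= 0.0:
        raise GeneFilterError("tree has zero total branch length")
    return internal / total


def rcv(msa: Msa | TrimmedMsa) -> float:
    """Relative composition variability of an alignment.

    With c_is the count of state s in row i, c_bar_s the across-row mean,
    n rows and t columns: RCV = sum_i sum_s |c_is - c_bar_s| / (n * t).
    Gaps and ambiguity codes are excluded from the counts.  0 means every
    row has identical composition.
    """
    if isinstance(msa, TrimmedMsa):
        msa = msa.msa
    if msa.length < 1:
        raise GeneFilterError("cannot compute RCV on a zero-length alignment")
    if msa.n_rows < 2:
        raise GeneFilterError("RCV needs >= 2 rows")
    arr = msa.to_array()
    states = np.array(list(msa.alphabet.states), dtype="U1")
    counts = np.stack([(arr == s).sum(axis=1) for s in states]).T  # (n, K)
    mean = counts.mean(axis=0)
    return float(np.abs(counts - mean).sum() / (msa.n_rows * msa.length))


def score_marker(marker_id: str, trimmed: TrimmedMsa) -> ScoredMarker:
    """Score one marker: NJ tree treeness over alignment RCV."""
    tree = neighbor_joining(distance_matrix(trimmed))
    return ScoredMarker(
        marker_id=marker_id,
        treeness=treeness(tree),
        rcv=rcv(trimmed),
    )


def rank_markers(scored: Sequence[ScoredMarker], top_n: int | None = None) -> list[str]:
    """Marker ids in descending score order, ties broken by ascending id.

    Returns all markers when *top_n* is None, else the best
    ``min(top_n, available)``.
    """
    if not scored:
        raise GeneFilterError("no markers to rank")
    if top_n is not None and top_n < 1:
        raise GeneFilterError("top_n must be >= 1")
    ranked = sorted(scored, key=lambda s: (-s.score, s.marker_id))
    ids = [s.marker_id for s in ranked]
    return ids if top_n is None else ids[:top_n]
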