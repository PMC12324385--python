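"""Species-tree inference: quartet consensus and supermatrix concatenation.

Two strategies mirror standard phylogenomic practice.  The consensus
strategy scores candidate species trees by their quartet score -- the
number of 4-taxon subsets on which a candidate agrees with the gene
trees -- and returns a maximizer: by exhaustive search over all (2n-5)!!
unrooted topologies for small taxon counts, or over a documented candidate
set (gene-tree topologies, greedy majority-rule consensus, NJ on mean
gene-tree path distances) above that.  The concatenation strategy joins the
marker alignments into one gap-filled supermatrix with a partition table
and infers a distance tree from it; branch support comes from a standard
nonparametric (Felsenstein) bootstrap, and gene/site concordance factors
quantify per-branch agreement of gene trees and alignment sites.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .genefilter import DistanceMatrix, distance_matrix, neighbor_joining
from .msa import GAP, Alphabet, Msa, TrimmedMsa
from . import trees as _t

DEFAULT_TAXA_LIMIT_EXACT = 8
DEFAULT_BOOTSTRAP_REPLICATES = 100
DEFAULT_QUARTETS_PER_BRANCH = 100


class SpeciesTreeError(ValueError):
    """Invalid input to species-tree inference."""


@dataclass(frozen=True)
class Supermatrix:
    """Concatenated marker alignments with 1-based inclusive partitions.

    ``n_constant_removed`` counts the columns the per-marker trimming
    discarded (summed over markers, when known); distance estimation on the
    supermatrix restores them as shared invariant sites.
    """

    msa: Msa
    partitions: tuple[tuple[str, int, int], ...]
    n_constant_removed: int = 0

    def __post_init__(self):
        expected = 1
        for marker_id, start, end in self.partitions:
            if start != expected or end < start:
                raise SpeciesTreeError(
                    f"partitions must be contiguous; {marker_id} spans "
                    f"{start}-{end}, expected start {expected}"
                )
            expected = end + 1
        if expected != self.msa.length + 1:
            raise SpeciesTreeError("partitions do not cover the alignment")


@dataclass(frozen=True)
class SupportedTree:
    """A species tree with optional per-internal-branch annotations.

    Annotation dicts are keyed by the branch's nontrivial bipartition (the
    frozenset of leaf labels on the side not containing the smallest label);
    values are percentages in [0, 100].  ``scf`` values may be ``None`` for
    branches with no decisive quartet sample.
    """

    tree: dendropy.Tree
    bootstrap: dict | None = None
    gcf: dict | None = None
    scf: dict | None = None


# ---------------------------------------------------------------------------
# Concatenation
# ---------------------------------------------------------------------------

def concatenate(msas: Mapping[str, Msa | TrimmedMsa]) -> Supermatrix:
    """Concatenate marker alignments in ascending marker-id order.

    Taxa absent from a marker are gap-filled across its span; the partition
    table records each marker's 1-based inclusive coordinates.
    """
    if not msas:
        raise SpeciesTreeError("no marker alignments to concatenate")
    plain = {
        mid: (m.msa if isinstance(m, TrimmedMsa) else m)
        for mid, m in msas.items()
    }
    n_removed = sum(
        m.n_removed for m in msas.values() if isinstance(m, TrimmedMsa)
    )
    taxa = sorted(set().union(*(m.taxa for m in plain.values())))
    if len(taxa) < 4:
        raise SpeciesTreeError(f"supermatrix needs >= 4 taxa, got {len(taxa)}")
    alphabet = next(iter(plain.values())).alphabet
    if any(m.alphabet is not alphabet for m in plain.values()):
        raise SpeciesTreeError("marker alignments mix alphabets")
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    partitions = []
    pos = 1
    for mid in sorted(plain):
        m = plain[mid]
        if m.length == 0:
            continue
        rows = dict(m.rows)
        for t in taxa:
            chunks[t].append(rows.get(t, GAP * m.length))
        partitions.append((mid, pos, pos + m.length - 1))
        pos += m.length
    if not partitions:
        raise SpeciesTreeError("all marker alignments are empty")
    sm_msa = Msa(tuple((t, "".join(chunks[t])) for t in taxa), alphabet)
    return Supermatrix(
        msa=sm_msa,
        partitions=tuple(partitions),
        n_constant_removed=n_removed,
    )


def write_phylip(sm: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP supermatrix for external ML tools."""
    with open(path, "w") as fh:
        fh.write(f"{sm.msa.n_rows} {sm.msa.length}\n")
        for taxon, seq in sm.msa.rows:
            fh.write(f"{taxon}  {seq}\n")


def write_partitions(sm: Supermatrix, path: str | Path) -> None:
    """RAxML-style partition table (one substitution model per marker)."""
    model = "GTR" if sm.msa.alphabet is Alphabet.NUCLEOTIDE4 else "LG"
    with open(path, "w") as fh:
        for marker_id, start, end in sm.partitions:
            fh.write(f"{model}, {marker_id} = {start}-{end}\n")


# ---------------------------------------------------------------------------
# Quartet scoring
# ---------------------------------------------------------------------------

def quartet_score(
    species: dendropy.Tree, gene_trees: Sequence[dendropy.Tree]
) -> int:
    """Number of gene-tree quartets whose topology the species tree shares.

    Sums over gene trees the count of 4-taxon subsets (of that gene tree's
    taxa) with the same induced unrooted quartet topology in both trees.
    Gene trees may lack taxa; a gene tree with a taxon absent from the
    species tree is an error.
    """
    sp_labels = sorted(_t.leaf_labels(species))
    index = {l: i for i, l in enumerate(sp_labels)}
    sp_masks = _t.split_masks(species, index)
    total = 0
    for gt in gene_trees:
        gt_labels = sorted(_t.leaf_labels(gt))
        missing = [l for l in gt_labels if l not in index]
        if missing:
            raise SpeciesTreeError(
                f"gene tree taxa absent from species tree: {missing}"
            )
        gt_masks = _t.split_masks(gt, index)
        bits = [index[l] for l in gt_labels]
        for quartet in combinations(bits, 4):
            rg = _t.resolve_quartet(gt_masks, quartet)
            if rg is None:
                continue
            if _t.resolve_quartet(sp_masks, quartet) == rg:
                total += 1
    return total


def _quartet_weights(
    gene_trees: Sequence[dendropy.Tree], index: dict[str, int]
) -> dict[tuple[int, ...], np.ndarray]:
    """For each 4-taxon subset, how many gene trees induce each pairing."""
    weights: dict[tuple[int, ...], np.ndarray] = {}
    for gt in gene_trees:
        bits = sorted(index[l] for l in _t.leaf_labels(gt))
        masks = _t.split_masks(gt, index)
        for quartet in combinations(bits, 4):
            r = _t.resolve_quartet(masks, quartet)
            if r is None:
                continue
            w = weights.setdefault(quartet, np.zeros(3, dtype=np.int64))
            w[r] += 1
    return weights


def _score_masks(
    masks: Sequence[int],
    weights: Mapping[tuple[int, ...], np.ndarray],
) -> int:
    total = 0
    for quartet, w in weights.items():
        r = _t.resolve_quartet(masks, quartet)
        if r is not None:
            total += int(w[r])
    return total


def consensus_species_tree(
    gene_trees: Sequence[dendropy.Tree],
    taxa_limit_exact: int = DEFAULT_TAXA_LIMIT_EXACT,
) -> dendropy.Tree:
    """Quartet-score-maximizing species tree from a set of gene trees.

    For taxon counts up to *taxa_limit_exact* every unrooted binary topology
    is scored and a maximizer returned (ties broken by lexicographically
    smallest canonical newick).  Above the limit, the best of a candidate
    set is returned: every full-coverage gene-tree topology, a greedy
    majority-rule consensus, and an NJ tree on mean gene-tree path
    distances.  The returned tree is topology-only (no branch lengths).
    """
    if len(gene_trees) < 2:
        raise SpeciesTreeError("need >= 2 gene trees")
    labels = sorted(set().union(*(_t.leaf_labels(gt) for gt in gene_trees)))
    if len(labels) < 4:
        raise SpeciesTreeError(f"need >= 4 taxa, got {len(labels)}")
    index = {l: i for i, l in enumerate(labels)}
    weights = _quartet_weights(gene_trees, index)

    best_masks = None
    best_score = -1
    best_canon = None
    if len(labels) <= taxa_limit_exact:
        for masks, canon in _t.enumerate_topologies(labels):
            s = _score_masks(masks, weights)
            if s > best_score or (s == best_score and canon < best_canon):
                best_masks, best_score, best_canon = masks, s, canon
        return _t.tree_from_masks(best_masks, labels)

    candidates: list[dendropy.Tree] = []
    full = frozenset(labels)
    seen: set[str] = set()
    for gt in gene_trees:
        if _t.leaf_labels(gt) == full:
            canon = _t.canonical_topology(gt)
            if canon not in seen:
                seen.add(canon)
                candidates.append(gt)
    greedy = _greedy_consensus(gene_trees, labels)
    if greedy is not None:
        candidates.append(greedy)
    njc = _mean_path_nj(gene_trees, labels)
    if njc is not None:
        candidates.append(njc)
    if not candidates:
        raise SpeciesTreeError("no consensus candidates cover all taxa")
    best = None
    for cand in candidates:
        masks = _t.split_masks(cand, index)
        s = _score_masks(masks, weights)
        canon = _t.canonical_topology(cand)
        if s > best_score or (s == best_score and canon < best_canon):
            best, best_score, best_canon = cand, s, canon
    out = dendropy.Tree.get(data=best_canon, schema="newick")
    out.is_rooted = False
    return out


def _greedy_consensus(
    gene_trees: Sequence[dendropy.Tree], labels: Sequence[str]
) -> dendropy.Tree | None:
    """Greedy majority-rule consensus over full-coverage gene-tree splits."""
    index = {l: i for i, l in enumerate(sorted(labels))}
    full_set = frozenset(labels)
    counts: dict[int, int] = {}
    n_full = 0
    for gt in gene_trees:
        if _t.leaf_labels(gt) != full_set:
            continue
        n_full += 1
        for m in _t.split_masks(gt, index):
            counts[m] = counts.get(m, 0) + 1
    if n_full == 0:
        return None
    chosen: list[int] = []
    n = len(labels)
    fullmask = (1 << n) - 1
    for m in sorted(counts, key=lambda m: (-counts[m], m)):
        ok = True
        for c in chosen:
            inter = m & c
            if inter and inter != m and inter != c and (m | c) != fullmask:
                ok = False
                break
        if ok:
            chosen.append(m)
    try:
        return _t.tree_from_masks(chosen, labels)
    except ValueError:
        return None


def _mean_path_nj(
    gene_trees: Sequence[dendropy.Tree], labels: Sequence[str]
) -> dendropy.Tree | None:
    """NJ on gene-tree path distances averaged over trees sharing each pair."""
    labels = sorted(labels)
    pos = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    for gt in gene_trees:
        pdm = gt.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in gt.taxon_namespace
                if t.label in pos and any(
                    lf.taxon is t for lf in gt.leaf_node_iter())}
        for a, b in combinations(sorted(taxa), 2):
            d = pdm.distance(taxa[a], taxa[b])
            i, j = pos[a], pos[b]
            total[i, j] += d
            total[j, i] += d
            count[i, j] += 1
            count[j, i] += 1
    if (count[np.triu_indices(n, 1)] == 0).any():
        return None
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    np.fill_diagonal(mean, 0.0)
    return neighbor_joining(DistanceMatrix(tuple(labels), mean))


# ---------------------------------------------------------------------------
# Supermatrix tree + bootstrap
# ---------------------------------------------------------------------------

def supermatrix_tree(sm: Supermatrix) -> dendropy.Tree:
    """Distance tree (corrected distances + NJ) on the whole supermatrix.

    Distances account for any constant sites removed by per-marker
    trimming (``sm.n_constant_removed``).
    """
    return neighbor_joining(
        distance_matrix(sm.msa, constant_pad=sm.n_constant_removed)
    )


def bootstrap_support(
    sm: Supermatrix,
    tree: dendropy.Tree,
    replicates: int = DEFAULT_BOOTSTRAP_REPLICATES,
    seed: int = 0,
) -> SupportedTree:
    """Standard nonparametric bootstrap support on internal branches.

    Sites are resampled with replacement across the whole supermatrix, the
    tree is rebuilt per replicate with the same distance+NJ method, and each
    internal branch of *tree* is annotated with the percentage of replicates
    whose tree contains its bipartition.  Reproducible given *seed*.
    """
    if replicates < 1:
        raise SpeciesTreeError("replicates must be >= 1")
    if sm.msa.length < 1:
        raise SpeciesTreeError("cannot bootstrap a zero-length supermatrix")
    rng = np.random.default_rng(seed)
    target = _t.nontrivial_splits(tree)
    hits = {s: 0 for s in target}
    L = sm.msa.length
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        rep = sm.msa.select_columns([int(c) for c in cols])
        rep_tree = neighbor_joining(
            distance_matrix(rep, constant_pad=sm.n_constant_removed)
        )
        rep_splits = _t.nontrivial_splits(rep_tree)
        for s in target:
            if s in rep_splits:
                hits[s] += 1
    support = {s: 100.0 * hits[s] / replicates for s in target}
    return SupportedTree(tree=tree, bootstrap=support)


# ---------------------------------------------------------------------------
# Concordance factors
# ---------------------------------------------------------------------------

def _edge_quadrants(tree: dendropy.Tree):
    """For each internal branch: its split and the four leaf groups around it.

    Yields ``(split_key, (A1, A2, B1, B2))`` where A1/A2 are the leaf sets
    of the two subtrees on the child side and B1/B2 those on the parent
    side.  Requires a binary (trifurcating-root) tree.
    """
    labels = _t.leaf_labels(tree)
    ref = min(labels)
    n = len(labels)
    below = _t._below_sets(tree)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = below[node]
        if not (2 <= len(side) <= n - 2):
            continue
        kids = node.child_nodes()
        if len(kids) != 2:
            continue
        a1, a2 = below[kids[0]], below[kids[1]]
        parent = node.parent_node
        sibs = [c for c in parent.child_nodes() if c is not node]
        if parent is tree.seed_node and len(sibs) == 2:
            b1, b2 = below[sibs[0]], below[sibs[1]]
        elif len(sibs) == 1:
            b1 = below[sibs[0]]
            b2 = labels - side - b1
        else:
            continue
        if not b1 or not b2:
            continue
        key = frozenset(labels - side) if ref in side else frozenset(side)
        yield key, (sorted(a1), sorted(a2), sorted(b1), sorted(b2))


def gene_concordance(
    species: dendropy.Tree, gene_trees: Sequence[dendropy.Tree]
) -> dict[frozenset, float]:
    """gCF: percent of decisive gene trees containing each internal branch.

    A gene tree is decisive for a branch when it has at least two taxa on
    each side of the branch's bipartition; it is concordant when its own
    induced split set contains the restricted bipartition.
    """
    labels = _t.leaf_labels(species)
    out: dict[frozenset, float] = {}
    gt_info = []
    for gt in gene_trees:
        gl = _t.leaf_labels(gt)
        ref = min(gl)
        restricted_splits = set()
        for node_set in _t.nontrivial_splits(gt):
            restricted_splits.add(node_set)
        gt_info.append((gl, ref, restricted_splits))
    for split in _t.nontrivial_splits(species):
        side_a = split
        side_b = labels - split
        n_decisive = 0
        n_conc = 0
        for gl, ref, gt_splits in gt_info:
            ra = side_a & gl
            rb = side_b & gl
            if len(ra) < 2 or len(rb) < 2:
                continue
            n_decisive += 1
            key = frozenset(rb) if ref in ra else frozenset(ra)
            if key in gt_splits:
                n_conc += 1
        out[split] = 100.0 * n_conc / n_decisive if n_decisive else 0.0
    return out


def site_concordance(
    species: dendropy.Tree,
    sm: Supermatrix,
    quartets_per_branch: int = DEFAULT_QUARTETS_PER_BRANCH,
    seed: int = 0,
) -> dict[frozenset, float | None]:
    """sCF: mean percent of decisive sites supporting each internal branch.

    For each internal branch, quartets are sampled with one taxon from each
    of the four subtrees around the branch; a site is decisive for a
    sampled quartet when its four states show exactly two distinct states,
    twice each, and it supports the branch when the equal-state pairs match
    the species-tree pairing.  Branches where no sampled quartet has any
    decisive site get ``None``.
    """
    if quartets_per_branch < 1:
        raise SpeciesTreeError("quartets_per_branch must be >= 1")
    rng = np.random.default_rng(seed)
    arr = sm.msa.to_array()
    row_of = {t: i for i, t in enumerate(sm.msa.taxa)}
    states = set(sm.msa.alphabet.states)
    valid = np.isin(arr, list(states))
    out: dict[frozenset, float | None] = {}
    for key, (a1, a2, b1, b2) in _edge_quadrants(species):
        fractions = []
        for _ in range(quartets_per_branch):
            qa = a1[rng.integers(len(a1))]
            qb = a2[rng.integers(len(a2))]
            qc = b1[rng.integers(len(b1))]
            qd = b2[rng.integers(len(b2))]
            rows = [row_of[t] for t in (qa, qb, qc, qd)]
            sub = arr[rows]
            ok = valid[rows].all(axis=0)
            x = sub[:, ok]
            if x.shape[1] == 0:
                continue
            eq_ab = x[0] == x[1]
            eq_cd = x[2] == x[3]
            eq_ac = x[0] == x[2]
            eq_ad = x[0] == x[3]
            eq_bc = x[1] == x[2]
            eq_bd = x[1] == x[3]
            support_sp = eq_ab & eq_cd & ~eq_ac
            support_1 = eq_ac & eq_bd & ~eq_ab
            support_2 = eq_ad & eq_bc & ~eq_ab
            decisive = support_sp | support_1 | support_2
            nd = int(decisive.sum())
            if nd == 0:
                continue
            fractions.append(100.0 * int(support_sp.sum()) / nd)
        out[key] = float(np.mean(fractions)) if fractions else None
    return out


def concordance_factors(
    species: SupportedTree | dendropy.Tree,
    gene_trees: Sequence[dendropy.Tree],
    sm: Supermatrix | None = None,
    quartets_per_branch: int = DEFAULT_QUARTETS_PER_BRANCH,
    seed: int = 0,
) -> SupportedTree:
    """Annotate a species tree with gene and site concordance factors."""
    st = (
        species
        if isinstance(species, SupportedTree)
        else SupportedTree(tree=species)
    )
    gcf = gene_concordance(st.tree, gene_trees)
    scf = (
        site_concordance(st.tree, sm, quartets_per_branch, seed)
        if sm is not None
        else None
    )
    return replace(st, gcf=gcf, scf=scf)


# ---------------------------------------------------------------------------
# Annotated newick round trip
# ---------------------------------------------------------------------------

def _format_slot(value: float | None) -> str:
    if value is None:
        return ""
    return format(value, ".17g")


def write_supported_newick(st: SupportedTree) -> str:
    """Newick with internal labels ``bootstrap/gCF/sCF`` (empty slots kept)."""
    tree = dendropy.Tree.get(
        data=_t.to_newick(st.tree), schema="newick"
    )
    edges = _t.split_edge_map(tree)
    for split, edge in edges.items():
        slots = []
        for ann in (st.bootstrap, st.gcf, st.scf):
            slots.append(_format_slot(ann.get(split)) if ann is not None else "")
        edge.head_node.label = "/".join(slots)
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_internal_node_labels=False,
    ).strip()


def read_supported_newick(newick: str) -> SupportedTree:
    """Parse a tree written by :func:`write_supported_newick`."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    edges = _t.split_edge_map(tree)
    boot: dict = {}
    gcf: dict = {}
    scf: dict = {}
    any_boot = any_gcf = any_scf = False
    for split, edge in edges.items():
        label = edge.head_node.label
        if not label:
            continue
        slots = str(label).split("/")
        slots += [""] * (3 - len(slots))
        if slots[0]:
            boot[split] = float(slots[0])
            any_boot = True
        if slots[1]:
            gcf[split] = float(slots[1])
            any_gcf = True
        if slots[2]:
            scf[split] = float(slots[2])
            any_scf = True
        edge.head_node.label = None
    return SupportedTree(
        tree=tree,
        bootstrap=boot if any_boot else None,
        gcf=gcf if any_gcf else None,
        scf=scf if any_scf else None,
    )
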