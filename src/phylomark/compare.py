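"""Tree comparison: Robinson-Foulds distance and monophyly assessment."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy

from . import trees as _t

MONOPHYLETIC = "monophyletic"
NON_MONOPHYLETIC = "non_monophyletic"
SINGLETON = "singleton"


class CompareError(ValueError):
    """Invalid tree-comparison input."""


@dataclass(frozen=True)
class TaxonomyMap:
    """Assignment of each taxon label to exactly one group label."""

    assignments: dict[str, str]

    def __post_init__(self):
        if not self.assignments:
            raise CompareError("taxonomy map is empty")

    @property
    def groups(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for taxon, group in self.assignments.items():
            out.setdefault(group, set()).add(taxon)
        return {g: frozenset(m) for g, m in out.items()}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyMap":
        """Two-column TSV: taxon <TAB> group."""
        assignments = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CompareError(f"bad taxonomy line: {line!r}")
            assignments[parts[0]] = parts[1]
        return cls(assignments)


def robinson_foulds(
    t1: dendropy.Tree, t2: dendropy.Tree
) -> tuple[int, float]:
    """Robinson-Foulds distance between two unrooted trees.

    Returns ``(distance, normalized)``: the size of the symmetric
    difference of the nontrivial bipartition sets, and that distance over
    the maximum ``2 * (n - 3)`` attainable by binary trees.
    """
    l1, l2 = _t.leaf_labels(t1), _t.leaf_labels(t2)
    if l1 != l2:
        only1 = sorted(l1 - l2)
        only2 = sorted(l2 - l1)
        raise CompareError(
            f"leaf sets differ: only in first {only1}, only in second {only2}"
        )
    s1 = _t.nontrivial_splits(t1)
    s2 = _t.nontrivial_splits(t2)
    distance = len(s1 ^ s2)
    n = len(l1)
    denom = 2 * (n - 3)
    normalized = distance / denom if denom > 0 else 0.0
    return distance, normalized


def assess_monophyly(
    tree: dendropy.Tree,
    taxonomy: TaxonomyMap | Mapping[str, str],
    outgroup: Sequence[str],
) -> dict[str, str]:
    """Monophyly status of every taxonomy group on an outgroup-rooted tree.

    The tree is rooted on the attachment edge of the outgroup; a group is
    monophyletic iff some clade's leaf set equals the group exactly.
    Groups of size one are reported as singletons.
    """
    if isinstance(taxonomy, Mapping) and not isinstance(taxonomy, TaxonomyMap):
        taxonomy = TaxonomyMap(dict(taxonomy))
    if not outgroup:
        raise CompareError("outgroup must be non-empty")
    labels = _t.leaf_labels(tree)
    missing_og = sorted(set(outgroup) - labels)
    if missing_og:
        raise CompareError(f"outgroup taxa absent from tree: {missing_og}")
    unassigned = sorted(labels - set(taxonomy.assignments))
    if unassigned:
        raise CompareError(f"taxa missing from taxonomy: {unassigned}")

    work = dendropy.Tree.get(data=_t.to_newick(tree), schema="newick")
    work.is_rooted = True
    work.update_bipartitions(suppress_unifurcations=True)
    if len(outgroup) == 1:
        og_node = next(
            lf for lf in work.leaf_node_iter() if lf.taxon.label == outgroup[0]
        )
    else:
        og_node = work.mrca(taxon_labels=list(outgroup))
    if og_node is not work.seed_node:
        work.reroot_at_edge(og_node.edge, update_bipartitions=False)

    clades: set[frozenset[str]] = set()
    below: dict = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(
                *(below[c] for c in node.child_nodes())
            )
        clades.add(below[node])

    out: dict[str, str] = {}
    for group, members in sorted(taxonomy.groups.items()):
        members = frozenset(members & labels)
        if not members:
            continue
        if len(members) == 1:
            out[group] = SINGLETON
        elif members in clades:
            out[group] = MONOPHYLETIC
        else:
            out[group] = NON_MONOPHYLETIC
    return out
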