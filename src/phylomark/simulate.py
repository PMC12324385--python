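"""Synthetic phylogenomic datasets with a known species tree.

The generator emulates the inputs the pipeline consumes in practice: a set
of proteomes (and matching CDS files) sharing a panel of single-copy marker
genes evolved along a known pure-birth (Yule) species tree, plus a seed
alignment per marker (an independent replicate of the same family) from
which profiles can be built.  Optional per-(sample, marker) duplications
insert a second, further-mutated copy of a marker gene to exercise the
multi-hit exclusion rule.  The true tree is written alongside, so topology
recovery can be measured exactly.

Sequence evolution uses a uniform-exchange (Jukes-Cantor-style) k-state
substitution model with no rate heterogeneity across sites and no indels;
gene trees equal the species tree (no coalescent discordance).  All
randomness flows from the single configured seed, so regeneration is
byte-identical.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .msa import Alphabet
from . import trees as _t


class SimulateError(ValueError):
    """Invalid simulation configuration or input."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a small low-divergence clade: 8 taxa, 20 single-copy
    markers of 300 residues, branch lengths scaled to 0.1 expected
    substitutions per site per unit branch length, and no duplications.
    """

    n_taxa: int = 8
    n_markers: int = 20
    marker_length: int = 300
    birth_rate: float = 1.0
    mutation_scale: float = 0.1
    duplication_prob: float = 0.0
    #: extra divergence (expected substitutions/site) of a duplicated copy
    duplicate_extra_divergence: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise SimulateError("n_taxa must be >= 4")
        if self.n_markers < 1 or self.marker_length < 1:
            raise SimulateError("n_markers and marker_length must be positive")
        if not (0.0 <= self.duplication_prob <= 1.0):
            raise SimulateError("duplication_prob must be in [0, 1]")
        if self.birth_rate <= 0 or self.mutation_scale <= 0:
            raise SimulateError("rates must be positive")


@dataclass(frozen=True)
class DatasetManifest:
    """What :func:`generate_dataset` wrote and where."""

    out_dir: Path
    true_tree_path: Path
    seed_msa_dir: Path
    peptide_fastas: dict[str, Path]
    cds_fastas: dict[str, Path]
    marker_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    duplicated: tuple[tuple[str, str], ...]  # (sample_id, marker_id)


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_yule_tree(
    n_taxa: int, birth_rate: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Pure-birth ultrametric species tree with taxa ``t01..tNN``."""
    if n_taxa < 4:
        raise SimulateError("n_taxa must be >= 4")
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=random.Random(seed),
    )
    width = max(2, len(str(n_taxa)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i:0{width}d}"
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _substitute(
    seq: np.ndarray, branch: float, mutation_scale: float, k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve a state vector along one branch of the k-state JC model."""
    if branch < 0:
        raise SimulateError(f"negative branch length {branch}")
    expected = branch * mutation_scale
    p_change = (k - 1) / k * (1.0 - math.exp(-k / (k - 1) * expected))
    out = seq.copy()
    hit = rng.random(seq.shape[0]) < p_change
    n_hit = int(hit.sum())
    if n_hit:
        draw = rng.integers(0, k - 1, size=n_hit)
        cur = out[hit]
        out[hit] = np.where(draw >= cur, draw + 1, draw)
    return out


def evolve_sequences(
    tree: dendropy.Tree,
    root_sequence: str,
    mutation_scale: float,
    seed: int = 0,
    alphabet: Alphabet = Alphabet.AMINO20,
) -> dict[str, str]:
    """Evolve a root sequence along a rooted tree; returns leaf sequences.

    Each site substitutes independently under the uniform-exchange model at
    ``branch_length * mutation_scale`` expected substitutions per site.
    All leaf sequences have the root sequence's length.
    """
    if not root_sequence:
        raise SimulateError("root sequence must be non-empty")
    states = alphabet.states
    lut = {ch: i for i, ch in enumerate(states)}
    try:
        root = np.array([lut[ch] for ch in root_sequence.upper()], dtype=np.int64)
    except KeyError as exc:
        raise SimulateError(f"root sequence has invalid residue {exc}")
    k = alphabet.size
    rng = np.random.default_rng(seed)
    seqs: dict = {tree.seed_node: root}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[node.parent_node]
        branch = node.edge.length or 0.0
        seqs[node] = _substitute(parent_seq, branch, mutation_scale, k, rng)
        if node.is_leaf():
            out[node.taxon.label] = "".join(states[i] for i in seqs[node])
    return out


def random_sequence(
    length: int, rng: np.random.Generator, alphabet: Alphabet = Alphabet.AMINO20
) -> str:
    states = alphabet.states
    return "".join(states[i] for i in rng.integers(0, len(states), size=length))


# ---------------------------------------------------------------------------
# Back-translation
# ---------------------------------------------------------------------------

_CODON_TABLE = unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, tuple[str, ...]] = {}
for codon, aa in sorted(_CODON_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(aa, ())
    _CODONS_FOR[aa] = _CODONS_FOR[aa] + (codon,)


def back_translate(
    peptide: str, rng: np.random.Generator, stop: str = "TAA"
) -> str:
    """CDS for a peptide, codons drawn uniformly among synonymous choices."""
    codons = []
    for aa in peptide:
        options = _CODONS_FOR[aa]
        codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons) + stop


# ---------------------------------------------------------------------------
# Dataset emission
# ---------------------------------------------------------------------------

def _write_fasta(records: Mapping[str, str], path: Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def generate_dataset(cfg: SimConfig, out_dir: str | Path) -> DatasetManifest:
    """Write a complete synthetic dataset under *out_dir*.

    Layout: ``true_tree.nwk``; ``seed_msas/<marker>.fasta`` (independent
    replicate per marker, for profile building); ``pep/<sample>.faa`` and
    ``cds/<sample>.fna``; ``manifest.tsv``.  Fully deterministic given
    ``cfg.seed``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise SimulateError(f"cannot create output directory {out_dir}: {exc}")
    (out_dir / "seed_msas").mkdir(exist_ok=True)
    (out_dir / "pep").mkdir(exist_ok=True)
    (out_dir / "cds").mkdir(exist_ok=True)

    tree = simulate_yule_tree(cfg.n_taxa, cfg.birth_rate, cfg.seed)
    samples = sorted(l for l in (lf.taxon.label for lf in tree.leaf_node_iter()))
    width = max(2, len(str(cfg.n_markers)))
    marker_ids = tuple(f"m{i:0{width}d}" for i in range(1, cfg.n_markers + 1))

    ss = np.random.SeedSequence(cfg.seed)
    marker_seeds = ss.spawn(cfg.n_markers)
    aux_rng = np.random.default_rng(ss.spawn(1)[0])

    peptides: dict[str, dict[str, str]] = {s: {} for s in samples}
    duplicated: list[tuple[str, str]] = []
    for mid, mseed in zip(marker_ids, marker_seeds):
        root_rng_seed, evo_seed, seed_rep_seed, dup_seed = mseed.spawn(4)
        mrng = np.random.default_rng(root_rng_seed)
        root_seq = random_sequence(cfg.marker_length, mrng)
        leaf_seqs = evolve_sequences(
            tree, root_seq, cfg.mutation_scale, seed=evo_seed
        )
        # held-out replicate of the same family, used as the profile seed MSA
        seed_rep = evolve_sequences(
            tree, root_seq, cfg.mutation_scale, seed=seed_rep_seed
        )
        _write_fasta(
            {f"{mid}_rep_{s}": seed_rep[s] for s in samples},
            out_dir / "seed_msas" / f"{mid}.fasta",
        )
        dup_rng = np.random.default_rng(dup_seed)
        for s in samples:
            peptides[s][f"{mid}|{s}"] = leaf_seqs[s]
            if dup_rng.random() < cfg.duplication_prob:
                extra = _substitute(
                    np.array(
                        [Alphabet.AMINO20.states.index(ch) for ch in leaf_seqs[s]],
                        dtype=np.int64,
                    ),
                    1.0,
                    cfg.duplicate_extra_divergence,
                    Alphabet.AMINO20.size,
                    dup_rng,
                )
                peptides[s][f"{mid}|{s}|copy2"] = "".join(
                    Alphabet.AMINO20.states[i] for i in extra
                )
                duplicated.append((s, mid))

    pep_paths: dict[str, Path] = {}
    cds_paths: dict[str, Path] = {}
    for s in samples:
        pep_path = out_dir / "pep" / f"{s}.faa"
        _write_fasta(peptides[s], pep_path)
        pep_paths[s] = pep_path
        cds_records = {
            name: back_translate(seq, aux_rng)
            for name, seq in peptides[s].items()
        }
        cds_path = out_dir / "cds" / f"{s}.fna"
        _write_fasta(cds_records, cds_path)
        cds_paths[s] = cds_path

    true_tree_path = out_dir / "true_tree.nwk"
    true_tree_path.write_text(_t.to_newick(tree) + "\n")
    with open(out_dir / "manifest.tsv", "w") as fh:
        fh.write("sample_id\tpeptide_fasta\tcds_fasta\tn_sequences\n")
        for s in samples:
            fh.write(
                f"{s}\t{pep_paths[s].name}\t{cds_paths[s].name}\t"
                f"{len(peptides[s])}\n"
            )
    return DatasetManifest(
        out_dir=out_dir,
        true_tree_path=true_tree_path,
        seed_msa_dir=out_dir / "seed_msas",
        peptide_fastas=pep_paths,
        cds_fastas=cds_paths,
        marker_ids=marker_ids,
        sample_ids=tuple(samples),
        duplicated=tuple(sorted(duplicated)),
    )
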