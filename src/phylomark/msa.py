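"""Multiple sequence alignments: containers, FASTA IO, profile alignment,
codon threading, and trimming to parsimony-informative sites.

An :class:`Msa` is an ordered, immutable set of equal-length rows over a
single alphabet.  Rows are normalized on construction: residues are
uppercased and the ``.`` gap character is rewritten to ``-``.  Ambiguity
codes (``X`` for amino acids, ``N`` for nucleotides) carry no state
information here and are treated as gaps wherever states are counted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .markerset import MarkerProfile

GAP = "-"


class Alphabet(enum.Enum):
    """Residue alphabet of an alignment or profile."""

    AMINO20 = "amino20"
    NUCLEOTIDE4 = "nucleotide4"

    @property
    def states(self) -> str:
        return _STATES[self]

    @property
    def size(self) -> int:
        return len(_STATES[self])

    @property
    def gap_like(self) -> frozenset[str]:
        """Characters carrying no state information (gap + ambiguity)."""
        return _GAP_LIKE[self]


_STATES = {
    Alphabet.AMINO20: "ACDEFGHIKLMNPQRSTVWY",
    Alphabet.NUCLEOTIDE4: "ACGT",
}
_GAP_LIKE = {
    Alphabet.AMINO20: frozenset("-X*BZJUO"),
    Alphabet.NUCLEOTIDE4: frozenset("-NRYSWKMBDHV"),
}


class MsaError(ValueError):
    """Invalid alignment input."""


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", GAP)


@dataclass(frozen=True)
class Msa:
    """An immutable multiple sequence alignment.

    Parameters
    ----------
    rows:
        Ordered ``(taxon, aligned sequence)`` pairs.  All sequences must
        have equal length and taxa must be unique.
    alphabet:
        The shared residue alphabet.
    """

    rows: tuple[tuple[str, str], ...]
    alphabet: Alphabet

    def __init__(self, rows: Iterable[tuple[str, str]], alphabet: Alphabet):
        rows = tuple((str(t), _normalize(str(s))) for t, s in rows)
        if not rows:
            raise MsaError("alignment has no rows")
        lengths = {len(s) for _, s in rows}
        if len(lengths) != 1:
            raise MsaError(f"rows have unequal lengths: {sorted(lengths)}")
        taxa = [t for t, _ in rows]
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if taxa.count(t) > 1})
            raise MsaError(f"duplicate taxa in alignment: {dupes}")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "alphabet", alphabet)

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.rows)

    def sequence(self, taxon: str) -> str:
        for t, s in self.rows:
            if t == taxon:
                return s
        raise KeyError(taxon)

    def to_array(self) -> np.ndarray:
        """Alignment as a 2-D array of single characters."""
        return np.array([list(s) for _, s in self.rows], dtype="U1")

    def select_columns(self, columns: Sequence[int]) -> "Msa":
        cols = list(columns)
        rows = tuple(
            (t, "".join(s[c] for c in cols)) for t, s in self.rows
        )
        return Msa(rows, self.alphabet)


@dataclass(frozen=True)
class TrimmedMsa:
    """A trimmed alignment plus the 0-based source columns that were kept.

    ``source_length`` (when known) records how many columns the source
    alignment had, so downstream distance estimation can account for the
    trimmed-away, overwhelmingly constant sites.
    """

    msa: Msa
    kept_columns: tuple[int, ...] = field(default_factory=tuple)
    source_length: int | None = None

    def __post_init__(self):
        if list(self.kept_columns) != sorted(set(self.kept_columns)):
            raise MsaError("kept_columns must be strictly increasing")
        if self.msa.length != len(self.kept_columns):
            raise MsaError("kept_columns length must match trimmed alignment")
        if self.source_length is not None:
            if self.kept_columns and self.source_length <= self.kept_columns[-1]:
                raise MsaError("source_length inconsistent with kept_columns")

    @property
    def n_removed(self) -> int:
        """Columns removed by trimming (0 when the source length is unknown)."""
        if self.source_length is None:
            return 0
        return self.source_length - len(self.kept_columns)


# ---------------------------------------------------------------------------
# FASTA IO
# ---------------------------------------------------------------------------

def read_fasta_msa(path: str | Path, alphabet: Alphabet) -> Msa:
    """Read an aligned FASTA file into an :class:`Msa`."""
    from Bio import SeqIO

    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise MsaError(f"no sequences in {path}")
    return Msa(records, alphabet)


def write_fasta_msa(msa: Msa, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for taxon, seq in msa.rows:
            fh.write(f">{taxon}\n")
            if not seq:
                fh.write("\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Profile alignment (glocal: global in the profile, insertions projected out)
# ---------------------------------------------------------------------------

def _encode(seq: str, alphabet: Alphabet) -> np.ndarray:
    """Map residues to state indices; unknown/ambiguous residues map to -1."""
    lut = np.full(128, -1, dtype=np.int64)
    for i, ch in enumerate(alphabet.states):
        lut[ord(ch)] = i
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return lut[arr]


def _column_scores(seq_idx: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score matrix S[i, j] = log-odds of residue i under profile column j.

    Ambiguous residues (index -1) score 0 bits everywhere (background odds).
    """
    n = seq_idx.shape[0]
    L = log_odds.shape[0]
    S = np.zeros((n, L))
    known = seq_idx >= 0
    S[known, :] = log_odds[:, seq_idx[known]].T
    return S


def align_to_profile(sequence: str, profile: "MarkerProfile") -> str:
    """Globally align a sequence to a profile's match columns.

    Returns one symbol per match column: a residue where the column is
    matched, ``-`` where the profile column is skipped (deletion).  Residues
    aligned as insertions relative to the profile are omitted, so the output
    length always equals ``profile.length``.  Scoring uses the profile's
    per-column log-odds with affine gap penalties (both gap directions).
    """
    return _global_alignment(sequence, profile)[0]


def _global_alignment(sequence: str, profile: "MarkerProfile") -> tuple[str, float]:
    """Alignment row plus its optimal global DP score in bits."""
    if not sequence:
        raise MsaError("cannot align an empty sequence")
    seq_idx = _encode(sequence, profile.alphabet)
    bad = [sequence[i] for i in range(len(sequence)) if seq_idx[i] < 0
           and sequence[i].upper() not in profile.alphabet.gap_like]
    if bad:
        raise MsaError(
            f"sequence contains residues outside alphabet "
            f"{profile.alphabet.value}: {sorted(set(bad))}"
        )
    go, ge = profile.gap_open, profile.gap_extend
    S = _column_scores(seq_idx, profile.log_odds)
    n, L = S.shape
    NEG = -np.inf

    # H: best score aligning seq[:i] to columns[:j]; F: in an insertion run
    # (sequence consumed, column untouched); E: in a deletion run.  E is
    # vectorized with the prefix-max trick, exact because gap_open >= gap_extend
    # makes re-opening a running gap never optimal.
    H = np.full((n + 1, L + 1), NEG)
    Hm = np.full((n + 1, L + 1), NEG)  # H restricted to match/insert endings
    E = np.full((n + 1, L + 1), NEG)
    F = np.full((n + 1, L + 1), NEG)
    K = np.zeros((n + 1, L + 1), dtype=np.int64)  # deletion-run start column

    H[0, 0] = 0.0
    Hm[0, 0] = 0.0
    if L > 0:
        E[0, 1:] = -go - np.arange(L) * ge
        H[0, 1:] = E[0, 1:]
        K[0, 1:] = 0
    cols = np.arange(1, L + 1)
    for i in range(1, n + 1):
        F[i, 0] = max(H[i - 1, 0] - go, F[i - 1, 0] - ge)
        H[i, 0] = F[i, 0]
        Hm[i, 0] = H[i, 0]
        if L == 0:
            continue
        diag = H[i - 1, :-1] + S[i - 1, :]
        F[i, 1:] = np.maximum(H[i - 1, 1:] - go, F[i - 1, 1:] - ge)
        Hm[i, 1:] = np.maximum(diag, F[i, 1:])
        A = Hm[i, :] + np.arange(L + 1) * ge
        pref = np.maximum.accumulate(A)
        idx = np.arange(L + 1)
        arg = np.maximum.accumulate(np.where(A >= pref, idx, -1))
        E[i, 1:] = pref[:-1] - go - cols * ge + ge
        K[i, 1:] = arg[:-1]
        H[i, 1:] = np.maximum(Hm[i, 1:], E[i, 1:])

    # Traceback (bitwise-exact: every comparison recomputes the same float op
    # the forward pass used, or reads a stored matrix).
    out = [GAP] * L
    i, j = n, L
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if j > 0 and H[i, j] == E[i, j]:
                k = int(K[i, j])
                # columns k+1 .. j are deletions
                i, j, state = i, k, "Hm"
                continue
            state = "Hm"
            continue
        if state == "Hm":
            if j == 0:
                state = "F" if i > 0 else "H"
                if i == 0:
                    break
                continue
            if i > 0 and Hm[i, j] == H[i - 1, j - 1] + S[i - 1, j - 1]:
                out[j - 1] = sequence[i - 1]
                i, j, state = i - 1, j - 1, "H"
                continue
            state = "F"
            continue
        # state == "F": insertion run, consume sequence rows
        if i > 1 and F[i, j] == F[i - 1, j] - ge:
            i = i - 1
            continue
        i, state = i - 1, "H"
    return "".join(out), float(H[n, L])


# ---------------------------------------------------------------------------
# Codon threading
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def strip_terminal_stop(cds: str) -> str:
    """Drop a single terminal stop codon if present."""
    cds = cds.upper().replace("U", "T")
    if len(cds) >= 3 and cds[-3:] in _STOPS:
        return cds[:-3]
    return cds


def thread_codons(peptide_msa: Msa, cds_by_taxon: Mapping[str, str]) -> Msa:
    """Expand a peptide alignment to nucleotides using each taxon's CDS.

    Each amino-acid column becomes three nucleotide columns and each peptide
    gap becomes ``---``.  The CDS must translate (standard code) exactly to
    the ungapped peptide row; a terminal stop codon is stripped first.
    """
    out_rows = []
    for taxon, pep_row in peptide_msa.rows:
        if taxon not in cds_by_taxon:
            raise MsaError(f"no CDS provided for taxon {taxon!r}")
        cds = strip_terminal_stop(cds_by_taxon[taxon])
        pep = pep_row.replace(GAP, "")
        if len(cds) != 3 * len(pep):
            raise MsaError(
                f"taxon {taxon!r}: CDS length {len(cds)} != 3 x ungapped "
                f"peptide length {len(pep)}"
            )
        if "N" not in cds:
            translated = str(Seq(cds).translate())
            for pos, (a, b) in enumerate(zip(translated, pep)):
                if a != b:
                    raise MsaError(
                        f"taxon {taxon!r}: CDS translation disagrees with "
                        f"peptide at position {pos} ({a!r} != {b!r})"
                    )
        chunks = []
        k = 0
        for ch in pep_row:
            if ch == GAP:
                chunks.append("---")
            else:
                chunks.append(cds[3 * k : 3 * k + 3])
                k += 1
        out_rows.append((taxon, "".join(chunks)))
    return Msa(out_rows, Alphabet.NUCLEOTIDE4)


# ---------------------------------------------------------------------------
# Trimming to parsimony-informative sites
# ---------------------------------------------------------------------------

def column_is_informative(column: Iterable[str], alphabet: Alphabet) -> bool:
    """True iff >= 2 distinct non-gap states each occur in >= 2 rows."""
    counts: dict[str, int] = {}
    for ch in column:
        ch = ch.upper()
        if ch in alphabet.gap_like or ch not in alphabet.states:
            continue
        counts[ch] = counts.get(ch, 0) + 1
    return sum(1 for c in counts.values() if c >= 2) >= 2


def trim_kpi(msa: Msa) -> TrimmedMsa:
    """Keep only the parsimony-informative columns of an alignment.

    A column is parsimony-informative when at least two distinct states each
    occur in at least two rows; gaps and ambiguity codes are not states.
    Requires >= 4 rows (fewer can never yield an informative column pattern
    worth keeping for tree building).
    """
    if msa.n_rows < 4:
        raise MsaError(f"trim_kpi requires >= 4 rows, got {msa.n_rows}")
    arr = msa.to_array()
    states = np.array(list(msa.alphabet.states), dtype="U1")
    counts = np.stack([(arr == s).sum(axis=0) for s in states])  # (K, L)
    keep = ((counts >= 2).sum(axis=0) >= 2)
    kept = tuple(int(c) for c in np.nonzero(keep)[0])
    return TrimmedMsa(
        msa=msa.select_columns(kept),
        kept_columns=kept,
        source_length=msa.length,
    )
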