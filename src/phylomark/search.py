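"""Profile search, single-copy ortholog resolution, and checkpointing.

Each sample (a proteome or CDS FASTA) is identified by the SHA-256 digest
of its file bytes, never by its name or path, so search results can be
reused across renames and shared between analyses.  Every sequence is
scored against every marker profile by Smith-Waterman-style local alignment
on the profile's log-odds columns with affine gap penalties; hits at or
above the bit-score threshold are kept.  A sample with two or more distinct
sequences hitting the same marker is excluded from that marker (the
multi-hit rule protecting single-copy orthology), and markers retained by
fewer than four samples are dropped.

The checkpoint stores hits keyed by sample digest under a parameter
fingerprint (marker set identity + scoring parameters); on rerun only
samples whose digest is absent are searched, and a fingerprint mismatch
invalidates everything.
"""

from __future__ import annotations

import hashlib
import json
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .markerset import MarkerProfile, MarkerSet
from .msa import Alphabet, _column_scores, _encode, strip_terminal_stop

#: Default hit threshold in bits.  Unrelated random sequences reach the low
#: twenties against a 300-column profile under the default gap penalties,
#: while genuine family members score in the hundreds; 50 bits separates the
#: two regimes with a wide margin on both sides.
DEFAULT_MIN_BIT_SCORE = 50.0
MIN_SAMPLES = 4
CHECKPOINT_VERSION = 1


class SearchError(ValueError):
    """Invalid sample input or search parameters."""


class CheckpointError(RuntimeError):
    """Unreadable or corrupt checkpoint file."""


class SeqType:
    PEPTIDE = "pep"
    CDS = "cds"


@dataclass(frozen=True)
class SampleRecord:
    """A sample keyed by the digest of its file content."""

    sample_id: str
    content_digest: str
    seq_type: str
    path: str
    n_sequences: int


@dataclass(frozen=True)
class Hit:
    """One above-threshold (sequence, marker) local-alignment match."""

    sample_digest: str
    marker_id: str
    sequence_id: str
    bit_score: float
    target_start: int
    target_end: int
    e_value: float | None = None

    @property
    def target_span(self) -> tuple[int, int]:
        return (self.target_start, self.target_end)


@dataclass(frozen=True)
class Checkpoint:
    """Persisted search results keyed by sample content digest."""

    parameter_fingerprint: str
    parameters: dict
    hits_by_sample: dict[str, tuple[Hit, ...]]
    sample_ids: dict[str, str]
    created: float
    updated: float
    version: int = CHECKPOINT_VERSION


@dataclass(frozen=True)
class OrthologTable:
    """Per-marker single-copy assignments after the multi-hit rule."""

    assignments: dict[str, dict[str, str]]  # marker -> sample_id -> sequence_id
    excluded: dict[str, tuple[str, ...]]    # marker -> sample_ids removed
    dropped_markers: tuple[str, ...]        # markers with < 4 retained samples


# ---------------------------------------------------------------------------
# Sample digestion
# ---------------------------------------------------------------------------

_PEP_OK = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")
_CDS_OK = frozenset("ACGTUNRYSWKMBDHV-")


def digest_sample(path: str | Path, sample_id: str, seq_type: str) -> SampleRecord:
    """Digest a FASTA sample: SHA-256 over raw bytes, plus basic validation.

    The digest depends only on file content, so renaming or moving the file
    leaves it unchanged.
    """
    path = Path(path)
    if seq_type not in (SeqType.PEPTIDE, SeqType.CDS):
        raise SearchError(f"unknown seq_type {seq_type!r}")
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise SearchError(f"cannot read {path}: {exc}")
    digest = hashlib.sha256(raw).hexdigest()
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SearchError(f"{path}: empty FASTA")
    ok = _PEP_OK if seq_type == SeqType.PEPTIDE else _CDS_OK
    for rec in records:
        bad = set(str(rec.seq).upper()) - ok
        if bad:
            raise SearchError(
                f"{path}: sequence {rec.id!r} has characters {sorted(bad)} "
                f"inconsistent with seq_type {seq_type!r}"
            )
    return SampleRecord(
        sample_id=sample_id,
        content_digest=digest,
        seq_type=seq_type,
        path=str(path),
        n_sequences=len(records),
    )


def _load_sequences(
    sample: SampleRecord, translate: bool = True
) -> list[tuple[str, str]]:
    """Sequences of a sample; CDS are stop-stripped and optionally translated."""
    out = []
    for rec in SeqIO.parse(sample.path, "fasta"):
        seq = str(rec.seq).upper()
        if sample.seq_type == SeqType.CDS:
            seq = strip_terminal_stop(seq)
            if len(seq) % 3 != 0:
                raise SearchError(
                    f"{sample.sample_id}/{rec.id}: CDS length {len(seq)} not "
                    f"divisible by 3"
                )
            if translate:
                pep = str(Seq(seq).translate())
                if "*" in pep:
                    raise SearchError(
                        f"{sample.sample_id}/{rec.id}: internal stop codon"
                    )
                seq = pep
        out.append((rec.id, seq))
    return out


# ---------------------------------------------------------------------------
# Local alignment against a profile
# ---------------------------------------------------------------------------

def _sw_forward(S: np.ndarray, go: float, ge: float):
    """Local-alignment forward pass; returns (best, end_row, end_col).

    Vectorized Gotoh with the prefix-max trick for the in-row gap state;
    exact because gap_open >= gap_extend makes re-opening a gap run never
    better than extending it.  end_row/end_col are 1-based DP coordinates of
    the best-scoring cell (deterministic: first maximum in scan order).
    """
    n, L = S.shape
    H_prev = np.zeros(L + 1)
    F_prev = np.full(L, -np.inf)
    cols = np.arange(1, L + 1)
    idx = np.arange(L + 1)
    best = 0.0
    best_i = 0
    best_j = 0
    for i in range(1, n + 1):
        diag = H_prev[:-1] + S[i - 1, :]
        F = np.maximum(H_prev[1:] - go, F_prev - ge)
        Hm = np.maximum(np.maximum(diag, F), 0.0)
        A = np.concatenate(([-np.inf], Hm)) + idx * ge
        pref = np.maximum.accumulate(A)
        E = pref[:-1] - go - cols * ge + ge
        H = np.maximum(Hm, E)
        m = float(H.max())
        if m > best:
            best = m
            best_i = i
            best_j = int(H.argmax()) + 1
        H_prev[1:] = H
        F_prev = F
    return best, best_i, best_j


def profile_local_score(
    sequence: str, profile: MarkerProfile
) -> tuple[float, tuple[int, int]]:
    """Best local-alignment bit score of a sequence against a profile.

    Returns ``(score, (start, end))`` with a 0-based half-open span on the
    sequence.  The span of a zero-score alignment is empty.
    """
    seq_idx = _encode(sequence, profile.alphabet)
    S = _column_scores(seq_idx, profile.log_odds)
    go, ge = profile.gap_open, profile.gap_extend
    best, i_end, j_end = _sw_forward(S, go, ge)
    if best <= 0.0:
        return 0.0, (0, 0)
    # locate the start by rerunning the DP on the reversed prefix
    S_rev = S[:i_end, :j_end][::-1, ::-1]
    score_rev, ri, _ = _sw_forward(S_rev, go, ge)
    start = i_end - ri
    return best, (start, i_end)


def search_sample(
    sample: SampleRecord,
    markers: MarkerSet,
    min_bit_score: float = DEFAULT_MIN_BIT_SCORE,
) -> list[Hit]:
    """Score every sequence of a sample against every marker profile.

    All hits with bit score >= *min_bit_score* are reported (multi-hit
    resolution happens later).  Deterministic: hits are ordered by
    (marker_id, sequence_id).
    """
    if markers.alphabet is Alphabet.AMINO20:
        # CDS samples are translated with the standard code before scoring
        sequences = _load_sequences(sample, translate=True)
    else:
        if sample.seq_type == SeqType.PEPTIDE:
            raise SearchError(
                "peptide samples cannot be searched against a nucleotide "
                "marker set"
            )
        sequences = _load_sequences(sample, translate=False)
    hits: list[Hit] = []
    for profile in markers.profiles:
        for seq_id, seq in sequences:
            if not seq:
                continue
            score, (start, end) = profile_local_score(seq, profile)
            if score >= min_bit_score:
                hits.append(
                    Hit(
                        sample_digest=sample.content_digest,
                        marker_id=profile.marker_id,
                        sequence_id=seq_id,
                        bit_score=round(score, 6),
                        target_start=start,
                        target_end=end,
                    )
                )
    hits.sort(key=lambda h: (h.marker_id, h.sequence_id))
    return hits


# ---------------------------------------------------------------------------
# Ortholog resolution
# ---------------------------------------------------------------------------

def resolve_orthologs(
    hits_by_sample: Mapping[str, Iterable[Hit]],
    samples: Sequence[SampleRecord],
    min_taxa: int = MIN_SAMPLES,
) -> OrthologTable:
    """Resolve single-copy orthologs with the multi-hit exclusion rule.

    For each marker, a sample with two or more distinct hit sequences is
    excluded for that marker; a sample with exactly one contributes it.
    Markers retained by fewer than *min_taxa* samples are dropped (an
    unrooted tree needs at least four taxa).  Output is invariant to sample
    input order.
    """
    if len(samples) < MIN_SAMPLES:
        raise SearchError(
            f"at least {MIN_SAMPLES} samples are required, got {len(samples)}"
        )
    by_digest = {s.content_digest: s for s in samples}
    if len(by_digest) != len(samples):
        raise SearchError("duplicate sample content digests")
    per_marker: dict[str, dict[str, set[str]]] = {}
    for digest, hits in hits_by_sample.items():
        if digest not in by_digest:
            continue
        sid = by_digest[digest].sample_id
        for h in hits:
            per_marker.setdefault(h.marker_id, {}).setdefault(sid, set()).add(
                h.sequence_id
            )
    assignments: dict[str, dict[str, str]] = {}
    excluded: dict[str, tuple[str, ...]] = {}
    dropped: list[str] = []
    for marker_id in sorted(per_marker):
        kept: dict[str, str] = {}
        removed: list[str] = []
        for sid in sorted(per_marker[marker_id]):
            seq_ids = per_marker[marker_id][sid]
            if len(seq_ids) >= 2:
                removed.append(sid)
            else:
                kept[sid] = next(iter(seq_ids))
        if removed:
            excluded[marker_id] = tuple(removed)
        if len(kept) >= min_taxa:
            assignments[marker_id] = kept
        else:
            dropped.append(marker_id)
    return OrthologTable(
        assignments=assignments,
        excluded=excluded,
        dropped_markers=tuple(dropped),
    )


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def parameter_fingerprint(
    markers: MarkerSet, min_bit_score: float
) -> tuple[str, dict]:
    """Digest over the marker-set identity and every scoring parameter."""
    p0 = markers.profiles[0]
    params = {
        "marker_set": markers.name,
        "n_markers": len(markers),
        "alphabet": markers.alphabet.value,
        "min_bit_score": float(min_bit_score),
        "gap_open": float(p0.gap_open),
        "gap_extend": float(p0.gap_extend),
    }
    blob = json.dumps(params, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest(), params


def update_checkpoint(
    ckpt: Checkpoint | None,
    samples: Sequence[SampleRecord],
    markers: MarkerSet,
    min_bit_score: float = DEFAULT_MIN_BIT_SCORE,
    threads: int = 1,
) -> tuple[Checkpoint, list[str]]:
    """Search only samples not already covered by the checkpoint.

    Samples whose digest appears in a checkpoint with a matching parameter
    fingerprint are served from stored hits; the rest are searched and their
    hits added.  A fingerprint mismatch discards all stored hits.  Returns
    the (possibly unchanged) checkpoint and the ids of samples actually
    searched.  When nothing needed searching the input checkpoint object is
    returned unchanged, so repeated application is byte-stable.
    """
    fp, params = parameter_fingerprint(markers, min_bit_score)
    if ckpt is not None and ckpt.parameter_fingerprint == fp:
        stored = dict(ckpt.hits_by_sample)
        stored_ids = dict(ckpt.sample_ids)
        created = ckpt.created
    else:
        stored = {}
        stored_ids = {}
        created = time.time()
    todo = [s for s in samples if s.content_digest not in stored]
    if not todo:
        if ckpt is not None and ckpt.parameter_fingerprint == fp:
            return ckpt, []
        new = Checkpoint(
            parameter_fingerprint=fp,
            parameters=params,
            hits_by_sample=stored,
            sample_ids=stored_ids,
            created=created,
            updated=created,
        )
        return new, []

    def work(sample: SampleRecord) -> tuple[str, tuple[Hit, ...]]:
        return sample.content_digest, tuple(
            search_sample(sample, markers, min_bit_score)
        )

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(work, todo))
    else:
        results = [work(s) for s in todo]
    for sample, (digest, hits) in zip(todo, results):
        stored[digest] = hits
        stored_ids[digest] = sample.sample_id
    for s in samples:  # keep labels current for reused digests too
        stored_ids[s.content_digest] = s.sample_id
    new = Checkpoint(
        parameter_fingerprint=fp,
        parameters=params,
        hits_by_sample=stored,
        sample_ids=stored_ids,
        created=created,
        updated=time.time(),
    )
    return new, [s.sample_id for s in todo]


def checkpoint_to_json(ckpt: Checkpoint) -> str:
    payload = {
        "format": "phylomark-checkpoint",
        "version": ckpt.version,
        "parameter_fingerprint": ckpt.parameter_fingerprint,
        "parameters": ckpt.parameters,
        "created": ckpt.created,
        "updated": ckpt.updated,
        "sample_ids": ckpt.sample_ids,
        "hits": {
            digest: [
                {
                    "marker_id": h.marker_id,
                    "sequence_id": h.sequence_id,
                    "bit_score": h.bit_score,
                    "target_start": h.target_start,
                    "target_end": h.target_end,
                    "e_value": h.e_value,
                }
                for h in hits
            ]
            for digest, hits in ckpt.hits_by_sample.items()
        },
    }
    return json.dumps(payload, sort_keys=True, indent=1)


def save_checkpoint(ckpt: Checkpoint, path: str | Path) -> None:
    Path(path).write_text(checkpoint_to_json(ckpt) + "\n")


def load_checkpoint(path: str | Path) -> Checkpoint:
    """Load a checkpoint, refusing (never silently ignoring) corrupt files."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise CheckpointError(f"corrupt or unreadable checkpoint {path}: {exc}")
    if not isinstance(payload, dict) or payload.get("format") != "phylomark-checkpoint":
        raise CheckpointError(f"{path} is not a phylomark checkpoint")
    if payload.get("version") != CHECKPOINT_VERSION:
        raise CheckpointError(
            f"{path}: unsupported checkpoint version {payload.get('version')!r}"
        )
    try:
        hits = {
            digest: tuple(
                Hit(
                    sample_digest=digest,
                    marker_id=h["marker_id"],
                    sequence_id=h["sequence_id"],
                    bit_score=float(h["bit_score"]),
                    target_start=int(h["target_start"]),
                    target_end=int(h["target_end"]),
                    e_value=h.get("e_value"),
                )
                for h in hit_list
            )
            for digest, hit_list in payload["hits"].items()
        }
        return Checkpoint(
            parameter_fingerprint=payload["parameter_fingerprint"],
            parameters=payload["parameters"],
            hits_by_sample=hits,
            sample_ids=payload["sample_ids"],
            created=float(payload["created"]),
            updated=float(payload["updated"]),
            version=int(payload["version"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise CheckpointError(f"corrupt checkpoint {path}: {exc}")
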