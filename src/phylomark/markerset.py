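"""Marker sets: position-specific scoring profiles for single-copy orthologs.

A marker set plays the role a BUSCO-style profile-HMM collection plays in
ortholog identification: one profile per single-copy gene family, built from
a seed alignment.  Profiles here are position-specific score matrices over
the match columns of the seed alignment, searched with affine gap penalties;
insert states are not modeled.

Sets are stored on disk as a directory of one ``<marker_id>.profile`` text
file per marker plus a ``manifest.json`` recording the set name, alphabet
and marker count.  :func:`fetch_marker_set` materializes named sets into a
home-directory cache (``~/.phylomark/markersets`` by default, overridable by
the ``PHYLOMARK_CACHE_DIR`` environment variable or an explicit argument)
through a pluggable transport, so later calls are served from the cache.
"""

from __future__ import annotations

import json
import math
import os
import shutil
import tarfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping
from urllib.parse import urlparse
from urllib.request import url2pathname

import numpy as np

from .msa import Alphabet, Msa

DEFAULT_GAP_OPEN = 4.0
DEFAULT_GAP_EXTEND = 0.5
DEFAULT_PSEUDOCOUNT = 1.0

PROFILE_SUFFIX = ".profile"
MANIFEST_NAME = "manifest.json"
_FORMAT_TAG = "phylomark-profile-v1"


class MarkerSetError(ValueError):
    """Invalid profile, marker set, or fetch request."""


@dataclass(frozen=True)
class MarkerProfile:
    """Position-specific scoring profile over match columns.

    ``emissions[i, s]`` is the (pseudocounted, strictly positive) probability
    of alphabet state ``s`` at match column ``i``; ``background`` is the null
    state distribution.  Scores derived from the profile are log2 odds
    (bits); ``gap_open``/``gap_extend`` are affine penalties in bits, with
    ``gap_open >= gap_extend`` required by the alignment recurrences.
    """

    marker_id: str
    alphabet: Alphabet
    emissions: np.ndarray
    background: np.ndarray
    consensus: str
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND

    def __post_init__(self):
        em = np.asarray(self.emissions, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "emissions", em)
        object.__setattr__(self, "background", bg)
        K = self.alphabet.size
        if em.ndim != 2 or em.shape[0] < 1 or em.shape[1] != K:
            raise MarkerSetError(
                f"{self.marker_id}: emissions must be (length, {K}), "
                f"got {em.shape}"
            )
        if bg.shape != (K,):
            raise MarkerSetError(f"{self.marker_id}: bad background shape")
        if not (em > 0).all() or not (bg > 0).all():
            raise MarkerSetError(
                f"{self.marker_id}: probabilities must be strictly positive"
            )
        if not np.allclose(em.sum(axis=1), 1.0, atol=1e-9):
            raise MarkerSetError(f"{self.marker_id}: emission columns must sum to 1")
        if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise MarkerSetError(f"{self.marker_id}: background must sum to 1")
        if len(self.consensus) != em.shape[0]:
            raise MarkerSetError(f"{self.marker_id}: consensus length mismatch")
        if self.gap_open < self.gap_extend:
            raise MarkerSetError(
                f"{self.marker_id}: gap_open must be >= gap_extend"
            )

    @property
    def length(self) -> int:
        return int(self.emissions.shape[0])

    @property
    def log_odds(self) -> np.ndarray:
        """Per-column log2 odds scores, shape ``(length, alphabet size)``."""
        return np.log2(self.emissions / self.background)

    @property
    def max_score(self) -> float:
        """Score of a gapless alignment of the consensus to every column."""
        return float(self.log_odds.max(axis=1).sum())


@dataclass(frozen=True)
class MarkerSet:
    """A named, non-empty collection of profiles sharing one alphabet."""

    name: str
    alphabet: Alphabet
    profiles: tuple[MarkerProfile, ...]
    source: str = ""

    def __post_init__(self):
        if not self.profiles:
            raise MarkerSetError(f"marker set {self.name!r} is empty")
        ids = [p.marker_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            dupes = sorted({m for m in ids if ids.count(m) > 1})
            raise MarkerSetError(f"duplicate marker ids: {dupes}")
        if any(p.alphabet is not self.alphabet for p in self.profiles):
            raise MarkerSetError("profiles do not all share the set alphabet")
        ordered = tuple(sorted(self.profiles, key=lambda p: p.marker_id))
        object.__setattr__(self, "profiles", ordered)

    def __len__(self) -> int:
        return len(self.profiles)

    def __getitem__(self, marker_id: str) -> MarkerProfile:
        for p in self.profiles:
            if p.marker_id == marker_id:
                return p
        raise KeyError(marker_id)

    @property
    def marker_ids(self) -> tuple[str, ...]:
        return tuple(p.marker_id for p in self.profiles)


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------

def uniform_background(alphabet: Alphabet) -> np.ndarray:
    return np.full(alphabet.size, 1.0 / alphabet.size)


def build_profile_from_msa(
    msa: Msa,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    marker_id: str = "marker",
    background: np.ndarray | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> MarkerProfile:
    """Build a profile from a seed alignment.

    Match columns are those with gap fraction < 0.5 (gap-like characters,
    including ambiguity codes, count as gaps).  Emission probabilities use
    background-weighted pseudocounts::

        emissions[i][s] = (count(s, col i) + pseudocount * background[s])
                          / (non_gap(col i) + pseudocount)

    The consensus is the per-column argmax state, ties broken by alphabet
    order.
    """
    if pseudocount <= 0:
        raise MarkerSetError("pseudocount must be positive")
    if msa.length == 0:
        raise MarkerSetError("cannot build a profile from an empty alignment")
    alphabet = msa.alphabet
    bg = uniform_background(alphabet) if background is None else np.asarray(
        background, dtype=float
    )
    arr = msa.to_array()
    states = np.array(list(alphabet.states), dtype="U1")
    counts = np.stack([(arr == s).sum(axis=0) for s in states]).T  # (L, K)
    non_gap = counts.sum(axis=1)
    gap_frac = 1.0 - non_gap / msa.n_rows
    match = gap_frac < 0.5
    if not match.any():
        raise MarkerSetError("no match columns: every column is gap-majority")
    counts = counts[match]
    non_gap = non_gap[match]
    emissions = (counts + pseudocount * bg[None, :]) / (
        non_gap[:, None] + pseudocount
    )
    consensus = "".join(alphabet.states[i] for i in emissions.argmax(axis=1))
    return MarkerProfile(
        marker_id=marker_id,
        alphabet=alphabet,
        emissions=emissions,
        background=bg,
        consensus=consensus,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_profile(profile: MarkerProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_FORMAT_TAG}\n")
        fh.write(f"marker_id\t{profile.marker_id}\n")
        fh.write(f"alphabet\t{profile.alphabet.value}\n")
        fh.write(f"length\t{profile.length}\n")
        fh.write(f"gap_open\t{float(profile.gap_open):.17g}\n")
        fh.write(f"gap_extend\t{float(profile.gap_extend):.17g}\n")
        fh.write(
            "background\t"
            + " ".join(f"{float(x):.17g}" for x in profile.background)
            + "\n"
        )
        fh.write("columns\n")
        for i in range(profile.length):
            probs = " ".join(f"{float(x):.17g}" for x in profile.emissions[i])
            fh.write(f"{i + 1}\t{profile.consensus[i]}\t{probs}\n")


def read_profile(path: str | Path) -> MarkerProfile:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or _FORMAT_TAG not in lines[0]:
        raise MarkerSetError(f"{path}: not a recognized profile file")
    header: dict[str, str] = {}
    i = 1
    while i < len(lines) and lines[i].strip() != "columns":
        key, _, value = lines[i].partition("\t")
        header[key] = value
        i += 1
    try:
        alphabet = Alphabet(header["alphabet"])
        length = int(header["length"])
        gap_open = float(header["gap_open"])
        gap_extend = float(header["gap_extend"])
        background = np.array([float(x) for x in header["background"].split()])
        marker_id = header["marker_id"]
    except (KeyError, ValueError) as exc:
        raise MarkerSetError(f"{path}: malformed profile header ({exc})")
    consensus = []
    emissions = []
    for line in lines[i + 1 :]:
        if not line.strip():
            continue
        _, cons, probs = line.split("\t")
        consensus.append(cons)
        emissions.append([float(x) for x in probs.split()])
    if len(emissions) != length:
        raise MarkerSetError(f"{path}: expected {length} columns, got {len(emissions)}")
    return MarkerProfile(
        marker_id=marker_id,
        alphabet=alphabet,
        emissions=np.array(emissions),
        background=background,
        consensus="".join(consensus),
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


def write_marker_set(markers: MarkerSet, directory: str | Path) -> Path:
    """Write a marker set as a profile directory with a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for profile in markers.profiles:
        write_profile(profile, directory / f"{profile.marker_id}{PROFILE_SUFFIX}")
    manifest = {
        "name": markers.name,
        "alphabet": markers.alphabet.value,
        "n_markers": len(markers),
        "source": markers.source,
    }
    (directory / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1) + "\n")
    return directory


def load_marker_set(path: str | Path) -> MarkerSet:
    """Load a marker set from a profile directory.

    The directory must contain at least one ``*.profile`` file; a
    ``manifest.json`` is used for the set name when present, otherwise the
    directory name is used.  Profiles are ordered by marker id.
    """
    path = Path(path)
    if not path.exists():
        raise MarkerSetError(f"marker set path does not exist: {path}")
    if not path.is_dir():
        raise MarkerSetError(f"marker set path is not a directory: {path}")
    profiles = []
    for pf in sorted(path.glob(f"*{PROFILE_SUFFIX}")):
        profiles.append(read_profile(pf))
    if not profiles:
        raise MarkerSetError(f"no parseable profile files under {path}")
    ids = [p.marker_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({m for m in ids if ids.count(m) > 1})
        raise MarkerSetError(f"duplicate marker ids in {path}: {dupes}")
    name = path.name
    alphabet = profiles[0].alphabet
    manifest_path = path / MANIFEST_NAME
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        name = manifest.get("name", name)
    return MarkerSet(
        name=name, alphabet=alphabet, profiles=tuple(profiles), source=str(path)
    )


def build_marker_set_from_seed_msas(
    seed_dir: str | Path,
    alphabet: Alphabet = Alphabet.AMINO20,
    name: str | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> MarkerSet:
    """Build a marker set from a directory of aligned seed FASTA files.

    Each ``*.fasta``/``*.fa``/``*.faa`` file becomes one profile named after
    the file stem.
    """
    from .msa import read_fasta_msa

    seed_dir = Path(seed_dir)
    files = sorted(
        p for p in seed_dir.iterdir()
        if p.suffix in {".fasta", ".fa", ".faa", ".fna", ".aln"}
    )
    if not files:
        raise MarkerSetError(f"no seed alignment files under {seed_dir}")
    profiles = tuple(
        build_profile_from_msa(
            read_fasta_msa(f, alphabet), pseudocount=pseudocount, marker_id=f.stem
        )
        for f in files
    )
    return MarkerSet(
        name=name or seed_dir.name,
        alphabet=alphabet,
        profiles=profiles,
        source=str(seed_dir),
    )


# ---------------------------------------------------------------------------
# Fetch + cache
# ---------------------------------------------------------------------------

Transport = Callable[[str, Path], None]
"""A transport materializes the profile files for a URL into a directory."""


def default_transport(url: str, dest: Path) -> None:
    """Built-in transport: handles ``file://`` URLs and local paths.

    A directory source is copied; a ``.tar``/``.tar.gz`` archive is
    extracted.  Remote protocols require a user-supplied transport.
    """
    parsed = urlparse(url)
    if parsed.scheme in ("", "file"):
        src = Path(url2pathname(parsed.path) if parsed.scheme == "file" else url)
        if not src.exists():
            raise MarkerSetError(f"transport source does not exist: {src}")
        if src.is_dir():
            shutil.copytree(src, dest, dirs_exist_ok=True)
            return
        if src.suffixes[-1:] == [".tar"] or src.suffixes[-2:] == [".tar", ".gz"] \
                or src.suffix == ".tgz":
            try:
                with tarfile.open(src) as tar:
                    tar.extractall(dest, filter="data")
            except tarfile.TarError as exc:
                raise MarkerSetError(f"corrupt archive {src}: {exc}")
            return
        raise MarkerSetError(f"unsupported source file type: {src}")
    raise MarkerSetError(
        f"no built-in transport for scheme {parsed.scheme!r}; pass a transport"
    )


def default_cache_dir() -> Path:
    env = os.environ.get("PHYLOMARK_CACHE_DIR")
    if env:
        return Path(env)
    return Path.home() / ".phylomark" / "markersets"


def fetch_marker_set(
    name_or_url: str,
    cache_dir: str | Path | None = None,
    registry: Mapping[str, str] | None = None,
    transport: Transport | None = None,
) -> MarkerSet:
    """Fetch a marker set by name, URL, or local path, caching by name.

    Resolution order: an already-cached set of that name; a registry entry
    mapping the name to a URL; a URL (handled by *transport*); an existing
    local profile directory (loaded in place, not cached).  On a cache miss
    the transport materializes the set under ``cache_dir/<name>`` and later
    calls never invoke the transport again.
    """
    cache = Path(cache_dir) if cache_dir is not None else default_cache_dir()
    transport = transport or default_transport
    registry = registry or {}

    cached = cache / name_or_url
    if cached.is_dir():
        return load_marker_set(cached)

    if name_or_url in registry:
        url = registry[name_or_url]
        dest_name = name_or_url
    elif urlparse(name_or_url).scheme not in ("",):
        url = name_or_url
        dest_name = Path(urlparse(name_or_url).path).name or "markerset"
        for suffix in (".tar.gz", ".tgz", ".tar"):
            if dest_name.endswith(suffix):
                dest_name = dest_name[: -len(suffix)]
    elif Path(name_or_url).is_dir():
        return load_marker_set(name_or_url)
    else:
        raise MarkerSetError(
            f"cannot resolve marker set {name_or_url!r}: not cached, not in "
            f"the registry, and not a URL or existing directory"
        )

    dest = cache / dest_name
    if dest.is_dir():
        return load_marker_set(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    tmp = dest.with_name(dest.name + ".partial")
    if tmp.exists():
        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)
    try:
        transport(url, tmp)
        # tolerate archives wrapping the profile dir in one top-level folder
        root = tmp
        entries = list(tmp.iterdir())
        if len(entries) == 1 and entries[0].is_dir():
            root = entries[0]
        markers = load_marker_set(root)
        if root is tmp:
            tmp.rename(dest)
        else:
            root.rename(dest)
            shutil.rmtree(tmp, ignore_errors=True)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    return load_marker_set(dest)
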