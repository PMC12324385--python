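"""Sample digestion, profile search against a DP oracle, ortholog
resolution, and checkpoint semantics."""

import numpy as np
import pytest

from phylomark import (
    Alphabet,
    Hit,
    Msa,
    SearchError,
    CheckpointError,
    build_profile_from_msa,
    MarkerSet,
    digest_sample,
    load_checkpoint,
    resolve_orthologs,
    save_checkpoint,
    search_sample,
    update_checkpoint,
)
from phylomark.search import (
    SeqType,
    _sw_forward,
    checkpoint_to_json,
    profile_local_score,
)
from phylomark.msa import _column_scores, _encode
from phylomark.simulate import random_sequence


# ---------------------------------------------------------------------------
# oracle: plain-loop three-state Gotoh local alignment
# ---------------------------------------------------------------------------

def gotoh_local_oracle(S, go, ge):
    """Textbook cell-by-cell Smith-Waterman with affine gaps."""
    n, L = S.shape
    NEG = -np.inf
    H = np.zeros((n + 1, L + 1))
    E = np.full((n + 1, L + 1), NEG)
    F = np.full((n + 1, L + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, L + 1):
            E[i, j] = max(H[i, j - 1] - go, E[i, j - 1] - ge)
            F[i, j] = max(H[i - 1, j] - go, F[i - 1, j] - ge)
            H[i, j] = max(0.0, H[i - 1, j - 1] + S[i - 1, j - 1],
                          E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def _random_profile(rng, length, alphabet=Alphabet.AMINO20):
    rows = [
        (f"r{i}", random_sequence(length, rng, alphabet)) for i in range(4)
    ]
    return build_profile_from_msa(Msa(rows, alphabet), marker_id="p")


def test_search_score_equals_exhaustive_dp_oracle(rng):
    """Vectorized search scores match cell-by-cell Gotoh on small instances."""
    for trial in range(40):
        L = int(rng.integers(1, 11))
        n = int(rng.integers(1, 16))
        profile = _random_profile(rng, L)
        seq = random_sequence(n, rng)
        S = _column_scores(_encode(seq, profile.alphabet), profile.log_odds)
        fast = _sw_forward(S, profile.gap_open, profile.gap_extend)[0]
        slow = gotoh_local_oracle(S, profile.gap_open, profile.gap_extend)
        assert fast == pytest.approx(slow, abs=1e-9)


def test_consensus_attains_profile_maximum(toy_profile):
    score, span = profile_local_score(toy_profile.consensus, toy_profile)
    assert score == pytest.approx(toy_profile.max_score, abs=1e-9)
    assert span == (0, toy_profile.length)


def test_embedded_consensus_span_covers_the_substring(toy_profile):
    seq = "MMM" + toy_profile.consensus + "WW"
    score, span = profile_local_score(seq, toy_profile)
    assert score == pytest.approx(toy_profile.max_score, abs=1e-9)
    assert span == (3, 3 + toy_profile.length)


def test_shuffled_null_yields_no_hits_above_empirical_threshold(rng):
    """A 99.9th-percentile shuffle threshold excludes random sequences."""
    profile = _random_profile(rng, 60)
    base = list(random_sequence(200, rng))
    null_scores = []
    for _ in range(1000):
        rng.shuffle(base)
        null_scores.append(profile_local_score("".join(base), profile)[0])
    threshold = float(np.quantile(null_scores, 0.999))
    misses = 0
    trials = 100
    for _ in range(trials):
        seq = random_sequence(200, rng)
        if profile_local_score(seq, profile)[0] < threshold:
            misses += 1
    assert misses >= 0.99 * trials


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def test_digest_depends_only_on_content(tmp_path):
    content = ">s1\nMKLV\n>s2\nMKWW\n"
    p1 = tmp_path / "alpha.faa"
    p2 = tmp_path / "sub" / "beta.renamed.fa"
    p2.parent.mkdir()
    p1.write_text(content)
    p2.write_text(content)
    r1 = digest_sample(p1, "alpha", SeqType.PEPTIDE)
    r2 = digest_sample(p2, "beta", SeqType.PEPTIDE)
    assert r1.content_digest == r2.content_digest
    assert r1.n_sequences == 2

    p3 = tmp_path / "gamma.faa"
    p3.write_text(content.replace("MKLV", "MKLW"))
    assert digest_sample(p3, "g", SeqType.PEPTIDE).content_digest != r1.content_digest


def test_digest_rejects_empty_and_mismatched_files(tmp_path):
    empty = tmp_path / "empty.faa"
    empty.write_text("")
    with pytest.raises(SearchError):
        digest_sample(empty, "e", SeqType.PEPTIDE)
    pep = tmp_path / "pep.fna"
    pep.write_text(">x\nMKLVFF\n")
    with pytest.raises(SearchError, match="inconsistent"):
        digest_sample(pep, "p", SeqType.CDS)


# ---------------------------------------------------------------------------
# ortholog resolution
# ---------------------------------------------------------------------------

def _hit(digest, marker, seq):
    return Hit(sample_digest=digest, marker_id=marker, sequence_id=seq,
               bit_score=99.0, target_start=0, target_end=5)


def _sample(i):
    from phylomark.search import SampleRecord

    return SampleRecord(
        sample_id=f"s{i}", content_digest=f"d{i}", seq_type="pep",
        path=f"/x/s{i}.faa", n_sequences=1,
    )


def test_multi_hit_sample_is_excluded_for_that_marker_only():
    samples = [_sample(i) for i in range(5)]
    hits = {f"d{i}": [_hit(f"d{i}", "M", f"g{i}")] for i in range(5)}
    hits["d0"].append(_hit("d0", "M", "g0b"))  # second sequence hits M
    hits["d0"].append(_hit("d0", "N", "h0"))
    for i in range(1, 5):
        hits[f"d{i}"].append(_hit(f"d{i}", "N", f"h{i}"))
    table = resolve_orthologs(hits, samples)
    assert "s0" not in table.assignments["M"]
    assert table.excluded["M"] == ("s0",)
    assert set(table.assignments["M"]) == {"s1", "s2", "s3", "s4"}
    assert set(table.assignments["N"]) == {"s0", "s1", "s2", "s3", "s4"}


def test_clean_single_copy_case_has_no_exclusions():
    samples = [_sample(i) for i in range(4)]
    hits = {f"d{i}": [_hit(f"d{i}", "M", f"g{i}")] for i in range(4)}
    table = resolve_orthologs(hits, samples)
    assert table.excluded == {}
    assert table.dropped_markers == ()
    assert len(table.assignments["M"]) == 4


def test_marker_below_four_samples_is_dropped():
    samples = [_sample(i) for i in range(5)]
    hits = {f"d{i}": [_hit(f"d{i}", "M", f"g{i}")] for i in range(3)}
    hits["d3"] = []
    hits["d4"] = []
    table = resolve_orthologs(hits, samples)
    assert table.dropped_markers == ("M",)
    assert "M" not in table.assignments


def test_resolution_invariant_to_sample_order():
    samples = [_sample(i) for i in range(6)]
    hits = {f"d{i}": [_hit(f"d{i}", "M", f"g{i}")] for i in range(6)}
    hits["d2"].append(_hit("d2", "M", "extra"))
    t1 = resolve_orthologs(hits, samples)
    t2 = resolve_orthologs(hits, list(reversed(samples)))
    assert t1 == t2


def test_fewer_than_four_samples_rejected():
    samples = [_sample(i) for i in range(3)]
    with pytest.raises(SearchError, match="4"):
        resolve_orthologs({}, samples)


# ---------------------------------------------------------------------------
# checkpoint semantics
# ---------------------------------------------------------------------------

def _mini_world(tmp_path, n_samples=4):
    """Four tiny samples + a two-marker set where each sample has one gene
    per marker."""
    rng = np.random.default_rng(5)
    fams = {}
    for mid in ("mA", "mB"):
        root = random_sequence(40, rng)
        rows = []
        for i in range(n_samples + 2):
            seq = list(root)
            for _ in range(3):
                pos = int(rng.integers(len(seq)))
                seq[pos] = Alphabet.AMINO20.states[int(rng.integers(20))]
            rows.append((f"r{i}", "".join(seq)))
        fams[mid] = rows
    profiles = tuple(
        build_profile_from_msa(Msa(rows[:3], Alphabet.AMINO20), marker_id=mid)
        for mid, rows in fams.items()
    )
    markers = MarkerSet(name="mini", alphabet=Alphabet.AMINO20,
                        profiles=profiles)
    samples = []
    for i in range(n_samples):
        path = tmp_path / f"s{i}.faa"
        path.write_text(
            f">gA{i}\n{fams['mA'][3 + (i % 2)][1]}\n"
            f">gB{i}\n{fams['mB'][3 + (i % 2)][1]}\n"
        )
        samples.append(digest_sample(path, f"s{i}", SeqType.PEPTIDE))
    return markers, samples


def test_incremental_rerun_searches_only_new_samples(tmp_path):
    markers, samples = _mini_world(tmp_path, n_samples=5)
    ckpt, searched = update_checkpoint(None, samples[:4], markers, 30.0)
    assert sorted(searched) == [s.sample_id for s in samples[:4]]
    ckpt2, searched2 = update_checkpoint(ckpt, samples, markers, 30.0)
    assert searched2 == [samples[4].sample_id]
    # stored hits unchanged for old samples
    for s in samples[:4]:
        assert ckpt2.hits_by_sample[s.content_digest] == \
            ckpt.hits_by_sample[s.content_digest]


def test_identical_rerun_is_a_full_cache_hit_and_byte_stable(tmp_path):
    markers, samples = _mini_world(tmp_path)
    ckpt, _ = update_checkpoint(None, samples, markers, 30.0)
    ckpt2, searched = update_checkpoint(ckpt, samples, markers, 30.0)
    assert searched == []
    assert checkpoint_to_json(ckpt2) == checkpoint_to_json(ckpt)


def test_parameter_change_forces_full_research(tmp_path):
    markers, samples = _mini_world(tmp_path)
    ckpt, _ = update_checkpoint(None, samples, markers, 30.0)
    ckpt2, searched = update_checkpoint(ckpt, samples, markers, 35.0)
    assert sorted(searched) == [s.sample_id for s in samples]
    assert ckpt2.parameter_fingerprint != ckpt.parameter_fingerprint


def test_checkpoint_save_load_round_trip(tmp_path):
    markers, samples = _mini_world(tmp_path)
    ckpt, _ = update_checkpoint(None, samples, markers, 30.0)
    path = tmp_path / "hits.ckpt"
    save_checkpoint(ckpt, path)
    loaded = load_checkpoint(path)
    assert loaded == ckpt


def test_corrupt_checkpoint_is_refused(tmp_path):
    path = tmp_path / "bad.ckpt"
    path.write_text("{not json")
    with pytest.raises(CheckpointError):
        load_checkpoint(path)
    path.write_text('{"format": "something-else"}')
    with pytest.raises(CheckpointError):
        load_checkpoint(path)


def test_thread_count_does_not_change_results(tmp_path):
    markers, samples = _mini_world(tmp_path, n_samples=5)
    c1, _ = update_checkpoint(None, samples, markers, 30.0, threads=1)
    c2, _ = update_checkpoint(None, samples, markers, 30.0, threads=4)
    assert c1.hits_by_sample == c2.hits_by_sample
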