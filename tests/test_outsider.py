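"""Read-mapping (OUTSIDER) track: signals, clustering, best-read selection."""

import numpy as np
import pytest

import tedetect as td
from tedetect.core import parse_cigar
from tedetect.outsider import cluster_signals, collect_candidate_reads, select_best_read

from conftest import random_dna


def _read_record(cigar, pos, name="r1", tname="chr1", seq=None):
    cig = parse_cigar(cigar)
    qlen = sum(n for op, n in cig if op in "M=XIS")
    tlen = sum(n for op, n in cig if op in "M=XDN")
    return td.AlignmentRecord(
        query_id=name, target_id=tname, target_start=pos, target_end=pos + tlen,
        strand="+", cigar=cig, sequence=seq or "A" * qlen,
    )


# -- signal collection --------------------------------------------------------


def test_insertion_op_signal_position_and_size(config):
    rec = _read_record("4000M5000I4000M", pos=100_000)
    (sig,) = collect_candidate_reads([rec], config)
    assert sig.position == 104_000
    assert sig.size == 5000
    assert sig.signal_kind == "ins"
    assert sig.read_span == (4000, 9000)


def test_clip_signal_sequence_is_clipped_tail(config):
    seq = "A" * 6000 + "C" * 3000
    rec = _read_record("6000M3000S", pos=50_000, seq=seq)
    (sig,) = collect_candidate_reads([rec], config)
    assert sig.signal_kind == "clip_right"
    assert sig.position == 56_000
    assert sig.sequence == "C" * 3000


def test_left_clip_anchors_at_target_start(config):
    seq = "C" * 2500 + "A" * 4000
    rec = _read_record("2500S4000M", pos=70_000, seq=seq)
    (sig,) = collect_candidate_reads([rec], config)
    assert sig.signal_kind == "clip_left"
    assert sig.position == 70_000
    assert sig.sequence == "C" * 2500


def test_small_signals_and_secondary_records_ignored(config):
    small = _read_record("4000M29I4000M", pos=0)
    sec = _read_record("6000M3000S", pos=0)
    sec.flags = frozenset({"secondary"})
    assert collect_candidate_reads([small, sec], config) == []


# -- clustering ---------------------------------------------------------------


def _signal(pos, name, size=500):
    return td.SVCandidate(
        sv_type="INSERTION", contig="chr1", position=pos, size=size,
        sequence="A" * size, source="reads", supporting_read_ids=[name],
        signal_kind="ins", read_span=(0, size),
    )


def test_cluster_median_position(config):
    sigs = [_signal(1000, "a"), _signal(1010, "b"), _signal(1025, "c")]
    (cl,) = cluster_signals(sigs, config)
    assert cl.position == 1010
    assert cl.supporting_read_ids == ["a", "b", "c"]


def test_signals_beyond_window_split(config):
    sigs = [_signal(1000, "a"), _signal(1100, "b")]
    assert len(cluster_signals(sigs, config)) == 2


def test_clustering_invariant_under_input_order(config):
    rng = np.random.default_rng(0)
    sigs = [_signal(int(p), f"r{i}") for i, p in enumerate(rng.integers(0, 50_000, 200))]
    a = cluster_signals(sigs, config)
    shuffled = list(sigs)
    rng.shuffle(shuffled)
    b = cluster_signals(shuffled, config)
    assert [(c.position, tuple(c.supporting_read_ids)) for c in a] == [
        (c.position, tuple(c.supporting_read_ids)) for c in b
    ]


# -- best-read selection ------------------------------------------------------


def _cluster_with(members):
    return td.SVCandidate(
        sv_type="INSERTION", contig="chr1",
        position=members[0].position, size=members[0].size,
        source="reads",
        supporting_read_ids=sorted({m.supporting_read_ids[0] for m in members}),
        member_signals=members,
    )


def _mutated(seq, rate, seed):
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        out[i] = bases[(bases.index(out[i]) + 1) % 4]
    return "".join(out)


def test_select_best_read_prefers_highest_identity(library, config):
    zam = next(c for c in library if c.family == "ZAM").sequence
    members = [
        _te_signal(zam, 0.08, "r1", 1),
        _te_signal(zam, 0.02, "r2", 2),
        _te_signal(zam, 0.10, "r3", 3),
    ]
    rid, match, _ = select_best_read(_cluster_with(members), library, config)
    assert rid == "r2"
    assert match.family == "ZAM"


def _te_signal(te, rate, name, seed, pos=1000):
    seq = _mutated(te, rate, seed)
    sig = _signal(pos, name, size=len(seq))
    sig.sequence = seq
    return sig


def test_select_best_read_tie_breaks_on_read_id(library, config):
    zam = next(c for c in library if c.family == "ZAM").sequence
    members = [_te_signal(zam, 0.0, "rB", 1), _te_signal(zam, 0.0, "rA", 2)]
    rid, _, _ = select_best_read(_cluster_with(members), library, config)
    assert rid == "rA"


def test_cluster_of_non_te_reads_dropped(library, config):
    members = [_signal(1000, "r1", 500), _signal(1001, "r2", 500)]
    for m in members:
        m.sequence = random_dna(500, 77)
    assert select_best_read(_cluster_with(members), library, config) is None


# -- end-to-end ---------------------------------------------------------------


def test_no_planted_tes_no_calls(library, config):
    g = td.GenomeSequence("chr1", random_dna(100_000, 5))
    recs = [
        _read_record("20000M", pos=i * 10_000, name=f"r{i}") for i in range(8)
    ]
    calls = td.call_outsider({"chr1": g}, None, library, recs, config)
    assert calls == []


def test_single_read_with_full_te_yields_one_call(library, config):
    """A single spanning read suffices for an unambiguous insertion call."""
    g = td.GenomeSequence("chr1", random_dna(30_000, 6))
    zam = next(c for c in library if c.family == "ZAM")
    read_seq = g.sequence[5000:15_000] + zam.sequence + g.sequence[15_000:25_000]
    rec = td.AlignmentRecord(
        query_id="lone", target_id="chr1", target_start=5000, target_end=25_000,
        strand="+", cigar=[("M", 10_000), ("I", zam.length), ("M", 10_000)],
        sequence=read_seq,
    )
    calls = td.call_outsider({"chr1": g}, None, library, [rec], config)
    assert len(calls) == 1
    c = calls[0]
    assert c.family == "ZAM" and c.call_class == "OUTSIDER" and c.kind == "insertion"
    assert c.start == 15_000
    assert c.best_read_id == "lone"


def test_outsider_determinism_under_read_permutation(tiny_sample, config):
    s = tiny_sample
    asm = {s.assembly.id: s.assembly}
    calls_a = td.call_outsider(asm, s.reads, s.library, s.alignments, config)
    rng = np.random.default_rng(1)
    shuffled = list(s.alignments)
    rng.shuffle(shuffled)
    calls_b = td.call_outsider(asm, s.reads, s.library, shuffled, config)
    key = lambda c: (c.contig, c.start, c.family, c.best_read_id)
    assert [key(c) for c in calls_a] == [key(c) for c in calls_b]


def test_outsider_positions_near_truth(tiny_sample, config):
    s = tiny_sample
    calls = td.call_outsider(
        {s.assembly.id: s.assembly}, s.reads, s.library, s.alignments, config
    )
    res = td.match_calls(calls, s.truth.of_class("OUTSIDER"), tolerance=30)
    assert res.fp / max(1, res.tp + res.fp) <= 0.08
    assert res.tp + res.fn == len(s.truth.of_class("OUTSIDER"))
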