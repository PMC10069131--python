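"""Frequency estimation: local depth, spanning/clipped read counting,
CIGAR clip rewriting."""

import numpy as np
import pytest

import tedetect as td
from tedetect.core import parse_cigar
from tedetect.frequency import (
    AlignmentIndex,
    insider_frequency,
    local_depth,
    outsider_frequency,
    rewrite_clips_as_insertions,
)


def _read(name, start, length, cigar=None, flags=frozenset(), seq=True):
    cig = parse_cigar(cigar) if cigar else [("M", length)]
    qlen = sum(n for op, n in cig if op in "M=XIS")
    tlen = sum(n for op, n in cig if op in "M=XDN")
    return td.AlignmentRecord(
        query_id=name, target_id="chr1", target_start=start,
        target_end=start + tlen, strand="+", cigar=cig, flags=flags,
        sequence=("A" * qlen) if seq else None,
    )


def test_local_depth_uniform_coverage(config):
    # 60 reads each fully covering the windows -> depth 60
    recs = [_read(f"r{i}", 0, 5000) for i in range(60)]
    idx = AlignmentIndex(recs)
    assert local_depth(idx, "chr1", 2000, 2000, config) == 60


def test_local_depth_mean_of_two_windows(config):
    # 5' window covered by 50 reads, 3' window by 70
    recs = [_read(f"a{i}", 0, 1000) for i in range(50)]
    recs += [_read(f"b{i}", 1000, 1000) for i in range(70)]
    idx = AlignmentIndex(recs)
    assert local_depth(idx, "chr1", 1000, 1000, config) == 60


def test_local_depth_excludes_supplementary_and_secondary(config):
    recs = [_read(f"r{i}", 0, 5000) for i in range(10)]
    recs += [_read(f"s{i}", 0, 5000, flags=frozenset({"supplementary"})) for i in range(5)]
    recs += [_read(f"x{i}", 0, 5000, flags=frozenset({"secondary"})) for i in range(5)]
    idx = AlignmentIndex(recs)
    assert local_depth(idx, "chr1", 2000, 2000, config) == 10


def test_simulated_depth_matches_expectation(tiny_sample, config):
    """Mean 30 bp flank depth across random loci tracks the 60x design."""
    idx = AlignmentIndex(tiny_sample.alignments)
    rng = np.random.default_rng(3)
    total = sum(tiny_sample.recipe.depth_mix)
    vals = [
        local_depth(idx, tiny_sample.assembly.id, int(p), int(p), config)
        for p in rng.integers(50_000, len(tiny_sample.assembly) - 50_000, 40)
    ]
    assert abs(np.mean(vals) - total) / total < 0.10


# -- INSIDER ------------------------------------------------------------------


def _insider_call(start=10_000, end=15_000):
    return td.TECall(
        contig="chr1", start=start, end=end, family="ZAM",
        call_class="INSIDER", kind="insertion",
    )


def test_insider_frequency_arithmetic(config):
    # 50 reads through both junctions, 10 extra only in the flanks
    recs = [_read(f"c{i}", 5000, 15_000) for i in range(50)]
    recs += [_read(f"l{i}", 9100, 900) for i in range(5)]
    recs += [_read(f"r{i}", 15_000, 900) for i in range(5)]
    call = _insider_call()
    est = insider_frequency(AlignmentIndex(recs), call, config)
    assert est is not None
    assert est.supporting_reads == 50
    assert est.frequency == pytest.approx(50 / est.spanning_total, abs=1e-9)
    assert 0.0 <= est.frequency <= 1.0


def test_insider_frequency_zero_supporting(config):
    # all reads clipped at the 5' junction: none aligned through it
    recs = [_read(f"c{i}", 5000, 5000, cigar="5000M2000S") for i in range(30)]
    call = _insider_call()
    est = insider_frequency(AlignmentIndex(recs), call, config)
    assert est is not None and est.supporting_reads == 0
    assert est.frequency == 0.0


def test_insider_frequency_absent_when_no_depth(config):
    est = insider_frequency(AlignmentIndex([]), _insider_call(), config)
    assert est is None


def test_clipped_reads_do_not_support(config):
    # reads clipped exactly at the insertion start (non-carrier haplotype)
    carriers = [_read(f"c{i}", 5000, 15_000) for i in range(30)]
    clipped = [_read(f"n{i}", 5000, 5000, cigar="5000M8000S") for i in range(30)]
    est = insider_frequency(AlignmentIndex(carriers + clipped), _insider_call(), config)
    assert est is not None
    assert est.supporting_reads == 30  # only carriers count


# -- clip rewriting -----------------------------------------------------------


def _outsider_call(start=56_000):
    return td.TECall(
        contig="chr1", start=start, end=start + 1, family="ZAM",
        call_class="OUTSIDER", kind="insertion",
    )


def test_rewrite_clip_to_insertion_op(config):
    rec = _read("r1", 50_000, 6000, cigar="6000M3000S")
    (new,) = rewrite_clips_as_insertions([rec], _outsider_call(), 4990, config)
    assert new.cigar == [("M", 6000), ("I", 5000)]
    assert new.sequence.endswith("N" * 5000)
    assert len(new.sequence) == 11_000
    assert set(new.qualities[-5000:]) == {config.fake_quality}
    new.validate()


def test_rewrite_leaves_unrelated_records_alone(config):
    spanning = _read("r2", 50_000, 12_000, cigar="6000M5000I6000M")
    far = _read("r3", 10_000, 6000, cigar="6000M3000S")
    out = rewrite_clips_as_insertions([spanning, far], _outsider_call(), 4990, config)
    assert out[0].cigar == spanning.cigar
    assert out[1].cigar == far.cigar


def test_outsider_frequency_counts_each_read_once(config):
    """5 carriers (3 spanning + 2 clipped) over total depth 60 -> ~0.07."""
    te = 5000
    carriers = [
        _read(f"s{i}", 46_000, 20_000 + te, cigar=f"10000M{te}I10000M") for i in range(3)
    ]
    carriers += [_read("cl1", 46_000, 10_000, cigar="10000M4000S")]
    carriers += [_read("cl2", 56_000, 10_000, cigar="3000S10000M")]
    others = [_read(f"o{i}", 36_000, 40_000) for i in range(55)]
    est = outsider_frequency(
        AlignmentIndex(carriers + others), _outsider_call(), te, config
    )
    assert est is not None
    # 3 spanning reads count fully, 2 clip-only reads at half weight
    assert est.supporting_reads == 4
    assert est.spanning_total == 59
    assert est.frequency == pytest.approx(4 / 59)


def test_outsider_frequency_absent_without_depth(config):
    est = outsider_frequency(AlignmentIndex([]), _outsider_call(), 5000, config)
    assert est is None


def test_frequencies_always_in_unit_interval(tiny_sample, config):
    s = tiny_sample
    calls = td.call_outsider(
        {s.assembly.id: s.assembly}, s.reads, s.library, s.alignments, config
    )
    td.add_frequencies(calls, s.alignments, s.library, config)
    for c in calls:
        if c.frequency is not None:
            assert 0.0 <= c.frequency.frequency <= 1.0
            assert c.frequency.supporting_reads >= 0
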