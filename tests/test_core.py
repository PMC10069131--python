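"""Domain types and file I/O: coordinate conventions and round-trips."""

import pytest

import tedetect as td
from tedetect.core import parse_cigar, sanitize_dna


# -- alphabet -----------------------------------------------------------------


def test_sanitize_maps_iupac_ambiguity_to_n():
    assert sanitize_dna("acgtR") == "ACGTN"
    assert sanitize_dna("ACGU") == "ACGT"
    with pytest.raises(ValueError):
        sanitize_dna("ACG!")


def test_revcomp_involution():
    s = "ACGTTGCANN"
    assert td.revcomp(td.revcomp(s)) == s
    assert td.revcomp("ACGT") == "ACGT"
    assert td.revcomp("AAAC") == "GTTT"


# -- TE library ---------------------------------------------------------------


def test_load_te_library_counts_and_lengths(tmp_path):
    p = tmp_path / "lib.fa"
    p.write_text(">ZAM\n" + "A" * 8400 + "\n>gtwin\n" + "C" * 7400 + "\n")
    lib = td.load_te_library(p)
    assert [c.family for c in lib] == ["ZAM", "gtwin"]
    assert [c.length for c in lib] == [8400, 7400]


def test_load_te_library_rejects_duplicate_family(tmp_path):
    p = tmp_path / "lib.fa"
    p.write_text(">ZAM\nACGT\n>ZAM\nACGT\n")
    with pytest.raises(ValueError, match="duplicate"):
        td.load_te_library(p)


def test_load_te_library_rejects_empty(tmp_path):
    p = tmp_path / "lib.fa"
    p.write_text("")
    with pytest.raises(ValueError):
        td.load_te_library(p)


def test_default_library_parses_back_with_independent_reader(tmp_path, library):
    # round-trip through FASTA and an independent parser (Biopython)
    from Bio import SeqIO

    p = tmp_path / "lib.fa"
    td.write_fasta(library, p)
    recs = list(SeqIO.parse(str(p), "fasta"))
    assert len(recs) == 12
    assert {r.id for r in recs} == {c.family for c in library}
    for r in recs:
        cons = next(c for c in library if c.family == r.id)
        assert str(r.seq) == cons.sequence


# -- SAM / PAF parsing --------------------------------------------------------

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:200000\n"


def _parse_sam(tmp_path, body: str):
    p = tmp_path / "t.sam"
    p.write_text(SAM_HEADER + body)
    return td.parse_alignments(p)


def test_sam_pos_converts_to_zero_based_half_open(tmp_path):
    recs = _parse_sam(tmp_path, "r1\t0\tchr1\t1001\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n")
    (r,) = recs
    assert (r.target_start, r.target_end) == (1000, 1050)
    assert r.strand == "+" and r.is_primary


def test_sam_clips_and_supplementary_flag(tmp_path):
    recs = _parse_sam(
        tmp_path, "r2\t2048\tchr1\t501\t60\t20S80M\t*\t0\t0\t" + "A" * 100 + "\t*\n"
    )
    (r,) = recs
    assert r.left_clip == 20 and r.left_clip_is_soft
    assert "supplementary" in r.flags and not r.is_primary


def test_sam_unmapped_record_retained(tmp_path):
    recs = _parse_sam(tmp_path, "r3\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n")
    (r,) = recs
    assert r.is_unmapped and r.sequence == "ACGT"


def test_sam_cigar_sequence_mismatch_skipped(tmp_path):
    recs = _parse_sam(tmp_path, "r4\t0\tchr1\t100\t60\t10M\t*\t0\t0\tACGT\t*\n")
    assert recs == []


def test_paf_cg_tag_round_trips_insertion_op(tmp_path):
    p = tmp_path / "t.paf"
    p.write_text("q1\t65\t0\t65\t+\tchr1\t100\t10\t70\t60\t65\t60\tcg:Z:30M5I30M\n")
    (r,) = td.parse_alignments(p)
    assert ("I", 5) in r.cigar
    assert (r.target_start, r.target_end) == (10, 70)
    assert r.query_length == 65


def test_sam_writer_round_trip(tmp_path):
    rec = td.AlignmentRecord(
        query_id="r1", target_id="chr1", target_start=100, target_end=180,
        strand="+", cigar=[("S", 5), ("M", 80), ("S", 15)], sequence="A" * 100,
        qualities=tuple([20] * 100),
    )
    path = tmp_path / "o.sam"
    td.write_sam([rec], {"chr1": 1000}, path)
    (back,) = td.parse_alignments(path)
    assert back.cigar == rec.cigar
    assert (back.target_start, back.target_end) == (100, 180)
    assert back.sequence == rec.sequence
    assert back.qualities == rec.qualities


def test_paf_writer_round_trip(tmp_path):
    rec = td.AlignmentRecord(
        query_id="asm", target_id="chr1", target_start=0, target_end=10_000,
        strand="+", cigar=[("M", 5000), ("I", 300), ("M", 5000)], query_length=10_300,
    )
    path = tmp_path / "o.paf"
    td.write_paf([rec], {"asm": 10_300}, {"chr1": 10_000}, path)
    (back,) = td.parse_alignments(path)
    assert [op for op, _ in back.cigar if op != "S"] == ["M", "I", "M"]
    assert back.target_end == 10_000


# -- alignment record arithmetic ---------------------------------------------


def test_record_walk_and_blocks():
    rec = td.AlignmentRecord(
        query_id="r", target_id="c", target_start=1000, target_end=1105,
        strand="+", cigar=parse_cigar("10S40M5D20M5I40M10S"),
        sequence="A" * 125,
    )
    rec.validate()
    assert rec.query_consumed() == 125
    assert rec.aligned_blocks() == [(1000, 1040), (1045, 1105)]
    assert rec.covers(1050, 1100)
    assert not rec.covers(1030, 1050)  # interrupted by the deletion


def test_record_invariant_violations():
    with pytest.raises(ValueError):
        td.AlignmentRecord(
            query_id="r", target_id="c", target_start=10, target_end=10,
            strand="+", cigar=[("M", 5)], sequence="AAAAA",
        ).validate()


# -- calls BED round trip -----------------------------------------------------


def _example_calls():
    return [
        td.TECall(
            contig="chr1", start=1000, end=1005, family="ZAM",
            call_class="OUTSIDER", kind="insertion", strand="+",
            tsd=td.TSDRecord("ACGTA", 0, 0, 0),
            frequency=td.FrequencyEstimate(5, 60, 5 / 60),
            best_read_id="sb3_000001",
        ),
        td.TECall(
            contig="chr1", start=5000, end=9000, family="gtwin",
            call_class="INSIDER", kind="insertion", strand="-",
            ref_contig="chr1", ref_position=4800,
        ),
        td.TECall(
            contig="chr2", start=100, end=400, family="Doc",
            call_class="INSIDER", kind="deletion",
        ),
    ]


def test_calls_bed_round_trip(tmp_path):
    calls = _example_calls()
    p = tmp_path / "calls.bed"
    td.write_calls_bed(calls, p)
    back = td.read_calls_bed(p)
    assert len(back) == len(calls)
    for a, b in zip(calls, back):
        assert (a.contig, a.start, a.end, a.family, a.call_class, a.kind) == (
            b.contig, b.start, b.end, b.family, b.call_class, b.kind
        )
        assert a.tsd == b.tsd
        assert a.frequency == b.frequency
        assert a.best_read_id == b.best_read_id
        assert (a.ref_contig, a.ref_position) == (b.ref_contig, b.ref_position)


def test_calls_bed_score_is_percent_frequency(tmp_path):
    p = tmp_path / "calls.bed"
    td.write_calls_bed(_example_calls()[:1], p)
    line = [l for l in p.read_text().splitlines() if not l.startswith("#")][0]
    fields = line.split("\t")
    assert fields[:6] == ["chr1", "1000", "1005", "ZAM", "8", "+"]


def test_calls_bed_empty_and_unsorted(tmp_path):
    p = tmp_path / "empty.bed"
    td.write_calls_bed([], p)
    assert td.read_calls_bed(p) == []
    # unsorted input is sorted before writing
    calls = list(reversed(_example_calls()))
    td.write_calls_bed(calls, p)
    back = td.read_calls_bed(p)
    assert [c.start for c in back] == sorted(c.start for c in back[:2]) + [back[2].start]
    assert [c.contig for c in back] == ["chr1", "chr1", "chr2"]


def test_truth_bed_round_trip(tmp_path, tiny_sample):
    p = tmp_path / "truth.bed"
    td.write_truth_bed(tiny_sample.truth, p)
    back = td.read_truth_bed(p)
    orig = sorted(tiny_sample.truth, key=lambda e: (e.contig, e.position))
    assert len(back) == len(orig)
    for a, b in zip(orig, back.events):
        assert (a.contig, a.position, a.family, a.class_label, a.tsd) == (
            b.contig, b.position, b.family, b.class_label, b.tsd
        )
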