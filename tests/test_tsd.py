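"""TSD detection: Boyer-Moore search, flank motif finding, filters,
position correction."""

import numpy as np
import pytest

import tedetect as td
from tedetect.tsd import (
    boyer_moore_search,
    check_tsd_uniqueness,
    correct_position,
    detect_call_tsd,
    filter_tsd,
    find_tsd,
)

from conftest import random_dna


# -- Boyer-Moore --------------------------------------------------------------


def _naive_all(text, pattern):
    return [i for i in range(len(text) - len(pattern) + 1) if text[i : i + len(pattern)] == pattern]


def test_boyer_moore_agrees_with_naive_search_on_random_inputs():
    rng = np.random.default_rng(13)
    for _ in range(300):
        n = int(rng.integers(1, 60))
        m = int(rng.integers(1, 8))
        text = "".join(rng.choice(list("ACGT"), size=n))
        pattern = "".join(rng.choice(list("ACGT"), size=m))
        assert boyer_moore_search(text, pattern) == _naive_all(text, pattern)


def test_boyer_moore_overlapping_occurrences():
    assert boyer_moore_search("ATATATAT", "ATAT") == [0, 2, 4]
    assert boyer_moore_search("AAAA", "AA") == [0, 1, 2]
    assert boyer_moore_search("ACGT", "ACGTA") == []


# -- find_tsd -----------------------------------------------------------------


def _brute_force_tsd(left, right, max_mm, min_len=2):
    """Exhaustive search over all substring placements; independent oracle."""
    best = None
    for length in range(min(len(left), len(right)), min_len - 1, -1):
        cands = []
        for lo in range(len(left) - length + 1):
            motif = left[len(left) - length - lo : len(left) - lo]
            for ro in range(len(right) - length + 1):
                mm = sum(a != b for a, b in zip(motif, right[ro : ro + length]))
                if mm <= max_mm:
                    cands.append((lo + ro, ro, lo, motif, mm))
        if cands:
            lo_ro, ro, lo, motif, mm = min(cands)
            return motif, lo, ro, mm
    return None


def test_find_tsd_exact_motif_at_junctions():
    left = random_dna(25, 1) + "ACGTA"
    right = "ACGTA" + random_dna(25, 2)
    t = find_tsd(left, right, max_mismatch=0)
    assert t is not None
    assert t.motif.endswith("ACGTA") and t.left_pos == 0 and t.right_pos == 0
    assert t.mismatches == 0


def test_find_tsd_mismatch_tolerance():
    left = "TTTTTTTTTTTTTTTTTTTTTTTTTACGTA"
    right_exact = "ACTTA" + "G" * 25
    t1 = find_tsd(left, right_exact, max_mismatch=1)
    assert t1 is not None and len(t1.motif) >= 5 and t1.mismatches <= 1
    t0 = find_tsd(left, right_exact, max_mismatch=0)
    assert t0 is None or len(t0.motif) < 5


def test_find_tsd_short_flanks_return_none():
    assert find_tsd("A", "ACGT", 0) is None


def test_find_tsd_matches_brute_force_oracle():
    rng = np.random.default_rng(99)
    for i in range(200):
        n = int(rng.integers(4, 16))
        left = "".join(rng.choice(list("ACGT"), size=n))
        right = "".join(rng.choice(list("ACGT"), size=n))
        got = find_tsd(left, right, max_mismatch=0)
        expected = _brute_force_tsd(left, right, 0)
        if expected is None:
            assert got is None
        else:
            motif, lo, ro, mm = expected
            assert got is not None
            assert len(got.motif) == len(motif)
            assert got.left_pos + got.right_pos == lo + ro


def test_random_flank_motifs_stay_short():
    """Independent 30-mers share only short chance motifs (median <= 4)."""
    rng = np.random.default_rng(7)
    lengths = []
    for _ in range(1000):
        left = "".join(rng.choice(list("ACGT"), size=30))
        right = "".join(rng.choice(list("ACGT"), size=30))
        t = find_tsd(left, right, max_mismatch=0)
        lengths.append(len(t.motif) if t else 0)
    assert np.median(lengths) <= 4


# -- filters ------------------------------------------------------------------


@pytest.mark.parametrize(
    "lo,ro,kept", [(0, 0, True), (2, 2, True), (3, 0, False), (0, 3, False)]
)
def test_filter_tsd_junction_tolerance(lo, ro, kept, config):
    t = td.TSDRecord("ACGTA", lo, ro, 0)
    assert (filter_tsd(t, config) is not None) == kept


def test_uniqueness_filter():
    t = td.TSDRecord("ACGTA", 0, 0, 0)
    assert check_tsd_uniqueness(t, "TTTTACGTATTTT")
    assert not check_tsd_uniqueness(t, "ACGTATTACGTA")
    assert not check_tsd_uniqueness(t, "TTTTTTTTTT")
    at = td.TSDRecord("AT", 0, 0, 0)
    assert not check_tsd_uniqueness(at, "ATATATATAT")


# -- position correction ------------------------------------------------------


def _call(start=1003, end=1004):
    return td.TECall(
        contig="chr1", start=start, end=end, family="ZAM",
        call_class="OUTSIDER", kind="insertion",
    )


def test_correct_position_applies_shift(config):
    t = td.TSDRecord("ACGTA", 0, 0, 0)
    c = correct_position(_call(), t, shift5=0, shift3=0, config=config)
    assert (c.start, c.end) == (1003, 1004)
    assert c.tsd == t
    c2 = correct_position(_call(), t, shift5=3, shift3=0, config=config)
    assert c2.start == 1006


def test_correct_position_bounded_by_flank(config):
    t = td.TSDRecord("ACGTA", 0, 0, 0)
    c = correct_position(_call(), t, shift5=1000, config=config)
    assert c.start - 1003 <= config.tsd_flank


def test_insider_call_tsd_trims_duplicated_motif(config):
    """An element whose reported interval still contains the trailing copy
    of the site motif is trimmed back to the true 3' junction."""
    motif = "CATTG"
    left = "T" * 25 + motif
    te = random_dna(399, 4) + "A"  # last element base differs from left context
    right = "G" * 30
    insert = te + motif  # SV sequence: element plus duplicated site motif
    tsd, s5, s3 = detect_call_tsd(left, insert, right, 0, config)
    assert tsd is not None and tsd.motif == motif
    assert (s5, s3) == (0, 5)


def test_detected_tsds_on_simulated_insertions(tiny_sample, config):
    """Planted 4-6 bp TSDs: most corrected calls sit within 2 bp of the
    planted junction and carry the planted motif."""
    s = tiny_sample
    calls = td.call_outsider(
        {s.assembly.id: s.assembly}, s.reads, s.library, s.alignments, config
    )
    truth = {e.position: e for e in s.truth.of_class("OUTSIDER")}
    with_tsd = 0
    good = 0
    for c in calls:
        near = [e for p, e in truth.items() if abs(p - c.start) <= 30]
        if not near:
            continue
        e = near[0]
        if c.tsd is not None:
            with_tsd += 1
            overlap = e.tsd in c.tsd.motif or c.tsd.motif in e.tsd
            if overlap and abs(c.start - e.position) <= 2:
                good += 1
    assert with_tsd >= 0.8 * len(calls)
    assert good >= 0.9 * with_tsd
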