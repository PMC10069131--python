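"""Target-site duplication (TSD) detection and junction correction.

TE integration via staggered double-strand breaks duplicates a short motif
of the insertion site, leaving one copy immediately 5' and one immediately
3' of the inserted element.  Detecting that duplicated motif (i) confirms a
genuine integration event and (ii) pins the junctions down to base-pair
precision, so call coordinates are corrected to the TSD-defined junctions.

Exact motif search uses the Boyer-Moore algorithm (bad-character + good-
suffix rules); the mismatch-tolerant mode used for read-derived calls runs
a Hamming-distance scan per candidate motif (mismatches, not edits).
"""

from __future__ import annotations

from dataclasses import replace

from .core import PipelineConfig, TECall, TSDRecord, logger

# ---------------------------------------------------------------------------
# Boyer-Moore exact search
# ---------------------------------------------------------------------------


def _bad_char_table(pattern: str) -> dict[str, int]:
    return {ch: i for i, ch in enumerate(pattern)}


def _good_suffix_tables(pattern: str) -> tuple[list[int], list[int]]:
    m = len(pattern)
    # border positions (classic preprocessing, strong good-suffix rule)
    shift = [0] * (m + 1)
    border = [0] * (m + 1)
    i, j = m, m + 1
    border[i] = j
    while i > 0:
        while j <= m and pattern[i - 1] != pattern[j - 1]:
            if shift[j] == 0:
                shift[j] = j - i
            j = border[j]
        i -= 1
        j -= 1
        border[i] = j
    j = border[0]
    for i in range(m + 1):
        if shift[i] == 0:
            shift[i] = j
        if i == j:
            j = border[j]
    return shift, border


def boyer_moore_search(text: str, pattern: str) -> list[int]:
    """All start positions of exact occurrences of ``pattern`` in ``text``."""
    n, m = len(text), len(pattern)
    if m == 0 or n < m:
        return []
    bad = _bad_char_table(pattern)
    shift, _ = _good_suffix_tables(pattern)
    hits: list[int] = []
    s = 0
    while s <= n - m:
        j = m - 1
        while j >= 0 and pattern[j] == text[s + j]:
            j -= 1
        if j < 0:
            hits.append(s)
            s += shift[0]
        else:
            bc = j - bad.get(text[s + j], -1)
            s += max(shift[j + 1], bc, 1)
    return hits


def _hamming_occurrences(text: str, pattern: str, max_mismatch: int) -> list[tuple[int, int]]:
    """(position, mismatches) for every placement with <= max_mismatch."""
    if max_mismatch == 0:
        return [(p, 0) for p in boyer_moore_search(text, pattern)]
    out = []
    m = len(pattern)
    for s in range(len(text) - m + 1):
        mm = 0
        for a, b in zip(pattern, text[s : s + m]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            out.append((s, mm))
    return out


# ---------------------------------------------------------------------------
# TSD search on junction flanks
# ---------------------------------------------------------------------------


def find_tsd(
    left_flank: str,
    right_flank: str,
    max_mismatch: int = 0,
    min_len: int = 2,
    max_len: int | None = None,
) -> TSDRecord | None:
    """Longest motif shared between the tail of ``left_flank`` and the head
    of ``right_flank``.

    The motif is taken verbatim from the left flank (candidate motifs are
    its suffix-region substrings) and searched in the right flank allowing
    ``max_mismatch`` mismatches (no indels); exact mode uses Boyer-Moore.
    ``left_pos`` is the distance of the motif's end from the end of the left
    flank; ``right_pos`` the distance of its start from the beginning of the
    right flank (both are junction offsets, 0 = flush with the junction).
    Ties on length break by smallest total offset, then leftmost.
    """
    L, R = left_flank.upper(), right_flank.upper()
    if len(L) < min_len or len(R) < min_len:
        return None
    if max_len is None:
        max_len = min(len(L), len(R))
    best: TSDRecord | None = None
    for length in range(min(max_len, len(L), len(R)), min_len - 1, -1):
        candidates: list[TSDRecord] = []
        for end_off in range(0, len(L) - length + 1):
            motif = L[len(L) - length - end_off : len(L) - end_off]
            for pos, mm in _hamming_occurrences(R, motif, max_mismatch):
                candidates.append(TSDRecord(motif, end_off, pos, mm))
        if candidates:
            best = min(candidates, key=lambda t: (t.left_pos + t.right_pos, t.right_pos, t.left_pos))
            break
    return best


def filter_tsd(tsd: TSDRecord | None, config: PipelineConfig) -> TSDRecord | None:
    """Reject TSDs whose motif sits more than the junction tolerance away
    from either junction (a distant repeat is likely a pre-existing genomic
    duplication, not a TSD)."""
    if tsd is None:
        return None
    tol = config.tsd_junction_tolerance
    if tsd.left_pos > tol or tsd.right_pos > tol:
        return None
    return tsd


def check_tsd_uniqueness(tsd: TSDRecord, locus_window: str, max_mismatch: int = 0) -> bool:
    """True iff the motif occurs exactly once in the empty-site window.

    A motif repeated at the locus cannot anchor the empty site, so such
    TSDs are discarded for read-derived (OUTSIDER) calls.
    """
    return len(boyer_moore_search(locus_window.upper(), tsd.motif)) == 1


def _tail_tsd(left_flank: str, insert_seq: str, max_mismatch: int,
              min_len: int, max_len: int) -> tuple[TSDRecord, int] | None:
    """TSD whose 3' copy was absorbed into the tail of the insertion.

    An aligner placing the insertion after the (single) site copy yields an
    inserted sequence ending with the duplicated motif; the left flank then
    ends with the other copy.  Returns the record and the junction shift d
    (the corrected 3' junction is insertion_end - d).
    """
    best: tuple[int, int, TSDRecord, int] | None = None  # (score, -mm, tsd, d)
    for d in range(min(max_len, len(left_flank), len(insert_seq)), min_len - 1, -1):
        a, b = left_flank[-d:], insert_seq[-d:]
        mm = sum(1 for x, y in zip(a, b) if x != y)
        if mm <= max_mismatch:
            # score penalizes mismatches so the exact motif beats a longer
            # extension that merely fits within the mismatch budget (flank
            # context matching 1-3 extra bases by chance is common)
            cand = (d - 4 * mm, -mm, TSDRecord(b, 0, 0, mm), d)
            if best is None or cand[:2] > best[:2]:
                best = cand
    return (best[2], best[3]) if best else None


def _head_tsd(insert_seq: str, right_flank: str, max_mismatch: int,
              min_len: int, max_len: int) -> tuple[TSDRecord, int] | None:
    """Mirror case: the 5' copy was absorbed into the head of the insertion."""
    best: tuple[int, int, TSDRecord, int] | None = None
    for d in range(min(max_len, len(right_flank), len(insert_seq)), min_len - 1, -1):
        a, b = insert_seq[:d], right_flank[:d]
        mm = sum(1 for x, y in zip(a, b) if x != y)
        if mm <= max_mismatch:
            cand = (d - 4 * mm, -mm, TSDRecord(a, 0, 0, mm), d)
            if best is None or cand[:2] > best[:2]:
                best = cand
    return (best[2], best[3]) if best else None


def detect_call_tsd_candidates(
    left_flank: str,
    insert_seq: str,
    right_flank: str,
    max_mismatch: int,
    config: PipelineConfig,
) -> list[tuple[TSDRecord, int, int]]:
    """Ranked TSD candidates for one call, best first.

    Each entry is (tsd, shift5, shift3): positive shifts move the 5'
    junction right / the 3' junction left (motif copies absorbed into the
    reported insertion).  Three placements are tried — flank-vs-flank
    (junctions already correct), insertion tail vs left flank, insertion
    head vs right flank — and ranked by ``length - 4 x mismatches`` so an
    exact motif outranks a longer extension allowed by the mismatch
    budget.  Returning the ranking (not just the winner) lets the caller
    fall back when a downstream filter rejects the top candidate.
    """
    max_len = config.tsd_flank
    found: list[tuple[int, TSDRecord, int, int]] = []  # (len, tsd, shift5, shift3)
    t = filter_tsd(find_tsd(left_flank, right_flank, max_mismatch, max_len=max_len), config)
    if t:
        found.append((len(t.motif), t, 0, 0))
    for mm_budget in range(max_mismatch + 1):
        tail = _tail_tsd(left_flank, insert_seq, mm_budget, 2, max_len)
        if tail:
            found.append((len(tail[0].motif), tail[0], 0, tail[1]))
        head = _head_tsd(insert_seq, right_flank, mm_budget, 2, max_len)
        if head:
            found.append((len(head[0].motif), head[0], head[1], 0))
    ranked = sorted(
        {(f[1], f[2], f[3]) for f in found},
        key=lambda f: (-(len(f[0].motif) - 4 * f[0].mismatches), f[1] + f[2]),
    )
    return ranked


def detect_call_tsd(
    left_flank: str,
    insert_seq: str,
    right_flank: str,
    max_mismatch: int,
    config: PipelineConfig,
) -> tuple[TSDRecord | None, int, int]:
    """Best TSD for one call (see :func:`detect_call_tsd_candidates`)."""
    ranked = detect_call_tsd_candidates(
        left_flank, insert_seq, right_flank, max_mismatch, config
    )
    if not ranked:
        return None, 0, 0
    return ranked[0]


def correct_position(call: TECall, tsd: TSDRecord, shift5: int = 0, shift3: int = 0,
                     config: PipelineConfig | None = None) -> TECall:
    """Attach a retained TSD and move the call to the TSD-defined junctions.

    The correction never moves a junction by more than the flank length.
    """
    cfg = config or PipelineConfig()
    shift5 = min(shift5, cfg.tsd_flank)
    shift3 = min(shift3, cfg.tsd_flank)
    new_start = call.start + shift5
    if call.call_class == "OUTSIDER":
        # point insertion on the assembly: only the 5' shift moves the
        # junction; the 3' shift trims the inserted segment, not the locus
        new_end = new_start + 1
    else:
        new_end = max(call.end - shift3, new_start + 1)
    if (shift5 or shift3) and call.kind == "insertion":
        logger.debug(
            "TSD %s corrects %s:%d-%d -> %d-%d", tsd.motif, call.contig,
            call.start, call.end, new_start, new_end,
        )
    return replace(call, start=new_start, end=new_end, tsd=tsd)


def annotate_call_tsd(
    call: TECall,
    assembly_seq: str,
    insert_seq: str | None,
    config: PipelineConfig,
    read_seq: str | None = None,
    read_insert_span: tuple[int, int] | None = None,
) -> TECall:
    """Run the full TSD stage on one call and return the (possibly
    corrected) call.

    INSIDER insertions take their flanks from the assembly around the call
    interval and use exact matching; OUTSIDER insertions take flanks from
    the best supporting read around the inserted segment, allow mismatches,
    and additionally require the motif to be unique in the empty-site
    window of the assembly.  Deletions are left untouched.
    """
    if call.kind != "insertion":
        return call
    flank = config.tsd_flank
    if call.call_class == "INSIDER":
        left = assembly_seq[max(0, call.start - flank) : call.start]
        right = assembly_seq[call.end : call.end + flank]
        seq = insert_seq if insert_seq is not None else assembly_seq[call.start : call.end]
        mm = config.tsd_max_mismatch_insider
    else:
        if read_seq is None or read_insert_span is None:
            return call
        i0, i1 = read_insert_span
        left = read_seq[max(0, i0 - flank) : i0]
        right = read_seq[i1 : i1 + flank]
        seq = read_seq[i0:i1]
        mm = config.tsd_max_mismatch_outsider
    if len(left) < 2 or len(seq) < 2:
        return call
    candidates = detect_call_tsd_candidates(left, seq, right, mm, config)
    for tsd, s5, s3 in candidates[:5]:
        # a candidate that moves the junction must be longer than a chance
        # 2-3mer; zero-shift candidates only annotate and are harmless
        if (s5 or s3) and len(tsd.motif) < 4:
            continue
        if call.call_class == "OUTSIDER":
            w0 = max(0, call.start - flank)
            window = assembly_seq[w0 : call.start + flank]
            if not check_tsd_uniqueness(tsd, window):
                continue
        return correct_position(call, tsd, s5, s3, config)
    return call
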