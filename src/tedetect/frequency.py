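"""Allele-frequency estimation for TE calls.

The frequency of an insertion is the number of reads carrying it divided
by the total number of reads spanning the locus.  The denominator is the
rounded mean per-base depth of the two 30 bp windows flanking the
junctions (supplementary and secondary records excluded).  The numerator
differs by track:

* INSIDER (element present in the assembly): reads overlapping the call
  interval (with a 100 bp margin) that align straight through a junction
  — no clip or gap within a 5 bp window of it — are supporting; reads
  from haplotypes lacking the element get clipped at the junction and are
  excluded.  The default counts junction-crossing reads (mean of the two
  junctions); a stricter variant requiring a single read to span the
  whole element is available via ``insider_support_mode='span'``.
* OUTSIDER (element absent from the assembly): terminal soft clips
  abutting the call position are rewritten into insertion operations of
  the element length plus 10 bp (the clipped bases replaced by that many
  N's at quality 8), the rewritten records are re-clustered with the same
  signal logic used for detection, and the supporting count is the number
  of distinct reads in the cluster at the call position.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from intervaltree import IntervalTree

from .core import (
    AlignmentRecord,
    FrequencyEstimate,
    PipelineConfig,
    TECall,
    TEConsensus,
    logger,
)
from .outsider import cluster_signals, collect_candidate_reads


class AlignmentIndex:
    """Interval index over primary + supplementary mapped records."""

    def __init__(self, records: list[AlignmentRecord]):
        self._trees: dict[str, IntervalTree] = {}
        for rec in records:
            if rec.is_unmapped or "secondary" in rec.flags:
                continue
            self._trees.setdefault(rec.target_id, IntervalTree()).addi(
                rec.target_start, max(rec.target_end, rec.target_start + 1), rec
            )

    def overlapping(self, contig: str, start: int, end: int) -> list[AlignmentRecord]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        recs = [iv.data for iv in tree.overlap(start, end)]
        recs.sort(key=lambda r: (r.target_start, r.query_id))
        return recs


def _window_mean_depth(records: list[AlignmentRecord], start: int, end: int) -> float:
    if end <= start:
        return 0.0
    cov = np.zeros(end - start, dtype=np.int32)
    for rec in records:
        if rec.flags & {"secondary", "supplementary"} or rec.is_unmapped:
            continue
        for b0, b1 in rec.aligned_blocks():
            lo, hi = max(b0, start), min(b1, end)
            if lo < hi:
                cov[lo - start : hi - start] += 1
    return float(cov.mean())


def local_depth(
    index: AlignmentIndex,
    contig: str,
    junction5: int,
    junction3: int,
    config: PipelineConfig,
) -> int:
    """Rounded mean per-base depth of the 30 bp windows 5' of ``junction5``
    and 3' of ``junction3`` (supplementary/secondary excluded)."""
    w = config.depth_window
    w5 = (max(0, junction5 - w), junction5)
    w3 = (junction3, junction3 + w)
    if junction5 - w < 0:
        logger.warning("5' depth window truncated at contig start (%s:%d)", contig, junction5)
    means = []
    for s, e in (w5, w3):
        recs = index.overlapping(contig, s, e)
        means.append(_window_mean_depth(recs, s, e))
    return round(sum(means) / 2)


def _covers_through(rec: AlignmentRecord, junction: int, halfwin: int) -> bool:
    """Aligned straight through [junction-halfwin, junction+halfwin)."""
    return rec.covers(max(0, junction - halfwin), junction + halfwin)


def insider_frequency(
    index: AlignmentIndex, call: TECall, config: PipelineConfig
) -> FrequencyEstimate | None:
    """Frequency of an assembly-borne (INSIDER) insertion."""
    fetch = config.insider_fetch_window
    jw = config.insider_junction_window
    recs = [
        r
        for r in index.overlapping(call.contig, call.start - fetch, call.end + fetch)
        if not (r.flags & {"secondary", "supplementary"})
    ]
    if config.insider_support_mode == "span":
        supporting = sum(
            1 for r in recs if r.covers(max(0, call.start - jw), call.end + jw)
        )
    else:
        n5 = sum(1 for r in recs if _covers_through(r, call.start, jw))
        n3 = sum(1 for r in recs if _covers_through(r, call.end, jw))
        supporting = round((n5 + n3) / 2)
    total = local_depth(index, call.contig, call.start, call.end, config)
    if total == 0:
        logger.warning("no flank depth at %s:%d; frequency absent", call.contig, call.start)
        return None
    freq = supporting / total
    if freq > 1.0:
        logger.debug("raw frequency %.3f clamped to 1 at %s:%d", freq, call.contig, call.start)
    return FrequencyEstimate(supporting, total, min(freq, 1.0))


def rewrite_clips_as_insertions(
    records: list[AlignmentRecord],
    call: TECall,
    te_length: int,
    config: PipelineConfig,
) -> list[AlignmentRecord]:
    """Turn junction-abutting terminal soft clips into insertion operations.

    The clip is replaced by an I run of ``te_length + 10`` bp and the read
    sequence receives that many N bases at quality 8, so a re-clustering
    pass sees clipped reads as full-length insertion carriers.  Records
    whose clip is on the wrong side of (or far from) the junction are left
    untouched; the rewritten CIGAR stays length-consistent.
    """
    ins_len = te_length + config.cigar_rewrite_pad
    win = config.cluster_window
    out: list[AlignmentRecord] = []
    for rec in records:
        new = rec
        if rec.sequence and not rec.is_unmapped:
            seq, cigar = rec.sequence, list(rec.cigar)
            quals = list(rec.qualities) if rec.qualities else [config.fake_quality + 4] * len(seq)
            changed = False
            if (
                rec.right_clip_is_soft
                and rec.right_clip >= config.min_rewrite_clip
                and abs(rec.target_end - call.start) <= win
            ):
                c = cigar.pop()[1]
                cigar.append(("I", ins_len))
                seq = seq[:-c] + "N" * ins_len
                quals = quals[:-c] + [config.fake_quality] * ins_len
                changed = True
            elif (
                rec.left_clip_is_soft
                and rec.left_clip >= config.min_rewrite_clip
                and abs(rec.target_start - call.start) <= win
            ):
                c = cigar.pop(0)[1]
                cigar.insert(0, ("I", ins_len))
                seq = "N" * ins_len + seq[c:]
                quals = [config.fake_quality] * ins_len + quals[c:]
                changed = True
            if changed:
                new = replace(
                    rec, cigar=cigar, sequence=seq, qualities=tuple(quals)
                )
                new.validate()
        out.append(new)
    return out


def outsider_frequency(
    index: AlignmentIndex,
    call: TECall,
    te_length: int,
    config: PipelineConfig,
) -> FrequencyEstimate | None:
    """Frequency of a read-only (OUTSIDER) insertion.

    Supporting reads are the distinct reads in the re-clustered signal at
    the call position, counting both reads that already carried a full
    insertion operation and clipped reads rewritten into carriers; a read
    contributing several signals is counted once.
    """
    win = config.cluster_window
    recs = [
        r
        for r in index.overlapping(call.contig, call.start - win, call.start + win + 1)
        if not (r.flags & {"secondary", "supplementary"})
    ]
    spanning_ids = {
        s.supporting_read_ids[0]
        for s in collect_candidate_reads(recs, config)
        if s.signal_kind == "ins" and abs(s.position - call.start) <= win
    }
    rewritten = rewrite_clips_as_insertions(recs, call, te_length, config)
    signals = [
        s for s in collect_candidate_reads(rewritten, config) if s.signal_kind != "unmapped"
    ]
    clusters = cluster_signals(signals, config)
    supporting_ids: set[str] = set()
    for cl in clusters:
        if cl.contig == call.contig and abs(cl.position - call.start) <= win:
            supporting_ids.update(cl.supporting_read_ids)
    total = local_depth(index, call.contig, call.start, call.start, config)
    if total == 0:
        logger.warning(
            "no reads span %s:%d; frequency absent (NA)", call.contig, call.start
        )
        return None
    # a clipped read shows only one junction side, and correspondingly
    # contributes to only one of the two flank-depth windows of the
    # denominator; weight clip-only carriers by 1/2 to keep the ratio an
    # unbiased estimate of the haplotype fraction
    n_span = len(supporting_ids & spanning_ids)
    n_clip = len(supporting_ids - spanning_ids)
    supporting = int(n_span + 0.5 * n_clip + 0.5)
    freq = supporting / total
    return FrequencyEstimate(supporting, total, min(freq, 1.0))


def add_frequencies(
    calls: list[TECall],
    records: list[AlignmentRecord],
    library: list[TEConsensus],
    config: PipelineConfig | None = None,
) -> list[TECall]:
    """Attach frequency estimates to calls in place (deletions get none,
    as no read-level procedure applies to an element the sample lost)."""
    config = config or PipelineConfig()
    index = AlignmentIndex(records)
    te_len = {c.family: c.length for c in library}
    for call in calls:
        if call.kind != "insertion":
            continue
        if call.call_class == "INSIDER":
            call.frequency = insider_frequency(index, call, config)
        else:
            call.frequency = outsider_frequency(
                index, call, te_len.get(call.family, call.end - call.start), config
            )
    return calls
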