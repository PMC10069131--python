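"""OUTSIDER detection: low-frequency TE insertions from read-to-assembly
alignments.

Insertions carried by minor haplotypes are absent from the assembly, so
reads containing them map partially: a spanning read shows a large
insertion operation, a read ending inside the element shows a long soft
clip at the junction.  Raw per-read signals are clustered by position
(30 bp anchor window), each cluster's member sequences are annotated
against the TE library, and the cluster is reported as a call if its most
informative read (highest alignment score) passes the 80/80 filter.
"""

from __future__ import annotations

import statistics

from .annotate import (
    TELibraryIndex,
    apply_length_bounds,
    best_family_match,
    group_fragments,
    search_te_library,
)
from .core import (
    AlignmentRecord,
    GenomeSequence,
    LongRead,
    PipelineConfig,
    SVCandidate,
    TECall,
    TEConsensus,
    TEMatch,
    logger,
)
from .tsd import annotate_call_tsd


def collect_candidate_reads(
    alignments: list[AlignmentRecord], config: PipelineConfig
) -> list[SVCandidate]:
    """Raw insertion signals from read alignments.

    Per primary record: CIGAR I runs of at least ``min_ins_signal`` bp
    (with their inserted sequence and target position) and terminal soft
    clips of at least ``min_clip_signal`` bp anchored at the clip's target
    coordinate.  Fully unmapped reads are returned position-less
    (position -1) for whole-read TE search; they never produce a
    positioned call.  Secondary/supplementary records are skipped.
    """
    signals: list[SVCandidate] = []
    skipped = 0
    for rec in alignments:
        if rec.flags & {"secondary", "supplementary"}:
            skipped += 1
            continue
        if rec.is_unmapped:
            if rec.sequence and len(rec.sequence) >= config.min_clip_signal:
                signals.append(
                    SVCandidate(
                        sv_type="INSERTION", contig="*", position=-1,
                        size=len(rec.sequence), sequence=rec.sequence,
                        source="reads", supporting_read_ids=[rec.query_id],
                        signal_kind="unmapped", record=rec,
                        read_span=(0, len(rec.sequence)),
                    )
                )
            continue
        if rec.sequence is None:
            skipped += 1
            continue
        seq = rec.sequence
        for op, n, t, q in rec.walk():
            if op == "I" and n >= config.min_ins_signal:
                signals.append(
                    SVCandidate(
                        sv_type="INSERTION", contig=rec.target_id, position=t,
                        size=n, sequence=seq[q : q + n], source="reads",
                        supporting_read_ids=[rec.query_id], signal_kind="ins",
                        read_span=(q, q + n), record=rec,
                    )
                )
        if rec.left_clip_is_soft and rec.left_clip >= config.min_clip_signal:
            c = rec.left_clip
            signals.append(
                SVCandidate(
                    sv_type="INSERTION", contig=rec.target_id,
                    position=rec.target_start, size=c, sequence=seq[:c],
                    source="reads", supporting_read_ids=[rec.query_id],
                    signal_kind="clip_left", read_span=(0, c), record=rec,
                )
            )
        if rec.right_clip_is_soft and rec.right_clip >= config.min_clip_signal:
            c = rec.right_clip
            signals.append(
                SVCandidate(
                    sv_type="INSERTION", contig=rec.target_id,
                    position=rec.target_end, size=c, sequence=seq[-c:],
                    source="reads", supporting_read_ids=[rec.query_id],
                    signal_kind="clip_right", read_span=(len(seq) - c, len(seq)),
                    record=rec,
                )
            )
    if skipped:
        logger.debug("skipped %d secondary/supplementary/sequence-less records", skipped)
    return signals


def cluster_signals(signals: list[SVCandidate], config: PipelineConfig) -> list[SVCandidate]:
    """Merge signals whose positions fall within the anchor window of a
    cluster's running median; cluster position and size are the medians of
    the members (lower median, so always an observed value)."""
    positioned = sorted(
        (s for s in signals if s.position >= 0),
        key=lambda s: (s.contig, s.position, s.supporting_read_ids, s.signal_kind),
    )
    clusters: list[SVCandidate] = []
    members: list[SVCandidate] = []

    def _flush() -> None:
        if not members:
            return
        positions = sorted(m.position for m in members)
        sizes = sorted(m.size for m in members)
        clusters.append(
            SVCandidate(
                sv_type="INSERTION",
                contig=members[0].contig,
                position=statistics.median_low(positions),
                size=statistics.median_low(sizes),
                source="reads",
                supporting_read_ids=sorted({r for m in members for r in m.supporting_read_ids}),
                member_signals=list(members),
            )
        )

    for s in positioned:
        if members and (
            s.contig != members[0].contig
            or abs(s.position - statistics.median_low([m.position for m in members]))
            > config.cluster_window
        ):
            _flush()
            members = []
        members.append(s)
    _flush()
    return clusters


def _read_candidate_sequences(cluster: SVCandidate) -> dict[str, tuple[str, SVCandidate]]:
    """Per supporting read: the candidate sequence to annotate (signals of
    one read concatenated in read order) and its highest-signal member."""
    per_read: dict[str, list[SVCandidate]] = {}
    for m in cluster.member_signals:
        per_read.setdefault(m.supporting_read_ids[0], []).append(m)
    out: dict[str, tuple[str, SVCandidate]] = {}
    for rid, sigs in per_read.items():
        sigs.sort(key=lambda s: s.read_span or (0, 0))
        seq = "".join(s.sequence for s in sigs)
        main = max(sigs, key=lambda s: s.size)
        out[rid] = (seq, main)
    return out


def select_best_read(
    cluster: SVCandidate,
    library: list[TEConsensus] | TELibraryIndex,
    config: PipelineConfig,
) -> tuple[str, TEMatch, SVCandidate] | None:
    """The most informative supporting read: the one whose best library
    match has the highest score (ties: lexicographically smaller read id).
    Returns None when no member sequence passes the 80/80 filter."""
    index = library if isinstance(library, TELibraryIndex) else TELibraryIndex(list(library))
    best: tuple[float, str, TEMatch, SVCandidate] | None = None
    # longest candidate first: a match score can never exceed the candidate
    # length, so shorter reads are pruned once they cannot beat the leader
    ranked = sorted(
        _read_candidate_sequences(cluster).items(), key=lambda kv: (-len(kv[1][0]), kv[0])
    )
    for rid, (seq, main) in ranked:
        if best is not None and len(seq) < best[0]:
            break
        match = best_family_match(seq, index, config)
        if match is None:
            continue
        if best is None or match.score > best[0] or (match.score == best[0] and rid < best[1]):
            best = (match.score, rid, match, main)
    if best is None:
        return _pooled_fragment_match(cluster, index, config)
    return best[1], best[2], best[3]


def _pooled_fragment_match(
    cluster: SVCandidate,
    index: TELibraryIndex,
    config: PipelineConfig,
) -> tuple[str, TEMatch, SVCandidate] | None:
    """Cluster-level fallback: fragments of one family carried by
    *different* reads are pooled before the 80/80 filter.

    Reads clipped at the element's 5' junction carry its head and reads
    clipped at the 3' junction its tail; neither alone may reach the
    coverage threshold although together they tile the consensus.  The
    composite uses the union of consensus spans and a span-weighted mean
    identity; the best-scoring member read labels the call.
    """
    pools: dict[tuple[str, str], list[tuple[TEMatch, str, SVCandidate]]] = {}
    for rid, (seq, main) in sorted(_read_candidate_sequences(cluster).items()):
        for m in group_fragments(search_te_library(seq, index, config), config=config):
            if m.identity_pct >= config.min_identity_pct:
                pools.setdefault((m.family, m.strand), []).append((m, rid, main))
    best: tuple[tuple[float, float, str], str, TEMatch, SVCandidate] | None = None
    for (family, strand), items in sorted(pools.items()):
        ref = max(items, key=lambda it: it[0].te_coverage_pct)[0]
        span = ref.te_span[1] - ref.te_span[0]
        if not ref.te_coverage_pct:
            continue
        cons_len = span / (ref.te_coverage_pct / 100.0)
        ivals = sorted(m.te_span for m, _, _ in items)
        union = 0
        cur0, cur1 = ivals[0]
        for s0, s1 in ivals[1:]:
            if s0 > cur1:
                union += cur1 - cur0
                cur0, cur1 = s0, s1
            else:
                cur1 = max(cur1, s1)
        union += cur1 - cur0
        coverage = min(100.0, 100.0 * union / cons_len)
        weights = [m.candidate_span[1] - m.candidate_span[0] for m, _, _ in items]
        identity = sum(m.identity_pct * w for (m, _, _), w in zip(items, weights)) / sum(weights)
        if identity < config.min_identity_pct or coverage < config.min_te_coverage_pct:
            continue
        top_m, top_rid, top_main = min(items, key=lambda it: (-it[0].score, it[1]))
        composite = TEMatch(
            family=family,
            identity_pct=identity,
            te_coverage_pct=coverage,
            candidate_span=top_m.candidate_span,
            strand=strand,
            score=top_m.score,
            te_span=(min(i[0] for i in ivals), max(i[1] for i in ivals)),
        )
        key = (-top_m.score, -coverage, family)
        if best is None or key < best[0]:
            best = (key, top_rid, composite, top_main)
    if best is None:
        return None
    logger.debug(
        "cluster at %s:%d accepted via pooled fragments (%s, coverage %.1f%%)",
        cluster.contig, cluster.position, best[2].family, best[2].te_coverage_pct,
    )
    return best[1], best[2], best[3]


def call_outsider(
    assembly: dict[str, GenomeSequence],
    reads: list[LongRead] | None,
    library: list[TEConsensus] | TELibraryIndex,
    alignments: list[AlignmentRecord],
    config: PipelineConfig | None = None,
) -> list[TECall]:
    """The full mapping track: collect signals, cluster, bound sizes,
    pick the best supporting read per cluster, and report OUTSIDER calls
    (mismatch-tolerant TSD detection with junction correction).

    ``reads`` is accepted for interface completeness; all sequence content
    is taken from the alignment records themselves.
    """
    config = config or PipelineConfig()
    index = library if isinstance(library, TELibraryIndex) else TELibraryIndex(list(library))
    signals = collect_candidate_reads(alignments, config)
    for s in signals:
        if s.signal_kind == "unmapped":
            match = best_family_match(s.sequence, index, config)
            if match is not None:
                logger.info(
                    "unmapped read %s matches %s (identity %.1f%%, coverage %.1f%%); no position",
                    s.supporting_read_ids[0], match.family,
                    match.identity_pct, match.te_coverage_pct,
                )
    clusters = cluster_signals([s for s in signals if s.signal_kind != "unmapped"], config)
    clusters = apply_length_bounds(clusters, config)
    calls: list[TECall] = []
    for cluster in clusters:
        if len(cluster.supporting_read_ids) < config.min_support:
            continue
        picked = select_best_read(cluster, index, config)
        if picked is None:
            continue
        rid, match, main_signal = picked
        call = TECall(
            contig=cluster.contig,
            start=cluster.position,
            end=cluster.position + 1,
            family=match.family,
            call_class="OUTSIDER",
            kind="insertion",
            strand=match.strand,
            best_read_id=rid,
            match=match,
            cluster=cluster,
        )
        # TSD flanks need a read spanning the insertion (both junctions):
        # try insertion-op members largest-first, then the labeling signal
        spanning = sorted(
            (m for m in cluster.member_signals if m.signal_kind == "ins"),
            key=lambda m: (-m.size, m.supporting_read_ids[0]),
        )
        for tsd_signal in (spanning[:3] or [main_signal]):
            rec = tsd_signal.record
            if rec is None or not rec.sequence or not tsd_signal.read_span:
                continue
            if cluster.contig not in assembly:
                break
            annotated = annotate_call_tsd(
                call,
                assembly[cluster.contig].sequence,
                None,
                config,
                read_seq=rec.sequence,
                read_insert_span=tsd_signal.read_span,
            )
            if annotated.tsd is not None:
                call = annotated
                break
        calls.append(call)
    calls.sort(key=lambda c: (c.contig, c.start, c.family))
    logger.info("OUTSIDER: %d signals -> %d clusters -> %d TE calls",
                len(signals), len(clusters), len(calls))
    return calls
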