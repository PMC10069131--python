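"""INSIDER detection: TE insertions/deletions from an assembly-vs-reference
whole-genome alignment.

High-frequency insertions end up in the sample's genome assembly, so they
appear as structural differences between the assembly and the reference:
large insertion/deletion operations inside an alignment, or length
discrepancies between consecutive anchor alignments of one contig.  Each
such SV candidate has its sequence retrieved (from the assembly for
insertion-like types, from the reference for deletion-like types) and is
annotated against the TE library; candidates passing the 80/80 filter
become INSIDER calls.
"""

from __future__ import annotations

from .annotate import TELibraryIndex, apply_length_bounds, best_family_match
from .core import (
    AlignmentRecord,
    GenomeSequence,
    PipelineConfig,
    SVCandidate,
    TECall,
    TEConsensus,
    logger,
)
from .tsd import annotate_call_tsd


def _query_positions(rec: AlignmentRecord):
    """Yield (op, n, target_pos, contig_pos) with contig_pos in contig-forward
    coordinates (reverse-strand alignments walk the contig backwards)."""
    qlen = rec.query_length or rec.query_consumed()
    for op, n, t, q in rec.walk():
        if rec.strand == "+":
            yield op, n, t, q
        else:
            yield op, n, t, qlen - q - (n if op in "M=XIS" else 0)


def _is_anchor(rec: AlignmentRecord, config: PipelineConfig) -> bool:
    """Assembly-pair anchor rule: a long alignment or the contig's primary."""
    aligned = sum(n for op, n in rec.cigar if op in "M=X")
    return aligned >= config.anchor_min_len or rec.is_primary


def extract_svs(alignments: list[AlignmentRecord], config: PipelineConfig) -> list[SVCandidate]:
    """Structural-variant candidates from contig-to-reference alignments.

    Within-alignment signals are CIGAR I/D runs of at least ``min_te_len``;
    between-alignment signals compare the query gap and reference gap of
    consecutive anchors of one contig.  Insertion-like candidates carry
    assembly coordinates, deletion-like candidates reference coordinates.
    """
    out: list[SVCandidate] = []
    for rec in alignments:
        if rec.is_unmapped or "secondary" in rec.flags:
            continue
        for op, n, t, q in _query_positions(rec):
            if op == "I" and n >= config.min_te_len:
                out.append(
                    SVCandidate(
                        sv_type="INSERTION", contig=rec.query_id, position=q,
                        size=n, source="assembly_pair",
                        ref_contig=rec.target_id, ref_position=t,
                    )
                )
            elif op == "D" and n >= config.min_te_len:
                out.append(
                    SVCandidate(
                        sv_type="DELETION", contig=rec.target_id, position=t,
                        size=n, source="assembly_pair",
                        ref_contig=rec.target_id, ref_position=t,
                    )
                )

    # between-alignment signals from consecutive anchors of one contig
    by_contig: dict[str, list[AlignmentRecord]] = {}
    for rec in alignments:
        if not rec.is_unmapped and _is_anchor(rec, config):
            by_contig.setdefault(rec.query_id, []).append(rec)
    for contig, recs in sorted(by_contig.items()):
        recs.sort(key=lambda r: (r.left_clip if r.strand == "+" else (r.query_length or 0) - r.left_clip - r.query_consumed()))
        for a, b in zip(recs, recs[1:]):
            if a.target_id != b.target_id:
                continue
            qlen = a.query_length or a.query_consumed()
            if a.strand == "+":
                a_qend = a.left_clip + sum(n for op, n in a.cigar if op in "M=XI")
            else:
                a_qend = qlen - a.right_clip
            b_qstart = b.left_clip if b.strand == "+" else (b.query_length or qlen) - b.left_clip - sum(
                n for op, n in b.cigar if op in "M=XI"
            )
            qgap = b_qstart - a_qend
            rgap = b.target_start - a.target_end
            non_unique = bool((a.flags | b.flags) & {"secondary"})
            overlap = rgap < 0
            if qgap > rgap + config.min_te_len:
                sv_type = (
                    "Repeat_expansion" if non_unique
                    else "Tandem_expansion" if overlap
                    else "INSERTION"
                )
                out.append(
                    SVCandidate(
                        sv_type=sv_type, contig=contig, position=a_qend,
                        size=qgap - max(rgap, 0), source="assembly_pair",
                        ref_contig=a.target_id, ref_position=a.target_end,
                    )
                )
            elif rgap > qgap + config.min_te_len:
                sv_type = (
                    "Repeat_contraction" if non_unique
                    else "Tandem_contraction" if qgap < 0
                    else "DELETION"
                )
                out.append(
                    SVCandidate(
                        sv_type=sv_type, contig=a.target_id, position=a.target_end,
                        size=rgap - max(qgap, 0), source="assembly_pair",
                        ref_contig=a.target_id, ref_position=a.target_end,
                    )
                )
    out.sort(key=lambda s: (s.contig, s.position))
    return out


def retrieve_sv_sequence(
    sv: SVCandidate,
    reference: dict[str, GenomeSequence],
    assembly: dict[str, GenomeSequence],
) -> str:
    """Insertion-like candidates come from the assembly (query), deletion-
    like ones from the reference."""
    if sv.sv_type in ("INSERTION", "Repeat_expansion", "Tandem_expansion"):
        source, label = assembly, "assembly"
    else:
        source, label = reference, "reference"
    if sv.contig not in source:
        raise KeyError(f"contig {sv.contig!r} absent from {label} FASTA")
    seq = source[sv.contig].sequence
    if sv.position < 0 or sv.position + sv.size > len(seq):
        raise ValueError(f"SV at {sv.contig}:{sv.position} out of {label} bounds")
    return seq[sv.position : sv.position + sv.size]


def call_insider(
    reference: dict[str, GenomeSequence],
    assembly: dict[str, GenomeSequence],
    library: list[TEConsensus] | TELibraryIndex,
    alignments: list[AlignmentRecord],
    config: PipelineConfig | None = None,
) -> list[TECall]:
    """The full assembly-comparison track: extract SVs, bound their sizes,
    retrieve sequences, annotate against the library, and report TE calls
    (with exact-mode TSD detection and junction correction for insertions)."""
    config = config or PipelineConfig()
    index = library if isinstance(library, TELibraryIndex) else TELibraryIndex(list(library))
    svs = apply_length_bounds(extract_svs(alignments, config), config)
    calls: list[TECall] = []
    for sv in svs:
        seq = retrieve_sv_sequence(sv, reference, assembly)
        match = best_family_match(seq, index, config)
        if match is None:
            continue
        insertion_like = sv.sv_type in ("INSERTION", "Repeat_expansion", "Tandem_expansion")
        call = TECall(
            contig=sv.contig,
            start=sv.position,
            end=sv.position + sv.size,
            family=match.family,
            call_class="INSIDER",
            kind="insertion" if insertion_like else "deletion",
            strand=match.strand,
            ref_contig=sv.ref_contig,
            ref_position=sv.ref_position,
            match=match,
        )
        if insertion_like and sv.contig in assembly:
            call = annotate_call_tsd(
                call, assembly[sv.contig].sequence, seq, config
            )
        calls.append(call)
    calls.sort(key=lambda c: (c.contig, c.start))
    logger.info(
        "INSIDER: %d SV candidates -> %d TE calls (%d insertions, %d deletions)",
        len(svs), len(calls),
        sum(c.kind == "insertion" for c in calls),
        sum(c.kind == "deletion" for c in calls),
    )
    return calls
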