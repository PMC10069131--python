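"""Shared domain types and file I/O.

Everything downstream (annotation, the two detection tracks, TSD and
frequency analysis, the simulator and the scorer) works on the small set of
dataclasses defined here.  Coordinates are uniformly 0-based half-open
internally; SAM positions are converted at parse time, BED and PAF are
native 0-based half-open.

Formats: FASTA/FASTQ via Biopython, SAM/BAM via pysam, PAF (with ``cg:Z``
tags) and BED6+ with a small fixed column contract (see
:func:`write_calls_bed`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO

logger = logging.getLogger("tedetect")
if not logger.handlers:  # library default: stderr, INFO
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

# ---------------------------------------------------------------------------
# sequence alphabet helpers
# ---------------------------------------------------------------------------

_VALID = frozenset("ACGTN")
_IUPAC = frozenset("ACGTNRYSWKMBDHVU")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


def sanitize_dna(seq: str, context: str = "") -> str:
    """Uppercase and restrict to the ACGTN alphabet.

    IUPAC ambiguity codes outside ACGTN are mapped to N with a warning;
    characters that are not even IUPAC raise ``ValueError``.
    """
    s = seq.upper().replace("U", "T")
    if _NON_ACGTN.search(s):
        bad = set(_NON_ACGTN.findall(s))
        if not bad <= _IUPAC:
            raise ValueError(f"non-DNA characters {sorted(bad - _IUPAC)} in {context or 'sequence'}")
        logger.warning("ambiguity codes %s mapped to N in %s", sorted(bad), context or "sequence")
        s = _NON_ACGTN.sub("N", s)
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence (reference contig, assembly contig, haplotype)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TEConsensus:
    """One family's consensus sequence from the TE library."""

    family: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LongRead:
    id: str
    sequence: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"quality/sequence length mismatch for read {self.id!r}")


# CIGAR ops that consume the query / the target
_Q_OPS = frozenset("M=XIS")
_T_OPS = frozenset("M=XDN")
_CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(text: str) -> list[tuple[str, int]]:
    ops = [(m.group(2), int(m.group(1))) for m in _CIG_RE.finditer(text)]
    if not ops and text not in ("", "*"):
        raise ValueError(f"unparseable CIGAR {text!r}")
    return ops


def cigar_to_string(cigar: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar) or "*"


@dataclass
class AlignmentRecord:
    """One read-to-genome or contig-to-genome alignment.

    ``sequence`` is the query sequence in target-forward orientation (as
    stored in SAM), or ``None`` when unavailable (e.g. PAF, secondary
    records).  ``target_start``/``target_end`` are 0-based half-open.
    """

    query_id: str
    target_id: str
    target_start: int
    target_end: int
    strand: str  # '+' or '-'
    cigar: list[tuple[str, int]] = field(default_factory=list)
    flags: frozenset[str] = frozenset()  # subset of {secondary, supplementary, unmapped}
    sequence: str | None = None
    qualities: tuple[int, ...] | None = None
    query_length: int | None = None  # full query length incl. hard clips

    @property
    def is_unmapped(self) -> bool:
        return "unmapped" in self.flags

    @property
    def is_primary(self) -> bool:
        return not (self.flags & {"secondary", "supplementary", "unmapped"})

    @property
    def left_clip(self) -> int:
        if self.cigar and self.cigar[0][0] in "SH":
            return self.cigar[0][1]
        return 0

    @property
    def right_clip(self) -> int:
        if self.cigar and self.cigar[-1][0] in "SH":
            return self.cigar[-1][1]
        return 0

    @property
    def left_clip_is_soft(self) -> bool:
        return bool(self.cigar) and self.cigar[0][0] == "S"

    @property
    def right_clip_is_soft(self) -> bool:
        return bool(self.cigar) and self.cigar[-1][0] == "S"

    def query_consumed(self) -> int:
        """Length of the query implied by the CIGAR (S included, H excluded)."""
        return sum(n for op, n in self.cigar if op in _Q_OPS)

    def target_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in _T_OPS)

    def aligned_blocks(self) -> list[tuple[int, int]]:
        """Target intervals covered by M/=/X ops (half-open), merged."""
        blocks: list[tuple[int, int]] = []
        t = self.target_start
        for op, n in self.cigar:
            if op in "M=X":
                if blocks and blocks[-1][1] == t:
                    blocks[-1] = (blocks[-1][0], t + n)
                else:
                    blocks.append((t, t + n))
            if op in _T_OPS:
                t += n
        return blocks

    def covers(self, start: int, end: int) -> bool:
        """True iff some aligned block fully contains [start, end)."""
        return any(b0 <= start and end <= b1 for b0, b1 in self.aligned_blocks())

    def walk(self) -> Iterator[tuple[str, int, int, int]]:
        """Yield (op, length, target_pos, query_pos) per CIGAR run.

        ``query_pos`` counts soft-clipped bases (SAM SEQ coordinates).
        """
        t, q = self.target_start, 0
        for op, n in self.cigar:
            yield op, n, t, q
            if op in _T_OPS:
                t += n
            if op in _Q_OPS:
                q += n

    def validate(self) -> None:
        if not self.is_unmapped:
            if self.target_end <= self.target_start:
                raise ValueError(f"empty target interval for {self.query_id!r}")
            if self.target_consumed() != self.target_end - self.target_start:
                raise ValueError(f"CIGAR/interval mismatch for {self.query_id!r}")
        if self.sequence is not None and self.cigar:
            if self.query_consumed() != len(self.sequence):
                raise ValueError(f"CIGAR/sequence length mismatch for {self.query_id!r}")


SV_INSERTION_TYPES = ("INSERTION", "Repeat_expansion", "Tandem_expansion")
SV_DELETION_TYPES = ("DELETION", "Repeat_contraction", "Tandem_contraction")


@dataclass
class SVCandidate:
    """A raw structural-variant signal before TE annotation.

    For assembly-pair candidates, ``contig``/``position`` are assembly
    coordinates for insertion-like types and reference coordinates for
    deletion-like types; ``ref_contig``/``ref_position`` always carry the
    homologous reference-side anchor.  For read candidates, coordinates are
    on the assembly the reads were mapped to.
    """

    sv_type: str
    contig: str
    position: int
    size: int
    sequence: str = ""
    source: str = "assembly_pair"  # or "reads"
    supporting_read_ids: list[str] = field(default_factory=list)
    ref_contig: str | None = None
    ref_position: int | None = None
    signal_kind: str = ""  # for read signals: "ins" or "clip_left"/"clip_right"
    member_signals: list["SVCandidate"] = field(default_factory=list)
    read_span: tuple[int, int] | None = None  # signal span in read (SEQ) coords
    record: "AlignmentRecord | None" = None  # source alignment for read signals

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("SV size must be positive")
        if self.sequence and self.sv_type in SV_INSERTION_TYPES and self.source == "assembly_pair":
            if len(self.sequence) != self.size:
                raise ValueError("insertion sequence length != size")


@dataclass(frozen=True)
class TEMatch:
    """A similarity hit between a candidate sequence and one TE consensus."""

    family: str
    identity_pct: float
    te_coverage_pct: float
    candidate_span: tuple[int, int]
    strand: str
    score: float
    te_span: tuple[int, int] = (0, 0)  # consensus-forward coordinates

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError("identity_pct out of [0,100]")
        if not (0.0 <= self.te_coverage_pct <= 100.0 + 1e-9):
            raise ValueError("te_coverage_pct out of [0,100]")


@dataclass(frozen=True)
class TSDRecord:
    motif: str
    left_pos: int
    right_pos: int
    mismatches: int

    def __post_init__(self) -> None:
        if len(self.motif) < 2:
            raise ValueError("TSD motif shorter than 2 bp")


@dataclass(frozen=True)
class FrequencyEstimate:
    supporting_reads: int
    spanning_total: int
    frequency: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.frequency <= 1.0):
            raise ValueError("frequency out of [0,1]")


@dataclass
class TECall:
    """One reported TE insertion or deletion."""

    contig: str
    start: int
    end: int
    family: str
    call_class: str  # INSIDER | OUTSIDER
    kind: str  # insertion | deletion
    strand: str = "+"
    tsd: TSDRecord | None = None
    frequency: FrequencyEstimate | None = None
    best_read_id: str | None = None
    ref_contig: str | None = None
    ref_position: int | None = None
    match: TEMatch | None = None
    cluster: SVCandidate | None = None

    def __post_init__(self) -> None:
        if self.call_class == "OUTSIDER" and self.kind != "insertion":
            raise ValueError("OUTSIDER calls are insertions")
        if self.kind == "deletion" and self.call_class != "INSIDER":
            raise ValueError("deletions only arise from assembly comparison")


@dataclass
class PipelineConfig:
    """All numeric knobs of the pipeline, with their defaults.

    Identity/coverage thresholds implement the 80/80 rule; length bounds are
    the 200 bp / 15 kb insertion-size window; the 30 bp anchor window drives
    both signal clustering and local depth; TSD search uses 30 bp flanks
    with a 2 bp junction tolerance (exact matching for assembly-derived
    calls, 1 mismatch allowed on read-derived calls).
    """

    min_identity_pct: float = 80.0
    min_te_coverage_pct: float = 80.0
    min_te_len: int = 200
    max_te_len: int = 15000
    tsd_flank: int = 30
    tsd_max_mismatch_insider: int = 0
    tsd_max_mismatch_outsider: int = 1
    tsd_junction_tolerance: int = 2
    cluster_window: int = 30
    insider_fetch_window: int = 100
    insider_junction_window: int = 5
    depth_window: int = 30
    cigar_rewrite_pad: int = 10
    fake_quality: int = 8
    min_ins_signal: int = 30
    min_clip_signal: int = 200
    min_rewrite_clip: int = 10
    min_support: int = 1
    fragment_gap_tolerance: int = 100
    anchor_min_len: int = 10000
    benchmark_tolerance: int = 30
    insider_support_mode: str = "junction"  # or "span"

    def __post_init__(self) -> None:
        for name in (
            "min_te_len", "max_te_len", "tsd_flank", "tsd_junction_tolerance",
            "cluster_window", "insider_fetch_window", "insider_junction_window",
            "depth_window", "cigar_rewrite_pad", "fake_quality",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_te_len >= self.max_te_len:
            raise ValueError("min_te_len must be < max_te_len")

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class TruthEvent:
    """One planted insertion in the simulation ledger.

    ``position`` is the insertion point on the assembly haplotype for
    OUTSIDER events, and the TE start on the assembly for INSIDER events.
    """

    contig: str
    position: int
    family: str
    te_length: int
    population_frequency: float
    class_label: str  # INSIDER | OUTSIDER
    strand: str = "+"
    tsd: str = ""
    ref_position: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.population_frequency <= 1.0):
            raise ValueError("population frequency must be in (0,1]")


@dataclass
class SimulationTruth:
    events: list[TruthEvent] = field(default_factory=list)

    def of_class(self, label: str) -> "SimulationTruth":
        return SimulationTruth([e for e in self.events if e.class_label == label])

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[TruthEvent]:
        return iter(self.events)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def load_genome(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a (multi-)FASTA into a dict of GenomeSequence keyed by id."""
    genomes: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genomes:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        genomes[rec.id] = GenomeSequence(rec.id, sanitize_dna(str(rec.seq), rec.id))
    if not genomes:
        raise ValueError(f"no FASTA records in {path}")
    return genomes


def write_fasta(seqs: Iterable[GenomeSequence | TEConsensus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            name = s.id if isinstance(s, GenomeSequence) else s.family
            fh.write(f">{name}\n")
            seq = s.sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def load_te_library(path: str | Path) -> list[TEConsensus]:
    """Read the TE consensus library (FASTA, one record per family)."""
    library: list[TEConsensus] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate TE family {rec.id!r} in library {path}")
        seen.add(rec.id)
        library.append(TEConsensus(rec.id, sanitize_dna(str(rec.seq), rec.id)))
    if not library:
        raise ValueError(f"empty TE library {path}")
    mean_len = sum(c.length for c in library) / len(library)
    logger.info("TE library: %d families, mean length %.0f bp", len(library), mean_len)
    return library


def load_reads(path: str | Path) -> list[LongRead]:
    fmt = "fastq" if str(path).endswith(("q", "fastq", "fq")) else "fasta"
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        quals = rec.letter_annotations.get("phred_quality")
        reads.append(LongRead(rec.id, str(rec.seq).upper(), tuple(quals) if quals else None))
    return reads


def write_fastq(reads: Iterable[LongRead], path: str | Path, default_quality: int = 12) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = r.qualities or (default_quality,) * len(r.sequence)
            qs = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qs}\n")


# ---------------------------------------------------------------------------
# SAM / BAM / PAF
# ---------------------------------------------------------------------------


def _record_from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord | None:
    flags = set()
    if seg.is_secondary:
        flags.add("secondary")
    if seg.is_supplementary:
        flags.add("supplementary")
    if seg.is_unmapped:
        flags.add("unmapped")
    cigar = []
    if seg.cigartuples:
        opmap = "MIDNSHP=XB"
        cigar = [(opmap[op], n) for op, n in seg.cigartuples]
    seq = seg.query_sequence
    quals = tuple(seg.query_qualities) if seg.query_qualities is not None else None
    rec = AlignmentRecord(
        query_id=seg.query_name,
        target_id=seg.reference_name or "*",
        target_start=seg.reference_start if not seg.is_unmapped else 0,
        target_end=seg.reference_end if (not seg.is_unmapped and seg.reference_end is not None) else 0,
        strand="-" if seg.is_reverse else "+",
        cigar=cigar,
        flags=frozenset(flags),
        sequence=seq,
        qualities=quals,
    )
    try:
        rec.validate()
    except ValueError as exc:
        logger.warning("skipping record %s: %s", seg.query_name, exc)
        return None
    return rec


def parse_paf_line(line: str) -> AlignmentRecord:
    """Parse one PAF line; query start/end become terminal soft clips."""
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise ValueError("truncated PAF line")
    cigar: list[tuple[str, int]] = []
    flags = set()
    for tag in f[12:]:
        if tag.startswith("cg:Z:"):
            cigar = parse_cigar(tag[5:])
        elif tag.startswith("tp:A:") and tag[5] in "SI":
            flags.add("secondary")
    qlen, qstart, qend, strand = int(f[1]), int(f[2]), int(f[3]), f[4]
    if strand == "+":
        lead, tail = qstart, qlen - qend
    else:
        lead, tail = qlen - qend, qstart
    if lead:
        cigar.insert(0, ("S", lead))
    if tail:
        cigar.append(("S", tail))
    return AlignmentRecord(
        query_id=f[0],
        target_id=f[5],
        target_start=int(f[7]),
        target_end=int(f[8]),
        strand=strand,
        cigar=cigar,
        flags=frozenset(flags),
        query_length=qlen,
    )


def parse_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Parse SAM/BAM or PAF into AlignmentRecords (0-based half-open).

    PAF query start/end are folded into the CIGAR as soft clips so that
    query coordinates can be reconstructed with the same arithmetic as SAM.
    """
    p = str(path)
    records: list[AlignmentRecord] = []
    if p.endswith(".paf"):
        with open(p) as fh:
            for line in fh:
                if line.strip():
                    records.append(parse_paf_line(line))
    else:
        mode = "rb" if p.endswith(".bam") else "r"
        with pysam.AlignmentFile(p, mode, check_sq=False) as fh:
            try:
                for seg in fh:
                    rec = _record_from_pysam(seg)
                    if rec is not None:
                        records.append(rec)
            except OSError as exc:  # malformed record aborts the stream
                logger.warning("stopped parsing %s at a malformed record: %s", p, exc)
    return records


def write_sam(records: Iterable[AlignmentRecord], targets: dict[str, int], path: str | Path) -> None:
    """Write AlignmentRecords to a plain-text SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in targets.items()],
    }
    tid = {name: i for i, name in enumerate(targets)}
    opmap = {op: i for i, op in enumerate("MIDNSHP=XB")}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in sorted(records, key=lambda r: (r.is_unmapped, r.target_id, r.target_start)):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.query_id
            flag = 0
            if rec.strand == "-":
                flag |= 16
            if "secondary" in rec.flags:
                flag |= 256
            if "supplementary" in rec.flags:
                flag |= 2048
            if rec.is_unmapped:
                flag |= 4
            seg.flag = flag
            if not rec.is_unmapped:
                seg.reference_id = tid[rec.target_id]
                seg.reference_start = rec.target_start
                seg.mapping_quality = 60
                seg.cigartuples = [(opmap[op], n) for op, n in rec.cigar]
            if rec.sequence:
                seg.query_sequence = rec.sequence
                if rec.qualities is not None:
                    seg.query_qualities = pysam.qualitystring_to_array(
                        "".join(chr(q + 33) for q in rec.qualities)
                    )
            out.write(seg)


def write_paf(records: Iterable[AlignmentRecord], query_lengths: dict[str, int],
              target_lengths: dict[str, int], path: str | Path) -> None:
    """Write contig-to-reference alignments as PAF with cg:Z tags.

    Terminal soft clips in the record CIGAR become the PAF query start/end.
    """
    with open(path, "w") as fh:
        for rec in records:
            qlen = query_lengths[rec.query_id]
            cig = list(rec.cigar)
            lead = cig.pop(0)[1] if cig and cig[0][0] in "SH" else 0
            tail = cig.pop()[1] if cig and cig[-1][0] in "SH" else 0
            if rec.strand == "+":
                qstart, qend = lead, qlen - tail
            else:
                qstart, qend = tail, qlen - lead
            nmatch = sum(n for op, n in cig if op in "M=")
            blen = sum(n for _, n in cig)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        rec.query_id, qlen, qstart, qend, rec.strand,
                        rec.target_id, target_lengths[rec.target_id],
                        rec.target_start, rec.target_end,
                        nmatch, blen, 60,
                    )
                )
                + f"\tcg:Z:{cigar_to_string(cig)}\n"
            )


# ---------------------------------------------------------------------------
# BED (calls + truth)
# ---------------------------------------------------------------------------

_BED_HEADER = (
    "#contig\tstart\tend\tfamily\tscore\tstrand\tclass\tkind\ttsd_motif\t"
    "tsd_left\ttsd_right\ttsd_mismatches\tsupporting\tspanning\tfrequency\t"
    "best_read\tref_contig\tref_position\n"
)


def write_calls_bed(calls: list[TECall], path: str | Path) -> None:
    """Write calls as BED6+ (see header line for the column contract).

    Score is ``round(frequency * 100)`` or '.' when no frequency was
    estimated.  Input is sorted by (contig, start) if it is not already.
    """
    if any(
        (a.contig, a.start) > (b.contig, b.start) for a, b in zip(calls, calls[1:])
    ):
        logger.info("sorting %d calls before writing %s", len(calls), path)
        calls = sorted(calls, key=lambda c: (c.contig, c.start))
    with open(path, "w") as fh:
        fh.write(_BED_HEADER)
        for c in calls:
            freq = c.frequency
            row = [
                c.contig, c.start, c.end, c.family,
                round(freq.frequency * 100) if freq else ".",
                c.strand, c.call_class, c.kind,
                c.tsd.motif if c.tsd else ".",
                c.tsd.left_pos if c.tsd else ".",
                c.tsd.right_pos if c.tsd else ".",
                c.tsd.mismatches if c.tsd else ".",
                freq.supporting_reads if freq else ".",
                freq.spanning_total if freq else ".",
                f"{freq.frequency:.4f}" if freq else ".",
                c.best_read_id or ".",
                c.ref_contig or ".",
                c.ref_position if c.ref_position is not None else ".",
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_calls_bed(path: str | Path) -> list[TECall]:
    calls: list[TECall] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            tsd = None
            if f[8] != ".":
                tsd = TSDRecord(f[8], int(f[9]), int(f[10]), int(f[11]))
            freq = None
            if f[14] != ".":
                sup, tot = int(f[12]), int(f[13])
                value = min(sup / tot, 1.0) if tot > 0 else float(f[14])
                freq = FrequencyEstimate(sup, tot, value)
            calls.append(
                TECall(
                    contig=f[0], start=int(f[1]), end=int(f[2]), family=f[3],
                    call_class=f[6], kind=f[7], strand=f[5], tsd=tsd,
                    frequency=freq,
                    best_read_id=None if f[15] == "." else f[15],
                    ref_contig=None if f[16] == "." else f[16],
                    ref_position=None if f[17] == "." else int(f[17]),
                )
            )
    return calls


def write_truth_bed(truth: SimulationTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#contig\tstart\tend\tfamily\tfrequency\tstrand\tclass\ttsd\tref_position\n")
        for e in sorted(truth.events, key=lambda e: (e.contig, e.position)):
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        e.contig, e.position, e.position + e.te_length, e.family,
                        f"{e.population_frequency:.4f}", e.strand, e.class_label,
                        e.tsd or ".",
                        e.ref_position if e.ref_position is not None else ".",
                    )
                )
                + "\n"
            )


def read_truth_bed(path: str | Path) -> SimulationTruth:
    events = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            events.append(
                TruthEvent(
                    contig=f[0], position=int(f[1]), family=f[3],
                    te_length=int(f[2]) - int(f[1]),
                    population_frequency=float(f[4]), class_label=f[6],
                    strand=f[5], tsd="" if f[7] == "." else f[7],
                    ref_position=None if len(f) < 9 or f[8] == "." else int(f[8]),
                )
            )
    return SimulationTruth(events)
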