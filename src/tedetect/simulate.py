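"""Synthetic benchmark generator.

Emulates the three-haplotype simulation design used to validate the
caller: a base genome (the "reference"), an assembly haplotype carrying
high-frequency INSIDER insertions, and a full haplotype additionally
carrying low-frequency OUTSIDER insertions.  Long reads are drawn from the
three haplotypes at a configurable depth mixture (default 10x / 45x / 5x,
total 60x), so insertion allele frequencies are encoded purely by the
depth ratios.  Each planted insertion duplicates a short target-site motif
(TSD, default 4-6 bp) around the element.

Instead of signal-level nanopore simulation, reads carry a parametric
error model (substitutions / insertions / deletions at a configurable
total rate, split 40/30/30).  Because read provenance is known, the
generator also emits exact ground-truth alignments: reads against the
assembly haplotype (SAM) and the assembly against the base genome (PAF),
which let the detection modules run without an external aligner.

The default full recipe plants 100 INSIDER insertions (5+5 for two
families, 10 for each of nine more) and 1000 OUTSIDER insertions
(200+200+8x50+100+100) across a 12-family library; ``desk_recipe`` scales
that down for fast runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    AlignmentRecord,
    GenomeSequence,
    LongRead,
    SimulationTruth,
    TEConsensus,
    TruthEvent,
    logger,
    revcomp,
)

# Family set and consensus lengths modelled on a Drosophila-style library
# (lengths span ~1.3-13 kb, mean ~6 kb).  Sequences are synthetic random
# DNA stand-ins for the real consensuses.
DEFAULT_FAMILY_LENGTHS: dict[str, int] = {
    "ZAM": 8435,
    "gtwin": 7411,
    "Doc": 4726,
    "roo": 9092,
    "copia": 5143,
    "F-element": 4708,
    "hopper": 1435,
    "Helena": 1317,
    "HB": 1657,
    "TART-A": 13000,
    "gypsy": 7469,
    "Idefix": 7411,
}

FULL_INSIDER_COUNTS: dict[str, int] = {
    "ZAM": 5, "gtwin": 5, "Doc": 10, "roo": 10, "copia": 10,
    "F-element": 10, "hopper": 10, "Helena": 10, "HB": 10,
    "TART-A": 10, "gypsy": 10,
}

FULL_OUTSIDER_COUNTS: dict[str, int] = {
    "ZAM": 200, "gtwin": 200, "Doc": 50, "roo": 50, "copia": 50,
    "F-element": 50, "hopper": 50, "Helena": 50, "HB": 50,
    "TART-A": 50, "gypsy": 100, "Idefix": 100,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class SimulationRecipe:
    """All knobs of one simulated sample."""

    genome_length: int = 20_000_000
    gc: float = 0.42
    insider_counts: dict[str, int] = field(default_factory=lambda: dict(FULL_INSIDER_COUNTS))
    outsider_counts: dict[str, int] = field(default_factory=lambda: dict(FULL_OUTSIDER_COUNTS))
    depth_mix: tuple[float, float, float] = (10.0, 45.0, 5.0)  # base, insider, outsider pools
    read_mean_len: int = 20_000
    read_len_sigma: float = 0.4  # lognormal shape
    min_read_len: int = 500
    error_rate: float = 0.05
    error_ratio: tuple[float, float, float] = (0.4, 0.3, 0.3)  # sub, ins, del
    tsd_len_range: tuple[int, int] = (4, 6)
    min_edge_distance: int = 2000
    min_event_spacing: int = 1000
    contig: str = "chr1"
    library_seed: int = 97531
    seed: int = 1

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.depth_mix):
            raise ValueError("depths must be positive")
        if any(c < 0 for c in {**self.insider_counts, **self.outsider_counts}.values()):
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.error_rate < 0.3):
            raise ValueError("error_rate must be in [0, 0.3)")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")


def scaled_counts(counts: dict[str, int], scale: float) -> dict[str, int]:
    """Divide family counts by ``scale`` keeping the scaled total exact
    (largest-remainder apportionment, deterministic tie-break by name)."""
    total = round(sum(counts.values()) / scale)
    quotas = {f: c / scale for f, c in counts.items()}
    out = {f: int(q) for f, q in quotas.items()}
    rest = total - sum(out.values())
    order = sorted(quotas, key=lambda f: (-(quotas[f] - int(quotas[f])), f))
    for f in order[:rest]:
        out[f] += 1
    return {f: c for f, c in out.items() if c > 0}


def desk_recipe(seed: int = 1, scale: float = 10.0, **overrides) -> SimulationRecipe:
    """The scaled-down benchmark: 2 Mb genome, 10 INSIDER + 100 OUTSIDER
    planted insertions, 10x/45x/5x depth mix, 2% read error."""
    kw = dict(
        genome_length=2_000_000,
        insider_counts=scaled_counts(FULL_INSIDER_COUNTS, scale),
        outsider_counts=scaled_counts(FULL_OUTSIDER_COUNTS, scale),
        error_rate=0.02,
        seed=seed,
    )
    kw.update(overrides)
    return SimulationRecipe(**kw)


# ---------------------------------------------------------------------------
# genome + library generation
# ---------------------------------------------------------------------------


def _random_dna(n: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)].tobytes().decode()


def generate_base_genome(length: int, seed: int, gc: float = 0.42,
                         contig: str = "chr1") -> GenomeSequence:
    """Seeded pseudo-random genome with the requested GC content."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    rng = np.random.default_rng(seed)
    return GenomeSequence(contig, _random_dna(length, rng, gc))


def default_te_library(seed: int = 97531,
                       lengths: dict[str, int] | None = None) -> list[TEConsensus]:
    """Synthetic TE consensus library (random sequences, fixed lengths)."""
    lengths = lengths or DEFAULT_FAMILY_LENGTHS
    rng = np.random.default_rng(seed)
    return [TEConsensus(fam, _random_dna(n, rng, 0.45)) for fam, n in lengths.items()]


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MapBlock:
    """One block of a haplotype-to-parent coordinate map.

    kind 'M': haplotype [h0,h1) equals parent [p0, p0+(h1-h0)).
    kind 'I': haplotype [h0,h1) is inserted content at parent junction p0.
    """

    kind: str
    h0: int
    h1: int
    p0: int


@dataclass
class HaplotypeMap:
    blocks: list[MapBlock]
    length: int


def _sample_positions(n: int, low: int, high: int, spacing: int,
                      rng: np.random.Generator,
                      forbidden: list[tuple[int, int]] | None = None) -> list[int]:
    """n sorted positions in [low, high), pairwise >= spacing apart and
    outside forbidden intervals.

    The forbidden intervals (padded by the spacing) are subtracted from
    [low, high); within the remaining segments the classic gap-shrink
    construction yields exact uniform min-gap samples: draw sorted uniforms
    in the shrunk space, re-add i*spacing, and map through the allowed
    segments (distances across segment boundaries only grow).
    """
    # allowed segments = [low, high) minus padded forbidden intervals
    segments: list[tuple[int, int]] = []
    cursor = low
    for f0, f1 in sorted(forbidden or []):
        a, b = max(low, f0 - spacing), min(high, f1 + spacing)
        if b <= cursor:
            continue
        if a > cursor:
            segments.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < high:
        segments.append((cursor, high))
    widths = np.array([b - a for a, b in segments], dtype=np.int64)
    total = int(widths.sum())
    span = total - (n - 1) * spacing
    if span <= n:
        raise ValueError("genome too small for requested insertion count/spacing")
    base = np.sort(rng.uniform(0, span, size=n)) + np.arange(n) * spacing
    starts = np.array([a for a, _ in segments], dtype=np.int64)
    offsets = np.concatenate(([0], np.cumsum(widths)[:-1]))
    idx = np.searchsorted(np.cumsum(widths), base, side="right")
    pos = (starts[idx] + (base - offsets[idx])).astype(np.int64)
    return [int(p) for p in pos]


def plant_insertions(
    genome: GenomeSequence,
    library: list[TEConsensus],
    counts: dict[str, int],
    class_label: str,
    population_frequency: float,
    rng: np.random.Generator,
    tsd_len_range: tuple[int, int] = (4, 6),
    min_edge_distance: int = 2000,
    min_event_spacing: int = 1000,
    forbidden: list[tuple[int, int]] | None = None,
) -> tuple[GenomeSequence, list[TruthEvent], HaplotypeMap]:
    """Insert TE copies with TSDs at random positions of ``genome``.

    Each event duplicates the ``k`` bases at the insertion site (k drawn
    from ``tsd_len_range``) around the element, so the output is
    ``G[:p+k] + TE + G[p:p+k] + G[p+k:]`` per event.  Truth positions are
    recorded on the *input* genome for the insertion point and on the
    *output* genome for the element interval; the returned map describes
    output-to-input coordinates for downstream read simulation.
    """
    by_family = {c.family: c for c in library}
    unknown = set(counts) - set(by_family)
    if unknown:
        raise ValueError(f"families not in library: {sorted(unknown)}")
    n = sum(counts.values())
    if n == 0:
        return genome, [], HaplotypeMap([MapBlock("M", 0, len(genome), 0)], len(genome))
    positions = _sample_positions(
        n, min_edge_distance, len(genome) - min_edge_distance,
        min_event_spacing, rng, forbidden,
    )
    labels = [f for f, c in sorted(counts.items()) for _ in range(c)]
    rng.shuffle(labels)
    strands = rng.choice(["+", "-"], size=n)
    tsd_lens = rng.integers(tsd_len_range[0], tsd_len_range[1] + 1, size=n)

    G = genome.sequence
    pieces: list[str] = []
    blocks: list[MapBlock] = []
    events: list[TruthEvent] = []
    prev = 0
    out_pos = 0
    for p, fam, strand, k in zip(positions, labels, strands, tsd_lens):
        k = int(k)
        cons = by_family[fam]
        te = cons.sequence if strand == "+" else revcomp(cons.sequence)
        junction = p + k  # input-genome coordinate of the insertion point
        # matched block up to the junction
        pieces.append(G[prev:junction])
        blocks.append(MapBlock("M", out_pos, out_pos + (junction - prev), prev))
        out_pos += junction - prev
        # inserted content: element followed by the duplicated site motif
        motif = G[p:junction]
        pieces.append(te + motif)
        blocks.append(MapBlock("I", out_pos, out_pos + len(te) + k, junction))
        events.append(
            TruthEvent(
                contig=genome.id,
                position=out_pos if class_label == "INSIDER" else junction,
                family=fam,
                te_length=cons.length,
                population_frequency=population_frequency,
                class_label=class_label,
                strand=str(strand),
                tsd=motif,
                ref_position=junction,
            )
        )
        out_pos += len(te) + k
        prev = junction
    pieces.append(G[prev:])
    blocks.append(MapBlock("M", out_pos, out_pos + len(G) - prev, prev))
    out_pos += len(G) - prev
    mutated = GenomeSequence(genome.id, "".join(pieces))
    assert len(mutated) == out_pos
    logger.info("planted %d %s insertions into %s", n, class_label, genome.id)
    return mutated, events, HaplotypeMap(blocks, out_pos)


def invert_map(hmap: HaplotypeMap, parent_length: int) -> list[MapBlock]:
    """Parent-to-haplotype matched blocks (for reads drawn from the parent
    and aligned to the haplotype): the parent maps 1-1 onto the haplotype's
    'M' blocks, with jumps where the haplotype carries insertions."""
    return [
        MapBlock("M", b.p0, b.p0 + (b.h1 - b.h0), b.h0)
        for b in hmap.blocks
        if b.kind == "M" and b.h1 > b.h0
    ]


# ---------------------------------------------------------------------------
# read simulation with a parametric error model
# ---------------------------------------------------------------------------


def _mutate_match(seq: str, rng: np.random.Generator, rate: float,
                  ratio: tuple[float, float, float]) -> tuple[str, list[tuple[str, int]]]:
    """Mutate an M-piece; returns (read_seq, cigar pieces vs the template).

    Deletions consume the template (D), insertion errors add one query base
    (I); the target span of the piece is preserved.
    """
    n = len(seq)
    if rate == 0.0 or n == 0:
        return seq, ([("M", n)] if n else [])
    p_sub, p_ins, p_del = (rate * r for r in ratio)
    u = rng.random(n)
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    sub_pos = np.flatnonzero(u < p_sub)
    if sub_pos.size:
        orig = _CODE[codes[sub_pos]]
        shift = rng.integers(1, 4, size=sub_pos.size)
        codes[sub_pos] = _BASES[(orig + shift) % 4]
    del_pos = np.flatnonzero((u >= p_sub) & (u < p_sub + p_del))
    ins_pos = np.flatnonzero((u >= p_sub + p_del) & (u < p_sub + p_del + p_ins))
    if del_pos.size == 0 and ins_pos.size == 0:
        return codes.tobytes().decode(), [("M", n)]
    events = sorted(
        [(int(p), "D") for p in del_pos] + [(int(p), "I") for p in ins_pos]
    )
    parts: list[bytes] = []
    cigar: list[tuple[str, int]] = []
    prev = 0
    for pos, typ in events:
        if typ == "D":
            if pos > prev:
                parts.append(codes[prev:pos].tobytes())
                cigar.append(("M", pos - prev))
            cigar.append(("D", 1))
            prev = pos + 1
        else:  # insertion error after the base at pos
            parts.append(codes[prev : pos + 1].tobytes())
            cigar.append(("M", pos + 1 - prev))
            parts.append(_BASES[rng.integers(0, 4)].tobytes())
            cigar.append(("I", 1))
            prev = pos + 1
    if n > prev:
        parts.append(codes[prev:].tobytes())
        cigar.append(("M", n - prev))
    return b"".join(parts).decode(), cigar


def _mutate_plain(seq: str, rng: np.random.Generator, rate: float,
                  ratio: tuple[float, float, float]) -> str:
    """Mutate an inserted/clipped piece (no template to track)."""
    mutated, _ = _mutate_match(seq, rng, rate, ratio)
    return mutated


def _merge_cigar(cigar: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, n in cigar:
        if n == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def _read_pieces(blocks: list[MapBlock], s: int, e: int) -> list[tuple[str, int, int, int]]:
    """Pieces (kind, h0, h1, p0) of haplotype interval [s,e) vs the parent."""
    pieces = []
    for b in blocks:
        h0, h1 = max(b.h0, s), min(b.h1, e)
        if h0 < h1:
            p0 = b.p0 + (h0 - b.h0) if b.kind == "M" else b.p0
            pieces.append((b.kind, h0, h1, p0))
    return pieces


def _align_read(
    hap_seq: str,
    pieces: list[tuple[str, int, int, int]],
    rng: np.random.Generator,
    rate: float,
    ratio: tuple[float, float, float],
) -> tuple[str, list[tuple[str, int]], int] | None:
    """Build the (mutated) read sequence and its CIGAR vs the parent genome.

    Returns (read_seq, cigar, target_start) or None when the read has no
    aligned block (fully inside inserted sequence -> unmapped).  Where the
    parent coordinate jumps between matched pieces (reads from the base
    genome crossing an assembly-only insertion), only the longest
    contiguous run is kept aligned and the remainder is soft-clipped, the
    way a read aligner represents such reads.
    """
    # split into contiguous runs: list of lists of piece indices
    runs: list[list[int]] = []
    prev_end: int | None = None
    for i, (kind, h0, h1, p0) in enumerate(pieces):
        if kind == "M":
            if prev_end is not None and p0 != prev_end and runs and runs[-1]:
                runs.append([i])
            elif runs:
                runs[-1].append(i)
            else:
                runs.append([i])
            prev_end = p0 + (h1 - h0)
        else:
            if not runs:
                runs.append([i])
            else:
                runs[-1].append(i)
    if not runs:
        return None

    def run_m_len(run: list[int]) -> int:
        return sum(h1 - h0 for (k, h0, h1, _) in (pieces[i] for i in run) if k == "M")

    if all(run_m_len(r) == 0 for r in runs):
        return None  # read entirely within inserted content
    primary = max(runs, key=run_m_len)

    seq_parts: list[str] = []
    cigar: list[tuple[str, int]] = []
    target_start = None
    for run in runs:
        in_primary = run is primary
        for idx, i in enumerate(run):
            kind, h0, h1, p0 = pieces[i]
            piece_seq = hap_seq[h0:h1]
            if kind == "M" and in_primary:
                mut, cig = _mutate_match(piece_seq, rng, rate, ratio)
                if target_start is None:
                    target_start = p0
                seq_parts.append(mut)
                cigar.extend(cig)
            else:
                mut = _mutate_plain(piece_seq, rng, rate, ratio)
                seq_parts.append(mut)
                if in_primary and kind == "I" and 0 < idx < len(run) - 1:
                    cigar.append(("I", len(mut)))
                else:
                    cigar.append(("S", len(mut)))
    # a leading/trailing I inside the primary run was emitted as S above
    # only when it is the run's first/last piece; stray S in the middle can
    # occur when a non-primary run sits between primary pieces -- collapse
    # any clip that is not terminal into the nearest terminal clip side
    cigar = _merge_cigar(cigar)
    # move any internal S ops to the nearest end (they arise when a read
    # crosses several assembly-only insertions)
    if len(cigar) > 2:
        first_m = next((i for i, (op, _) in enumerate(cigar) if op != "S"), None)
        last_m = next(
            (len(cigar) - 1 - i for i, (op, _) in enumerate(reversed(cigar)) if op != "S"),
            None,
        )
        if first_m is not None and last_m is not None:
            inner = cigar[first_m : last_m + 1]
            if any(op == "S" for op, _ in inner):
                # clip everything outside the longest clean stretch: fall
                # back to aligning only the primary run
                return _align_primary_only(hap_seq, pieces, primary, rng, rate, ratio)
    return "".join(seq_parts), cigar, target_start or 0


def _align_primary_only(
    hap_seq: str,
    pieces: list[tuple[str, int, int, int]],
    primary: list[int],
    rng: np.random.Generator,
    rate: float,
    ratio: tuple[float, float, float],
) -> tuple[str, list[tuple[str, int]], int]:
    seq_parts: list[str] = []
    cigar: list[tuple[str, int]] = []
    target_start = 0
    pset = set(primary)
    for i, (kind, h0, h1, p0) in enumerate(pieces):
        piece_seq = hap_seq[h0:h1]
        if i in pset and kind == "M":
            mut, cig = _mutate_match(piece_seq, rng, rate, ratio)
            if not any(op in "M=X" for op, _ in cigar):
                target_start = p0
            seq_parts.append(mut)
            cigar.extend(cig)
        elif i in pset and kind == "I" and cigar and any(op in "M=X" for op, _ in cigar):
            mut = _mutate_plain(piece_seq, rng, rate, ratio)
            seq_parts.append(mut)
            cigar.append(("I", len(mut)))
        else:
            mut = _mutate_plain(piece_seq, rng, rate, ratio)
            seq_parts.append(mut)
            cigar.append(("S", len(mut)))
    return "".join(seq_parts), _merge_cigar(cigar), target_start


def simulate_pool(
    hap: GenomeSequence,
    blocks: list[MapBlock],
    depth: float,
    recipe: SimulationRecipe,
    rng: np.random.Generator,
    pool_name: str,
    target_contig: str,
) -> tuple[list[LongRead], list[AlignmentRecord]]:
    """Reads from one haplotype at the given depth, with truth alignments
    against the parent (assembly) genome described by ``blocks``."""
    n_target = depth * len(hap)
    mu = np.log(recipe.read_mean_len) - recipe.read_len_sigma**2 / 2
    reads: list[LongRead] = []
    records: list[AlignmentRecord] = []
    total = 0
    i = 0
    while total < n_target:
        length = int(rng.lognormal(mu, recipe.read_len_sigma))
        length = max(recipe.min_read_len, min(length, len(hap)))
        s = int(rng.integers(0, len(hap) - length + 1))
        e = s + length
        strand = "+" if rng.random() < 0.5 else "-"
        pieces = _read_pieces(blocks, s, e)
        aligned = _align_read(hap.sequence, pieces, rng, recipe.error_rate, recipe.error_ratio)
        name = f"{pool_name}_{i:06d}"
        if aligned is None:
            raw = _mutate_plain(hap.sequence[s:e], rng, recipe.error_rate, recipe.error_ratio)
            rec = AlignmentRecord(
                query_id=name, target_id=target_contig, target_start=0, target_end=0,
                strand="+", cigar=[], flags=frozenset({"unmapped"}), sequence=raw,
            )
            read_seq = raw
        else:
            seq, cigar, t0 = aligned
            t_span = sum(n for op, n in cigar if op in "MD")
            rec = AlignmentRecord(
                query_id=name, target_id=target_contig, target_start=t0,
                target_end=t0 + t_span, strand=strand, cigar=cigar, sequence=seq,
            )
            rec.validate()
            read_seq = seq if strand == "+" else revcomp(seq)
        reads.append(LongRead(name, read_seq))
        records.append(rec)
        total += len(read_seq)
        i += 1
    return reads, records


# ---------------------------------------------------------------------------
# whole-sample assembly
# ---------------------------------------------------------------------------


@dataclass
class SimulatedSample:
    recipe: SimulationRecipe
    library: list[TEConsensus]
    base: GenomeSequence  # reference genome
    assembly: GenomeSequence  # base + INSIDER insertions (the "assembly")
    full: GenomeSequence  # assembly + OUTSIDER insertions (minor haplotype)
    truth: SimulationTruth  # all events, assembly coordinates
    reads: list[LongRead]
    alignments: list[AlignmentRecord]  # reads vs assembly (truth SAM)
    genome_alignment: list[AlignmentRecord]  # assembly vs base (truth PAF)


def genome_pair_alignment(assembly: GenomeSequence, base_length: int,
                          insider_map: HaplotypeMap) -> AlignmentRecord:
    """The exact assembly-to-reference alignment implied by the planting."""
    cigar: list[tuple[str, int]] = []
    for b in insider_map.blocks:
        if b.h1 == b.h0:
            continue
        cigar.append(("M" if b.kind == "M" else "I", b.h1 - b.h0))
    rec = AlignmentRecord(
        query_id=assembly.id, target_id=assembly.id,
        target_start=0, target_end=base_length, strand="+",
        cigar=_merge_cigar(cigar), query_length=len(assembly),
    )
    return rec


def simulate_sample(recipe: SimulationRecipe) -> SimulatedSample:
    """Run the full generative recipe: genomes, planted events, reads and
    ground-truth alignments."""
    seeds = np.random.SeedSequence(recipe.seed).spawn(6)
    library = default_te_library(recipe.library_seed)
    base = generate_base_genome(
        recipe.genome_length, seed=recipe.seed ^ 0x5EED, gc=recipe.gc, contig=recipe.contig
    )

    rng_plant = np.random.default_rng(seeds[0])
    assembly, insider_events, insider_map = plant_insertions(
        base, library, recipe.insider_counts, "INSIDER",
        population_frequency=(recipe.depth_mix[1] + recipe.depth_mix[2]) / sum(recipe.depth_mix),
        rng=rng_plant, tsd_len_range=recipe.tsd_len_range,
        min_edge_distance=recipe.min_edge_distance,
        min_event_spacing=recipe.min_event_spacing,
    )
    forbidden = [
        (e.position - recipe.min_event_spacing, e.position + e.te_length + recipe.min_event_spacing)
        for e in insider_events
    ]
    rng_plant2 = np.random.default_rng(seeds[1])
    full, outsider_events, outsider_map = plant_insertions(
        assembly, library, recipe.outsider_counts, "OUTSIDER",
        population_frequency=recipe.depth_mix[2] / sum(recipe.depth_mix),
        rng=rng_plant2, tsd_len_range=recipe.tsd_len_range,
        min_edge_distance=recipe.min_edge_distance,
        min_event_spacing=recipe.min_event_spacing,
        forbidden=forbidden,
    )

    identity_blocks = [MapBlock("M", 0, len(assembly), 0)]
    pools = (
        ("sb1", base, invert_map(insider_map, len(base)), recipe.depth_mix[0]),
        ("sb2", assembly, identity_blocks, recipe.depth_mix[1]),
        ("sb3", full, outsider_map.blocks, recipe.depth_mix[2]),
    )
    reads: list[LongRead] = []
    records: list[AlignmentRecord] = []
    for (name, hap, blocks, depth), seed in zip(pools, seeds[2:5]):
        r, a = simulate_pool(
            hap, blocks, depth, recipe, np.random.default_rng(seed), name, assembly.id
        )
        reads.extend(r)
        records.extend(a)
    logger.info(
        "simulated %d reads (%.0f Mb) from 3 pools at %sx",
        len(reads), sum(len(r.sequence) for r in reads) / 1e6,
        "/".join(str(d) for d in recipe.depth_mix),
    )
    truth = SimulationTruth(insider_events + outsider_events)
    return SimulatedSample(
        recipe=recipe,
        library=library,
        base=base,
        assembly=assembly,
        full=full,
        truth=truth,
        reads=reads,
        alignments=records,
        genome_alignment=[genome_pair_alignment(assembly, len(base), insider_map)],
    )


def subsample_reads(reads: list[LongRead], fraction: float, seed: int) -> list[LongRead]:
    """Keep each read independently with probability ``fraction``."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(reads)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < fraction
    return [r for r, k in zip(reads, keep) if k]
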