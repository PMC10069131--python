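"""TE annotation: decide whether a candidate sequence is a transposable element.

A candidate (an SV sequence, a large insertion operation from a read, or a
clipped read tail) is searched against the TE consensus library with
edit-distance local alignment, hits are filtered with the 80/80 rule
(>= 80% identity over >= 80% of the consensus length, both configurable),
and collinear fragment hits to the same family are grouped into composite
matches before filtering.

The search runs each candidate/consensus pair in two infix modes — the
consensus embedded in the candidate (full-length TE inside a larger
insertion) and the candidate embedded in the consensus (a clipped TE
fragment) — keeps the better interpretation, masks the matched span and
recurses on the flanks so that multiple fragments of one consensus (or
tandem copies) each yield their own hit.  A 15-mer prescreen skips
consensus sequences that share no seeds with the candidate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

from .core import (
    PipelineConfig,
    SVCandidate,
    TEConsensus,
    TEMatch,
    logger,
    revcomp,
)

_SEED_K = 15
_SEED_MIN_SHARED = 3
_MIN_SEGMENT = 150  # do not recurse into candidate pieces shorter than this
_MIN_HIT_LEN = 30
_IDENTITY_FLOOR = 30.0  # raw-hit floor; real filtering happens in filter_matches
_MAX_DEPTH = 4

# local-alignment style scoring used to rank hits (match/mismatch/gap)
_MATCH, _MISMATCH, _GAP = 1, -1, -1


def _kmer_set(seq: str, k: int = _SEED_K) -> set[str]:
    return {seq[i : i + k] for i in range(0, len(seq) - k + 1)}


@dataclass
class TELibraryIndex:
    """The consensus library plus cached k-mer seed sets for prescreening."""

    consensuses: list[TEConsensus]
    _kmers: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in self.consensuses:
            self._kmers[c.family] = _kmer_set(c.sequence)

    def shares_seed(self, family: str, candidate_kmers: set[str]) -> bool:
        shared = self._kmers[family] & candidate_kmers
        return len(shared) >= _SEED_MIN_SHARED


_CIG_RUN = re.compile(r"(\d+)([=XID])")


def _cigar_stats(cigar: str) -> tuple[int, int, int, int]:
    """(matches, mismatches, gap_bases, columns) from an extended cigar."""
    match = mismatch = gap = 0
    for m in _CIG_RUN.finditer(cigar):
        length = int(m.group(1))
        op = m.group(2)
        if op == "=":
            match += length
        elif op == "X":
            mismatch += length
        else:
            gap += length
    return match, mismatch, gap, match + mismatch + gap


def _align_infix(query: str, target: str) -> tuple[float, float, tuple[int, int], tuple[int, int]] | None:
    """Align full ``query`` inside ``target``; return (identity, score,
    query_span_in_target, consumed_query_span) or None."""
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    loc = res["locations"][0]
    match, mismatch, gap, cols = _cigar_stats(res["cigar"])
    if cols == 0:
        return None
    identity = 100.0 * match / cols
    score = _MATCH * match + _MISMATCH * mismatch + _GAP * gap
    return identity, score, (loc[0], loc[1] + 1), (0, len(query))


def _best_hit(segment: str, consensus: TEConsensus) -> tuple[TEMatch, tuple[int, int]] | None:
    """Best single hit of ``segment`` vs one consensus (forward strand of
    both), or None.  Returns the match and the segment span it consumed."""
    cons = consensus.sequence
    hits: list[tuple[float, TEMatch, tuple[int, int]]] = []

    def _mode_a() -> None:
        # consensus embedded in the candidate segment
        a = _align_infix(cons, segment)
        if a is not None:
            identity, score, seg_span, _ = a
            hits.append(
                (
                    score,
                    TEMatch(
                        family=consensus.family,
                        identity_pct=identity,
                        te_coverage_pct=100.0,
                        candidate_span=seg_span,
                        strand="+",
                        score=score,
                        te_span=(0, consensus.length),
                    ),
                    seg_span,
                )
            )

    def _mode_b() -> None:
        # candidate segment embedded in the consensus
        b = _align_infix(segment, cons)
        if b is not None:
            identity, score, cons_span, _ = b
            coverage = 100.0 * (cons_span[1] - cons_span[0]) / consensus.length
            hits.append(
                (
                    score,
                    TEMatch(
                        family=consensus.family,
                        identity_pct=identity,
                        te_coverage_pct=min(coverage, 100.0),
                        candidate_span=(0, len(segment)),
                        strand="+",
                        score=score,
                        te_span=cons_span,
                    ),
                    (0, len(segment)),
                )
            )

    # run the mode suggested by the length relation first; the alternative
    # only when the first is weak (saves one large alignment per pair)
    first, second = (_mode_a, _mode_b) if len(segment) >= consensus.length else (_mode_b, _mode_a)
    first()
    if not hits or hits[0][1].identity_pct < 75.0:
        second()

    hits = [
        h
        for h in hits
        if h[1].identity_pct >= _IDENTITY_FLOOR
        and (h[2][1] - h[2][0]) >= _MIN_HIT_LEN
        and h[0] > 0
    ]
    if not hits:
        return None
    best = max(hits, key=lambda h: h[0])
    return best[1], best[2]


def _search_segment(
    segment: str,
    offset: int,
    consensus: TEConsensus,
    out: list[TEMatch],
    depth: int = 0,
    cons_kmers: set[str] | None = None,
) -> None:
    if len(segment) < _MIN_HIT_LEN:
        return
    if cons_kmers is not None and len(segment) >= 4 * _SEED_K:
        if len(_kmer_set(segment) & cons_kmers) < _SEED_MIN_SHARED:
            return
    hit = _best_hit(segment, consensus)
    if hit is None:
        # a composite candidate (fragment + spacer + fragment) may align
        # poorly as a whole: bisect and retry each half
        if depth < _MAX_DEPTH and len(segment) >= 2 * _MIN_SEGMENT:
            mid = len(segment) // 2
            _search_segment(segment[:mid], offset, consensus, out, depth + 1, cons_kmers)
            _search_segment(segment[mid:], offset + mid, consensus, out, depth + 1, cons_kmers)
        return
    match, (s0, s1) = hit
    out.append(
        TEMatch(
            family=match.family,
            identity_pct=match.identity_pct,
            te_coverage_pct=match.te_coverage_pct,
            candidate_span=(offset + s0, offset + s1),
            strand=match.strand,
            score=match.score,
            te_span=match.te_span,
        )
    )
    if depth < _MAX_DEPTH:
        if s0 >= _MIN_SEGMENT:
            _search_segment(segment[:s0], offset, consensus, out, depth + 1, cons_kmers)
        if len(segment) - s1 >= _MIN_SEGMENT:
            _search_segment(segment[s1:], offset + s1, consensus, out, depth + 1, cons_kmers)


def search_te_library(
    candidate: str,
    library: list[TEConsensus] | TELibraryIndex,
    config: PipelineConfig | None = None,
) -> list[TEMatch]:
    """Local similarity hits of ``candidate`` against every library family.

    Both strands are searched (the reverse strand by aligning the
    reverse-complemented candidate and mapping spans back to candidate
    coordinates).  Hits are sorted by descending score; an empty list means
    no family resembles the candidate at even the permissive raw floor.
    """
    if not candidate:
        return []
    index = library if isinstance(library, TELibraryIndex) else TELibraryIndex(list(library))
    fwd = candidate.upper()
    rev = revcomp(fwd)
    kmers_fwd = _kmer_set(fwd)
    kmers_rev = _kmer_set(rev)
    matches: list[TEMatch] = []
    for cons in index.consensuses:
        short = len(fwd) < _SEED_K + _SEED_MIN_SHARED or cons.length < _SEED_K + _SEED_MIN_SHARED
        for strand, seq, kmers in (("+", fwd, kmers_fwd), ("-", rev, kmers_rev)):
            if not short and not index.shares_seed(cons.family, kmers):
                continue
            found: list[TEMatch] = []
            _search_segment(seq, 0, cons, found, cons_kmers=index._kmers[cons.family])
            if strand == "-":
                n = len(fwd)
                found = [
                    TEMatch(
                        family=m.family,
                        identity_pct=m.identity_pct,
                        te_coverage_pct=m.te_coverage_pct,
                        candidate_span=(n - m.candidate_span[1], n - m.candidate_span[0]),
                        strand="-",
                        score=m.score,
                        te_span=m.te_span,
                    )
                    for m in found
                ]
            matches.extend(found)
    matches.sort(key=lambda m: (-m.score, -m.te_coverage_pct, m.family, m.candidate_span))
    return matches


def filter_matches(matches: list[TEMatch], config: PipelineConfig) -> list[TEMatch]:
    """Apply the 80/80 rule: keep hits with identity and consensus-length
    coverage both at or above their configured minima (inclusive)."""
    return [
        m
        for m in matches
        if m.identity_pct >= config.min_identity_pct
        and m.te_coverage_pct >= config.min_te_coverage_pct
    ]


def _collinear(a: TEMatch, b: TEMatch, gap: int) -> bool:
    """True iff ``b`` continues ``a`` on both the candidate and consensus."""
    if a.family != b.family or a.strand != b.strand:
        return False
    cand_gap = b.candidate_span[0] - a.candidate_span[1]
    if not (-gap <= cand_gap <= gap):
        return False
    if a.strand == "+":
        te_gap = b.te_span[0] - a.te_span[1]
    else:
        te_gap = a.te_span[0] - b.te_span[1]
    return -gap <= te_gap <= gap


def group_fragments(matches: list[TEMatch], gap_tolerance: int | None = None,
                    config: PipelineConfig | None = None) -> list[TEMatch]:
    """Merge collinear fragment hits of the same family/strand.

    Composite identity is the alignment-length-weighted mean, composite
    coverage the union of consensus spans over the consensus length.  The
    consensus length is recovered from ``te_coverage_pct``/``te_span`` of
    the members, so no library access is needed here.
    """
    if gap_tolerance is None:
        gap_tolerance = (config or PipelineConfig()).fragment_gap_tolerance
    by_key: dict[tuple[str, str], list[TEMatch]] = {}
    for m in matches:
        by_key.setdefault((m.family, m.strand), []).append(m)

    out: list[TEMatch] = []
    for (family, strand), group in by_key.items():
        group.sort(key=lambda m: m.candidate_span)
        chains: list[list[TEMatch]] = []
        for m in group:
            if chains and _collinear(chains[-1][-1], m, gap_tolerance):
                chains[-1].append(m)
            else:
                chains.append([m])
        for chain in chains:
            if len(chain) == 1:
                out.append(chain[0])
                continue
            # consensus length from any member with nonzero coverage
            ref = max(chain, key=lambda m: m.te_coverage_pct)
            span = ref.te_span[1] - ref.te_span[0]
            cons_len = span / (ref.te_coverage_pct / 100.0) if ref.te_coverage_pct else 0.0
            ivals = sorted(m.te_span for m in chain)
            union = 0
            cur0, cur1 = ivals[0]
            for s0, s1 in ivals[1:]:
                if s0 > cur1:
                    union += cur1 - cur0
                    cur0, cur1 = s0, s1
                else:
                    cur1 = max(cur1, s1)
            union += cur1 - cur0
            weights = [m.candidate_span[1] - m.candidate_span[0] for m in chain]
            identity = sum(m.identity_pct * w for m, w in zip(chain, weights)) / sum(weights)
            coverage = min(100.0, 100.0 * union / cons_len) if cons_len else 0.0
            out.append(
                TEMatch(
                    family=family,
                    identity_pct=identity,
                    te_coverage_pct=coverage,
                    candidate_span=(chain[0].candidate_span[0], chain[-1].candidate_span[1]),
                    strand=strand,
                    score=sum(m.score for m in chain),
                    te_span=(min(i[0] for i in ivals), max(i[1] for i in ivals)),
                )
            )
    out.sort(key=lambda m: (-m.score, -m.te_coverage_pct, m.family, m.candidate_span))
    return out


def apply_length_bounds(candidates: list[SVCandidate], config: PipelineConfig) -> list[SVCandidate]:
    """Keep candidates within [min_te_len, max_te_len] (inclusive)."""
    kept = [c for c in candidates if config.min_te_len <= c.size <= config.max_te_len]
    if len(kept) != len(candidates):
        logger.debug("length bounds dropped %d of %d candidates", len(candidates) - len(kept), len(candidates))
    return kept


def best_family_match(
    candidate: str,
    library: list[TEConsensus] | TELibraryIndex,
    config: PipelineConfig,
) -> TEMatch | None:
    """Full annotation of one candidate: search, group, filter, pick best.

    Returns the winning composite match or None if no family passes the
    80/80 filter.  Ties on score break by higher coverage then family name;
    runner-up families are logged.
    """
    grouped = group_fragments(search_te_library(candidate, library, config), config=config)
    passing = filter_matches(grouped, config)
    if not passing:
        return None
    best = passing[0]
    others = {m.family for m in passing if m.family != best.family}
    if others:
        logger.debug("candidate also matched families %s (best %s)", sorted(others), best.family)
    return best
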