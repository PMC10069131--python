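"""Scoring a call set against the simulation truth ledger.

Greedy nearest-first one-to-one matching within a positional tolerance
(default: the 30 bp anchor window).  Matched truth events are true
positives, unmatched calls false positives, unmatched truth events false
negatives; sensitivity is TP/(TP+FN) and the false-positive fraction
FP/(TP+FP).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import SimulationTruth, TECall, logger


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    fn: int
    table: pd.DataFrame  # one row per truth event and per FP call

    @property
    def sensitivity_pct(self) -> float | None:
        return 100.0 * self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def fp_fraction_pct(self) -> float | None:
        return 100.0 * self.fp / (self.tp + self.fp) if (self.tp + self.fp) else None


def match_calls(
    calls: list[TECall],
    truth: SimulationTruth,
    tolerance: int = 30,
    strict_family: bool = True,
) -> BenchmarkResult:
    """Match calls to truth events (same contig, positions within
    ``tolerance``); with ``strict_family`` a family mismatch disqualifies
    the pair (logged as a mislabeled detection)."""
    if calls and len(truth):
        call_contigs = {c.contig for c in calls}
        truth_contigs = {e.contig for e in truth}
        if not (call_contigs & truth_contigs):
            raise ValueError(
                f"disjoint contig sets: calls on {sorted(call_contigs)}, "
                f"truth on {sorted(truth_contigs)}"
            )
    events = sorted(truth, key=lambda e: (e.contig, e.position, e.family))
    ordered_calls = sorted(calls, key=lambda c: (c.contig, c.start, c.family))
    pairs = []
    mislabeled = 0
    for ei, e in enumerate(events):
        for ci, c in enumerate(ordered_calls):
            if c.contig != e.contig:
                continue
            d = abs(c.start - e.position)
            if d > tolerance:
                continue
            if c.family != e.family:
                mislabeled += 1
                logger.debug(
                    "call %s:%d labeled %s vs truth %s at %d",
                    c.contig, c.start, c.family, e.family, e.position,
                )
                if strict_family:
                    continue
            pairs.append((d, e.position, c.start, ei, ci))
    pairs.sort()
    matched_e: dict[int, int] = {}
    matched_c: set[int] = set()
    for d, _, _, ei, ci in pairs:
        if ei in matched_e or ci in matched_c:
            continue
        matched_e[ei] = ci
        matched_c.add(ci)

    rows = []
    for ei, e in enumerate(events):
        ci = matched_e.get(ei)
        call = ordered_calls[ci] if ci is not None else None
        rows.append(
            {
                "contig": e.contig,
                "truth_position": e.position,
                "truth_family": e.family,
                "truth_class": e.class_label,
                "status": "TP" if call else "FN",
                "call_position": call.start if call else pd.NA,
                "call_family": call.family if call else pd.NA,
                "call_class": call.call_class if call else pd.NA,
                "distance": abs(call.start - e.position) if call else pd.NA,
            }
        )
    for ci, c in enumerate(ordered_calls):
        if ci not in matched_c:
            rows.append(
                {
                    "contig": c.contig,
                    "truth_position": pd.NA,
                    "truth_family": pd.NA,
                    "truth_class": pd.NA,
                    "status": "FP",
                    "call_position": c.start,
                    "call_family": c.family,
                    "call_class": c.call_class,
                    "distance": pd.NA,
                }
            )
    table = pd.DataFrame(rows)
    tp = len(matched_e)
    fp = len(ordered_calls) - len(matched_c)
    fn = len(events) - len(matched_e)
    if mislabeled:
        logger.info("%d call/truth pairs within tolerance had mismatched families", mislabeled)
    return BenchmarkResult(tp=tp, fp=fp, fn=fn, table=table)


def summarize(tp: int, fp: int, fn: int) -> dict[str, float | int | None]:
    """Fig.-2-style tallies: TP / FP / FN counts plus sensitivity and
    false-positive fraction (absent when undefined)."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else None
    fpf = 100.0 * fp / (tp + fp) if (tp + fp) else None
    return {
        "true_positive": tp,
        "false_positive": fp,
        "false_negative": fn,
        "sensitivity_pct": sens,
        "fp_fraction_pct": fpf,
    }


def per_haplotype_depth(total_depth: float, n_haplotypes: int, ndigits: int = 2) -> float:
    """Depth available per haploid genome in a pooled sample, truncated to
    ``ndigits`` (e.g. 183x over 200 haploid genomes -> 0.91x per haplotype)."""
    if n_haplotypes <= 0:
        raise ValueError("n_haplotypes must be positive")
    scale = 10**ndigits
    return int(total_depth / n_haplotypes * scale) / scale
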