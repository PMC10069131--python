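# Methods

## Problem and model

`tedetect` calls non-reference transposable-element (TE) insertions (and
assembly-level deletions) in a pooled long-read sample, together with each
insertion's allele frequency. The design rests on one observation about
pooled samples: a polymorphic insertion either is frequent enough to be
incorporated into a de-novo assembly built from the same reads, or it is
not. That dichotomy yields two complementary detection tracks:

* **INSIDER track** (assembly comparison). Insertions carried by the major
  haplotype are present in the sample assembly and absent from the
  reference. Comparing the two genomes exposes them as large insertion
  operations within an alignment, or as length discrepancies between
  consecutive anchor alignments of one contig. Deletions (elements present
  in the reference but lost by the sample) appear symmetrically.
* **OUTSIDER track** (read mapping). Insertions on minor haplotypes are
  absent from the assembly, so reads carrying them map partially: a read
  spanning the element shows a large insertion CIGAR operation; a read
  ending inside it shows a long terminal soft clip whose clipped bases are
  TE sequence.

Both tracks are *naive-first*: structural signals are collected without
reference to any TE annotation, and only then classified by comparing the
candidate sequence against a user-provided TE consensus library. A
candidate is accepted when some family matches with at least 80% sequence
identity over at least 80% of the consensus length (the 80/80 rule; both
thresholds are configurable — lowering length coverage to, say, 10% admits
truncated or internally deleted copies at the cost of specificity).
Candidate sizes must fall in [200 bp, 15 kb].

### Similarity search

Candidates are compared to each consensus (both strands) with bit-parallel
edit-distance infix alignment (edlib). Each pair is tried in two
orientations — the consensus embedded in the candidate (full-length element
inside a larger inserted segment) and the candidate embedded in the
consensus (a clipped fragment) — and the better-scoring interpretation is
kept; the matched span is then masked and the flanks re-searched so that
separated fragments of one family produce individual hits. Identity is
identical columns over aligned columns; coverage is the aligned consensus
span over the consensus length. Hits are ranked by a match/mismatch/gap
score of +1/−1/−1. Collinear same-family, same-strand fragments separated
by at most 100 bp on both sequences are grouped into a composite hit
(length-weighted mean identity, union coverage). A 15-mer seed prescreen
(≥3 shared seeds) skips hopeless pairs; the thresholded decisions are
unaffected because any hit that could pass the identity filter shares far
more seeds than the prescreen requires. When several families pass the
filter the highest score wins (ties: higher coverage, then name), and
runners-up are logged.

### Clustering and best-read selection (OUTSIDER)

Raw per-read signals (insertion ops ≥ 30 bp; soft clips ≥ 200 bp) are
clustered along the assembly with a 30 bp anchor window around the running
median of member positions; cluster position and size are the (lower)
medians. One call may be supported by a single read — a full-length element
with flanking sequence inside one read is unambiguous evidence. For each
cluster the "most informative" read is chosen: every member's candidate
sequence is annotated and the read with the best-scoring passing match
labels the call (ties break to the lexicographically smaller read id;
reads whose candidate sequence is shorter than the current best score are
skipped, which cannot change the arg-max because a score never exceeds the
candidate length). When no single member passes, fragments of one family
carried by *different* reads are pooled before filtering: reads clipped at
the element's 5' junction hold its head and reads clipped at the 3'
junction its tail, so the union of their consensus spans (with
span-weighted mean identity) decides acceptance — without this, elements
whose locus happens to lack a spanning read at low carrier depth are
systematically missed. Clusters with no passing member or pooled family
are dropped. Fully unmapped reads are searched against the library and
logged but produce no positioned call, since nothing anchors them to the
assembly.

### Target-site duplications

TE integration duplicates a short motif of the insertion site on both
sides of the element. For each insertion call the 30 bp flanks of the
junctions are compared: exact matching (Boyer–Moore, bad-character plus
strong good-suffix rules) for assembly-derived calls; up to 1 mismatch
(Hamming, no indels) for read-derived calls, to tolerate read errors.
Because aligners absorb one TSD copy into the reported insertion (the
inserted segment typically ends, or begins, with the duplicated motif),
three placements are tried: flank-vs-flank, insertion-tail vs left flank,
and insertion-head vs right flank. Candidates are ranked by `length − 4 ×
mismatches` so the exact motif beats a longer extension that merely fits
within the mismatch budget (flank context matching 1–3 extra bases by
chance is common); motifs shorter than 2 bp are noise and discarded, and
motifs sitting more than 2 bp from a junction are rejected as pre-existing
duplications. For read-derived calls the motif must also occur exactly
once in the ±30 bp empty-site window of the assembly; when the top
candidate fails that filter the next-ranked ones are tried, flanks are
taken from the largest spanning (insertion-operation) reads — a clip-only
read lacks one flank — and up to three spanning reads are attempted.
A candidate that would move the junction must be at least 4 bp long
(a chance 2–3-mer is not evidence for a correction); zero-shift
candidates only annotate. Retained TSDs pin the junctions: corrected
coordinates move by at most the flank length, and in practice define the
insertion site to ~2 bp — the boundary is genuinely ambiguous by one base
when the flank context happens to extend the motif.

### Allele frequency

The frequency of an insertion is supporting reads over the local read
total. The denominator is the rounded mean per-base depth of the two 30 bp
windows flanking the junctions, excluding supplementary and secondary
records. Numerators differ by track:

* **INSIDER**: reads overlapping the call with a 100 bp margin support it
  if they align straight through a junction — no clip or alignment gap
  within 5 bp of it; the two junction counts are averaged. Reads from
  haplotypes lacking the element are clipped (or split) at the junction
  and therefore excluded. A stricter variant requiring one read to span
  the whole element is available (`insider_support_mode="span"`) but
  penalizes elements comparable in length to the reads. On simulated
  mixtures the default slightly overestimates (a few percent): non-carrier
  reads ending naturally near a junction deplete the flank-depth
  denominator relative to the junction-crossing numerator.
* **OUTSIDER**: terminal clips abutting the call within 30 bp are
  rewritten into insertion operations of the element length + 10 bp (the
  clipped bases replaced by that many N's at quality 8) and the records
  are re-clustered with the same signal logic used for detection, so
  clipped carriers are counted alongside spanning carriers. A read
  contributing several signals counts once. Clip-only carriers are
  weighted 1/2: clips from both element junctions anchor at the same
  assembly point while each such read contributes to only one of the two
  flank-depth windows, so full weighting would inflate the numerator by
  roughly `(R + L − max(0, L − R)) / R` for read length R and element
  length L. With the half weight, recovery on simulated mixtures is
  unbiased (mean absolute error 0.02–0.04 at frequencies 0.08–0.33).

Raw ratios above 1 (sampling noise) are clamped to 1 and logged. Deletion
calls receive no frequency: there is no read-level procedure for an
element the sample lost.

## Synthetic benchmark

The simulator reproduces a three-haplotype pooled design. A seeded random
base genome (default GC 0.42) stands in for the reference; a 12-family
consensus library with lengths from ~1.3 to 13 kb (mean ~6 kb) provides
the elements — the sequences are synthetic random DNA stand-ins, not real
consensus sequences, which suffices because every pipeline decision
depends only on similarity relations, not biological motif content. The
full recipe plants 100 high-frequency insertions (5+5 for two families,
10 each for nine), then 1000 low-frequency insertions (200+200, eight
fifties, 100+100) into the resulting assembly haplotype. Each event gets a
uniform random position (≥2 kb from ends, ≥1 kb between events), a random
strand, and a duplicated 4–6 bp target-site motif. Reads are drawn from
the three haplotypes at a 10×/45×/5× depth mix (total 60×), so allele
frequencies are encoded purely by depth ratios (high-frequency elements at
50/60 ≈ 0.83, low-frequency at 5/60 ≈ 0.083); lengths are lognormal with
mean 20 kb, and a parametric error model applies substitutions/insertions/
deletions in a 40/30/30 ratio (5% total by default; 0% for oracle tests).

Because read provenance is known, the simulator emits exact ground-truth
alignments: reads against the assembly haplotype (spanning reads of a
minor-haplotype element get an I operation, reads ending inside it get a
soft clip; base-genome reads crossing an assembly-only insertion keep
their longest contiguous piece and are soft-clipped, as a read aligner
would report them) and the assembly against the base genome (a single
alignment whose I operations are the planted insertions). This lets every
stage run and be tested without an external aligner.

The desk-scale benchmark divides event counts by 10 (largest-remainder
apportionment, so 10 + 100 events exactly) on a 2 Mb genome with 2% read
error. Test problem sizes were chosen so the full suite completes in a few
minutes: the shared benchmark fixture uses the 2 Mb recipe; unit-level
fixtures use 0.2–0.5 Mb genomes.

**What passing these tests does and does not show.** The generator covers
the structural signatures (insertion ops, junction clips, TSDs, depth
mixtures) but not several properties of real nanopore data: non-uniform
and context-dependent error profiles, chimeric reads, heterochromatic and
nested-repeat context, segmental duplications that mimic clip signals,
diverged element copies, or reference/assembly mis-assembly. Detection
rates and frequency errors measured here are therefore upper bounds on
real-data performance, useful chiefly for verifying the machinery and its
parameter plumbing end to end.

## Numerical choices and edge cases

* Coordinates are 0-based half-open everywhere internally; SAM is
  converted at parse time; BED and PAF are native.
* Hard clips count toward clip lengths but carry no sequence; candidate
  extraction uses soft clips only.
* IUPAC ambiguity codes outside ACGTN become N (warned); non-IUPAC
  characters are errors.
* All thresholds are inclusive (≥ / ≤): 80.0% identity passes, a 200 bp or
  15 kb candidate passes, a TSD offset of exactly 2 bp passes.
* Cluster medians are lower medians, so positions are always observed
  values; clustering input is sorted by (contig, position, read id, signal
  kind), making the output invariant to input order.
* Between-alignment SV classification: overlap of reference anchors →
  tandem; a non-unique anchor → repeat class; both gaps large → the larger
  gap wins, ties → insertion. Anchors are alignments ≥10 kb or primary.
* Degenerate inputs: empty call lists serialize to a header-only BED; zero
  flank depth yields an absent frequency (reported as missing, not 0);
  a malformed SAM record stops parsing that file with a warning.
* `per_haplotype_depth` truncates (183×/200 → 0.91×), matching how such
  per-haplotype budgets are conventionally quoted.

## Design decisions taken where the procedure was open

* The whole-genome aligner, read mapper and SV callers are external to the
  method; the pipeline consumes their standard outputs (PAF with cg tags,
  SAM/BAM) and the simulator provides exact equivalents for testing.
* A candidate matching two families above threshold yields one call (best
  family), with alternatives logged.
* Minimum supporting reads for a read-derived call: 1 (configurable).
* Clip-only clusters estimate element size from the best read's match span
  rather than the clip length, which underestimates.
* TSD uniqueness filtering applies to read-derived calls only; assembly
  flanks already place both copies explicitly.
* Benchmark scoring uses greedy nearest-first one-to-one matching within
  30 bp (the anchor window) and requires family agreement by default.

## Limitations

* Real sequencing data and external tools are out of scope: assembly
  quality comparisons across assemblers, wet-lab (PCR/ddPCR) concordance,
  and depth-titration studies on real libraries all require inputs this
  package does not ship. The property suites on synthetic data replace
  them here.
* The error model is i.i.d. per base; no homopolymer or signal-level
  modelling.
* Deletion calls are reported without frequencies.
* Unmapped reads full of TE sequence are logged, not placed.
* The similarity search is greedy per consensus (best hit, then flanks);
  pathological mosaics of many short fragments may be under-merged.
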