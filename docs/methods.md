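# Methods

This note documents the models, defaults and design choices behind
`hapasm`, and what the synthetic benchmarks do and do not demonstrate.

## Homopolymer compression and the error model

Accurate long reads err predominantly by ±1-base changes of homopolymer
run lengths. Compressing every run to one base (`HPCSequence`: compressed
bases plus a run-length vector) removes the error mode entirely when the
run keeps length ≥ 1 in both read and truth; what survives into compressed
space is a ~5–10× smaller mixture of substitutions and single-base
deletions (a length-1 run lost entirely, which may merge its neighbours).
The transform is lossless per read: decompression restores the original
bases exactly, and run starts give a monotone coordinate map both ways.

The simulator's HiFi-like error model places ≥80% of errors as run-length
±1 events and the rest as substitutions, specifically so that the
compressed-space residual error the corrector faces matches this picture.

## Correction: columns for substitutions, regions for indels

All-vs-all alignment is seeded by exact k-mers (k=15, base-5 integer
encoding, banded diagonal voting) and verified by bounded-edit-distance
global alignment (edlib) at an identity floor of 0.98 in compressed space.
Pileup columns then vote:

* **Substitutions** are corrected column-wise when the majority symbol has
  ≥ `min_depth` (4) support and leads the read's own symbol by
  `min_support_ratio` (2).
* **Indels** cannot be corrected column-wise: inside tandem or
  quasi-repeat context the same indel has several equivalent alignment
  placements, so per-column votes split and no placement reaches a
  majority — this is structural, not a matter of depth. Every site with
  indel evidence therefore seeds a small window (±5 columns, widened to
  any covering masked interval), each aligned partner votes for the whole
  window's content, and the majority content replaces the read's copy
  under the same support/ratio rules.

A support ratio of 2 (not higher) is required: placement ambiguity spreads
genuine majority support across shifted variants, while truly balanced
columns — diverged repeat copies, heterozygous-like sites — still fail a
2:1 test and are preserved. Correction runs for two rounds by default;
the second round operates on near-clean reads and converges.

Simple-sequence repeats are detected in compressed space (period ≤ 6).
The public detector defaults to the conventional ≥3 copies / ≥10 bp; the
pipeline masks more aggressively (≥2 copies / ≥6 bp) because in compressed
space even two copies of a short unit create indel-placement ambiguity.
Masked positions are never column-corrected and act as wildcards during
exact overlap matching.

## Exact overlaps and the string graph

After correction, only exact suffix–prefix matches (wildcarded at masked
positions) of ≥ `min_overlap` compressed bases become candidate edges.
Containments are flagged, excluded from edges, and placed onto their
container's unitig so depth reflects them. Two filters matter in repeat
context:

* Per (pair, orientation, direction) only the **longest** exact overlap is
  kept: tandem arrays admit unit-shifted exact self-similarity, and the
  shifted overlaps are always shorter than the true one.
* Graph edges additionally require `max(min_overlap, 0.2 × median
  compressed read length)`: spurious overlaps between reads from different
  array positions are bounded by a few unit lengths, true adjacencies at
  ~30× coverage overlap by most of a read.

Construction applies Myers-style transitive reduction (length-consistency
fuzz 12) and merges maximal unambiguous paths into unitigs, tracking every
read's placement (offset, orientation) for depth and consensus.
Simplification iterates to convergence (cap 10 rounds): transitive
reduction; clipping of dead-end spurs that are shorter than `tip_len`
*and* branch off a continuing, at-least-as-deep alternative (a genuine
chain end has no alternative and is never clipped); and popping of short
parallel branches between the same node ends, keeping the deeper branch.
Error-induced spurs and bubbles are read-sized objects, so the pipeline
scales `tip_len`/`bubble_len` to 2.5×/3× the median compressed read
length.

Multiplicity is `round(depth / base_depth)` floored at 1, with nodes below
`0.2 × base_depth` assigned 0 (artifact candidates, skipped by walks);
`base_depth` defaults to the median depth of nodes longer than the 90th
length percentile, which repeat-induced inflation cannot easily move.

## Walks, coverings, arbitration

A component's candidates are *coverings*: sets of maximal walks that
together traverse each node its multiplicity's worth of times. New walks
start at termini of the remaining subgraph (anywhere, if none exist —
cyclic remainders), and only minimum-walk-count coverings are kept: a
covering with fewer walks explains the same nodes with fewer chromosomes.
Enumeration is exhaustive with caps (10,000 candidates / 2M steps); hitting
a cap reports ambiguity rather than sampling.

Ultra-long reads are compressed, anchored by k-mers unique across all node
sequences (k=21), collapsed to oriented node paths, and checked against
graph adjacency (weakly supported offending segments are dropped). A read
supports a covering when its path, length ≥ 3 so an interior node is
traversed in full, is a contiguous subpath of one of its walks in either
orientation. The best covering must lead the runner-up by `min_margin`
(2×); ties and unsupported tangles stay ambiguous and are emitted as
per-node contigs.

Consensus lays out the walk's compressed backbone from node placements and
takes, at every position, the modal run length across all reads placed
there (ties break toward the smaller run — deterministic, and biased
toward the left tail of the run-length distribution). Positions with no
read support emit run length 1 and are reported as low-coverage intervals.

## Tandem-array ("morph") assembly

Arrays of near-identical units are assembled outside the string graph:

* The sparse de Bruijn graph samples k-mers by hash
  (`crc32(kmer) % stride == 0`, stride 50, k 21): the rule is a function
  of the k-mer alone, so all reads sample the same genomic positions —
  positional every-s-th sampling would not be consistent across reads.
  `stride=1` reduces to the classic graph. Nodes/edges below a read-count
  floor (3 at 20–30× accurate coverage) are pruned as error k-mers.
* Ultra-long reads are threaded through the graph: exact sampled-k-mer
  anchors, and between consecutive anchors every plausible graph path is
  rendered from edge labels and the path *closest to the read segment by
  edit distance* substitutes it. Choosing by read distance (not by length
  or coverage) preserves the variant structure the read actually carries;
  residual wrong-variant picks occur at a few percent of variant sites
  and are absorbed by the later majority consensus.
* Walks are oriented against the reference unit and segmented at the
  starts of successive reference hits, so indels stretch one copy rather
  than shifting its neighbours. Copies within ±10% of the reference
  length count as complete; flanking partials are emitted above 25% of a
  unit.
* Single-linkage clustering at 99.5% identity separates morphs expected
  to differ by ~1%; clusters with fewer than two supporting units are
  discarded as noise stragglers. The consensus aligns every member to the
  cluster medoid and takes column majorities (insertions emitted when
  more than half the members insert), which recovers the exact morph
  sequence from ≥20 noisy units at ~1% residual error.
* Copy number is `round(units_observed / mean_unit_depth)`, floored at 1.
  When reads span the whole array, the longest morph path equals the
  total copy count and yields an unbiased unit depth; otherwise the
  short-read depth ratio (`array depth / genome base depth`) estimates
  total copies.
* The layout is resolved when a full-array-spanning read pins it or when
  the morph graph admits a unique copy-number-consistent walk; otherwise
  morphs are arranged in descending-copy-number blocks and the output is
  flagged `model=True` — the flag travels with the sequence so downstream
  users can tell resolved order from modelled order.

## Validation statistics

Coverage uses per-base depth from interval accumulation; the band is
mean ± 3 s.d. (a constant profile counts as fully in-band), below-band
runs become `low_coverage` issues and above-band runs `error` candidates
(collapsed repeats). Markers are canonical k-mers (k=21) occurring exactly
once assembly-wide; marker-assisted assignment gives a multi-mapping read
to the candidate whose span contains the most read-confirmed markers,
keeping the primary alignment (flagged low-confidence) when no marker
agrees anywhere. Allele-ratio tracks flag windows where the primary-allele
fraction falls below 0.8 at ≥10× depth (0.3–0.8 → heterozygous-like,
<0.3 → error candidate). Windowed identity takes, for each window of one
sequence, the maximum global-alignment identity against any window of the
other (shared-k-mer prefiltering avoids all-pairs alignment) and smooths
with a boxcar. NG50 follows the fixed-genome-size definition; contigs are
split at runs of ≥3 Ns.

## Simulator: what it emulates and what it does not

The generator produces haploid genomes with dispersed repeats diverged to
a target identity by point mutation, satellite arrays, a shuffled
two-or-more-morph tandem array (the morph table, order and unit reference
are recorded as truth), optional GA-rich tracts and homopolymer boosting.
Read samplers draw fragments whose starts may fall off either sequence
end (clipped at the boundary), as in a real telomere-to-telomere library
where molecules end at chromosome ends — purely interior starts would
leave the last few hundred bases of each terminus uncovered, an artifact
no assembler could overcome. GA-dropout suppresses candidate reads
touching a tract with probability 0.9, reproducing the coverage-gap
phenotype of accurate reads over GA-rich sequence at scales where tracts
are shorter than a read.

Not emulated: diploidy/heterozygosity, base-quality strings, chimeric
reads, sequence-dependent error hotspots beyond homopolymers, methylation
or any mapping-bias structure. Passing benchmarks therefore demonstrate
the correctness of the algorithms under the stated error and repeat
models, not performance on real instrument data.

## Problem sizes and determinism

The reference experiments run at desk scale: 200 kbp genomes at 30×/40×
coverage for end-to-end assembly, 130 kbp two-chromosome constructions
for tangle trials, 54 kbp genomes with 24 kbp arrays for morph recovery,
100 kbp targets for coverage screening. All randomness flows from explicit
seeds; simulators accept either a seed or a generator, and every protocol
in `hapasm.protocols` is reproducible from its single seed argument.

## Known limitations

* Correction assumes enough depth (≥ `min_depth`) everywhere; below it,
  residual errors leave reads as multiplicity-0 spurs rather than being
  repaired.
* Tangles whose candidate count exceeds the enumeration caps are reported
  ambiguous wholesale; no sampling or scoring of partial walks is
  attempted.
* The morph-layout search treats reversed layouts as equivalent and does
  not model nested or inverted array rearrangements (none are emitted:
  units are always head-to-tail).
* GA-dropout gaps are reported as separate contigs with a note; no
  patching against a prior assembly is attempted.
* Windowed identity compares same-scale windows only; large structural
  rearrangements between the sequences show as identity loss rather than
  being aligned around.
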