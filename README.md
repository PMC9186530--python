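# hapasm

Desk-scale tooling for assembling a *complete* haploid genome from long
reads, and for validating the result — the methodology that finished the
last repeat-rich fraction of a genome, reduced to sizes where every stage
can be verified against simulated ground truth.

The package is aimed at people studying or teaching modern genome
assembly: it implements the full recipe as a library of small, testable
stages rather than a monolithic assembler.

## What it implements

**Homopolymer-compressed string graphs.** Accurate long reads (~20 kbp,
~0.1% error; "HiFi-like") err almost exclusively by lengthening or
shortening homopolymer runs, so every run is first compressed to a single
base: `AAACGGT → ACGT` with run lengths `[3,1,2,1]`. In compressed space,
reads are aligned all-vs-all, residual errors are corrected by pileup
majority (columns for substitutions, whole simple-sequence-repeat regions
for indels, whose placement inside tandem context is ambiguous), and only
**exact** suffix–prefix overlaps — masked microsatellite positions acting
as wildcards — become edges of a bidirected string graph. Nodes are
unitigs (maximal unambiguous paths); iterative simplification applies
transitive reduction, tip clipping and bubble popping; node multiplicity
is estimated as `round(depth / base_depth)` with depth below
`0.2 × base_depth` marking artifacts.

**Walks and ultra-long-read arbitration.** A chromosome is a walk that
traverses every multiplicity-*m* node exactly *m* times and skips
artifacts. All consistent walk coverings of a component are enumerated;
where repeats admit several (tangles), noisy ultra-long reads
(≥100 kbp, ~5% error; "ONT-like") are aligned to the graph by unique-k-mer
anchoring, and the covering supported by the most spanning read paths wins
if it leads the runner-up by a margin (default 2×) — otherwise the tangle
is honestly reported ambiguous. The consensus returns to uncompressed
space: each backbone position takes the modal run length over the accurate
reads placed there.

**rDNA-like tandem arrays.** Arrays of near-identical units defeat string
graphs, so they get a dedicated path: a sparse de Bruijn graph
(hash-sampled k-mers) built from accurate reads, ultra-long reads threaded
through it (each inter-anchor gap replaced by the graph path closest to
the read, which denoises it), walks segmented into units against a
reference unit, units clustered into **morphs** by single-linkage identity,
copy numbers estimated from supporting reads, and the array layout either
pinned by spanning reads or emitted as copy-number blocks flagged
`model=True`.

**Validation statistics.** Contig/NG50 statistics (contigs split at ≥3
consecutive Ns; NG50 = largest L with contigs ≥ L summing to half the
genome size), per-base coverage profiles with a mean ± 3 s.d. band and an
issue catalog, unique-k-mer marker maps and marker-assisted read
assignment inside near-identical repeats, primary/secondary allele-ratio
tracks, and windowed maximum-identity profiles.

**Simulator.** `hapasm.simulate` generates haploid genomes with dispersed
near-identical repeats, satellite arrays, two-morph tandem arrays, GA-rich
dropout tracts and homopolymer-dense tracts, plus HiFi-like and ONT-like
read sets with full per-read ground truth — every other module is tested
against it.

## Worked example

```python
import edlib
from hapasm import pipeline, simulate as sim
from hapasm.seqmodel import revcomp

spec = sim.GenomeSpec(seed=1, backbone_len=60_000,
                      repeats=[sim.RepeatSpec(2000, 2, 0.999)])
genome, truth = sim.simulate_genome(spec)
hifi = sim.simulate_hifi(genome, depth=20, mean_len=8000, seed=2)
result = pipeline.assemble(hifi, min_overlap=400)
for walk, contig in zip(result.walks, result.contigs):
    d = min(edlib.align(contig.bases, genome.bases, mode="NW")["editDistance"],
            edlib.align(contig.bases, revcomp(genome.bases), mode="NW")["editDistance"])
    print(walk.id, walk.status, len(contig), d)
```

prints

```
contig1 resolved 64000 3
```

— one resolved walk whose 64,000 bp consensus differs from the simulated
genome by 3 edits (99.995% identity). The `examples/` directory holds one
short narrative script per capability (assembly, tangle resolution, morph
assembly, validation); each prints what it computes and what the numbers
mean. A thin CLI (`hapasm simulate|assemble|stats`) wraps the same calls
for shell use.

## Layout

```
src/hapasm/
  seqmodel.py        sequences, FASTA/FASTQ, HPC transform, microsatellites
  overlap_correct.py all-vs-all alignment, correction, exact overlaps
  string_graph.py    bidirected graph, simplification, multiplicity, GFA
  walk_resolve.py    walk enumeration, read-to-graph alignment, consensus
  rdna_morphs.py     sparse DBG, unit segmentation, morph clustering/layout
  validate_stats.py  NG50, coverage bands, markers, allele ratios, issues
  simulate.py        genome and read simulator with ground truth
  pipeline.py        end-to-end assembly orchestration
  protocols.py       seeded reference experiments used by tests/examples
```

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
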