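"""Reference experiment protocols on synthetic data.

Each function builds a simulated dataset with known ground truth, runs one
capability of the toolkit end to end, and returns the measured outcome.
They are the backbone of the verification suite and of the worked examples;
all randomness flows from the single ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from . import rdna_morphs as rm
from . import simulate as sim
from . import string_graph as sg
from . import walk_resolve as wr
from .pipeline import assemble
from .seqmodel import Sequence, hpc_compress, revcomp


# ---------------------------------------------------------------------------
# End-to-end assembly
# ---------------------------------------------------------------------------

@dataclass
class EndToEndResult:
    n_contigs: int
    n_resolved: int
    identity: float  # best contig vs truth, NW identity over the longer
    total_len: int
    genome_len: int


def end_to_end_trial(seed: int, backbone_len: int = 161_000,
                     repeat_len: int = 15_000, repeat_identity: float = 0.999,
                     rdna_unit: int = 750, rdna_copies=(8, 4),
                     hifi_depth: float = 30.0, ont_depth: float = 40.0
                     ) -> EndToEndResult:
    """Assemble a simulated haploid genome with a near-identical dispersed
    repeat and a two-morph tandem array; measure consensus identity."""
    spec = sim.GenomeSpec(
        seed=seed, backbone_len=backbone_len,
        repeats=[sim.RepeatSpec(repeat_len, 2, repeat_identity)],
        rdna=sim.RdnaSpec(unit_len=rdna_unit, copy_numbers=tuple(rdna_copies),
                          morph_identity=0.99))
    genome, _ = sim.simulate_genome(spec)
    hifi = sim.simulate_hifi(genome, hifi_depth, seed=seed + 1)
    ont = sim.simulate_ont(genome, ont_depth, seed=seed + 2)
    res = assemble(hifi, ont)
    best = 0.0
    for c in res.contigs:
        d = min(edlib.align(c.bases, genome.bases, mode="NW")["editDistance"],
                edlib.align(c.bases, revcomp(genome.bases),
                            mode="NW")["editDistance"])
        best = max(best, 1.0 - d / max(len(c), len(genome)))
    return EndToEndResult(len(res.contigs),
                          sum(w.status == "resolved" for w in res.walks),
                          best, sum(len(c) for c in res.contigs), len(genome))


# ---------------------------------------------------------------------------
# X-tangle resolution
# ---------------------------------------------------------------------------

def build_xtangle(seed: int, flank_len: int = 25_000, repeat_len: int = 30_000):
    """Two chromosomes A.R.B and C.R.D sharing one identical repeat R,
    plus the truth string graph (R at multiplicity 2)."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def rand(n):
        return rng.choice(bases, size=n).tobytes().decode()

    A, B, C, D = (rand(flank_len) for _ in range(4))
    R = rand(repeat_len)
    chr1 = Sequence("chr1", A + R + B)
    chr2 = Sequence("chr2", C + R + D)
    graph = sg.StringGraph()
    for name, seq in [("A", A), ("B", B), ("C", C), ("D", D), ("R", R)]:
        node = sg.SGNode(name, hpc_compress(Sequence(name, seq)).bases)
        node.multiplicity = 2 if name == "R" else 1
        graph.add_node(node)
    graph.add_edge("A", "h", "R", "t", 0)
    graph.add_edge("R", "h", "B", "t", 0)
    graph.add_edge("C", "h", "R", "t", 0)
    graph.add_edge("R", "h", "D", "t", 0)
    truth = {wr._canonical([("A", "+"), ("R", "+"), ("B", "+")]),
             wr._canonical([("C", "+"), ("R", "+"), ("D", "+")])}
    return chr1, chr2, graph, truth


def xtangle_trial(seed: int, ont_depth: float = 20.0, with_ont: bool = True
                  ) -> tuple[bool, str]:
    """(correct pairing chosen, status) for one seeded X-tangle."""
    chr1, chr2, graph, truth = build_xtangle(seed)
    cands, _ = wr.enumerate_candidates(graph)
    if not with_ont:
        chosen = wr.select_walk(cands, [])
        return False, chosen.status
    ont = (sim.simulate_ont(chr1, ont_depth, seed=seed * 2 + 1)
           + sim.simulate_ont(chr2, ont_depth, seed=seed * 2 + 2))
    alns = wr.align_ont_to_graph(ont, graph)
    chosen = wr.select_walk(cands, alns)
    got = {wr._canonical(w) for w in chosen.walks}
    return (chosen.status == "resolved" and got == truth), chosen.status


# ---------------------------------------------------------------------------
# rDNA-like morph assembly
# ---------------------------------------------------------------------------

@dataclass
class RdnaResult:
    n_morphs: int
    copy_numbers: list[int]
    true_copy_numbers: list[int]
    total_copies: int
    layout: list[str]
    model_flag: bool
    model_flag_without_spanning: bool
    layout_matches_truth: bool


def rdna_trial(seed: int, unit_len: int = 2000, copy_numbers=(8, 4),
               morph_identity: float = 0.99, threshold: float = 0.995,
               hifi_depth: float = 30.0, ont_depth: float = 20.0
               ) -> RdnaResult:
    """Recover morphs, copy numbers and layout of a simulated tandem array."""
    spec = sim.GenomeSpec(
        seed=seed, backbone_len=30_000,
        rdna=sim.RdnaSpec(unit_len=unit_len,
                          copy_numbers=tuple(copy_numbers),
                          morph_identity=morph_identity))
    genome, truth = sim.simulate_genome(spec)
    hifi = sim.simulate_hifi(genome, hifi_depth, mean_len=18_000, seed=seed + 1)
    ont = sim.simulate_ont(genome, ont_depth, seed=seed + 2)
    dbg = rm.build_sparse_dbg([r.sequence for r in hifi], k=21,
                              sample_stride=50)
    walks, _ = rm.extract_walks([r.sequence for r in ont], dbg, min_count=3)
    walks = rm.orient_walks(walks, truth.rdna_unit_reference)
    units = []
    for w in walks:
        units.extend(rm.segment_units(w, truth.rdna_unit_reference,
                                      min_identity=0.85))
    morphs = rm.cluster_morphs(units, identity_threshold=threshold)
    mgraph = rm.build_morph_graph(units, morphs)
    unit_depth, total = rm.estimate_unit_depth(mgraph)
    rm.estimate_copy_number(morphs, unit_depth)
    copy_map = {m.id: m.copy_number for m in morphs}
    layout, model = rm.layout_array(mgraph, copy_map)
    # withheld spanning reads: only 3-unit stubs of each read path remain
    stub = rm.MorphGraph(mgraph.nodes, mgraph.edges,
                         [p[:3] for p in mgraph.read_paths])
    _, model_wo = rm.layout_array(stub, copy_map)

    # match recovered morphs to truth consensi for copy-number comparison
    true_cns = []
    relabel = {}
    for m in morphs:
        tid = min(truth.morph_table,
                  key=lambda t: edlib.align(m.consensus, t[1],
                                            mode="NW")["editDistance"])
        true_cns.append(tid[2])
        relabel[m.id] = tid[0]
    layout_relabelled = [relabel.get(x, x) for x in layout]
    matches = (layout_relabelled == truth.morph_order
               or layout_relabelled == list(reversed(truth.morph_order)))
    return RdnaResult(len(morphs), [m.copy_number for m in morphs], true_cns,
                      total, layout, model, model_wo, matches)


# ---------------------------------------------------------------------------
# Coverage validation
# ---------------------------------------------------------------------------

def coverage_trial(seed: int, target_len: int = 100_000, depth: int = 30,
                   dup_start: int = 40_000, dup_len: int = 10_000,
                   read_len: int = 1000, inject_duplication: bool = False):
    """Poisson-uniform coverage, optionally with a collapsed-duplication
    region at twice the depth; returns (in-band fraction, issues)."""
    from .validate_stats import coverage_profile, flag_coverage
    rng = np.random.default_rng(seed)
    n = depth * target_len // read_len
    starts = rng.integers(-read_len + 1, target_len, size=n)
    ivs = [(int(s), int(s) + read_len) for s in starts]
    if inject_duplication:
        extra = rng.integers(dup_start - read_len + 1, dup_start + dup_len,
                             size=depth * dup_len // read_len)
        ivs += [(int(s), int(s) + read_len) for s in extra]
    prof = coverage_profile(ivs, target_len, "sim", "hifi")
    return flag_coverage(prof, n_sd=3.0)
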