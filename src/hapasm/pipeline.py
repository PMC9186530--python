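"""End-to-end assembly orchestration.

``assemble`` runs the full accurate-read pipeline — homopolymer
compression, all-vs-all alignment, correction, simple-repeat masking,
exact overlapping, string-graph construction and simplification,
multiplicity estimation, per-component walk enumeration with optional
noisy-long-read arbitration, and uncompressed consensus — and returns the
contigs together with the graph and walk diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from . import overlap_correct as oc
from . import string_graph as sg
from . import walk_resolve as wr
from .seqmodel import Read, Sequence, hpc_compress


@dataclass
class AssemblyResult:
    contigs: list[Sequence]
    walks: list[wr.Walk]
    graph: sg.StringGraph
    low_coverage: list[tuple[str, int, int]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def assemble(hifi_reads: Iterable[Read],
             ont_reads: Optional[Iterable[Read]] = None,
             min_overlap: int = 500,
             align_k: int = 15,
             exact_k: int = 21,
             identity_floor: float = 0.98,
             min_depth: int = 4,
             min_support_ratio: float = 2.0,
             correction_rounds: int = 2,
             mask_min_length: int = 6,
             mask_min_copies: int = 2,
             tip_len: Optional[int] = None,
             bubble_len: Optional[int] = None,
             anchor_k: int = 21,
             min_margin: float = 2.0,
             max_candidates: int = 10_000) -> AssemblyResult:
    """Assemble accurate long reads, using noisy ultra-long reads to
    arbitrate repeat tangles where the graph alone is ambiguous."""
    hifi = list(hifi_reads)
    corrected = [hpc_compress(r.sequence) for r in hifi]
    mask_kw = dict(min_length=mask_min_length, min_copies=mask_min_copies)
    for _ in range(max(correction_rounds, 0)):
        masks = oc.compute_masks(corrected, **mask_kw)
        alns = oc.all_pairs_align(corrected, min_overlap=min_overlap,
                                  k=align_k, identity_floor=identity_floor)
        corrected = oc.correct_reads(corrected, alns, masks,
                                     min_support_ratio=min_support_ratio,
                                     min_depth=min_depth)
    masks2 = oc.compute_masks(corrected, **mask_kw)
    overlaps = oc.exact_overlaps(corrected, masks2, min_overlap=min_overlap,
                                 k=exact_k)
    # graph edges need more overlap than raw detection: short exact matches
    # arise spuriously inside tandem arrays (unit-shifted self-similarity)
    med_rl = int(np.median([len(r) for r in corrected])) if corrected else 0
    graph_min = max(min_overlap, int(0.2 * med_rl))
    graph = sg.build_graph(corrected, overlaps, min_overlap=graph_min)
    # error spurs and bubble branches are read-sized structures, so the
    # cleaning scales default to the compressed read length
    if tip_len is None:
        tip_len = int(2.5 * med_rl)
    if bubble_len is None:
        bubble_len = 3 * med_rl
    sg.simplify(graph, tip_len=tip_len, bubble_len=bubble_len)
    sg.estimate_multiplicity(graph)

    ont_alignments = None
    result = AssemblyResult([], [], graph)
    for ci, comp in enumerate(sorted(graph.components(), key=sorted)):
        active = [n for n in comp if graph.nodes[n].multiplicity >= 1]
        if not active:
            continue
        cands, status = wr.enumerate_candidates(graph, set(active),
                                                max_candidates=max_candidates)
        chosen = None
        if len(cands) == 1:
            chosen = cands[0]
            chosen.status = "resolved"
        elif len(cands) > 1:
            if ont_alignments is None and ont_reads is not None:
                ont_alignments = wr.align_ont_to_graph(list(ont_reads), graph,
                                                       anchor_k=anchor_k)
            chosen = wr.select_walk(cands, ont_alignments or [],
                                    min_margin=min_margin)
        if chosen is not None and chosen.status == "resolved":
            # identical walks (over-estimated multiplicity of an isolated
            # node) would emit duplicate contigs; keep one of each
            uniq = []
            seen_walks = set()
            for steps in chosen.walks:
                key = wr._canonical(steps)
                if key not in seen_walks:
                    seen_walks.add(key)
                    uniq.append(steps)
            chosen.walks = uniq
            for wi, steps in enumerate(chosen.walks):
                wid = (f"contig{ci}" if len(chosen.walks) == 1
                       else f"contig{ci}.{wi}")
                walk = wr.Walk(wid, steps, "resolved", chosen.support)
                cons = wr.consensus(walk, graph, corrected)
                result.walks.append(walk)
                result.contigs.append(cons.sequence)
                for s, e in cons.low_coverage:
                    result.low_coverage.append((wid, s, e))
        else:
            # ambiguous component: emit each node as its own contig
            note = status if isinstance(status, str) else "ambiguous"
            result.notes.append(f"component {ci}: {note}")
            for j, nid in enumerate(sorted(active)):
                w = wr.Walk(f"contig{ci}.{j}", [(nid, "+")], "ambiguous")
                cons = wr.consensus(w, graph, corrected)
                result.walks.append(w)
                result.contigs.append(cons.sequence)
    return result
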