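"""Tandem-array ("rDNA-like") assembly via sparse de Bruijn graphs.

Long near-identical tandem arrays defeat string-graph assembly, so they are
handled separately: a sparse de Bruijn graph is built from accurate reads,
noisy ultra-long reads are threaded through it to produce denoised *walks*,
walks are segmented into repeat units against a reference unit, units are
clustered into consensus variants ("morphs"), morph copy numbers are
estimated from supporting-read counts, and read-observed morph adjacencies
form a morph graph from which the array layout is either resolved (a unique
walk) or emitted as a *model* (copy-number blocks) when read lengths cannot
pin the order.

Sparse k-mer sampling is hash-based (a k-mer is a graph node iff
``crc32(kmer) % stride == 0``) so that all reads sample the same positions
of the underlying genome; ``stride=1`` reduces to a classic de Bruijn
graph.
"""

from __future__ import annotations

import re
import warnings
import zlib
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

import edlib
import numpy as np

from .seqmodel import Read, Sequence, revcomp


def _sampled(km: str, stride: int) -> bool:
    return stride <= 1 or zlib.crc32(km.encode()) % stride == 0


@dataclass
class SparseDBG:
    k: int
    stride: int
    nodes: Counter = field(default_factory=Counter)  # kmer -> read count
    edges: dict = field(default_factory=dict)  # (u, v) -> [count, Counter(labels)]
    skipped_reads: int = 0

    def succ(self, u: str):
        for (a, b), (cnt, labels) in self.edges.items():
            if a == u:
                yield b, cnt, labels.most_common(1)[0][0]

    def label(self, u: str, v: str) -> Optional[str]:
        rec = self.edges.get((u, v))
        if rec is None:
            return None
        return rec[1].most_common(1)[0][0]


def _bases_of(read) -> tuple[str, str]:
    if isinstance(read, Read):
        return read.sequence.bases, read.id
    if isinstance(read, Sequence):
        return read.bases, read.id
    return str(read), ""


def build_sparse_dbg(reads: Iterable, k: int = 21, sample_stride: int = 50
                     ) -> SparseDBG:
    """Sparse de Bruijn graph over hash-sampled k-mers.

    Edges join consecutive sampled k-mers within each read and carry the
    intervening sequence as a label (votes across reads; the most common
    label wins).  Reads shorter than k are skipped with a warning.
    """
    dbg = SparseDBG(k, sample_stride)
    # adjacency index for successors (built lazily by callers via edges)
    for read in reads:
        s, rid = _bases_of(read)
        if len(s) < k:
            warnings.warn(f"read {rid!r} shorter than k={k}; skipped")
            dbg.skipped_reads += 1
            continue
        prev = None
        prev_pos = -1
        for p in range(len(s) - k + 1):
            km = s[p:p + k]
            if not _sampled(km, sample_stride):
                continue
            dbg.nodes[km] += 1
            if prev is not None:
                rec = dbg.edges.setdefault((prev, km), [0, Counter()])
                rec[0] += 1
                rec[1][s[prev_pos + k:p + k]] += 1
            prev, prev_pos = km, p
    return dbg


def _adjacency(dbg: SparseDBG, min_count: int = 1) -> dict:
    adj = defaultdict(list)
    for (u, v), (cnt, labels) in dbg.edges.items():
        if cnt >= min_count:
            adj[u].append((v, cnt, labels.most_common(1)[0][0]))
    return adj


def _bridge_candidates(adj, u, v, gap_len, stride, max_paths=64):
    """Label strings of graph paths u -> v with plausible rendered length."""
    limit = gap_len + 3 * stride
    max_depth = gap_len // max(stride, 1) + 6
    out = []
    stack = [(u, "", 0)]
    while stack and len(out) < max_paths:
        cur, lab, depth = stack.pop()
        if depth > max_depth:
            continue
        for nxt, cnt, label in adj.get(cur, ()):
            nl = lab + label
            if len(nl) > limit:
                continue
            if nxt == v and len(nl) >= max(gap_len - 3 * stride, 1):
                out.append(nl)
            stack.append((nxt, nl, depth + 1))
    return out


def extract_walks(ont_reads: Iterable, dbg: SparseDBG, min_anchors: int = 2,
                  max_gap_identity: float = 0.65,
                  min_count: int = 1) -> tuple[list[Sequence], int]:
    """Thread noisy reads through the graph; returns (walks, n_omitted).

    Exact sampled-k-mer hits anchor the read on the graph; between
    consecutive anchors every plausible graph path is rendered from the
    (accurate-read-derived) edge labels and the one closest to the raw
    read segment by edit distance replaces it, which denoises the read
    while preserving the variant structure it actually carries.  Gaps no
    path can bridge keep the raw read segment.
    """
    adj = _adjacency(dbg, min_count)
    walks = []
    omitted = 0
    for read in ont_reads:
        s, rid = _bases_of(read)
        anchors = []
        for p in range(max(len(s) - dbg.k + 1, 0)):
            km = s[p:p + dbg.k]
            if _sampled(km, dbg.stride) and dbg.nodes.get(km, 0) >= min_count:
                anchors.append((p, km))
        if len(anchors) < min_anchors:
            omitted += 1
            continue
        parts = [anchors[0][1]]
        for (pu, u), (pv, v) in zip(anchors, anchors[1:]):
            gap = pv - pu
            raw = s[pu + dbg.k:pv + dbg.k]
            cands = _bridge_candidates(adj, u, v, gap, dbg.stride)
            lab = None
            if cands:
                scored = []
                for cand in set(cands):
                    d = edlib.align(cand, raw, mode="NW")["editDistance"]
                    scored.append((d, cand))
                d, best = min(scored)
                if d <= (1.0 - max_gap_identity) * max(len(best), len(raw), 1):
                    lab = best
            parts.append(lab if lab is not None else raw)
        walks.append(Sequence(f"{rid}|walk", "".join(parts)))
    return walks, omitted


def orient_walks(walks: Iterable[Sequence], unit_reference: str
                 ) -> list[Sequence]:
    """Flip walks so units run head-to-tail in the reference orientation."""
    out = []
    rc_ref = revcomp(unit_reference)
    for w in walks:
        df = edlib.align(unit_reference, w.bases, mode="HW")["editDistance"]
        dr = edlib.align(rc_ref, w.bases, mode="HW")["editDistance"]
        if dr >= 0 and (df < 0 or dr < df):
            out.append(Sequence(w.id, revcomp(w.bases)))
        else:
            out.append(w)
    return out


# ---------------------------------------------------------------------------
# Unit segmentation
# ---------------------------------------------------------------------------

@dataclass
class UnitSequence:
    source_id: str
    ordinal: int
    bases: str
    complete: bool
    start: int = 0
    end: int = 0


def _unit_hits(seq: str, ref: str, min_identity: float) -> list[tuple]:
    """Non-overlapping occurrences of ref in seq (recursive best-hit)."""
    hits = []

    def rec(lo: int, hi: int) -> None:
        if hi - lo < 0.5 * len(ref):
            return
        res = edlib.align(ref, seq[lo:hi], mode="HW", task="locations")
        d = res["editDistance"]
        if d < 0 or 1.0 - d / len(ref) < min_identity:
            return
        s, e = res["locations"][0]
        e += 1
        hits.append((lo + s, lo + e))
        rec(lo, lo + s)
        rec(lo + e, hi)

    rec(0, len(seq))
    return sorted(hits)


def segment_units(seq: Sequence, unit_reference: str,
                  min_identity: float = 0.85,
                  complete_tol: float = 0.10,
                  min_partial_frac: float = 0.25) -> list[UnitSequence]:
    """Tile a walk into repeat units anchored at the reference origin.

    Unit boundaries are the starts of successive reference hits, so indels
    within a copy stretch or shrink that copy rather than shifting its
    neighbours.  Units whose span deviates from the reference length by
    more than ``complete_tol`` are marked incomplete, as are the flanking
    partial copies (emitted only when at least ``min_partial_frac`` of a
    unit long).
    """
    s = seq.bases
    hits = _unit_hits(s, unit_reference, min_identity)
    if not hits:
        return []
    starts = [h[0] for h in hits]
    last_end = hits[-1][1]
    units = []
    ordinal = 0
    lead = starts[0]
    if lead >= min_partial_frac * len(unit_reference):
        units.append(UnitSequence(seq.id, ordinal, s[:lead], False, 0, lead))
        ordinal += 1
    bounds = starts + [last_end]
    for i in range(len(starts)):
        a, b = bounds[i], bounds[i + 1]
        complete = abs((b - a) - len(unit_reference)) \
            <= complete_tol * len(unit_reference)
        units.append(UnitSequence(seq.id, ordinal, s[a:b], complete, a, b))
        ordinal += 1
    tail = len(s) - last_end
    if tail >= min_partial_frac * len(unit_reference):
        units.append(UnitSequence(seq.id, ordinal, s[last_end:], False,
                                  last_end, len(s)))
    return units


# ---------------------------------------------------------------------------
# Morph clustering and consensus
# ---------------------------------------------------------------------------

@dataclass
class Morph:
    id: str
    consensus: str
    copy_number: int = -1
    supporting_reads: set = field(default_factory=set)
    n_units: int = 0


def _identity(a: str, b: str) -> float:
    d = edlib.align(a, b, mode="NW")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _medoid(seqs: list[str]) -> str:
    """The sequence minimising total edit distance to the others."""
    if len(seqs) <= 2:
        return min(seqs)
    best = None
    for s in seqs:
        tot = sum(edlib.align(s, t, mode="NW")["editDistance"]
                  for t in seqs if t is not s)
        cand = (tot, s)
        if best is None or cand < best:
            best = cand
    return best[1]


_CIG = re.compile(r"(\d+)([=XID])")


def majority_consensus(seqs: list[str]) -> str:
    """Column-majority consensus of near-identical sequences.

    The medoid serves as the backbone; every sequence is globally aligned to
    it, and each backbone column takes the majority base (or deletion).  An
    insertion is emitted at a junction when more than half the sequences
    insert there (most common inserted string).
    """
    if not seqs:
        return ""
    backbone = _medoid(seqs)
    n = len(seqs)
    L = len(backbone)
    col: list[Counter] = [Counter() for _ in range(L)]
    ins: list[Counter] = [Counter() for _ in range(L + 1)]
    for s in seqs:
        res = edlib.align(s, backbone, mode="NW", task="path")
        pq = pt = 0
        for num, op in _CIG.findall(res["cigar"]):
            m = int(num)
            if op in "=X":
                for i in range(m):
                    col[pt + i][s[pq + i]] += 1
                pq += m
                pt += m
            elif op == "I":  # present in s, absent in backbone
                ins[pt][s[pq:pq + m]] += 1
                pq += m
            else:  # 'D': backbone base absent in s
                for i in range(m):
                    col[pt + i]["-"] += 1
                pt += m
    out = []
    for p in range(L + 1):
        if ins[p]:
            text, cnt = ins[p].most_common(1)[0]
            if cnt > n / 2:
                out.append(text)
        if p == L:
            break
        base, _ = col[p].most_common(1)[0]
        if base != "-":
            out.append(base)
    return "".join(out)


def cluster_morphs(units: list[UnitSequence], identity_threshold: float = 0.995,
                   min_units: int = 2) -> list[Morph]:
    """Single-linkage clustering of complete units at an identity threshold.

    Clusters become morphs with a column-majority consensus; clusters with
    fewer than ``min_units`` members (straggler units from residual read
    noise) are not reported.  Output order (and ids) is by descending unit
    count, then consensus, so the result is invariant to input order.
    """
    comp = [u for u in units if u.complete]
    if not comp:
        return []
    n = len(comp)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if _identity(comp[i].bases, comp[j].bases) >= identity_threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[UnitSequence]] = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(comp[i])
    morphs = []
    for members in groups.values():
        if len(members) < min_units and len(comp) >= 2 * min_units:
            continue
        cons = majority_consensus(sorted(u.bases for u in members))
        morphs.append(Morph("", cons, -1,
                            {u.source_id for u in members}, len(members)))
    morphs.sort(key=lambda m: (-m.n_units, m.consensus))
    for i, m in enumerate(morphs):
        m.id = f"morph{i}"
    return morphs


def polish_consensus(consensus: str, fragments: list[str]) -> str:
    """One majority-polish pass of a consensus with accurate fragments."""
    if not fragments:
        return consensus
    return majority_consensus([consensus] + list(fragments))


# ---------------------------------------------------------------------------
# Copy numbers
# ---------------------------------------------------------------------------

def estimate_copy_number(morphs: list[Morph], mean_unit_depth: float
                         ) -> list[Morph]:
    """copy_number = round(units observed / mean unit depth), min 1."""
    if mean_unit_depth <= 0:
        raise ValueError("mean_unit_depth must be positive")
    for m in morphs:
        m.copy_number = max(1, int(np.floor(m.n_units / mean_unit_depth + 0.5)))
    return morphs


def estimate_unit_depth(mgraph: "MorphGraph") -> tuple[float, int]:
    """Mean per-slot unit coverage and total copies from read paths.

    Assumes at least one read spans the whole array, so the longest
    observed morph path equals the total copy count; the mean coverage of
    a unit slot is then total observed units / total copies.  For arrays
    longer than the reads, use the short-read depth ratio
    (:func:`estimate_array_copies_by_depth`) for total copies instead.
    """
    if not mgraph.read_paths:
        raise ValueError("no multi-unit read paths")
    total = max(len(p) for p in mgraph.read_paths)
    return sum(len(p) for p in mgraph.read_paths) / total, total


def estimate_array_copies_by_depth(array_depth: float, base_depth: float
                                   ) -> float:
    """Total array copies per assembled unit from short-read depth ratio."""
    if base_depth <= 0:
        raise ValueError("base_depth must be positive")
    return array_depth / base_depth


# ---------------------------------------------------------------------------
# Morph graph and array layout
# ---------------------------------------------------------------------------

@dataclass
class MorphGraph:
    nodes: list[str]
    edges: dict  # (m1, m2) -> weight
    read_paths: list[list[str]] = field(default_factory=list)


def assign_units(units: list[UnitSequence], morphs: list[Morph]
                 ) -> dict[tuple, str]:
    """Assign each complete unit to its closest morph consensus."""
    out = {}
    for u in units:
        if not u.complete:
            continue
        best = min(morphs,
                   key=lambda m: edlib.align(u.bases, m.consensus,
                                             mode="NW")["editDistance"])
        out[(u.source_id, u.ordinal)] = best.id
    return out


def build_morph_graph(units: list[UnitSequence], morphs: list[Morph]
                      ) -> MorphGraph:
    """Directed morph adjacencies observed in reads spanning >=2 units."""
    assign = assign_units(units, morphs)
    by_read: dict[str, list[UnitSequence]] = defaultdict(list)
    for u in units:
        if u.complete:
            by_read[u.source_id].append(u)
    edges: Counter = Counter()
    paths = []
    for rid, ulist in by_read.items():
        ulist.sort(key=lambda u: u.ordinal)
        path = []
        for a, b in zip(ulist, ulist[1:]):
            if b.ordinal == a.ordinal + 1:  # adjacent in the read
                edges[(assign[(rid, a.ordinal)], assign[(rid, b.ordinal)])] += 1
        for u in ulist:
            path.append(assign[(rid, u.ordinal)])
        if len(path) >= 2:
            paths.append(path)
    return MorphGraph([m.id for m in morphs], dict(edges), paths)


def layout_array(mgraph: MorphGraph, copy_numbers: dict[str, int],
                 max_enum: int = 1000) -> tuple[list[str], bool]:
    """Order the morphs along the array, or fall back to a model layout.

    Returns ``(ordered morph ids, model_flag)``.  The layout is resolved
    (``model_flag=False``) when a read spans the whole array or when the
    morph graph admits a unique walk consistent with the copy numbers;
    otherwise morphs are arranged in consecutive blocks by descending copy
    number and flagged as a model sequence.
    """
    total = sum(copy_numbers.values())
    blocks: list[str] = []
    for mid in sorted(copy_numbers, key=lambda m: -copy_numbers[m]):
        blocks.extend([mid] * copy_numbers[mid])
    # a full-array-spanning read pins the layout directly
    full = [tuple(p) for p in mgraph.read_paths if len(p) == total]
    if full:
        canon = Counter(min(p, tuple(reversed(p))) for p in full)
        best, _ = canon.most_common(1)[0]
        if Counter(best) == Counter(
                {m: c for m, c in copy_numbers.items() if c > 0}):
            return list(best), False
    if not mgraph.edges:
        return blocks, True
    # enumerate walks consistent with observed adjacencies and copy numbers
    found: set[tuple] = set()

    def dfs(path, remaining):
        if len(found) > max_enum:
            return
        if len(path) == total:
            t = tuple(path)
            found.add(min(t, tuple(reversed(t))))
            return
        for nxt in sorted(remaining):
            if remaining[nxt] > 0 and (path[-1], nxt) in mgraph.edges:
                remaining[nxt] -= 1
                path.append(nxt)
                dfs(path, remaining)
                path.pop()
                remaining[nxt] += 1

    for start in sorted(copy_numbers):
        if copy_numbers[start] > 0:
            rem = dict(copy_numbers)
            rem[start] -= 1
            dfs([start], rem)
    if len(found) == 1:
        return list(next(iter(found))), False
    return blocks, True


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def write_morphs_fasta(morphs: list[Morph], path, model_flag: bool = False
                       ) -> None:
    """Morph consensi as FASTA; headers carry copy number and model flag."""
    with open(path, "w") as fh:
        for m in morphs:
            fh.write(f">{m.id} copy_number={m.copy_number} "
                     f"model={'true' if model_flag else 'false'} "
                     f"n_units={m.n_units}\n")
            for i in range(0, len(m.consensus), 80):
                fh.write(m.consensus[i:i + 80] + "\n")


def write_morph_graph_gfa(mgraph: MorphGraph, morphs: list[Morph], path
                          ) -> None:
    by_id = {m.id: m for m in morphs}
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for mid in mgraph.nodes:
            seq = by_id[mid].consensus if mid in by_id else "*"
            fh.write(f"S\t{mid}\t{seq}\n")
        for (a, b), w in sorted(mgraph.edges.items()):
            fh.write(f"L\t{a}\t+\t{b}\t+\t0M\tRC:i:{w}\n")


def write_unit_table(units: list[UnitSequence], path) -> None:
    with open(path, "w") as fh:
        fh.write("source\tordinal\tstart\tend\tlength\tcomplete\n")
        for u in units:
            fh.write(f"{u.source_id}\t{u.ordinal}\t{u.start}\t{u.end}"
                     f"\t{len(u.bases)}\t{int(u.complete)}\n")


def write_layout_bed(layout: list[str], morphs: list[Morph], array_id: str,
                     path, model_flag: bool = False) -> None:
    """Array layout as BED against the rendered array sequence."""
    by_id = {m.id: m for m in morphs}
    pos = 0
    with open(path, "w") as fh:
        for mid in layout:
            ln = len(by_id[mid].consensus)
            flag = "model" if model_flag else "resolved"
            fh.write(f"{array_id}\t{pos}\t{pos + ln}\t{mid}\t{flag}\n")
            pos += ln


def render_array(layout: list[str], morphs: list[Morph],
                 array_id: str = "array") -> Sequence:
    by_id = {m.id: m for m in morphs}
    return Sequence(array_id, "".join(by_id[m].consensus for m in layout))
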