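"""Chromosome walks through the string graph.

A finished chromosome is a walk that traverses every multiplicity-``m``
node exactly ``m`` times and skips multiplicity-0 (artifact) nodes.  Where
repeats make several walks possible (tangles), ultra-long noisy reads are
aligned to the graph and the candidate consistent with the most spanning
read paths wins, provided it leads the runner-up by a configurable margin;
otherwise the tangle stays ambiguous.  The consensus of a resolved walk is
computed back in *uncompressed* space: every compressed backbone position
takes the modal homopolymer run length among the accurate reads placed
there (ties break toward the smaller run).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .seqmodel import HPCSequence, Read, Sequence, hpc_compress, revcomp
from .string_graph import StringGraph

ENTRY = {"+": "t", "-": "h"}
EXIT = {"+": "h", "-": "t"}


@dataclass
class Walk:
    id: str
    steps: list[tuple[str, str]]  # (node id, orientation)
    status: str = "ambiguous"  # resolved | ambiguous | gap-flagged
    support: int = 0
    note: str = ""


@dataclass
class Candidate:
    """One complete covering of a component: a set of maximal walks that
    together traverse every node exactly its multiplicity's worth of
    times.  A simple chromosome yields a single walk; a tangle shared by
    two chromosomes (the X pattern) yields two walks per candidate and
    several candidates."""

    walks: list[list[tuple[str, str]]]
    status: str = "ambiguous"
    support: int = 0
    note: str = ""


@dataclass
class GraphAlignment:
    read_id: str
    path: list[tuple[str, str]]
    anchors_per_node: list[int]
    span: int  # compressed bases anchored


def _canonical(steps) -> tuple:
    fwd = tuple(steps)
    rev = tuple((n, "-" if o == "+" else "+") for n, o in reversed(steps))
    return min(fwd, rev)


def _walk_edge(g: StringGraph, s1, s2) -> Optional[int]:
    """Overlap length of the edge joining consecutive steps, or None."""
    n1, o1 = s1
    n2, o2 = s2
    best = None
    for _, other, oe, ovl in g.neighbors(n1, EXIT[o1]):
        if other == n2 and oe == ENTRY[o2]:
            best = ovl if best is None else max(best, ovl)
    return best


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

def enumerate_candidates(g: StringGraph, component: Optional[set] = None,
                         max_candidates: int = 10_000,
                         max_steps: int = 2_000_000
                         ) -> tuple[list[Candidate], str]:
    """All coverings of a component by walks respecting multiplicities.

    Each candidate traverses every multiplicity-``m`` node exactly ``m``
    times and skips multiplicity-0 nodes; a new walk is started only when
    the current one cannot be extended (walks are maximal).  Returns
    ``(candidates, status)``; status is ``resolved`` when exactly one
    candidate exists and carries a diagnostic when enumeration was
    truncated.
    """
    nodes = component if component is not None else set(g.nodes)
    mult = {n: g.nodes[n].multiplicity for n in nodes}
    active = {n for n in nodes if mult.get(n, 0) >= 1}
    if not active:
        return [], "ambiguous"
    total = sum(mult[n] for n in active)

    def exits(n, o, remaining):
        out = set()
        for _, other, oe, _ in g.neighbors(n, EXIT[o]):
            if other in active and remaining.get(other, 0) > 0:
                out.add((other, "+" if oe == "t" else "-"))
        return sorted(out)

    def walk_starts(remaining):
        """Terminus starts among unconsumed nodes (fallback: any node)."""
        starts = []
        for n in sorted(k for k, v in remaining.items() if v > 0):
            for o in "+-":
                entry_deg = sum(
                    1 for _, other, _, _ in g.neighbors(n, ENTRY[o])
                    if other in active and remaining.get(other, 0) > 0)
                if entry_deg == 0:
                    starts.append((n, o))
        if not starts:  # cyclic remainder: any remaining node may lead
            starts = [(n, o) for n in sorted(remaining)
                      if remaining[n] > 0 for o in "+-"]
        return starts

    found: set[frozenset] = set()
    state = {"steps": 0, "truncated": False}

    def dfs(cur, done, remaining, visited):
        state["steps"] += 1
        if state["steps"] > max_steps or len(found) >= max_candidates:
            state["truncated"] = True
            return
        if visited == total:
            cover = Counter(_canonical(w) for w in done + [cur] if w)
            found.add(frozenset(cover.items()))
            return
        if cur:
            n, o = cur[-1]
            nxt = exits(n, o, remaining)
            if nxt:
                for other, oo in nxt:
                    remaining[other] -= 1
                    cur.append((other, oo))
                    dfs(cur, done, remaining, visited + 1)
                    cur.pop()
                    remaining[other] += 1
                    if state["truncated"]:
                        return
                return
        # current walk is stuck (or no walk open): start a new one
        done2 = done + [list(cur)] if cur else done
        for n, o in walk_starts(remaining):
            remaining[n] -= 1
            dfs([(n, o)], done2, remaining, visited + 1)
            remaining[n] += 1
            if state["truncated"]:
                return

    dfs([], [], dict(mult), 0)

    cands = []
    for cover in sorted(found, key=lambda c: sorted(c)):
        walks = []
        for steps, cnt in sorted(cover):
            walks.extend([list(steps)] * cnt)
        cands.append(Candidate(walks))
    if cands:
        # parsimony: a covering with fewer walks explains the same nodes
        # with fewer chromosomes; drop fragmentations of complete walks
        min_w = min(len(c.walks) for c in cands)
        cands = [c for c in cands if len(c.walks) == min_w]
    if state["truncated"]:
        return cands, ("ambiguous: enumeration truncated at "
                       f"{max_candidates} candidates / {max_steps} steps")
    if len(cands) == 1:
        cands[0].status = "resolved"
        return cands, "resolved"
    return cands, "ambiguous"


# ---------------------------------------------------------------------------
# ONT-to-graph alignment
# ---------------------------------------------------------------------------

def _canon(km: str) -> tuple[str, str]:
    rc = revcomp(km)
    return (km, "+") if km <= rc else (rc, "-")


def unique_node_kmers(g: StringGraph, k: int) -> dict[str, tuple]:
    """Canonical k-mers occurring exactly once across all node sequences."""
    counts: Counter = Counter()
    where = {}
    for nid, node in g.nodes.items():
        s = node.seq
        for p in range(len(s) - k + 1):
            km, o = _canon(s[p:p + k])
            counts[km] += 1
            where[km] = (nid, p, o)
    return {km: where[km] for km, c in counts.items() if c == 1}


def align_ont_to_graph(ont_reads: Iterable, g: StringGraph,
                       anchor_k: int = 21, min_anchors: int = 3,
                       min_node_anchors: int = 2) -> list[GraphAlignment]:
    """Anchor-and-chain alignment of noisy long reads to the graph.

    Reads are homopolymer-compressed, seeded with graph-unique k-mers, and
    the anchor sequence is collapsed into an oriented node path that must
    respect graph adjacency.  Reads without a confident path are omitted.
    """
    index = unique_node_kmers(g, anchor_k)
    out = []
    for read in ont_reads:
        if isinstance(read, Read):
            h = hpc_compress(read.sequence)
            rid = read.id
        elif isinstance(read, HPCSequence):
            h, rid = read, read.origin_id
        else:
            h, rid = hpc_compress(read), read.id
        s = h.bases
        anchors = []  # (read_pos, node, node_pos, rel_orient)
        for p in range(len(s) - anchor_k + 1):
            km, ro = _canon(s[p:p + anchor_k])
            hit = index.get(km)
            if hit is None:
                continue
            nid, npos, no = hit
            rel = "+" if ro == no else "-"
            anchors.append((p, nid, npos, rel))
        if len(anchors) < min_anchors:
            continue
        # collapse runs of anchors on the same oriented node, requiring a
        # consistent positional trend inside each run
        segs = []  # [node, orient, n_anchors, first_np, last_np]
        for p, nid, npos, rel in anchors:
            if segs and segs[-1][0] == nid and segs[-1][1] == rel:
                seg = segs[-1]
                trend_ok = (npos >= seg[4]) if rel == "+" else (npos <= seg[4])
                if trend_ok:
                    seg[2] += 1
                    seg[4] = npos
                continue
            segs.append([nid, rel, 1, npos, npos])
        # merge re-entries into the same node (split by stray anchors)
        segs = [seg for seg in segs if seg[2] >= min_node_anchors] or segs
        merged = []
        for seg in segs:
            if merged and merged[-1][0] == seg[0] and merged[-1][1] == seg[1]:
                merged[-1][2] += seg[2]
                merged[-1][4] = seg[4]
            else:
                merged.append(seg)
        segs = merged
        # enforce graph adjacency, dropping weakly supported offenders
        def consistent(path):
            return all(_walk_edge(g, path[i], path[i + 1]) is not None
                       for i in range(len(path) - 1))

        path = [(seg[0], seg[1]) for seg in segs]
        weights = [seg[2] for seg in segs]
        while path and not consistent(path):
            # drop the weakest segment involved in a broken junction
            bad = None
            for i in range(len(path) - 1):
                if _walk_edge(g, path[i], path[i + 1]) is None:
                    bad = i if weights[i] <= weights[i + 1] else i + 1
                    break
            if bad is None:
                break
            path.pop(bad)
            weights.pop(bad)
            # re-merge equal neighbours created by the deletion
            i = 1
            while i < len(path):
                if path[i] == path[i - 1]:
                    weights[i - 1] += weights.pop(i)
                    path.pop(i)
                else:
                    i += 1
        if not path or sum(weights) < min_anchors:
            continue
        out.append(GraphAlignment(rid, path, weights, sum(weights)))
    return out


# ---------------------------------------------------------------------------
# Walk selection
# ---------------------------------------------------------------------------

def _is_subpath(p: list, walk: list) -> bool:
    n, m = len(p), len(walk)
    if n > m:
        return False
    rev = [(nid, "-" if o == "+" else "+") for nid, o in reversed(p)]
    for i in range(m - n + 1):
        if walk[i:i + n] == p or walk[i:i + n] == rev:
            return True
    return False


def select_walk(candidates: list[Candidate],
                graph_alignments: Iterable[GraphAlignment],
                min_margin: float = 2.0,
                min_path_len: int = 3) -> Optional[Candidate]:
    """Arbitrate among candidate coverings with read-to-graph paths.

    A read supports a candidate when its aligned node path (length >=
    ``min_path_len``, so at least one interior node is traversed in full)
    is a contiguous subpath of one of the candidate's walks in either
    orientation.  The winner must lead the runner-up by ``min_margin``;
    otherwise the returned candidate is flagged ambiguous.  A single
    candidate is resolved outright.
    """
    if not candidates:
        return None
    if len(candidates) == 1:
        c = candidates[0]
        c.status = "resolved"
        return c
    paths = [a.path for a in graph_alignments if len(a.path) >= min_path_len]
    scores = []
    for cand in candidates:
        scores.append(sum(1 for p in paths
                          if any(_is_subpath(p, w) for w in cand.walks)))
    order = np.argsort(scores)[::-1]
    best, runner = int(order[0]), int(order[1])
    c = candidates[best]
    c.support = scores[best]
    if scores[best] >= max(1.0, min_margin * scores[runner]):
        c.status = "resolved"
    else:
        c.status = "ambiguous"
        c.note = (f"support {scores[best]} vs runner-up {scores[runner]} "
                  f"below margin {min_margin}")
    return c


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    sequence: Sequence
    low_coverage: list[tuple[int, int]] = field(default_factory=list)
    # intervals are in uncompressed output coordinates


def walk_backbone(walk: Walk, g: StringGraph) -> tuple[str, list[int]]:
    """Compressed backbone sequence of a walk plus per-step node offsets."""
    steps = walk.steps
    if not steps:
        return "", []
    n0, o0 = steps[0]
    seq = [g.nodes[n0].oriented_seq(o0)]
    offsets = [0]
    pos = len(seq[0])
    for i in range(1, len(steps)):
        ovl = _walk_edge(g, steps[i - 1], steps[i])
        if ovl is None:
            raise ValueError(f"walk {walk.id}: steps {i-1},{i} not adjacent")
        nid, o = steps[i]
        s = g.nodes[nid].oriented_seq(o)
        offsets.append(pos - ovl)
        seq.append(s[ovl:])
        pos += len(s) - ovl
    return "".join(seq), offsets


def consensus(walk: Walk, g: StringGraph, reads: Iterable[HPCSequence],
              max_run: int = 63) -> ConsensusResult:
    """Uncompressed consensus of a walk from accurate-read run lengths.

    Each compressed backbone position takes the modal run length over the
    reads placed there (ties toward the smaller value); positions with no
    read support get run length 1 and are reported as low-coverage.
    """
    runs_by_id = {}
    for r in reads:
        runs_by_id[r.origin_id] = r.run_lengths
    backbone, offsets = walk_backbone(walk, g)
    L = len(backbone)
    counts = np.zeros((L, max_run + 1), dtype=np.int32)
    for (nid, o), off in zip(walk.steps, offsets):
        node = g.nodes[nid]
        ln = len(node)
        for pl in node.placements:
            runs = runs_by_id.get(pl.read_id)
            if runs is None or len(runs) != pl.end - pl.start:
                continue
            npos = np.arange(pl.start, pl.end)
            r = runs if pl.orient == "+" else runs[::-1]
            if o == "-":
                npos = ln - 1 - npos
            bpos = off + npos
            np.add.at(counts, (bpos, np.minimum(r, max_run)), 1)
    chosen = counts.argmax(axis=1)  # ties -> smaller run length
    cov = counts.sum(axis=1)
    chosen[cov == 0] = 1
    chosen = np.maximum(chosen, 1)
    # uncompressed coordinates of each compressed position
    starts = np.zeros(L + 1, dtype=np.int64)
    np.cumsum(chosen, out=starts[1:])
    lows = []
    zero = np.flatnonzero(cov == 0)
    if len(zero):
        brk = np.flatnonzero(np.diff(zero) > 1)
        seg_starts = np.concatenate(([0], brk + 1))
        seg_ends = np.concatenate((brk, [len(zero) - 1]))
        for s, e in zip(seg_starts, seg_ends):
            lows.append((int(starts[zero[s]]), int(starts[zero[e] + 1])))
    out = "".join(b * int(n) for b, n in zip(backbone, chosen))
    return ConsensusResult(Sequence(walk.id, out), lows)


def write_walks_tsv(walks: Iterable[Walk], path) -> None:
    """GAF-like TSV: walk id, status, support, oriented node list."""
    with open(path, "w") as fh:
        for w in walks:
            steps = ",".join(f"{n}{o}" for n, o in w.steps)
            fh.write(f"{w.id}\t{w.status}\t{w.support}\t{steps}\n")


def write_low_coverage_bed(issues, walk_id: str, path) -> None:
    with open(path, "w") as fh:
        for s, e in issues:
            fh.write(f"{walk_id}\t{s}\t{e}\tlow_coverage\n")
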