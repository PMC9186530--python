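"""Bidirected string graph: construction, simplification, annotation, GFA.

Nodes are unambiguously assembled compressed sequences (unitigs); edges are
exact overlaps between node ends.  A node has a ``tail`` ('t', the start of
its forward sequence) and a ``head`` ('h', the end).  Traversing a node
tail-to-head reads its forward sequence; head-to-tail reads the reverse
complement.  An edge joins one end of each node; leaving node ``a`` via end
``ea`` enters node ``b`` via ``eb``, and ``b`` is then read in orientation
``+`` when entered at its tail, ``-`` at its head.

Construction keeps only exact dovetail overlaps (containments are folded in
for depth only), applies transitive reduction, and merges maximal
unambiguous paths into unitigs.  Simplification iterates transitive
reduction, tip clipping and small-bubble popping to convergence.  Node
multiplicity (copies in the genome) is estimated from read depth relative
to the single-copy base depth.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .overlap_correct import Overlap
from .seqmodel import HPCSequence, revcomp

OPP = {"h": "t", "t": "h"}


@dataclass
class ReadPlacement:
    """A read laid out on a node: [start, end) in node-forward coordinates."""

    read_id: str
    start: int
    end: int
    orient: str  # read strand relative to node-forward


@dataclass
class SGNode:
    id: str
    seq: str
    placements: list[ReadPlacement] = field(default_factory=list)
    depth: float = 0.0
    multiplicity: int = -1  # -1 = not yet estimated

    def __len__(self) -> int:
        return len(self.seq)

    def oriented_seq(self, orient: str) -> str:
        return self.seq if orient == "+" else revcomp(self.seq)


def _edge_key(a, ea, b, eb, ovl):
    if (a, ea) <= (b, eb):
        return (a, ea, b, eb, ovl)
    return (b, eb, a, ea, ovl)


class StringGraph:
    """Bidirected overlap graph over :class:`SGNode` objects."""

    def __init__(self) -> None:
        self.nodes: dict[str, SGNode] = {}
        self.edges: set[tuple] = set()
        self.adj: dict[tuple, set] = defaultdict(set)  # (node,end) -> edge keys
        self._auto = itertools.count()

    # -- mutation ----------------------------------------------------------
    def add_node(self, node: SGNode) -> SGNode:
        self.nodes[node.id] = node
        return node

    def new_node_id(self) -> str:
        return f"utg{next(self._auto):06d}"

    def add_edge(self, a: str, ea: str, b: str, eb: str, ovl: int) -> None:
        if a not in self.nodes or b not in self.nodes:
            raise KeyError(f"edge references unknown node {a!r} or {b!r}")
        key = _edge_key(a, ea, b, eb, ovl)
        if key in self.edges:
            return
        self.edges.add(key)
        self.adj[(a, ea)].add(key)
        self.adj[(b, eb)].add(key)

    def remove_edge(self, key: tuple) -> None:
        a, ea, b, eb, ovl = key
        self.edges.discard(key)
        self.adj[(a, ea)].discard(key)
        self.adj[(b, eb)].discard(key)

    def remove_node(self, nid: str) -> None:
        for end in "ht":
            for key in list(self.adj.get((nid, end), ())):
                self.remove_edge(key)
            self.adj.pop((nid, end), None)
        self.nodes.pop(nid, None)

    # -- queries -----------------------------------------------------------
    def degree(self, nid: str, end: str) -> int:
        return len(self.adj.get((nid, end), ()))

    def neighbors(self, nid: str, end: str):
        """Yield (edge_key, other_node, other_end, ovl) leaving (nid, end)."""
        for key in list(self.adj.get((nid, end), ())):
            a, ea, b, eb, ovl = key
            if (a, ea) == (nid, end):
                yield key, b, eb, ovl
            if (b, eb) == (nid, end) and (a, ea) != (b, eb):
                yield key, a, ea, ovl

    def components(self) -> list[set]:
        seen = set()
        comps = []
        for nid in self.nodes:
            if nid in seen:
                continue
            comp = {nid}
            stack = [nid]
            while stack:
                cur = stack.pop()
                for end in "ht":
                    for _, other, _, _ in self.neighbors(cur, end):
                        if other not in comp:
                            comp.add(other)
                            stack.append(other)
            seen |= comp
            comps.append(comp)
        return comps

    def total_assembled(self) -> int:
        """Sum of multiplicity-weighted node lengths (compressed bases)."""
        return sum(max(n.multiplicity, 0) * len(n) for n in self.nodes.values())


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def _dovetail_ends(ovl: Overlap):
    """Edge endpoints for a dovetail overlap record."""
    if ovl.kind == "ab":  # suffix of a <-> prefix of oriented b
        ea = "h"
        eb = "t" if ovl.b_orient == "+" else "h"
    else:  # 'ba': prefix of a <-> suffix of oriented b
        ea = "t"
        eb = "h" if ovl.b_orient == "+" else "t"
    return ea, eb


def build_graph(corrected_reads: list[HPCSequence], overlaps: list[Overlap],
                min_overlap: int = 1) -> StringGraph:
    """Build the unitig string graph from exact overlaps.

    Contained reads contribute no nodes or edges but are placed onto their
    container's unitig so that depth reflects them.  Transitive edges are
    reduced and maximal unambiguous paths merged before returning.
    """
    by_id = {r.origin_id: r for r in reads_list(corrected_reads)}
    for ov in overlaps:
        if ov.a_id not in by_id or ov.b_id not in by_id:
            raise KeyError(f"overlap references unknown read "
                           f"{ov.a_id!r}/{ov.b_id!r}")
    contained: dict[str, Overlap] = {}
    for ov in overlaps:
        if not ov.contained:
            continue
        if ov.kind == "contained_a" and ov.a_id not in contained:
            contained[ov.a_id] = ov
        elif ov.kind == "contained_b" and ov.b_id not in contained:
            contained[ov.b_id] = ov.flip()

    g = StringGraph()
    for rid, r in by_id.items():
        if rid in contained:
            continue
        g.add_node(SGNode(rid, r.bases,
                          [ReadPlacement(rid, 0, len(r.bases), "+")]))
    # tandem repeats admit several unit-shifted exact overlaps for the same
    # pair; only the longest per (pair, orientation, direction) is genuine
    best: dict[tuple, Overlap] = {}
    for ov in overlaps:
        if ov.contained or ov.a_id in contained or ov.b_id in contained:
            continue
        if ov.length < min_overlap:
            continue
        key = (ov.a_id, ov.b_id, ov.b_orient, ov.kind)
        if key not in best or ov.length > best[key].length:
            best[key] = ov
    for ov in best.values():
        ea, eb = _dovetail_ends(ov)
        g.add_edge(ov.a_id, ea, ov.b_id, eb, ov.length)

    transitive_reduction(g)
    merge_unambiguous(g)
    _place_contained(g, contained)
    compute_depth(g)
    return g


def reads_list(reads) -> list[HPCSequence]:
    return list(reads)


def _place_contained(g: StringGraph, contained: dict[str, Overlap]) -> None:
    """Map contained reads onto container placements (chains allowed)."""
    # read -> (node, start, end, orient) for reads already placed
    placed: dict[str, tuple] = {}
    for node in g.nodes.values():
        for pl in node.placements:
            placed[pl.read_id] = (node.id, pl.start, pl.end, pl.orient)

    def resolve(rid: str, guard: set) -> Optional[tuple]:
        if rid in placed:
            return placed[rid]
        if rid not in contained or rid in guard:
            return None
        guard.add(rid)
        ov = contained[rid]  # rid == ov.a_id contained in ov.b_id
        host = resolve(ov.b_id, guard)
        if host is None:
            return None
        # coordinates of rid within forward frame of its host read
        if ov.b_orient == "+":
            s, e, o = ov.b_start, ov.b_end, "+"
        else:
            s, e, o = ov.b_len - ov.b_end, ov.b_len - ov.b_start, "-"
        nid, hs, he, ho = host
        if ho == "+":
            ns, ne = hs + s, hs + e
        else:
            ns, ne = he - e, he - s
        no = o if ho == "+" else ("-" if o == "+" else "+")
        placed[rid] = (nid, ns, ne, no)
        return placed[rid]

    for rid in contained:
        res = resolve(rid, set())
        if res is not None:
            nid, s, e, o = res
            if nid in g.nodes:
                g.nodes[nid].placements.append(ReadPlacement(rid, s, e, o))


def compute_depth(g: StringGraph) -> None:
    for node in g.nodes.values():
        total = sum(min(pl.end, len(node)) - max(pl.start, 0)
                    for pl in node.placements)
        node.depth = total / max(len(node), 1)


# ---------------------------------------------------------------------------
# Transitive reduction (Myers-style, bidirected)
# ---------------------------------------------------------------------------

def transitive_reduction(g: StringGraph, fuzz: int = 12) -> int:
    """Remove edges implied by two-edge paths with consistent lengths."""
    doomed = set()
    for nid in list(g.nodes):
        for end in "ht":
            outs = [(key, w, ew, ovl) for key, w, ew, ovl
                    in g.neighbors(nid, end) if w != nid]
            if len(outs) < 2:
                continue
            # extension length of each out-edge
            ext = {key: len(g.nodes[w]) - ovl for key, w, ew, ovl in outs}
            inplay = {}
            for key, w, ew, ovl in outs:
                inplay.setdefault((w, ew), []).append(key)
            outs.sort(key=lambda t: ext[t[0]])
            for key, w, ew, ovl in outs:
                if key in doomed:
                    continue
                base_ext = ext[key]
                for key2, x, ex, ovl2 in g.neighbors(w, OPP[ew]):
                    if x == w or x == nid:
                        continue
                    implied = base_ext + (len(g.nodes[x]) - ovl2)
                    for cand in inplay.get((x, ex), ()):
                        if cand in doomed or cand == key:
                            continue
                        if abs(ext[cand] - implied) <= fuzz:
                            doomed.add(cand)
    for key in doomed:
        g.remove_edge(key)
    return len(doomed)


# ---------------------------------------------------------------------------
# Unitig merging
# ---------------------------------------------------------------------------

def _merge_pair(g: StringGraph, key) -> Optional[str]:
    a, ea, b, eb, ovl = key
    if a == b:
        return None
    na, nb = g.nodes[a], g.nodes[b]
    oa = "+" if ea == "h" else "-"  # a is exited via ea
    ob = "+" if eb == "t" else "-"  # b is entered via eb
    seq = na.oriented_seq(oa) + nb.oriented_seq(ob)[ovl:]
    new = SGNode(g.new_node_id(), seq)
    la, lb = len(na), len(nb)
    off_b = la - ovl

    def transform(placements, orient, length, offset):
        out = []
        for pl in placements:
            if orient == "+":
                s, e, o = pl.start, pl.end, pl.orient
            else:
                s, e = length - pl.end, length - pl.start
                o = "-" if pl.orient == "+" else "+"
            out.append(ReadPlacement(pl.read_id, s + offset, e + offset, o))
        return out

    new.placements = (transform(na.placements, oa, la, 0)
                      + transform(nb.placements, ob, lb, off_b))
    # edges to reattach: entry end of a -> new tail; exit end of b -> new head
    reattach = []
    for k2, other, oe, o2 in g.neighbors(a, OPP[ea]):
        if other == b and k2 == key:
            continue
        reattach.append(("t", other, oe, o2, k2))
    for k2, other, oe, o2 in g.neighbors(b, OPP[eb]):
        if other == a and k2 == key:
            continue
        reattach.append(("h", other, oe, o2, k2))
    g.remove_node(a)
    g.remove_node(b)
    g.add_node(new)
    for new_end, other, oe, o2, _ in reattach:
        if other in (a, b):  # edge back into the merged pair (loop)
            other_end = "t" if other == a else "h"
            g.add_edge(new.id, new_end, new.id, other_end, o2)
        else:
            g.add_edge(new.id, new_end, other, oe, o2)
    return new.id


def merge_unambiguous(g: StringGraph) -> int:
    """Merge every edge whose two endpoints both have degree one."""
    merged = 0
    progress = True
    while progress:
        progress = False
        for key in list(g.edges):
            a, ea, b, eb, ovl = key
            if key not in g.edges:
                continue
            if a == b:
                continue
            if g.degree(a, ea) == 1 and g.degree(b, eb) == 1:
                if _merge_pair(g, key) is not None:
                    merged += 1
                    progress = True
    if merged:
        compute_depth(g)
    return merged


# ---------------------------------------------------------------------------
# Simplification
# ---------------------------------------------------------------------------

def _median_depth(g: StringGraph) -> float:
    if not g.nodes:
        return 0.0
    ds = [(len(n), n.depth) for n in g.nodes.values()]
    lens = np.array([d[0] for d in ds], dtype=float)
    deps = np.array([d[1] for d in ds])
    order = np.argsort(deps)
    cum = np.cumsum(lens[order])
    i = int(np.searchsorted(cum, cum[-1] / 2.0))
    return float(deps[order[min(i, len(order) - 1)]])


def clip_tips(g: StringGraph, tip_len: int = 1000,
              depth_ratio: float = 1.0) -> int:
    """Remove short dead-end spurs that branch off a continuing path.

    A tip is a node with one dead end, shorter than ``tip_len``, whose
    attachment vertex has an alternative edge (so clipping cannot break a
    genuine chain end), and whose depth does not exceed ``depth_ratio``
    times the deepest alternative branch.
    """
    removed = 0
    for nid in list(g.nodes):
        if nid not in g.nodes:
            continue
        node = g.nodes[nid]
        dh, dt = g.degree(nid, "h"), g.degree(nid, "t")
        if min(dh, dt) != 0 or max(dh, dt) < 1 or len(node) >= tip_len:
            continue
        live_end = "h" if dh else "t"
        # all attachments must offer an alternative continuation
        clippable = True
        alt_depth = 0.0
        for _, w, ew, _ in g.neighbors(nid, live_end):
            alts = [g.nodes[o].depth for _, o, _, _ in g.neighbors(w, ew)
                    if o != nid]
            if not alts:
                clippable = False
                break
            alt_depth = max(alt_depth, max(alts))
        if clippable and node.depth <= depth_ratio * max(alt_depth, 1e-9):
            g.remove_node(nid)
            removed += 1
    return removed


def pop_bubbles(g: StringGraph, bubble_len: int = 500) -> int:
    """Pop pairs of short parallel single-node paths between shared ends.

    The deeper branch is retained; the shallower one removed.
    """
    groups: dict[frozenset, list[str]] = defaultdict(list)
    for nid, node in g.nodes.items():
        if g.degree(nid, "t") == 1 and g.degree(nid, "h") == 1:
            (kt,) = g.adj[(nid, "t")]
            (kh,) = g.adj[(nid, "h")]
            if kt == kh:
                continue
            ends = []
            for key, end in ((kt, "t"), (kh, "h")):
                a, ea, b, eb, _ = key
                ends.append((b, eb) if (a, ea) == (nid, end) else (a, ea))
            if any(e[0] == nid for e in ends):
                continue
            groups[frozenset(ends)].append(nid)
    removed = 0
    for ends, members in groups.items():
        members = [m for m in members if m in g.nodes]
        if len(members) < 2:
            continue
        keep = max(members, key=lambda m: (g.nodes[m].depth, m))
        for m in members:
            if m != keep and len(g.nodes[m]) <= bubble_len:
                g.remove_node(m)
                removed += 1
    return removed


def simplify(g: StringGraph, tip_len: int = 1000, bubble_len: int = 500,
             iterations: int = 10, tip_depth_ratio: float = 0.25
             ) -> StringGraph:
    """Iterate transitive reduction, tip clipping and bubble popping.

    Converges (no further change) in at most ``iterations`` rounds; each
    round re-merges newly unambiguous paths so unitigs stay maximal.
    """
    for _ in range(iterations):
        changed = transitive_reduction(g)
        changed += clip_tips(g, tip_len, tip_depth_ratio)
        changed += pop_bubbles(g, bubble_len)
        changed += merge_unambiguous(g)
        if not changed:
            break
    compute_depth(g)
    return g


# ---------------------------------------------------------------------------
# Multiplicity
# ---------------------------------------------------------------------------

def estimate_multiplicity(g: StringGraph, base_depth: Optional[float] = None,
                          noise_frac: float = 0.2) -> float:
    """Set node multiplicities from depth relative to the base depth.

    ``base_depth`` defaults to the median depth of long nodes (length above
    the 90th percentile), which is robust to repeat-induced depth inflation.
    Nodes below ``noise_frac * base_depth`` get multiplicity 0 (candidate
    artifacts); all others ``round(depth / base_depth)`` floored at 1.
    """
    if base_depth is None:
        lens = np.array([len(n) for n in g.nodes.values()])
        if len(lens) == 0:
            return 0.0
        cut = np.percentile(lens, 90)
        long_nodes = [n for n in g.nodes.values() if len(n) >= cut]
        base_depth = float(np.median([n.depth for n in long_nodes]))
    if base_depth <= 0:
        raise ValueError("base_depth must be positive")
    for node in g.nodes.values():
        if node.depth < noise_frac * base_depth:
            node.multiplicity = 0
        else:
            node.multiplicity = max(1, int(np.floor(node.depth / base_depth + 0.5)))
    return base_depth


# ---------------------------------------------------------------------------
# GFA1 serialisation
# ---------------------------------------------------------------------------

def _end_to_orients(a, ea, b, eb):
    return ("+" if ea == "h" else "-"), ("+" if eb == "t" else "-")


def export_gfa(g: StringGraph, path) -> None:
    """Write GFA1: S lines carry depth (dp:f) and multiplicity (ml:i) tags."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for nid in sorted(g.nodes):
            n = g.nodes[nid]
            fh.write(f"S\t{nid}\t{n.seq}\tdp:f:{n.depth:.4f}"
                     f"\tml:i:{n.multiplicity}\n")
        for key in sorted(g.edges):
            a, ea, b, eb, ovl = key
            oa, ob = _end_to_orients(a, ea, b, eb)
            fh.write(f"L\t{a}\t{oa}\t{b}\t{ob}\t{ovl}M\n")


def import_gfa(path) -> StringGraph:
    """Read a GFA1 file written by :func:`export_gfa` (topology + tags).

    Read placements are not serialised; depth/multiplicity travel as tags.
    """
    g = StringGraph()
    links = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line[0] in "H#":
                continue
            fields = line.split("\t")
            if fields[0] == "S":
                if len(fields) < 3:
                    raise ValueError(f"GFA parse error at line {ln}: bad S line")
                node = SGNode(fields[1], fields[2])
                for tag in fields[3:]:
                    if tag.startswith("dp:f:"):
                        node.depth = float(tag[5:])
                    elif tag.startswith("ml:i:"):
                        node.multiplicity = int(tag[5:])
                g.add_node(node)
            elif fields[0] == "L":
                if len(fields) < 6 or not fields[5].endswith("M"):
                    raise ValueError(f"GFA parse error at line {ln}: bad L line")
                links.append((fields[1], fields[2], fields[3], fields[4],
                              int(fields[5][:-1])))
    for a, oa, b, ob, ovl in links:
        ea = "h" if oa == "+" else "t"
        eb = "t" if ob == "+" else "h"
        g.add_edge(a, ea, b, eb, ovl)
    return g


def export_node_table(g: StringGraph, path) -> None:
    """TSV node table: id, length, depth, multiplicity, read support."""
    with open(path, "w") as fh:
        fh.write("node\tlength\tdepth\tmultiplicity\tn_reads\n")
        for nid in sorted(g.nodes):
            n = g.nodes[nid]
            fh.write(f"{nid}\t{len(n)}\t{n.depth:.4f}\t{n.multiplicity}"
                     f"\t{len(n.placements)}\n")
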