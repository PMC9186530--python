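"""Walk enumeration, read-to-graph alignment, selection, consensus."""

import itertools

import edlib
import numpy as np
import pytest

from hapasm import simulate as sim
from hapasm import string_graph as sg
from hapasm import walk_resolve as wr
from hapasm.pipeline import assemble
from hapasm.protocols import build_xtangle, xtangle_trial
from hapasm.seqmodel import (HPCSequence, Read, Sequence, hpc_compress,
                             revcomp)

from conftest import random_bases

ENTRY = wr.ENTRY
EXIT = wr.EXIT


def graph_of(nodes, edges, mult=None):
    g = sg.StringGraph()
    rng = np.random.default_rng(1)
    for nid, length in nodes:
        n = sg.SGNode(nid, random_bases(rng, length))
        n.multiplicity = (mult or {}).get(nid, 1)
        g.add_node(n)
    for e in edges:
        g.add_edge(*e)
    return g


class TestEnumerate:
    def test_linear_chain_single_candidate(self):
        g = graph_of([("a", 100), ("b", 100), ("c", 100)],
                     [("a", "h", "b", "t", 10), ("b", "h", "c", "t", 10)])
        cands, status = wr.enumerate_candidates(g)
        assert status == "resolved" and len(cands) == 1
        assert wr._canonical(cands[0].walks[0]) == \
            wr._canonical([("a", "+"), ("b", "+"), ("c", "+")])

    def test_xtangle_two_pairings(self):
        _, _, g, _ = build_xtangle(0)
        cands, status = wr.enumerate_candidates(g)
        assert status == "ambiguous" and len(cands) == 2
        assert all(len(c.walks) == 2 for c in cands)

    def test_loop_traversed_twice(self):
        """Backbone with a loop node at multiplicity 2: the unique walk
        passes through the loop twice."""
        g = graph_of([("a", 100), ("L", 100), ("b", 100)],
                     [("a", "h", "L", "t", 10), ("L", "h", "L", "t", 10),
                      ("L", "h", "b", "t", 10)], mult={"L": 2})
        cands, status = wr.enumerate_candidates(g)
        assert status == "resolved"
        steps = cands[0].walks[0]
        assert [s[0] for s in steps] == ["a", "L", "L", "b"] or \
            [s[0] for s in steps] == ["b", "L", "L", "a"]

    def test_multiplicity_zero_nodes_skipped(self):
        g = graph_of([("a", 100), ("b", 100), ("x", 100)],
                     [("a", "h", "b", "t", 10), ("a", "h", "x", "t", 10)],
                     mult={"x": 0})
        cands, status = wr.enumerate_candidates(g)
        assert status == "resolved"
        assert all("x" not in [s[0] for s in w]
                   for c in cands for w in c.walks)


def covering_bruteforce(g):
    """Independent exhaustive covering enumeration over raw edge tuples.

    Same contract as the implementation: walks are maximal, a new walk
    starts at a terminus of the remaining subgraph (fallback: any node),
    and only minimum-walk-count coverings are reported.
    """
    mult = {n: g.nodes[n].multiplicity for n in g.nodes}
    active = [n for n, m in mult.items() if m >= 1]
    total = sum(mult[n] for n in active)
    adj = set()
    for a, ea, b, eb, _ in g.edges:
        adj.add((a, ea, b, eb))
        adj.add((b, eb, a, ea))

    def can_follow(s1, s2):
        (n1, o1), (n2, o2) = s1, s2
        return (n1, EXIT[o1], n2, ENTRY[o2]) in adj

    def start_steps(remaining):
        starts = []
        # terminus: no edge enters (n, ENTRY[o]) from a remaining node
        for n in active:
            if remaining[n] <= 0:
                continue
            for o in "+-":
                incoming = [(a, ea, b, eb) for (a, ea, b, eb) in adj
                            if (a, ea) == (n, ENTRY[o])
                            and remaining.get(b, 0) > 0]
                if not incoming:
                    starts.append((n, o))
        if not starts:
            starts = [(n, o) for n in active if remaining[n] > 0
                      for o in "+-"]
        return starts

    results = set()
    steps_pool = [(n, o) for n in active for o in "+-"]

    def rec(walks, cur, remaining, visited):
        if visited == total:
            done = [w for w in walks + [cur] if w]
            results.add(frozenset(
                (wr._canonical(w), sum(1 for x in done
                                       if wr._canonical(x) == wr._canonical(w)))
                for w in done))
            return
        extendable = [s for s in steps_pool
                      if remaining[s[0]] > 0 and cur
                      and can_follow(cur[-1], s)]
        if cur and extendable:
            for step in extendable:
                remaining[step[0]] -= 1
                rec(walks, cur + [step], remaining, visited + 1)
                remaining[step[0]] += 1
            return
        # current walk (if any) is maximal: open a new one at a terminus
        nxt_walks = walks + [cur] if cur else walks
        for step in start_steps(remaining):
            remaining[step[0]] -= 1
            rec(nxt_walks, [step], remaining, visited + 1)
            remaining[step[0]] += 1

    rec([], [], dict(mult), 0)
    if results:  # same parsimony rule as the implementation
        min_w = min(sum(c for _, c in cover) for cover in results)
        results = {cover for cover in results
                   if sum(c for _, c in cover) == min_w}
    return results


class TestEnumerationOracle:
    def test_agrees_with_bruteforce_on_random_graphs(self, rng):
        """Covering enumeration matches an independent exhaustive search on
        random bidirected graphs with up to 8 nodes."""
        for trial in range(40):
            n_nodes = int(rng.integers(2, 9))
            nodes = [(f"n{i}", 50) for i in range(n_nodes)]
            mult = {f"n{i}": int(rng.integers(1, 3)) for i in range(n_nodes)}
            n_edges = int(rng.integers(1, n_nodes + 3))
            edges = []
            for _ in range(n_edges):
                a, b = rng.integers(0, n_nodes, size=2)
                edges.append((f"n{a}", rng.choice(["h", "t"]),
                              f"n{b}", rng.choice(["h", "t"]), 5))
            g = graph_of(nodes, edges, mult)
            if sum(mult.values()) > 8:
                continue
            cands, _ = wr.enumerate_candidates(g, max_candidates=5000)
            got = set()
            for c in cands:
                done = c.walks
                got.add(frozenset(
                    (wr._canonical(w),
                     sum(1 for x in done
                         if wr._canonical(x) == wr._canonical(w)))
                    for w in done))
            expect = covering_bruteforce(g)
            assert got == expect, (trial, nodes, edges, mult)


class TestAlignOntToGraph:
    def _three_node_graph(self, rng):
        A, R, B = (random_bases(rng, 12000) for _ in range(3))
        g = sg.StringGraph()
        for name, seq in [("A", A), ("R", R), ("B", B)]:
            node = sg.SGNode(name, hpc_compress(Sequence(name, seq)).bases)
            g.add_node(node)
        g.add_edge("A", "h", "R", "t", 0)
        g.add_edge("R", "h", "B", "t", 0)
        return Sequence("chr", A + R + B), g

    def test_error_free_read_recovers_path(self, rng):
        chrom, g = self._three_node_graph(rng)
        read = Read(Sequence("r", chrom.bases[6000:30000]), "ont")
        (aln,) = wr.align_ont_to_graph([read], g)
        assert [n for n, _ in aln.path] == ["A", "R", "B"]

    def test_read_inside_one_node(self, rng):
        chrom, g = self._three_node_graph(rng)
        read = Read(Sequence("r", chrom.bases[13000:22000]), "ont")
        (aln,) = wr.align_ont_to_graph([read], g)
        assert [n for n, _ in aln.path] == ["R"]

    def test_noisy_reads_recover_truth_path(self, rng):
        """5%-error reads over a known 3-node path: >=95% recovery."""
        chrom, g = self._three_node_graph(rng)
        ok = 0
        trials = 20
        for t in range(trials):
            r = np.random.default_rng(1000 + t)
            frag = chrom.bases[6000:30000]
            noisy = sim._apply_ont_errors(r, frag, 0.05)
            alns = wr.align_ont_to_graph([Read(Sequence("r", noisy), "ont")], g)
            if alns and [n for n, _ in alns[0].path] == ["A", "R", "B"]:
                ok += 1
        assert ok >= 0.95 * trials


class TestSelectWalk:
    def _cands(self):
        w1 = [[("A", "+"), ("R", "+"), ("B", "+")],
              [("C", "+"), ("R", "+"), ("D", "+")]]
        w2 = [[("A", "+"), ("R", "+"), ("D", "+")],
              [("C", "+"), ("R", "+"), ("B", "+")]]
        return [wr.Candidate([list(w) for w in w1]),
                wr.Candidate([list(w) for w in w2])]

    def _aln(self, path):
        return wr.GraphAlignment("r", path, [3] * len(path), 9)

    def test_one_sided_support_resolves(self):
        alns = [self._aln([("A", "+"), ("R", "+"), ("B", "+")])] * 6
        chosen = wr.select_walk(self._cands(), alns, min_margin=2.0)
        assert chosen.status == "resolved" and chosen.support == 6

    def test_balanced_support_is_ambiguous(self):
        alns = ([self._aln([("A", "+"), ("R", "+"), ("B", "+")])] * 3
                + [self._aln([("A", "+"), ("R", "+"), ("D", "+")])] * 3)
        chosen = wr.select_walk(self._cands(), alns, min_margin=2.0)
        assert chosen.status == "ambiguous"

    def test_single_candidate_forced(self):
        only = wr.Candidate([[("A", "+")]])
        chosen = wr.select_walk([only], [])
        assert chosen.status == "resolved"

    def test_reverse_complement_path_counts(self):
        rc = [("B", "-"), ("R", "-"), ("A", "-")]
        chosen = wr.select_walk(self._cands(), [self._aln(rc)] * 4,
                                min_margin=2.0)
        assert chosen.status == "resolved"


class TestConsensus:
    def _node_graph(self, bases, reads_runs):
        """Single-node graph with one placed read per run-length vector."""
        g = sg.StringGraph()
        node = sg.SGNode("n", bases)
        reads = []
        for i, runs in enumerate(reads_runs):
            rid = f"r{i}"
            node.placements.append(
                sg.ReadPlacement(rid, 0, len(bases), "+"))
            reads.append(HPCSequence(bases, np.array(runs), rid))
        g.add_node(node)
        return g, reads

    def test_modal_run_length(self):
        g, reads = self._node_graph("ACGT", [[3, 1, 1, 1], [3, 1, 1, 1],
                                             [3, 1, 1, 1], [2, 1, 1, 1]])
        walk = wr.Walk("w", [("n", "+")], "resolved")
        out = wr.consensus(walk, g, reads)
        assert out.sequence.bases == "AAACGT"

    def test_tie_breaks_to_smaller_run(self):
        g, reads = self._node_graph("ACGT", [[2, 1, 1, 1], [2, 1, 1, 1],
                                             [3, 1, 1, 1], [3, 1, 1, 1]])
        walk = wr.Walk("w", [("n", "+")], "resolved")
        out = wr.consensus(walk, g, reads)
        assert out.sequence.bases == "AACGT"

    def test_zero_support_emits_run_one_and_issue(self):
        g = sg.StringGraph()
        g.add_node(sg.SGNode("n", "ACGT"))
        walk = wr.Walk("w", [("n", "+")], "resolved")
        out = wr.consensus(walk, g, [])
        assert out.sequence.bases == "ACGT"
        assert out.low_coverage == [(0, 4)]

    def test_error_free_end_to_end_identity(self):
        """Full pipeline on error-free reads reproduces the genome exactly."""
        genome, _ = sim.simulate_genome(sim.GenomeSpec(seed=51,
                                                       backbone_len=40_000))
        hifi = sim.simulate_hifi(genome, 14, mean_len=6000, error_rate=0.0,
                                 seed=52)
        res = assemble(hifi, None, min_overlap=400)
        assert len(res.contigs) == 1
        c = res.contigs[0].bases
        assert c == genome.bases or c == revcomp(genome.bases)


class TestXTangleResolution:
    def test_ont_guides_correct_pairing(self):
        correct, status = xtangle_trial(7)
        assert correct and status == "resolved"

    def test_without_ont_stays_ambiguous(self):
        _, status = xtangle_trial(7, with_ont=False)
        assert status == "ambiguous"
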