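"""All-vs-all alignment of compressed reads, error correction, and exact
suffix-prefix overlap detection.

The workflow mirrors string-graph construction from accurate long reads:

1. :func:`all_pairs_align` — seeded, banded approximate alignment of all
   read pairs in compressed space (both orientations).
2. :func:`correct_reads` — pileup-based majority correction of the few
   residual compressed-space errors; positions inside simple-sequence-repeat
   masks are never altered.
3. :func:`exact_overlaps` — after correction, only *exact* suffix-prefix
   overlaps are kept (masked positions act as wildcards); containments are
   flagged and excluded from graph edges but retained for depth.

Coordinate convention: ``a`` is always in its forward frame.  When
``b_orient`` is ``-``, the ``b`` coordinates refer to the reverse-complement
of ``b`` (the "oriented frame"); :func:`flip` converts a record to the
symmetric ``(b, a)`` form.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Optional

import edlib
import numpy as np

from .seqmodel import (HPCSequence, MaskInterval, find_microsatellites,
                       mask_array, revcomp)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
GAP = 5
_COMP_CODE = np.array([3, 2, 1, 0, 4, 5], dtype=np.uint8)

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


def _flip_kind(kind: str, b_orient: str) -> str:
    """Dovetail direction under role exchange.

    Containment roles always swap.  For '+' records 'ab' <-> 'ba'; for '-'
    records the direction is preserved (reverse-complementing both sides of
    suffix(a) == prefix(rc b) yields suffix(b) == prefix(rc a)).
    """
    if kind == "contained_a":
        return "contained_b"
    if kind == "contained_b":
        return "contained_a"
    if b_orient == "+":
        return "ba" if kind == "ab" else "ab"
    return kind


def codes(bases: str) -> np.ndarray:
    return _CODE[np.frombuffer(bases.encode(), dtype=np.uint8)]


@dataclass
class Alignment:
    """Approximate pairwise alignment between compressed reads."""

    a_id: str
    b_id: str
    b_orient: str  # '+' or '-'
    a_start: int
    a_end: int
    b_start: int  # oriented-frame coordinates when b_orient == '-'
    b_end: int
    a_len: int
    b_len: int
    identity: float
    kind: str  # 'ab', 'ba', 'contained_a', 'contained_b'
    cigar: Optional[str] = None  # query = a substring, target = b substring

    def flip(self) -> "Alignment":
        """The symmetric record with the roles of a and b exchanged."""
        kind = _flip_kind(self.kind, self.b_orient)
        if self.b_orient == "+":
            return replace(self, a_id=self.b_id, b_id=self.a_id,
                           a_start=self.b_start, a_end=self.b_end,
                           b_start=self.a_start, b_end=self.a_end,
                           a_len=self.b_len, b_len=self.a_len,
                           kind=kind, cigar=None)
        # '-' : express as b-forward vs reverse-complemented a
        return Alignment(self.b_id, self.a_id, "-",
                         self.b_len - self.b_end, self.b_len - self.b_start,
                         self.a_len - self.a_end, self.a_len - self.a_start,
                         self.b_len, self.a_len, self.identity,
                         kind, None)


@dataclass
class Overlap:
    """An exact (outside masks) suffix-prefix overlap or containment."""

    a_id: str
    b_id: str
    a_orient: str
    b_orient: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    a_len: int
    b_len: int
    exact: bool = True
    contained: bool = False
    kind: str = "ab"  # 'ab': suffix of a matches prefix of oriented b

    @property
    def length(self) -> int:
        return self.a_end - self.a_start

    def flip(self) -> "Overlap":
        kind = _flip_kind(self.kind, self.b_orient)
        if self.b_orient == "+":
            return replace(self, a_id=self.b_id, b_id=self.a_id,
                           a_start=self.b_start, a_end=self.b_end,
                           b_start=self.a_start, b_end=self.a_end,
                           a_len=self.b_len, b_len=self.a_len, kind=kind)
        return replace(self, a_id=self.b_id, b_id=self.a_id,
                       a_start=self.b_len - self.b_end,
                       a_end=self.b_len - self.b_start,
                       b_start=self.a_len - self.a_end,
                       b_end=self.a_len - self.a_start,
                       a_len=self.b_len, b_len=self.a_len, kind=kind)


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def _kmer_values(code_arr: np.ndarray, k: int) -> np.ndarray:
    """Base-5 integer encoding of every k-mer (vectorised)."""
    if len(code_arr) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(code_arr, k)
    powers = (5 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    return win.astype(np.int64) @ powers


class _SeedIndex:
    """Sorted global k-mer table over all reads for vectorised seeding."""

    def __init__(self, seqs: list[str], k: int, max_occ: int):
        self.k = k
        self.lens = np.array([len(s) for s in seqs], dtype=np.int64)
        self.codes = [codes(s) for s in seqs]
        vals, rid, pos = [], [], []
        for i, c in enumerate(self.codes):
            v = _kmer_values(c, k)
            vals.append(v)
            rid.append(np.full(len(v), i, dtype=np.int32))
            pos.append(np.arange(len(v), dtype=np.int32))
        vals = np.concatenate(vals) if vals else np.empty(0, dtype=np.int64)
        rid = np.concatenate(rid) if rid else np.empty(0, dtype=np.int32)
        pos = np.concatenate(pos) if pos else np.empty(0, dtype=np.int32)
        order = np.argsort(vals, kind="stable")
        self.vals = vals[order]
        self.rid = rid[order]
        self.pos = pos[order]
        self.max_occ = max_occ

    def _hits(self, qvals: np.ndarray):
        lo = np.searchsorted(self.vals, qvals, "left")
        hi = np.searchsorted(self.vals, qvals, "right")
        cnt = hi - lo
        keep = (cnt > 0) & (cnt <= self.max_occ)
        lo, cnt = lo[keep], cnt[keep]
        qpos = np.flatnonzero(keep)
        # expand ranges into flat table indices
        idx = np.repeat(lo, cnt) + _ranges_offsets(cnt)
        qrep = np.repeat(qpos, cnt)
        return qrep, self.rid[idx], self.pos[idx].astype(np.int64)

    def diagonal_votes(self, i: int) -> dict:
        """(j, orient) -> Counter of diagonals, for all j > i."""
        la = int(self.lens[i])
        out: dict[tuple, Counter] = defaultdict(Counter)
        # forward
        q, j, pb = self._hits(_kmer_values(self.codes[i], self.k))
        sel = j > i
        q, jj, pb = q[sel], j[sel], pb[sel]
        if len(q):
            diag = q - pb
            key = jj.astype(np.int64) * (1 << 32) + (diag + (1 << 30))
            uk, uc = np.unique(key, return_counts=True)
            for kv, c in zip(uk, uc):
                out[(int(kv >> 32), "+")][int((kv & 0xFFFFFFFF) - (1 << 30))] += int(c)
        # reverse complement
        rc_codes = _COMP_CODE[self.codes[i]][::-1]
        q, j, pb = self._hits(_kmer_values(rc_codes, self.k))
        sel = j > i
        q, jj, pb = q[sel], j[sel], pb[sel]
        if len(q):
            diag = (la - self.lens[jj]) - (q - pb)
            key = jj.astype(np.int64) * (1 << 32) + (diag + (1 << 30))
            uk, uc = np.unique(key, return_counts=True)
            for kv, c in zip(uk, uc):
                out[(int(kv >> 32), "-")][int((kv & 0xFFFFFFFF) - (1 << 30))] += int(c)
        return out


def _ranges_offsets(cnt: np.ndarray) -> np.ndarray:
    """[0..cnt0-1, 0..cnt1-1, ...] as one flat array."""
    if len(cnt) == 0:
        return np.empty(0, dtype=np.int64)
    total = int(cnt.sum())
    out = np.ones(total, dtype=np.int64)
    ends = np.cumsum(cnt)
    out[0] = 0
    out[ends[:-1]] = 1 - cnt[:-1]
    return np.cumsum(out)


def _diagonal_extent(d: int, la: int, lb: int):
    """Overlap region implied by diagonal d (a = b_oriented + d)."""
    s_a, e_a = max(0, d), min(la, lb + d)
    return s_a, e_a, s_a - d, e_a - d


def _classify(s_a, e_a, s_b, e_b, la, lb) -> str:
    a_full = s_a == 0 and e_a == la
    b_full = s_b == 0 and e_b == lb
    if a_full:
        return "contained_a"
    if b_full:
        return "contained_b"
    if e_a == la and s_b == 0:
        return "ab"
    return "ba"


def all_pairs_align(reads: list[HPCSequence], min_overlap: int = 500,
                    k: int = 15, identity_floor: float = 0.98,
                    min_votes: int = 3, band: int = 30,
                    max_occ: int = 500) -> list[Alignment]:
    """Seeded all-vs-all approximate alignment in compressed space.

    For each read pair and orientation, k-mer matches vote for a diagonal;
    the extent implied by the best diagonal cluster is verified by global
    alignment (edlib) and kept if the identity clears ``identity_floor``.
    Each pair is reported once (canonical direction); the symmetric record
    is available through :meth:`Alignment.flip`.
    """
    seqs = [r.bases for r in reads]
    ids = [r.origin_id for r in reads]
    index = _SeedIndex(seqs, k, max_occ)
    out = []
    for i in range(len(reads)):
        votes = index.diagonal_votes(i)
        la = len(seqs[i])
        for (j, orient), diag_votes in votes.items():
            lb = len(seqs[j])
            # cluster diagonals within +-band around the strongest one
            best_d, _ = max(diag_votes.items(), key=lambda kv: (kv[1], -abs(kv[0])))
            total = sum(c for d, c in diag_votes.items() if abs(d - best_d) <= band)
            if total < min_votes:
                continue
            s_a, e_a, s_b, e_b = _diagonal_extent(best_d, la, lb)
            if e_a - s_a < min_overlap:
                continue
            b_seq = seqs[j] if orient == "+" else revcomp(seqs[j])
            span = e_a - s_a
            max_ed = int(span * (1.0 - identity_floor)) + 20
            res = edlib.align(seqs[i][s_a:e_a], b_seq[s_b:e_b],
                              mode="NW", task="path", k=max_ed)
            if res["editDistance"] < 0:
                continue
            ident = 1.0 - res["editDistance"] / span
            if ident < identity_floor:
                continue
            kind = _classify(s_a, e_a, s_b, e_b, la, lb)
            out.append(Alignment(ids[i], ids[j], orient, s_a, e_a, s_b, e_b,
                                 la, lb, ident, kind, res["cigar"]))
    return out


# ---------------------------------------------------------------------------
# Correction
# ---------------------------------------------------------------------------

def _walk_cigar(cigar: str):
    """Return (pa, pb) match columns plus I/D segments as index arrays.

    Positions are relative to the aligned substrings; 'I' consumes query
    (a), 'D' consumes target (b).
    """
    pa = pb = 0
    m_a, m_b, ins_a, ins_b_junc, del_b, del_a_junc = [], [], [], [], [], []
    for num, op in _CIG_RE.findall(cigar):
        n = int(num)
        if op in "=XM":
            m_a.append(np.arange(pa, pa + n))
            m_b.append(np.arange(pb, pb + n))
            pa += n
            pb += n
        elif op == "I":  # bases present in a, absent in b
            ins_a.append(np.arange(pa, pa + n))
            ins_b_junc.extend([pb] * n)
            pa += n
        elif op == "D":  # bases present in b, absent in a
            del_b.append(np.arange(pb, pb + n))
            del_a_junc.extend([pa] * n)
            pb += n
    cat = lambda lst: (np.concatenate(lst) if lst
                       else np.empty(0, dtype=np.int64))
    return (cat(m_a), cat(m_b), cat(ins_a), np.array(ins_b_junc, dtype=np.int64),
            cat(del_b), np.array(del_a_junc, dtype=np.int64))


def _op_groups(positions: np.ndarray, junctions: np.ndarray):
    """Group per-base indel records into contiguous (positions, junction)
    runs so that a multi-base indel votes as a single string."""
    if len(positions) == 0:
        return
    brk = np.flatnonzero((np.diff(positions) != 1)
                         | (np.diff(junctions) != 0))
    starts = np.concatenate(([0], brk + 1))
    ends = np.concatenate((brk + 1, [len(positions)]))
    for s, e in zip(starts, ends):
        yield positions[s:e], int(junctions[s])


def compute_masks(reads: list[HPCSequence], **kwargs) -> dict[str, np.ndarray]:
    """Per-read boolean SSR masks in compressed coordinates."""
    masks = {}
    for r in reads:
        ivs = find_microsatellites(r.bases, seq_id=r.origin_id, **kwargs)
        masks[r.origin_id] = mask_array(len(r.bases), ivs)
    return masks


def mask_intervals(reads: list[HPCSequence], **kwargs) -> list[MaskInterval]:
    out = []
    for r in reads:
        out.extend(find_microsatellites(r.bases, seq_id=r.origin_id, **kwargs))
    return out


def _mask_intervals_of(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return out
    brk = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], brk + 1))
    ends = np.concatenate((brk, [len(idx) - 1]))
    return [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]


_DECODE = "ACGTN-"


def correct_reads(reads: list[HPCSequence], alignments: list[Alignment],
                  masks: Optional[dict[str, np.ndarray]] = None,
                  min_support_ratio: float = 2.0, min_depth: int = 4,
                  region_pad: int = 5) -> list[HPCSequence]:
    """Majority-vote correction of compressed reads from pileup columns.

    Substitutions are corrected column-wise: a read's base is replaced by
    the pileup majority iff the majority has support >= ``min_depth`` and
    leads the read's own symbol by ``min_support_ratio``.  Masked
    (simple-sequence-repeat) columns are never altered column-wise.

    Indels are corrected region-wise.  Alignment paths place the same
    indel at different, equivalent positions inside tandem or quasi-repeat
    context, so column votes split and can never reach a majority.
    Instead, every site with indel evidence (gap or insertion votes)
    seeds a small window -- widened to the covering masked interval where
    one exists -- and each aligned partner votes for the *entire content*
    of that window; the majority content replaces the read's copy under
    the same support/ratio rules.  Balanced disagreements (diverged repeat
    copies, heterozygous-like columns) fail the ratio test and are left
    untouched.
    """
    idx = {r.origin_id: i for i, r in enumerate(reads)}
    code_fwd = [codes(r.bases) for r in reads]
    counts = [np.zeros((len(r.bases), 6), dtype=np.int32) for r in reads]
    ins_votes: list[dict[int, Counter]] = [defaultdict(Counter) for _ in reads]
    mask_ivs = [(_mask_intervals_of(masks[r.origin_id])
                 if masks and r.origin_id in masks else [])
                for r in reads]
    for i, r in enumerate(reads):
        np.add.at(counts[i], (np.arange(len(r.bases)), code_fwd[i]), 1)

    alns = [a for a in alignments
            if a.cigar is not None and a.a_id in idx and a.b_id in idx]

    # ---- pass 1: column counts and indel evidence --------------------------
    for aln in alns:
        ia, ib = idx[aln.a_id], idx[aln.b_id]
        lb = aln.b_len
        b_or = (code_fwd[ib] if aln.b_orient == "+"
                else _COMP_CODE[code_fwd[ib]][::-1])
        m_a, m_b, i_a, i_bj, d_b, d_aj = _walk_cigar(aln.cigar)
        pa = m_a + aln.a_start
        pb = m_b + aln.b_start
        np.add.at(counts[ia], (pa, b_or[pb]), 1)
        if aln.b_orient == "+":
            np.add.at(counts[ib], (pb, code_fwd[ia][pa]), 1)
        else:
            np.add.at(counts[ib], (lb - 1 - pb, _COMP_CODE[code_fwd[ia][pa]]), 1)
        # I: a has extra bases -> b votes gap in a; a votes insertion in b
        if len(i_a):
            pai = i_a + aln.a_start
            np.add.at(counts[ia], (pai, np.full(len(pai), GAP)), 1)
            for p_ai, junc in _op_groups(pai, i_bj + aln.b_start):
                text = "".join(_DECODE[c] for c in code_fwd[ia][p_ai])
                if aln.b_orient == "-":
                    jb = lb - junc
                    text = "".join(_DECODE[_COMP_CODE[_CODE[ord(ch)]]]
                                   for ch in reversed(text))
                else:
                    jb = junc
                ins_votes[ib][int(jb)][text] += 1
        # D: b has extra bases -> a votes gap in b; b votes insertion in a
        if len(d_b):
            pbd = d_b + aln.b_start
            if aln.b_orient == "+":
                np.add.at(counts[ib], (pbd, np.full(len(pbd), GAP)), 1)
            else:
                np.add.at(counts[ib], (lb - 1 - pbd, np.full(len(pbd), GAP)), 1)
            for p_bd, junc in _op_groups(pbd, d_aj + aln.a_start):
                text = "".join(_DECODE[c] for c in b_or[p_bd])
                ins_votes[ia][int(junc)][text] += 1

    # ---- candidate indel regions per read ----------------------------------
    evidence_floor = max(2, min_depth // 2)
    regions: list[list[tuple[int, int]]] = []
    for i, r in enumerate(reads):
        L = len(r.bases)
        sites = set()
        gap_cols = np.flatnonzero(counts[i][:, GAP] >= evidence_floor)
        sites.update(int(p) for p in gap_cols)
        for junc, votes in ins_votes[i].items():
            if sum(votes.values()) >= evidence_floor:
                sites.add(min(max(junc, 0), L - 1) if L else 0)
        ivs = []
        for p in sorted(sites):
            lo, hi = max(p - region_pad, 0), min(p + region_pad + 1, L)
            # widen to a covering or adjacent masked interval
            for ms, me in mask_ivs[i]:
                if ms - 1 <= hi and lo <= me + 1:
                    lo, hi = min(lo, ms), max(hi, me)
            if ivs and lo <= ivs[-1][1]:
                ivs[-1] = (ivs[-1][0], max(ivs[-1][1], hi))
            else:
                ivs.append((lo, hi))
        regions.append(ivs)

    # ---- pass 2: whole-region content votes --------------------------------
    region_votes: list[dict[tuple, Counter]] = [defaultdict(Counter)
                                                for _ in reads]

    def vote_regions(i_tgt, tgt_pos, oth_codes, oth_pos):
        if len(tgt_pos) == 0 or not regions[i_tgt]:
            return
        rv = region_votes[i_tgt]
        for rs, re_ in regions[i_tgt]:
            li = int(np.searchsorted(tgt_pos, rs)) - 1
            ri = int(np.searchsorted(tgt_pos, re_))
            if li < 0 or ri >= len(tgt_pos):
                continue
            a_lo, a_hi = int(tgt_pos[li]), int(tgt_pos[ri])
            b_lo, b_hi = int(oth_pos[li]), int(oth_pos[ri])
            if a_lo >= rs or a_hi < re_:
                continue
            if b_hi < b_lo:  # partner coordinates run backwards
                sub = "".join(_DECODE[c] for c in oth_codes[b_hi + 1:b_lo][::-1])
            else:
                sub = "".join(_DECODE[c] for c in oth_codes[b_lo + 1:b_hi])
            rv[(rs, re_)][((a_lo + 1, a_hi), sub)] += 1

    if any(regions[i] for i in range(len(reads))):
        for aln in alns:
            ia, ib = idx[aln.a_id], idx[aln.b_id]
            if not regions[ia] and not regions[ib]:
                continue
            lb = aln.b_len
            b_or = (code_fwd[ib] if aln.b_orient == "+"
                    else _COMP_CODE[code_fwd[ib]][::-1])
            m_a, m_b, _, _, _, _ = _walk_cigar(aln.cigar)
            pa = m_a + aln.a_start
            pb = m_b + aln.b_start
            vote_regions(ia, pa, b_or, pb)
            if aln.b_orient == "+":
                vote_regions(ib, pb, code_fwd[ia], pa)
            else:
                vote_regions(ib, (lb - 1 - pb)[::-1], _COMP_CODE[code_fwd[ia]],
                             pa[::-1])

    # ---- decide and rebuild ------------------------------------------------
    out = []
    for i, r in enumerate(reads):
        mask = masks.get(r.origin_id) if masks else None
        cnt = counts[i]
        cov = cnt.sum(axis=1)
        own = code_fwd[i]
        maj = cnt.argmax(axis=1)
        pos_idx = np.arange(len(own))
        maj_cnt = cnt[pos_idx, maj]
        own_cnt = cnt[pos_idx, own]
        change = ((maj != own) & (maj != GAP) & (maj_cnt >= min_depth)
                  & (maj_cnt >= min_support_ratio * np.maximum(own_cnt, 1)))
        if mask is not None:
            change &= ~mask

        accepted_reg: list[tuple[int, int, str]] = []
        for (rs, re_), votes in region_votes[i].items():
            (span, sub), n_top = votes.most_common(1)[0]
            own_content = r.bases[span[0]:span[1]]
            if sub == own_content:
                continue
            own_votes = votes.get((span, own_content), 0) + 1
            if n_top >= min_depth and n_top >= min_support_ratio * own_votes:
                accepted_reg.append((span[0], span[1], sub))
        accepted_reg.sort()
        pruned: list[tuple[int, int, str]] = []
        for s, e, sub in accepted_reg:
            if not pruned or s >= pruned[-1][1]:
                pruned.append((s, e, sub))
        reg_by_start = {s: (e, sub) for s, e, sub in pruned}

        if not change.any() and not pruned:
            out.append(r)
            continue
        new_bases: list[str] = []
        new_runs: list[int] = []
        p = 0
        while p < len(own):
            if p in reg_by_start:
                e, sub = reg_by_start[p]
                for ch in sub:
                    new_bases.append(ch)
                    new_runs.append(1)
                p = e
                continue
            if change[p]:
                new_bases.append(_DECODE[maj[p]])
            else:
                new_bases.append(r.bases[p])
            new_runs.append(int(r.run_lengths[p]))
            p += 1
        # restore the HPC invariant (merges can arise at edited positions)
        fb: list[str] = []
        fr: list[int] = []
        for b, n in zip(new_bases, new_runs):
            if fb and fb[-1] == b:
                fr[-1] += n
            else:
                fb.append(b)
                fr.append(n)
        out.append(HPCSequence("".join(fb), np.array(fr), r.origin_id))
    return out

# ---------------------------------------------------------------------------
# Exact overlaps
# ---------------------------------------------------------------------------

def exact_overlaps(reads: list[HPCSequence],
                   masks: Optional[dict[str, np.ndarray]] = None,
                   min_overlap: int = 500, k: int = 21,
                   min_votes: int = 3, max_occ: int = 500) -> list[Overlap]:
    """All exact suffix-prefix overlaps (masked positions are wildcards).

    Containments are flagged (``contained=True``) so graph construction can
    exclude them while depth computation retains them.  Records are
    canonicalised so that ``a_id < b_id``.
    """
    seqs = [r.bases for r in reads]
    ids = [r.origin_id for r in reads]
    index = _SeedIndex(seqs, k, max_occ)
    code_arr = index.codes
    msk = []
    for r in reads:
        m = masks.get(r.origin_id) if masks else None
        msk.append(m if m is not None else np.zeros(len(r.bases), dtype=bool))
    out = []
    seen = set()
    for i in range(len(reads)):
        votes = index.diagonal_votes(i)
        la = len(seqs[i])
        for (j, orient), diag_votes in votes.items():
            lb = len(seqs[j])
            for d, v in diag_votes.items():
                if v < min_votes:
                    continue
                s_a, e_a, s_b, e_b = _diagonal_extent(d, la, lb)
                if e_a - s_a < min_overlap:
                    continue
                a_reg = code_arr[i][s_a:e_a]
                if orient == "+":
                    b_reg = code_arr[j][s_b:e_b]
                    b_m = msk[j][s_b:e_b]
                else:
                    b_reg = _COMP_CODE[code_arr[j]][::-1][s_b:e_b]
                    b_m = msk[j][::-1][s_b:e_b]
                ok = (a_reg == b_reg) | msk[i][s_a:e_a] | b_m
                if not ok.all():
                    continue
                key = (i, j, orient, d)
                if key in seen:
                    continue
                seen.add(key)
                kind = _classify(s_a, e_a, s_b, e_b, la, lb)
                ovl = Overlap(ids[i], ids[j], "+", orient, s_a, e_a, s_b, e_b,
                              la, lb, exact=True,
                              contained=kind.startswith("contained"),
                              kind=kind)
                if ovl.a_id > ovl.b_id:
                    ovl = ovl.flip()
                out.append(ovl)
    return out


def truth_overlaps(reads, min_overlap: int) -> set:
    """Ground-truth dovetail overlap set implied by read truth intervals.

    Returns frozen tuples ``(id_lo, id_hi, orient, length)`` for every pair
    of reads whose true genomic intervals (same chromosome) overlap by at
    least ``min_overlap`` bases and where neither contains the other.  Used
    as an independent oracle on error-free, repeat-free simulations.

    Lengths are in original (uncompressed) coordinates.
    """
    out = set()
    for i, a in enumerate(reads):
        for b in reads[i + 1:]:
            ta, tb = a.truth, b.truth
            if ta is None or tb is None or ta.chrom != tb.chrom:
                continue
            o = min(ta.end, tb.end) - max(ta.start, tb.start)
            if o < min_overlap:
                continue
            if (ta.start <= tb.start and ta.end >= tb.end) or \
               (tb.start <= ta.start and tb.end >= ta.end):
                continue
            lo, hi = sorted([a.id, b.id])
            orient = "+" if ta.strand == tb.strand else "-"
            out.add((lo, hi, orient, o))
    return out


# ---------------------------------------------------------------------------
# PAF-like TSV serialisation
# ---------------------------------------------------------------------------

_OVL_FIELDS = ("a_id", "a_len", "a_start", "a_end", "b_orient", "b_id",
               "b_len", "b_start", "b_end")


def write_overlaps_tsv(overlaps: list[Overlap], path) -> None:
    """PAF-like TSV: query/target names, lengths, coordinates, orientation,
    plus exact/contained flags and the dovetail direction."""
    with open(path, "w") as fh:
        for o in overlaps:
            row = [str(getattr(o, f)) for f in _OVL_FIELDS]
            row += ["1" if o.exact else "0", "1" if o.contained else "0",
                    o.kind]
            fh.write("\t".join(row) + "\n")


def read_overlaps_tsv(path) -> list[Overlap]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            f = line.rstrip("\n").split("\t")
            if len(f) != 12:
                raise ValueError(f"bad overlap record at line {ln}")
            out.append(Overlap(
                f[0], f[5], "+", f[4], int(f[2]), int(f[3]), int(f[7]),
                int(f[8]), int(f[1]), int(f[6]), exact=f[9] == "1",
                contained=f[10] == "1", kind=f[11]))
    return out
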