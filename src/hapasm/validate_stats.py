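"""Assembly validation toolkit.

Implements the coverage/marker/identity screening used to certify a
finished assembly: contiguity statistics (NG50 against a fixed genome
size, contigs split at runs of >=3 Ns), per-base coverage profiles with a
mean +- 3 s.d. uniformity band, unique k-mer markers and marker-assisted
read assignment inside near-identical repeats, primary/secondary allele
ratios from accurate-read pileups, windowed maximum-identity profiles
between sequences, and a merged issue catalog reporting the fraction of
the assembly affected by potential problems.

Alignments are accepted as simple (start, end[, ...]) interval records or
objects with ``start``/``end`` attributes, keeping the module independent
of any particular aligner output format.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence as TSequence

import edlib
import numpy as np

from .seqmodel import Sequence, revcomp


@dataclass
class CoverageProfile:
    target_id: str
    depth: np.ndarray  # per-position integer depth
    tech: str = ""

    @property
    def mean(self) -> float:
        return float(self.depth.mean()) if len(self.depth) else 0.0

    @property
    def sd(self) -> float:
        return float(self.depth.std()) if len(self.depth) else 0.0


@dataclass
class Issue:
    target_id: str
    start: int
    end: int
    kind: str  # low_coverage | het_variant | error | ambiguous_walk
    evidence: str = ""

    KINDS = ("low_coverage", "het_variant", "error", "ambiguous_walk")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown issue kind {self.kind!r}")


@dataclass
class AssemblyStats:
    total_nonN_bases: int
    contig_count: int
    ng50: int
    genome_size: int
    contig_lengths: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Contiguity statistics
# ---------------------------------------------------------------------------

def _contig_lengths(bases: str, n_split: int = 3) -> list[int]:
    """Lengths of maximal non-N runs between N-runs of length >= n_split."""
    out = []
    cur = 0
    n_run = 0
    pending_ns = 0
    for b in bases:
        if b == "N":
            n_run += 1
            if n_run == n_split and cur:
                out.append(cur)
                cur = 0
        else:
            if 0 < n_run < n_split and cur:
                cur += n_run  # short N runs stay inside the contig
            n_run = 0
            cur += 1
    if cur:
        out.append(cur)
    return out


def ng50(contig_lengths: TSequence[int], genome_size: int) -> int:
    """Largest L with contigs >= L summing to at least genome_size / 2."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    half = genome_size / 2.0
    acc = 0
    for ln in sorted(contig_lengths, reverse=True):
        acc += ln
        if acc >= half:
            return ln
    return 0


def assembly_stats(assembly: Iterable[Sequence], genome_size: int,
                   n_split: int = 3) -> AssemblyStats:
    """Contiguity summary: non-N bases, 3-N-split contigs, NG50."""
    seqs = list(assembly)
    if not seqs or all(len(s) == 0 for s in seqs):
        raise ValueError("empty assembly")
    lengths: list[int] = []
    total = 0
    for s in seqs:
        total += len(s.bases) - s.bases.count("N")
        lengths.extend(_contig_lengths(s.bases, n_split))
    return AssemblyStats(total, len(lengths), ng50(lengths, genome_size),
                         genome_size, sorted(lengths, reverse=True))


# ---------------------------------------------------------------------------
# Coverage uniformity
# ---------------------------------------------------------------------------

def _iter_intervals(alignments):
    for a in alignments:
        if hasattr(a, "start"):
            yield int(a.start), int(a.end)
        else:
            yield int(a[0]), int(a[1])


def coverage_profile(alignments, target_len: int, target_id: str = "",
                     tech: str = "") -> CoverageProfile:
    """Per-position depth by interval accumulation (difference array)."""
    diff = np.zeros(target_len + 1, dtype=np.int64)
    for s, e in _iter_intervals(alignments):
        s = max(0, min(s, target_len))
        e = max(0, min(e, target_len))
        diff[s] += 1
        diff[e] -= 1
    return CoverageProfile(target_id, np.cumsum(diff[:-1]), tech)


def _merged_runs(flagged: np.ndarray):
    idx = np.flatnonzero(flagged)
    if len(idx) == 0:
        return
    brk = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], brk + 1))
    ends = np.concatenate((brk, [len(idx) - 1]))
    for s, e in zip(starts, ends):
        yield int(idx[s]), int(idx[e]) + 1


def flag_coverage(profile: CoverageProfile, n_sd: float = 3.0
                  ) -> tuple[float, list[Issue]]:
    """Fraction of positions within mean +- n_sd * sd, plus Issues.

    Below-band intervals become ``low_coverage`` issues; above-band
    intervals become ``error`` candidates (possible collapsed repeats).
    With perfectly constant coverage (sd == 0) the whole target counts as
    in-band.  The fraction is reported to 4 decimals.
    """
    d = profile.depth
    mean, sd = profile.mean, profile.sd
    lo, hi = mean - n_sd * sd, mean + n_sd * sd
    below = d < lo
    above = d > hi
    in_band = ~(below | above)
    issues = []
    for s, e in _merged_runs(below):
        issues.append(Issue(profile.target_id, s, e, "low_coverage",
                            f"depth<{lo:.2f} (mean {mean:.2f}, sd {sd:.2f})"))
    for s, e in _merged_runs(above):
        issues.append(Issue(profile.target_id, s, e, "error",
                            f"depth>{hi:.2f} (mean {mean:.2f}, sd {sd:.2f})"))
    frac = round(float(in_band.mean()) if len(d) else 1.0, 4)
    return frac, issues


# ---------------------------------------------------------------------------
# Unique k-mer markers
# ---------------------------------------------------------------------------

def _canon(km: str) -> str:
    rc = revcomp(km)
    return km if km <= rc else rc


def unique_markers(assembly: Iterable[Sequence], k: int = 21,
                   density_window: int = 10_000
                   ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Positions of canonical k-mers occurring exactly once genome-wide.

    Returns ``(markers, density)``: per-sequence sorted marker position
    arrays and markers-per-window density tracks.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts: Counter = Counter()
    seqs = list(assembly)
    for s in seqs:
        b = s.bases
        for p in range(len(b) - k + 1):
            counts[_canon(b[p:p + k])] += 1
    markers = {}
    density = {}
    for s in seqs:
        b = s.bases
        pos = [p for p in range(len(b) - k + 1)
               if counts[_canon(b[p:p + k])] == 1]
        arr = np.array(pos, dtype=np.int64)
        markers[s.id] = arr
        nwin = max(1, -(-len(b) // density_window))
        dens = np.zeros(nwin)
        if len(arr):
            np.add.at(dens, arr // density_window, 1)
        density[s.id] = dens
    return markers, density


@dataclass
class CandidateAlignment:
    """One candidate placement of a read on the assembly."""

    read_id: str
    target_id: str
    start: int
    end: int
    read_seq: str = ""
    primary: bool = False


def _agreeing_markers(cand: CandidateAlignment, target_seq: str,
                      marker_pos: np.ndarray, k: int) -> int:
    """Markers inside the candidate span confirmed by the read sequence."""
    span = marker_pos[(marker_pos >= cand.start)
                      & (marker_pos + k <= cand.end)]
    if len(span) == 0:
        return 0
    if not cand.read_seq:
        return len(span)
    tgt = target_seq[cand.start:cand.end]
    res = edlib.align(cand.read_seq, tgt, mode="NW", task="path")
    # map target positions covered by exact matches
    ok = np.zeros(len(tgt), dtype=bool)
    pq = pt = 0
    for num, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
        n = int(num)
        if op == "=":
            ok[pt:pt + n] = True
        if op in "=X":
            pq += n
            pt += n
        elif op == "I":
            pq += n
        elif op == "D":
            pt += n
    agree = 0
    for p in span:
        q = p - cand.start
        if ok[q:q + k].all():
            agree += 1
    return agree


def marker_assign(candidates_by_read: dict[str, list[CandidateAlignment]],
                  markers: dict[str, np.ndarray],
                  targets: dict[str, str], k: int = 21
                  ) -> dict[str, tuple[CandidateAlignment, bool]]:
    """Assign multi-mapping reads to the candidate with most agreeing markers.

    Returns read -> (chosen candidate, low_confidence flag).  Reads with no
    agreeing markers anywhere keep their primary alignment, flagged
    low-confidence.
    """
    out = {}
    for rid, cands in candidates_by_read.items():
        scored = []
        for c in cands:
            mpos = markers.get(c.target_id, np.empty(0, dtype=np.int64))
            scored.append((_agreeing_markers(c, targets[c.target_id], mpos, k), c))
        best_score = max(s for s, _ in scored)
        if best_score == 0:
            primary = next((c for _, c in scored if c.primary), scored[0][1])
            out[rid] = (primary, True)
        else:
            best = max(scored, key=lambda t: t[0])
            out[rid] = (best[1], False)
    return out


# ---------------------------------------------------------------------------
# Allele ratios
# ---------------------------------------------------------------------------

def allele_ratio(pileup_counts: np.ndarray, primary: np.ndarray,
                 window: int = 1000, min_depth: int = 10,
                 flag_threshold: float = 0.8, target_id: str = ""
                 ) -> tuple[np.ndarray, list[Issue]]:
    """Primary-allele fraction per window from a pileup count matrix.

    ``pileup_counts`` is (L, 4) base counts from accurate-read alignments;
    ``primary`` the assembly's base code per position.  Per window the
    fraction is sum(primary) / (sum(primary) + sum(top secondary)); windows
    under ``flag_threshold`` at adequate depth are flagged as heterozygous
    (fraction >= 0.3) or error (fraction < 0.3) candidates.
    """
    L = pileup_counts.shape[0]
    pos = np.arange(L)
    prim = pileup_counts[pos, primary]
    tmp = pileup_counts.copy()
    tmp[pos, primary] = -1
    sec = tmp.max(axis=1)
    sec = np.maximum(sec, 0)
    nwin = max(1, -(-L // window))
    fracs = np.ones(nwin)
    issues = []
    for w in range(nwin):
        sl = slice(w * window, min((w + 1) * window, L))
        p, s = prim[sl].sum(), sec[sl].sum()
        depth = pileup_counts[sl].sum() / max(sl.stop - sl.start, 1)
        frac = p / (p + s) if (p + s) > 0 else 1.0
        fracs[w] = frac
        if depth >= min_depth and frac < flag_threshold:
            kind = "het_variant" if frac >= 0.3 else "error"
            issues.append(Issue(target_id, sl.start, sl.stop, kind,
                                f"primary fraction {frac:.3f}"))
    return fracs, issues


# ---------------------------------------------------------------------------
# Windowed identity
# ---------------------------------------------------------------------------

def _window_kmers(s: str, k: int) -> set:
    return {s[i:i + k] for i in range(0, len(s) - k + 1, k)}


def window_identity(seq_a: Sequence, seq_b: Sequence, window: int = 10_000,
                    smooth: int = 100_000, k: int = 21,
                    prefilter_min_shared: int = 1) -> np.ndarray:
    """Max percent identity of each window of a against any window of b.

    Window pairs are prefiltered by shared k-mer count before global
    alignment; the profile is boxcar-smoothed over ``smooth/window``
    consecutive windows.  Values are percentages in [0, 100].
    """
    if not len(seq_a) or not len(seq_b):
        raise ValueError("both sequences must be non-empty")
    wa = [seq_a.bases[i:i + window] for i in range(0, len(seq_a), window)]
    wb = [seq_b.bases[i:i + window] for i in range(0, len(seq_b), window)]
    kb = [_window_kmers(w, k) for w in wb]
    out = np.zeros(len(wa))
    for i, a in enumerate(wa):
        ka = _window_kmers(a, k)
        best = 0.0
        order = sorted(range(len(wb)), key=lambda j: -len(ka & kb[j]))
        for j in order:
            shared = len(ka & kb[j])
            if shared < prefilter_min_shared and best > 0:
                break
            b = wb[j]
            d = edlib.align(a, b, mode="NW")["editDistance"]
            ident = 100.0 * (1.0 - d / max(len(a), len(b)))
            best = max(best, ident)
            if shared < prefilter_min_shared:
                break  # only the best unfiltered candidate is tried
        out[i] = best
    width = max(1, smooth // window)
    if width > 1 and len(out) >= 1:
        kernel = np.ones(min(width, len(out))) / min(width, len(out))
        out = np.convolve(out, kernel, mode="same")
    return out


# ---------------------------------------------------------------------------
# Issue catalog
# ---------------------------------------------------------------------------

def issue_catalog(issues: Iterable[Issue], assembly_len: int
                  ) -> tuple[list[Issue], dict]:
    """Merge overlapping issues per (target, kind); summarise affected bases.

    Returns the merged issue list and a summary dict with the total bases
    covered by any issue and the affected percentage (4 decimals).
    """
    by_key: dict[tuple, list[Issue]] = defaultdict(list)
    for iss in issues:
        by_key[(iss.target_id, iss.kind)].append(iss)
    merged: list[Issue] = []
    cover: dict[str, list] = defaultdict(list)
    for (tid, kind), group in sorted(by_key.items()):
        group.sort(key=lambda i: i.start)
        cur = None
        for iss in group:
            if cur is not None and iss.start <= cur.end:
                cur.end = max(cur.end, iss.end)
            else:
                if cur is not None:
                    merged.append(cur)
                cur = Issue(tid, iss.start, iss.end, kind, iss.evidence)
        if cur is not None:
            merged.append(cur)
    for iss in merged:
        cover[iss.target_id].append((iss.start, iss.end))
    affected = 0
    for tid, ivs in cover.items():
        ivs.sort()
        last = -1
        for s, e in ivs:
            s = max(s, last)
            if e > s:
                affected += e - s
                last = e
            last = max(last, e)
    pct = round(100.0 * affected / assembly_len, 4) if assembly_len else 0.0
    summary = {"affected_bases": affected, "affected_pct": pct,
               "n_issues": len(merged)}
    return merged, summary


def write_issues_bed(issues: Iterable[Issue], path) -> None:
    with open(path, "w") as fh:
        for iss in issues:
            fh.write(f"{iss.target_id}\t{iss.start}\t{iss.end}"
                     f"\t{iss.kind}\t{iss.evidence}\n")


def write_coverage_bedgraph(profile: CoverageProfile, path) -> None:
    """Per-position depth as bedGraph (adjacent equal depths merged)."""
    d = profile.depth
    with open(path, "w") as fh:
        if len(d) == 0:
            return
        start = 0
        for p in range(1, len(d) + 1):
            if p == len(d) or d[p] != d[start]:
                fh.write(f"{profile.target_id}\t{start}\t{p}\t{int(d[start])}\n")
                start = p


def write_markers_bed(markers: dict, k: int, path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(markers):
            for p in markers[sid]:
                fh.write(f"{sid}\t{int(p)}\t{int(p) + k}\n")


def stats_to_dict(st: AssemblyStats) -> dict:
    return {"total_nonN_bases": st.total_nonN_bases,
            "contig_count": st.contig_count, "ng50": st.ng50,
            "genome_size": st.genome_size}


def write_stats(st: AssemblyStats, tsv_path=None, json_path=None) -> None:
    d = stats_to_dict(st)
    if tsv_path:
        with open(tsv_path, "w") as fh:
            fh.write("\t".join(d.keys()) + "\n")
            fh.write("\t".join(str(v) for v in d.values()) + "\n")
    if json_path:
        import json
        with open(json_path, "w") as fh:
            json.dump(d, fh, indent=2)
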