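"""Core sequence types and transforms.

Everything downstream of read ingest works in *homopolymer-compressed* (HPC)
space: each run of identical bases is collapsed to a single base and the run
length is kept alongside, so that ``AAACGGT`` becomes ``ACGT`` with run
lengths ``[3, 1, 2, 1]``.  This neutralises the dominant error mode of
HiFi-style accurate long reads (single-base indels inside homopolymer runs)
while remaining losslessly invertible, and it is the coordinate space in
which read correction, masking and exact overlapping operate.

Simple-sequence repeats (microsatellites, unit length 1-6 bp) are detected
and masked in compressed space as well, because residual differences inside
them are unreliable for distinguishing repeat copies.

Coordinates are 0-based half-open throughout; strands are ``+`` / ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Literal, Optional, Sequence as TSequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(bases: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return bases.translate(_COMPLEMENT)[::-1]


class SequenceError(ValueError):
    """Raised on malformed sequence input (bad alphabet, bad FASTA)."""


@dataclass
class Sequence:
    """An identified nucleotide sequence over {A,C,G,T,N}.

    Lowercase input is normalised to uppercase on construction; any other
    character raises :class:`SequenceError`.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        b = self.bases.upper()
        if set(b) - ALPHABET:
            bad = sorted(set(b) - ALPHABET)
            raise SequenceError(f"sequence {self.id!r}: illegal characters {bad}")
        self.bases = b

    def __len__(self) -> int:
        return len(self.bases)

    def revcomp(self, new_id: Optional[str] = None) -> "Sequence":
        return Sequence(new_id or self.id, revcomp(self.bases))


@dataclass
class TruthInterval:
    """Ground-truth origin of a simulated read: 0-based half-open interval."""

    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'


@dataclass
class Read:
    """A sequencing read with a technology tag.

    ``tech`` is one of ``hifi`` (accurate ~20 kbp), ``ont`` (noisy >=100 kbp
    ultra-long) or ``ilmn`` (short accurate).  ``truth`` carries the simulated
    origin interval when the read came from the simulator.
    """

    sequence: Sequence
    tech: Literal["hifi", "ont", "ilmn"]
    truth: Optional[TruthInterval] = None

    @property
    def id(self) -> str:
        return self.sequence.id

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class HPCSequence:
    """A homopolymer-compressed sequence with its run-length vector.

    Invariants: no two adjacent equal bases; ``len(run_lengths) ==
    len(bases)``; ``sum(run_lengths)`` equals the original length.
    """

    bases: str
    run_lengths: np.ndarray
    origin_id: str = ""
    _starts: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.run_lengths = np.asarray(self.run_lengths, dtype=np.int64)
        if len(self.run_lengths) != len(self.bases):
            raise ValueError("run_lengths and bases length mismatch")
        if len(self.run_lengths) and self.run_lengths.min() < 1:
            raise ValueError("run lengths must be >= 1")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def original_length(self) -> int:
        return int(self.run_lengths.sum())

    def run_starts(self) -> np.ndarray:
        """Start position of each run in original coordinates (cached)."""
        if self._starts is None or len(self._starts) != len(self.bases):
            starts = np.zeros(len(self.bases) + 1, dtype=np.int64)
            np.cumsum(self.run_lengths, out=starts[1:])
            self._starts = starts
        return self._starts


@dataclass
class MaskInterval:
    """A masked simple-sequence-repeat interval in compressed coordinates."""

    seq_id: str
    start: int
    end: int
    unit: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty mask interval")


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[Sequence]:
    """Read a (multi-line) FASTA file into a list of :class:`Sequence`."""
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            out.append(Sequence(rec.id, str(rec.seq)))
    except SequenceError:
        raise
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise SequenceError(f"malformed FASTA {path}: {exc}") from exc
    return out


def write_fasta(seqs: Iterable[Sequence], path, wrap: int = 80) -> None:
    """Write sequences as FASTA with ``wrap``-column line wrapping."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, max(len(s.bases), 1), wrap):
                fh.write(s.bases[i:i + wrap] + "\n")


def read_fastq(path, tech: str = "hifi") -> list[Read]:
    """Read FASTQ; qualities are parsed but not retained downstream."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(Read(Sequence(rec.id, str(rec.seq)), tech))
    return reads


def write_fastq(reads: Iterable[Read], path) -> None:
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [30] * len(r)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def write_bed(intervals: Iterable[MaskInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.unit}\n")


# ---------------------------------------------------------------------------
# Homopolymer compression
# ---------------------------------------------------------------------------

def hpc_compress(seq: Sequence) -> HPCSequence:
    """Collapse homopolymer runs to single bases, keeping run lengths.

    N runs are compressed like any base (they are always masked downstream).
    """
    bases = []
    runs = []
    for b, grp in groupby(seq.bases):
        bases.append(b)
        runs.append(sum(1 for _ in grp))
    return HPCSequence("".join(bases), np.array(runs, dtype=np.int64), seq.id)


def hpc_decompress(h: HPCSequence, new_id: Optional[str] = None) -> Sequence:
    """Invert :func:`hpc_compress`: expand each base by its run length."""
    parts = [b * int(n) for b, n in zip(h.bases, h.run_lengths)]
    return Sequence(new_id or h.origin_id, "".join(parts))


def hpc_revcomp(h: HPCSequence) -> HPCSequence:
    """Reverse-complement in compressed space (run lengths reverse too)."""
    return HPCSequence(revcomp(h.bases), h.run_lengths[::-1].copy(), h.origin_id)


def map_coordinate(h: HPCSequence, pos: int,
                   direction: Literal["to_compressed", "to_original"]) -> int:
    """Map a position between original and compressed coordinate spaces.

    ``to_compressed`` maps an original-space position to the index of the run
    containing it; ``to_original`` maps a run index to the start of that run.
    Both directions are monotone non-decreasing.
    """
    starts = h.run_starts()
    if direction == "to_compressed":
        if not 0 <= pos < starts[-1]:
            raise IndexError(f"original position {pos} out of range")
        return int(np.searchsorted(starts, pos, side="right") - 1)
    elif direction == "to_original":
        if not 0 <= pos < len(h.bases):
            raise IndexError(f"compressed position {pos} out of range")
        return int(starts[pos])
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# Microsatellite (simple sequence repeat) detection
# ---------------------------------------------------------------------------

def _maximal_period_runs(arr: np.ndarray, period: int):
    """Yield (start, span) of maximal perfect tandem stretches for a period.

    A maximal run of ``arr[i] == arr[i+period]`` over ``[i, j)`` corresponds
    to a perfect tandem repetition spanning ``[i, j + period)``.
    """
    if len(arr) <= period:
        return
    eq = arr[:-period] == arr[period:]
    if not eq.any():
        return
    # run-length encode the boolean vector
    diff = np.diff(eq.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if eq[0]:
        starts = np.concatenate(([0], starts))
    if eq[-1]:
        ends = np.concatenate((ends, [len(eq)]))
    for s, e in zip(starts, ends):
        yield int(s), int(e - s + period)


def find_microsatellites(seq, max_unit: int = 6, min_length: int = 10,
                         min_copies: int = 3, seq_id: Optional[str] = None
                         ) -> list[MaskInterval]:
    """Find maximal perfect tandem repeats with unit length <= ``max_unit``.

    An interval qualifies when its total span is >= ``min_length`` and it
    contains >= ``min_copies`` full copies of the unit.  N runs are always
    masked.  Overlapping intervals (across periods) are merged; the reported
    unit is that of the earliest, smallest-period contributor.
    """
    if isinstance(seq, HPCSequence):
        bases, sid = seq.bases, seq.origin_id
    elif isinstance(seq, Sequence):
        bases, sid = seq.bases, seq.id
    else:
        bases, sid = str(seq), seq_id or ""
    sid = seq_id or sid
    arr = np.frombuffer(bases.encode(), dtype=np.uint8)
    found: list[tuple[int, int, str]] = []
    for p in range(1, max_unit + 1):
        for s, span in _maximal_period_runs(arr, p):
            if span >= min_length and span // p >= min_copies:
                found.append((s, s + span, bases[s:s + p]))
    # always mask N runs regardless of thresholds
    in_n = False
    for i, b in enumerate(bases + "$"):
        if b == "N" and not in_n:
            n_start, in_n = i, True
        elif b != "N" and in_n:
            found.append((n_start, i, "N"))
            in_n = False
    if not found:
        return []
    found.sort(key=lambda t: (t[0], t[1] - t[0]))
    merged: list[list] = []
    for s, e, u in found:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e, u])
    return [MaskInterval(sid, s, e, u) for s, e, u in merged]


def mask_array(length: int, intervals: TSequence[MaskInterval]) -> np.ndarray:
    """Boolean per-position mask from intervals."""
    m = np.zeros(length, dtype=bool)
    for iv in intervals:
        m[iv.start:iv.end] = True
    return m


def microsat_density(seq, window: int = 128, **kwargs) -> np.ndarray:
    """Per-window masked-base fraction; the final partial window is
    normalised by its own length."""
    if window < 1:
        raise ValueError("window must be >= 1")
    bases = seq.bases if hasattr(seq, "bases") else str(seq)
    m = mask_array(len(bases), find_microsatellites(bases, **kwargs))
    out = []
    for i in range(0, len(bases), window):
        chunk = m[i:i + window]
        out.append(chunk.mean() if len(chunk) else 0.0)
    return np.array(out)
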