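"""Synthetic genome and read simulator with full ground truth.

The generator emulates the features of a repeat-rich haploid genome that
drive assembly difficulty: near-identical multi-kilobase repeat copies,
satellite-like tandem arrays, an rDNA-like array that is a mixture of
distinct unit variants ("morphs"), homopolymer-dense tracts, and GA-rich
tracts in which accurate-long-read coverage drops out.  Two read
technologies are simulated:

* HiFi-like: ~20 kbp reads at ~0.1% error, with >=80% of errors placed as
  +-1 length changes of existing homopolymer runs (the error mode that
  homopolymer compression neutralises), the remainder substitutions.
* ONT-like: >=100 kbp reads (log-normal lengths) at ~5% error, mixed
  substitutions and indels.

Everything is deterministic given ``(spec, seed)``, and every read carries
its true origin interval; the TruthSet additionally records the repeat-copy
walk, the rDNA morph table and the element layout, so that each assembly
stage can be verified against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .seqmodel import Read, Sequence, TruthInterval, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rand_seq(rng: np.random.Generator, n: int, p=None) -> str:
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def _mutate(rng: np.random.Generator, bases: str, rate: float) -> str:
    """Substitute each position independently with probability ``rate``."""
    if rate <= 0:
        return bases
    arr = np.frombuffer(bases.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


@dataclass
class RepeatSpec:
    """A dispersed repeat: ``copies`` near-identical copies of one master."""

    length: int
    copies: int = 2
    identity: float = 0.999  # pairwise identity of each copy to the master
    positions: Optional[list[int]] = None  # backbone offsets; auto if None


@dataclass
class SatelliteSpec:
    """A satellite-like tandem array of a short unit."""

    unit_len: int = 171
    copies: int = 20
    divergence: float = 0.01  # per-copy divergence from the consensus unit
    unit: Optional[str] = None


@dataclass
class RdnaSpec:
    """An rDNA-like tandem array: a shuffled mixture of unit morphs.

    ``copy_numbers[i]`` units of morph ``i`` are concatenated head-to-tail in
    a deterministic shuffled order.  Morphs are derived from one master unit
    at pairwise identity ``morph_identity``.
    """

    unit_len: int = 2000
    copy_numbers: tuple[int, ...] = (8, 4)
    morph_identity: float = 0.99
    shuffle: bool = True


@dataclass
class GenomeSpec:
    seed: int = 0
    backbone_len: int = 100_000
    repeats: list[RepeatSpec] = field(default_factory=list)
    satellites: list[SatelliteSpec] = field(default_factory=list)
    rdna: Optional[RdnaSpec] = None
    homopolymer_boost: float = 0.0  # per-base prob of run expansion
    ga_tract_lens: list[int] = field(default_factory=list)
    chrom_id: str = "sim"


@dataclass
class TruthSet:
    """Ground truth for a simulated genome."""

    genome: Sequence
    # ordered (label, start, end) layout of backbone segments and elements
    walk: list[tuple[str, int, int]]
    repeat_intervals: list[tuple[str, int, int]]
    rdna_interval: Optional[tuple[int, int]] = None
    rdna_unit_reference: Optional[str] = None
    morph_table: Optional[list[tuple[str, str, int]]] = None  # (id, seq, copies)
    morph_order: Optional[list[str]] = None
    ga_tracts: list[tuple[int, int]] = field(default_factory=list)


def _boost_homopolymers(rng: np.random.Generator, bases: str, rate: float) -> str:
    """Expand random positions into homopolymer runs (geometric lengths)."""
    if rate <= 0:
        return bases
    out = []
    for b in bases:
        if rng.random() < rate:
            out.append(b * (2 + int(rng.geometric(0.4))))
        else:
            out.append(b)
    return "".join(out)


def simulate_genome(spec: GenomeSpec) -> tuple[Sequence, TruthSet]:
    """Build the genome described by ``spec``; deterministic given its seed."""
    rng = np.random.default_rng(spec.seed)
    backbone = _rand_seq(rng, spec.backbone_len)
    if spec.homopolymer_boost > 0:
        backbone = _boost_homopolymers(rng, backbone, spec.homopolymer_boost)

    # Assemble the list of inserted elements (label, sequence).
    elements: list[tuple[str, str]] = []
    truth_morphs = None
    morph_order = None
    rdna_ref = None
    for ri, rep in enumerate(spec.repeats):
        master = _rand_seq(rng, rep.length)
        for c in range(rep.copies):
            copy = _mutate(rng, master, 1.0 - rep.identity)
            elements.append((f"repeat{ri}_copy{c}", copy))
    for si, sat in enumerate(spec.satellites):
        unit = sat.unit or _rand_seq(rng, sat.unit_len)
        arr = "".join(_mutate(rng, unit, sat.divergence) for _ in range(sat.copies))
        elements.append((f"satellite{si}", arr))
    if spec.rdna is not None:
        rd = spec.rdna
        rdna_ref = _rand_seq(rng, rd.unit_len)
        morphs = []
        for mi in range(len(rd.copy_numbers)):
            morphs.append((f"morph{mi}",
                           _mutate(rng, rdna_ref, 1.0 - rd.morph_identity)))
        order = [m for (m, _), n in zip(morphs, rd.copy_numbers) for _ in range(n)]
        if rd.shuffle:
            order = [order[i] for i in rng.permutation(len(order))]
        by_id = dict(morphs)
        elements.append(("rdna_array", "".join(by_id[m] for m in order)))
        truth_morphs = [(m, s, n) for (m, s), n in zip(morphs, rd.copy_numbers)]
        morph_order = order
    for gi, glen in enumerate(spec.ga_tract_lens):
        tract = "".join(rng.choice(["G", "A"], size=glen))
        elements.append((f"ga_tract{gi}", tract))

    # Place elements by repeat-spec positions or evenly across the backbone.
    k = len(elements)
    if k:
        step = len(backbone) // (k + 1)
        cuts = [step * (i + 1) for i in range(k)]
    else:
        cuts = []
    # override with explicit repeat positions where given
    pos_overrides = {}
    for ri, rep in enumerate(spec.repeats):
        if rep.positions is not None:
            for c, p in enumerate(rep.positions):
                pos_overrides[f"repeat{ri}_copy{c}"] = p
    order_idx = sorted(range(k),
                       key=lambda i: pos_overrides.get(elements[i][0], cuts[i]))
    cutpoints = sorted(pos_overrides.get(elements[i][0], cuts[i]) for i in range(k))
    if len(set(cutpoints)) != len(cutpoints):
        raise ValueError("element placements overlap: duplicate cut positions")

    pieces = []
    walk: list[tuple[str, int, int]] = []
    repeat_ivs: list[tuple[str, int, int]] = []
    rdna_iv = None
    ga_tracts: list[tuple[int, int]] = []
    prev = 0
    gpos = 0
    for j, idx in enumerate(order_idx):
        cut = cutpoints[j]
        seg = backbone[prev:cut]
        if seg:
            pieces.append(seg)
            walk.append((f"backbone{j}", gpos, gpos + len(seg)))
            gpos += len(seg)
        label, seq = elements[idx]
        pieces.append(seq)
        walk.append((label, gpos, gpos + len(seq)))
        if label.startswith("repeat"):
            repeat_ivs.append((label, gpos, gpos + len(seq)))
        elif label == "rdna_array":
            rdna_iv = (gpos, gpos + len(seq))
        elif label.startswith("ga_tract"):
            ga_tracts.append((gpos, gpos + len(seq)))
        gpos += len(seq)
        prev = cut
    tail = backbone[prev:]
    if tail:
        pieces.append(tail)
        walk.append((f"backbone{k}", gpos, gpos + len(tail)))
        gpos += len(tail)

    genome = Sequence(spec.chrom_id, "".join(pieces))
    truth = TruthSet(genome=genome, walk=walk, repeat_intervals=repeat_ivs,
                     rdna_interval=rdna_iv, rdna_unit_reference=rdna_ref,
                     morph_table=truth_morphs, morph_order=morph_order,
                     ga_tracts=ga_tracts)
    return genome, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _apply_hifi_errors(rng: np.random.Generator, bases: str, rate: float) -> str:
    """HiFi error model: >=80% homopolymer run-length +-1, rest substitutions."""
    n_err = rng.binomial(len(bases), rate)
    if n_err == 0:
        return bases
    chars = list(bases)
    # run starts for homopolymer targeting
    for _ in range(n_err):
        if rng.random() < 0.8:
            # expand/shrink the run containing a random position by one base
            i = int(rng.integers(len(chars)))
            if chars[i] == "":
                continue
            b = chars[i][0]
            if rng.random() < 0.5:
                chars[i] = chars[i] + b  # insertion into the run
            else:
                chars[i] = chars[i][1:]  # deletion from the run
        else:
            i = int(rng.integers(len(chars)))
            if chars[i] == "":
                continue
            cur = chars[i][0]
            alt = "ACGT".replace(cur, "")
            chars[i] = alt[rng.integers(3)] + chars[i][1:]
    return "".join(chars)


def _apply_ont_errors(rng: np.random.Generator, bases: str, rate: float) -> str:
    """ONT error model: i.i.d. per-base errors, 40% sub / 30% ins / 30% del."""
    if rate <= 0:
        return bases
    out = []
    errs = rng.random(len(bases)) < rate
    kinds = rng.random(len(bases))
    ins_bases = rng.integers(0, 4, size=len(bases))
    for i, b in enumerate(bases):
        if not errs[i]:
            out.append(b)
            continue
        k = kinds[i]
        if k < 0.4:  # substitution
            out.append("ACGT".replace(b, "")[ins_bases[i] % 3])
        elif k < 0.7:  # insertion
            out.append(b)
            out.append("ACGT"[ins_bases[i]])
        # else deletion: emit nothing
    return "".join(out)


def _overlaps_tract(start: int, end: int, tracts) -> bool:
    return any(start < te and ts < end for ts, te in tracts)


def simulate_hifi(genome: Sequence, depth: float, mean_len: int = 20_000,
                  error_rate: float = 0.001, ga_dropout: bool = False,
                  ga_tracts=(), dropout_prob: float = 0.9,
                  seed: int = 0, rng: Optional[np.random.Generator] = None
                  ) -> list[Read]:
    """Simulate HiFi-like reads at the requested mean depth.

    Lengths are normal(mean, 0.1*mean) truncated to [500, genome length];
    start points uniform.  When ``ga_dropout`` is on, candidate reads
    touching a GA-rich tract are suppressed with probability
    ``dropout_prob``, reproducing the coverage-gap phenotype of accurate
    long reads over GA-rich sequence.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    glen = len(genome)
    n = max(1, int(round(depth * glen / min(mean_len, glen))))
    reads = []
    min_tail = 500
    for i in range(n):
        ln = int(rng.normal(mean_len, 0.1 * mean_len))
        ln = max(500, min(ln, glen))
        # fragments may run off either end of the (telomere-to-telomere)
        # sequence and are clipped, so coverage holds up to the termini
        start = int(rng.integers(-(ln - min_tail), glen - min_tail + 1))
        end = min(start + ln, glen)
        start = max(start, 0)
        if ga_dropout and _overlaps_tract(start, end, ga_tracts):
            if rng.random() < dropout_prob:
                continue
        strand = "+" if rng.random() < 0.5 else "-"
        frag = genome.bases[start:end]
        if strand == "-":
            frag = revcomp(frag)
        frag = _apply_hifi_errors(rng, frag, error_rate)
        reads.append(Read(Sequence(f"hifi_{i}", frag), "hifi",
                          TruthInterval(genome.id, start, end, strand)))
    return reads


def simulate_ont(genome: Sequence, depth: float, mean_len: int = 100_000,
                 error_rate: float = 0.05, sigma: float = 0.5,
                 seed: int = 0, rng: Optional[np.random.Generator] = None
                 ) -> list[Read]:
    """Simulate ONT-like ultra-long reads (log-normal lengths, ~5% error)."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    glen = len(genome)
    mu = np.log(mean_len) - sigma ** 2 / 2.0
    reads = []
    total = 0
    target = depth * glen
    i = 0
    min_tail = 1000
    while total < target:
        ln = int(rng.lognormal(mu, sigma))
        ln = max(1000, min(ln, glen))
        start = int(rng.integers(-(ln - min_tail), glen - min_tail + 1))
        end = min(start + ln, glen)
        start = max(start, 0)
        ln = end - start
        strand = "+" if rng.random() < 0.5 else "-"
        frag = genome.bases[start:start + ln]
        if strand == "-":
            frag = revcomp(frag)
        frag = _apply_ont_errors(rng, frag, error_rate)
        reads.append(Read(Sequence(f"ont_{i}", frag), "ont",
                          TruthInterval(genome.id, start, start + ln, strand)))
        total += ln
        i += 1
    return reads


# ---------------------------------------------------------------------------
# Spec (de)serialisation
# ---------------------------------------------------------------------------

def spec_to_dict(spec: GenomeSpec) -> dict:
    return {
        "seed": spec.seed,
        "backbone_len": spec.backbone_len,
        "repeats": [{"length": r.length, "copies": r.copies,
                     "identity": r.identity, "positions": r.positions}
                    for r in spec.repeats],
        "satellites": [{"unit_len": s.unit_len, "copies": s.copies,
                        "divergence": s.divergence, "unit": s.unit}
                       for s in spec.satellites],
        "rdna": (None if spec.rdna is None else
                 {"unit_len": spec.rdna.unit_len,
                  "copy_numbers": list(spec.rdna.copy_numbers),
                  "morph_identity": spec.rdna.morph_identity,
                  "shuffle": spec.rdna.shuffle}),
        "homopolymer_boost": spec.homopolymer_boost,
        "ga_tract_lens": list(spec.ga_tract_lens),
        "chrom_id": spec.chrom_id,
    }


def spec_from_dict(d: dict) -> GenomeSpec:
    rd = d.get("rdna")
    return GenomeSpec(
        seed=d.get("seed", 0),
        backbone_len=d.get("backbone_len", 100_000),
        repeats=[RepeatSpec(**r) for r in d.get("repeats", [])],
        satellites=[SatelliteSpec(**s) for s in d.get("satellites", [])],
        rdna=None if rd is None else RdnaSpec(
            unit_len=rd.get("unit_len", 2000),
            copy_numbers=tuple(rd.get("copy_numbers", (8, 4))),
            morph_identity=rd.get("morph_identity", 0.99),
            shuffle=rd.get("shuffle", True)),
        homopolymer_boost=d.get("homopolymer_boost", 0.0),
        ga_tract_lens=list(d.get("ga_tract_lens", [])),
        chrom_id=d.get("chrom_id", "sim"))


def load_spec(path) -> GenomeSpec:
    """Read a GenomeSpec from a JSON config file."""
    import json
    with open(path) as fh:
        return spec_from_dict(json.load(fh))


def save_spec(spec: GenomeSpec, path) -> None:
    import json
    with open(path, "w") as fh:
        json.dump(spec_to_dict(spec), fh, indent=2)
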