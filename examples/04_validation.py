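"""Validate an assembly: contiguity, coverage uniformity, unique markers.

Shows the screening a finished assembly goes through: NG50 against a fixed
genome size, the mean +- 3 s.d. coverage band with issue flagging, and
unique k-mer marker density inside a near-identical repeat.
"""

import numpy as np

from hapasm import validate_stats as vs
from hapasm.protocols import coverage_trial
from hapasm.seqmodel import Sequence

# contiguity: contigs split at >= 3 consecutive Ns, NG50 vs genome size
assembly = [Sequence("chr1", "ACGT" * 5000 + "NNN" + "ACGT" * 2000)]
st = vs.assembly_stats(assembly, genome_size=28_000)
print(f"non-N bases: {st.total_nonN_bases:,}; contigs: {st.contig_count}; "
      f"NG50: {st.ng50:,}")

# coverage band: uniform 30x passes, an injected duplication is flagged
frac, _ = coverage_trial(seed=0)
print(f"uniform coverage: {100 * frac:.2f}% within 3 s.d. of the mean")
frac, issues = coverage_trial(seed=0, inject_duplication=True)
above = [i for i in issues if i.kind == "error"]
print(f"with a 2x duplicated region: {100 * frac:.2f}% in band; "
      f"{len(above)} above-band issue(s) at "
      f"{[(i.start, i.end) for i in above[:3]]}")

# unique markers vanish inside a two-copy repeat
rng = np.random.default_rng(3)
bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=2000)
rep = bases[500:900].tobytes().decode()
seq = bases.tobytes().decode() + rep  # second copy appended
markers, density = vs.unique_markers([Sequence("a", seq)], k=21)
inside = [p for p in markers["a"] if 520 <= p < 880 - 21]
print(f"markers genome-wide: {len(markers['a'])}; "
      f"inside the repeat interior: {len(inside)} (expected 0)")
# Low marker density is exactly what flags repeats where read placement
# needs marker-assisted assignment.
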