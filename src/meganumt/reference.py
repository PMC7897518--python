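"""Packaged mtDNA reference handling.

The human mitochondrial genome is a 16,569 bp circle; variants are reported
relative to the revised Cambridge Reference Sequence (rCRS).  The file shipped
with this package, ``data/rcrs_synthetic.fasta``, is a *synthetic stand-in*:
it has the correct length and carries the true rCRS allele at every curated
position listed in :data:`CURATED_BASES` (the positions touched by the bundled
fixtures, the common control-region hotspots and the 303-315 C-tract), while
all remaining positions are deterministic pseudo-random bases.  It is suitable
for coordinate arithmetic, IUPAC mixing of the bundled haplotypes and for
simulation; it is *not* the deposited NC_012920 sequence, and analyses of real
data should supply the genuine reference via the ``reference`` arguments
exposed throughout the API.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

MT_LENGTH = 16569

#: Positions (1-based rCRS) whose base in the packaged reference is the true
#: rCRS allele.  Sources: alleles implied by the bundled mixed/component
#: haplotypes (an IUPAC mixed call together with its resolved components pins
#: the reference base) and universally documented control-region positions.
CURATED_BASES: dict[int, str] = {
    72: "T", 73: "A", 146: "T", 152: "T", 189: "A", 195: "T", 200: "A",
    263: "A", 310: "T", 489: "T", 499: "G", 4580: "G",
    16093: "T", 16179: "C", 16189: "T", 16223: "C", 16298: "T",
    16311: "T", 16356: "T", 16362: "T", 16512: "T", 16519: "T",
    **{p: "C" for p in range(303, 310)},   # homopolymeric C-tract I
    **{p: "C" for p in range(311, 316)},   # C-tract II, insertions as 315.1C
}


@lru_cache(maxsize=1)
def load_reference() -> str:
    """Return the packaged synthetic rCRS stand-in as an upper-case string."""
    ref = resources.files("meganumt.data").joinpath("rcrs_synthetic.fasta")
    lines = ref.read_text().splitlines()
    seq = "".join(line.strip() for line in lines if not line.startswith(">"))
    if len(seq) != MT_LENGTH:
        raise ValueError(f"packaged reference has length {len(seq)}, expected {MT_LENGTH}")
    return seq.upper()


def reference_base(position: int, reference: str | None = None) -> str:
    """Base at a 1-based rCRS position (packaged reference by default)."""
    ref = reference if reference is not None else load_reference()
    if not 1 <= position <= len(ref):
        raise ValueError(f"position {position} outside 1..{len(ref)}")
    return ref[position - 1]
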