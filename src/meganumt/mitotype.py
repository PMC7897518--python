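"""Core data model for rCRS-relative mtDNA haplotypes ("mitotypes").

A mitotype is the list of differences between an observed mtDNA sequence and
the 16,569 bp circular reference, written in forensic (EMPOP-style)
nomenclature: substitutions as ``263G``, insertions as ``315.1C`` (first base
inserted after position 315), deletions as ``249DEL``.  Direct Sanger
sequencing of a two-source mixture produces *mixed* mitotypes in which
positions differing between the sources are called with IUPAC ambiguity codes
(``73R`` = A/G), exactly as a heteroplasmic sample would look.

Coordinates are 1-based inclusive on the circle; the control region is the
origin-spanning interval 16024-576.  Canonical listing order follows the
circular walk of the covered range (16179 ... 72 73 ... for control-region
data), matching forensic reporting conventions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

from .reference import MT_LENGTH, load_reference

__all__ = [
    "IUPAC_BASES", "CircularInterval", "Variant", "Mitotype",
    "CONTROL_REGION", "FULL_GENOME",
    "MitotypeError", "MitotypeParseError", "UnsupportedMixtureError",
    "parse_mitotype", "serialize_mitotype", "mix", "diff_positions",
    "apply_to_reference", "circular_length",
]

#: IUPAC nucleotide codes mapped to the set of bases each denotes.
IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_CODE_FOR: dict[frozenset[str], str] = {v: k for k, v in IUPAC_BASES.items()}

_TOKEN_RE = re.compile(r"^(\d+)(?:\.(\d+))?([ACGTRYSWKMBDHVN]|DEL|-)$", re.IGNORECASE)


class MitotypeError(ValueError):
    """Base class for mitotype model errors."""


class MitotypeParseError(MitotypeError):
    """Raised for malformed, out-of-range or duplicated variant tokens."""


class UnsupportedMixtureError(MitotypeError):
    """Raised when a two-source mixture cannot be written as one IUPAC string
    (indel present in only one component, or a deletion opposite a base)."""


@dataclass(frozen=True)
class CircularInterval:
    """Inclusive interval on a circular genome; wraps when start > end."""

    start: int
    end: int
    L: int = MT_LENGTH

    def __post_init__(self) -> None:
        for v in (self.start, self.end):
            if not 1 <= v <= self.L:
                raise ValueError(f"interval bound {v} outside 1..{self.L}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    @property
    def length(self) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return (self.L - self.start + 1) + self.end

    def offset(self, position: int) -> int | None:
        """0-based offset of *position* along the interval walk, or None."""
        off = (position - self.start) % self.L
        return off if off < self.length else None

    def __contains__(self, position: int) -> bool:
        return self.offset(position) is not None

    def positions(self) -> Iterator[int]:
        p = self.start
        for _ in range(self.length):
            yield p
            p = p % self.L + 1


CONTROL_REGION = CircularInterval(16024, 576)
FULL_GENOME = CircularInterval(1, MT_LENGTH)


def circular_length(iv: CircularInterval) -> int:
    """Inclusive length of a (possibly origin-spanning) interval in bp."""
    return iv.length


@dataclass(frozen=True)
class Variant:
    """One rCRS-relative difference.

    ``insertion_index`` is 0 for substitutions/deletions and k >= 1 for the
    k-th base inserted after ``position`` (``315.1C``).  ``observed`` is a
    single IUPAC character, or ``-`` for a deletion.
    """

    position: int
    observed: str
    insertion_index: int = 0
    kind: str = field(init=False)

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_LENGTH:
            raise MitotypeError(f"position {self.position} outside 1..{MT_LENGTH}")
        if self.insertion_index < 0:
            raise MitotypeError("insertion_index must be >= 0")
        obs = self.observed.upper()
        object.__setattr__(self, "observed", obs)
        if obs == "-":
            if self.insertion_index:
                raise MitotypeError("deletions cannot carry an insertion index")
            kind = "deletion"
        elif obs in IUPAC_BASES:
            kind = "insertion" if self.insertion_index else "substitution"
        else:
            raise MitotypeError(f"invalid observed character {self.observed!r}")
        object.__setattr__(self, "kind", kind)

    @property
    def key(self) -> tuple[int, int]:
        return (self.position, self.insertion_index)

    @property
    def is_ambiguous(self) -> bool:
        """True iff the observed IUPAC code denotes two or more bases."""
        return self.observed != "-" and len(IUPAC_BASES[self.observed]) >= 2

    @property
    def bases(self) -> frozenset[str]:
        if self.kind == "deletion":
            raise MitotypeError("deletion has no base set")
        return IUPAC_BASES[self.observed]

    def token(self) -> str:
        if self.kind == "deletion":
            return f"{self.position}DEL"
        if self.kind == "insertion":
            return f"{self.position}.{self.insertion_index}{self.observed}"
        return f"{self.position}{self.observed}"

    @classmethod
    def from_token(cls, token: str) -> "Variant":
        m = _TOKEN_RE.match(token.strip())
        if m is None:
            raise MitotypeParseError(f"malformed variant token {token!r}")
        pos = int(m.group(1))
        idx = int(m.group(2)) if m.group(2) else 0
        obs = m.group(3).upper()
        if obs == "DEL":
            obs = "-"
        if obs == "-" and idx:
            raise MitotypeParseError(f"deletion token {token!r} cannot have an insertion index")
        try:
            return cls(position=pos, observed=obs, insertion_index=idx)
        except MitotypeError as exc:
            raise MitotypeParseError(f"invalid token {token!r}: {exc}") from exc

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token()


def _sort_key(v: Variant, covered: Sequence[CircularInterval]) -> tuple[int, int, int]:
    for i, iv in enumerate(covered):
        off = iv.offset(v.position)
        if off is not None:
            return (i, off, v.insertion_index)
    raise MitotypeError(f"variant {v.token()} outside covered range")


@dataclass(frozen=True)
class Mitotype:
    """An ordered, validated set of variants over a covered range."""

    variants: tuple[Variant, ...] = ()
    covered_range: tuple[CircularInterval, ...] = (CONTROL_REGION,)
    label: str = ""

    def __post_init__(self) -> None:
        covered = tuple(self.covered_range)
        ordered = tuple(sorted(self.variants, key=lambda v: _sort_key(v, covered)))
        seen: set[tuple[int, int]] = set()
        for v in ordered:
            if v.key in seen:
                raise MitotypeError(f"duplicate record at position {v.position}"
                                    + (f".{v.insertion_index}" if v.insertion_index else ""))
            seen.add(v.key)
        object.__setattr__(self, "variants", ordered)
        object.__setattr__(self, "covered_range", covered)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.variants)

    def get(self, position: int, insertion_index: int = 0) -> Variant | None:
        for v in self.variants:
            if v.key == (position, insertion_index):
                return v
        return None

    @property
    def is_ambiguous(self) -> bool:
        return any(v.is_ambiguous for v in self.variants)

    @property
    def ambiguous_variants(self) -> tuple[Variant, ...]:
        return tuple(v for v in self.variants if v.is_ambiguous)

    def same_range(self, other: "Mitotype") -> bool:
        return self.covered_range == other.covered_range

    def with_label(self, label: str) -> "Mitotype":
        return replace(self, label=label)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Mitotype):
            return NotImplemented
        return (self.variants, self.covered_range) == (other.variants, other.covered_range)

    def __hash__(self) -> int:
        return hash((self.variants, self.covered_range))

    def __str__(self) -> str:
        return serialize_mitotype(self)


def parse_mitotype(
    text: str,
    covered_range: Sequence[CircularInterval] = (CONTROL_REGION,),
    label: str = "",
) -> Mitotype:
    """Parse a whitespace-separated variant string into a canonical Mitotype.

    An empty string denotes a sequence identical to the reference over the
    covered range.  Errors name the offending token.
    """
    covered = tuple(covered_range)
    variants: list[Variant] = []
    seen: set[tuple[int, int]] = set()
    for token in text.split():
        v = Variant.from_token(token)
        if not any(v.position in iv for iv in covered):
            raise MitotypeParseError(f"token {token!r}: position {v.position} outside covered range")
        if v.key in seen:
            raise MitotypeParseError(f"duplicate token {token!r}")
        seen.add(v.key)
        variants.append(v)
    return Mitotype(tuple(variants), covered, label)


def serialize_mitotype(m: Mitotype) -> str:
    """Canonical space-separated string; inverse of :func:`parse_mitotype`."""
    return " ".join(v.token() for v in m.variants)


def diff_positions(a: Mitotype, b: Mitotype) -> list[tuple[int, int]]:
    """(position, insertion_index) keys at which two mitotypes differ.

    Symmetric; a record present in one and absent in the other counts.
    """
    if not a.same_range(b):
        raise MitotypeError("mitotypes cover different ranges")
    ra = {v.key: v.observed for v in a.variants}
    rb = {v.key: v.observed for v in b.variants}
    keys = {k for k in ra.keys() | rb.keys() if ra.get(k) != rb.get(k)}
    dummy = [Variant(p, "N", i) if i else Variant(p, "N") for p, i in keys]
    dummy.sort(key=lambda v: _sort_key(v, a.covered_range))
    return [v.key for v in dummy]


def mix(a: Mitotype, b: Mitotype, reference: str | None = None) -> Mitotype:
    """Superpose two unambiguous haplotypes into the mixed mitotype a Sanger
    trace of their mixture would show (above detection threshold).

    Positions where the haplotypes differ become the IUPAC code covering both
    alleles; where one haplotype carries no record its allele is the reference
    base.  ``mix(h, h) == h``.  Indels private to one component cannot be
    encoded on a single sequence string and raise
    :class:`UnsupportedMixtureError`.
    """
    if not a.same_range(b):
        raise MitotypeError("mitotypes cover different ranges")
    ref = reference if reference is not None else load_reference()
    ra = {v.key: v for v in a.variants}
    rb = {v.key: v for v in b.variants}
    out: list[Variant] = []
    for key in ra.keys() | rb.keys():
        pos, idx = key
        va, vb = ra.get(key), rb.get(key)
        for v in (va, vb):
            if v is not None and v.is_ambiguous:
                raise MitotypeError(f"component variant {v.token()} is ambiguous; components must be resolved haplotypes")
        if idx == 0:
            if (va and va.kind == "deletion") or (vb and vb.kind == "deletion"):
                if va and vb and va.observed == vb.observed == "-":
                    out.append(Variant(pos, "-"))
                    continue
                raise UnsupportedMixtureError(
                    f"deletion at {pos} in one component only cannot be IUPAC-encoded")
            base_a = va.observed if va else ref[pos - 1]
            base_b = vb.observed if vb else ref[pos - 1]
            alleles = frozenset({base_a, base_b})
            code = _CODE_FOR[alleles]
            if code != ref[pos - 1]:
                out.append(Variant(pos, code))
        else:
            if va is None or vb is None:
                present = (va or vb).token()
                raise UnsupportedMixtureError(
                    f"insertion {present} present in one component only cannot be IUPAC-encoded")
            alleles = frozenset({va.observed, vb.observed})
            out.append(Variant(pos, _CODE_FOR[alleles], idx))
    return Mitotype(tuple(out), a.covered_range)


def apply_to_reference(
    m: Mitotype,
    reference: str | None = None,
    expand_ambiguous: bool = False,
) -> str:
    """Reconstruct the haplotype sequence over the covered range.

    Output length equals covered length + #insertions - #deletions.  Ambiguous
    variants raise unless ``expand_ambiguous`` is set, in which case IUPAC
    characters are emitted verbatim.
    """
    ref = reference if reference is not None else load_reference()
    if m.is_ambiguous and not expand_ambiguous:
        raise MitotypeError("mitotype contains IUPAC mixed bases; resolve by "
                            "deconvolution or pass expand_ambiguous=True")
    subs = {v.position: v for v in m.variants if v.insertion_index == 0}
    inserts: dict[int, list[Variant]] = {}
    for v in m.variants:
        if v.insertion_index:
            inserts.setdefault(v.position, []).append(v)
    for vs in inserts.values():
        vs.sort(key=lambda v: v.insertion_index)
    chunks: list[str] = []
    for iv in m.covered_range:
        for pos in iv.positions():
            v = subs.get(pos)
            if v is None:
                chunks.append(ref[pos - 1])
            elif v.kind == "deletion":
                pass
            else:
                chunks.append(v.observed)
            for ins in inserts.get(pos, ()):
                chunks.append(ins.observed)
    return "".join(chunks)
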