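"""Haplogroup motif tables and plausibility scoring.

Human mtDNA haplogroups (hg) are clades of the mitochondrial phylogeny, each
defined by the cumulative set of signature variants accumulated along the path
from the phylogeny root.  This module holds a minimal motif-table container
(loadable from TSV, so a full published phylogeny can be supplied by the user)
and a concrete, monotone plausibility score used to rank haplogroup
assignments of an unambiguous mitotype.

Scoring: with hotspot positions masked, let E be the clade's cumulative motif
restricted to the mitotype's covered range and O the observed variants.  Then

    score = |E ∩ O| / (|E| + 0.5 * |O \\ E|)

i.e. the matched fraction of expected motif variants with a half-weight
penalty per private (unexpected) variant.  A clade with an empty expected set
scores 1 on an empty observation (vacuous match) and 0 otherwise.  This score
is deliberately simple and reproducible; it does not replicate any published
haplogrouping tool.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .mitotype import Mitotype, MitotypeError, Variant

__all__ = [
    "DEFAULT_HOTSPOTS", "MotifTable", "HgScore",
    "load_motif_table", "builtin_motif_table", "assign_haplogroup",
]

#: Positions masked from scoring by default: 263 and the 309/310/315 C-tract
#: indels occur in virtually every non-reference mitotype and carry no
#: phylogenetic signal at this resolution.  16519 is *not* masked: it is a
#: signature variant of the bundled U4c1 motif.
DEFAULT_HOTSPOTS: frozenset[int] = frozenset({263, 309, 310, 315})

ROOT = "root"


class MotifTableError(ValueError):
    """Raised for malformed or cyclic motif tables."""


@dataclass(frozen=True)
class HgScore:
    haplogroup: str
    score: float
    matches: int
    missing: int
    private: int
    depth: int

    def as_dict(self) -> dict:
        return {
            "haplogroup": self.haplogroup, "score": round(self.score, 6),
            "matches": self.matches, "missing": self.missing,
            "private": self.private, "depth": self.depth,
        }


@dataclass
class MotifTable:
    """Haplogroup -> (parent, defining variants), with acyclic parent links."""

    entries: dict[str, tuple[str | None, frozenset[Variant]]] = field(default_factory=dict)
    _motif_cache: dict[str, frozenset[Variant]] = field(
        default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name, (parent, _) in self.entries.items():
            if parent == name:
                raise MotifTableError(f"haplogroup {name!r} is its own parent")
            if parent is not None and parent not in self.entries:
                raise MotifTableError(f"haplogroup {name!r} references unknown parent {parent!r}")
        for name in self.entries:
            self._path(name)  # raises on cycles

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def names(self) -> list[str]:
        return sorted(self.entries)

    def _path(self, name: str) -> list[str]:
        path, cur = [], name
        seen: set[str] = set()
        while cur is not None:
            if cur in seen:
                raise MotifTableError(f"cyclic parent links at haplogroup {cur!r}")
            seen.add(cur)
            path.append(cur)
            cur = self.entries[cur][0]
        return path[::-1]

    def depth(self, name: str) -> int:
        return len(self._path(name)) - 1

    def cumulative_motif(self, name: str) -> frozenset[Variant]:
        """Union of defining variants along the root -> clade path."""
        cached = self._motif_cache.get(name)
        if cached is None:
            out: set[Variant] = set()
            for hg in self._path(name):
                out |= self.entries[hg][1]
            cached = self._motif_cache[name] = frozenset(out)
        return cached


def _parse_motif_variants(tokens: str, context: str) -> frozenset[Variant]:
    out = []
    for tok in tokens.split():
        try:
            out.append(Variant.from_token(tok))
        except MitotypeError as exc:
            raise MotifTableError(f"{context}: {exc}") from exc
    return frozenset(out)


def load_motif_table(path: str | Path) -> MotifTable:
    """Load a motif table from TSV columns haplogroup, parent, variants."""
    entries: dict[str, tuple[str | None, frozenset[Variant]]] = {}
    with open(path, newline="") as fh:
        rows = [r for r in csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t") if r.get("haplogroup")]
    for row in rows:
        name = row["haplogroup"].strip()
        parent = (row.get("parent") or "").strip() or None
        variants = _parse_motif_variants(row.get("variants") or "", f"haplogroup {name!r}")
        if name in entries:
            raise MotifTableError(f"duplicate haplogroup {name!r}")
        entries[name] = (parent, variants)
    return MotifTable(entries)


@lru_cache(maxsize=1)
def builtin_motif_table() -> MotifTable:
    """The packaged table: root, HV0, V (child of HV0, coding-region defining
    variant) and U4c1, transcribed from the bundled case haplotypes with the
    universal hotspots removed."""
    with resources.as_file(resources.files("meganumt.data").joinpath("motifs_builtin.tsv")) as p:
        return load_motif_table(p)


def assign_haplogroup(
    m: Mitotype,
    table: MotifTable,
    hotspot_mask: frozenset[int] | set[int] = DEFAULT_HOTSPOTS,
) -> list[HgScore]:
    """Rank all haplogroups of *table* for an unambiguous mitotype.

    Ordering: score descending, then clade depth descending (prefer the most
    derived clade on ties), then name.  Mixed mitotypes must be deconvolved
    first and raise here.
    """
    if m.is_ambiguous:
        raise MitotypeError(
            "mitotype contains IUPAC mixed bases; run two-source deconvolution "
            "before haplogroup assignment")
    mask = frozenset(hotspot_mask)
    observed = frozenset(v for v in m.variants if v.position not in mask)
    results: list[HgScore] = []
    for name in table.names():
        expected = frozenset(
            v for v in table.cumulative_motif(name)
            if v.position not in mask and any(v.position in iv for iv in m.covered_range))
        matches = len(expected & observed)
        missing = len(expected - observed)
        private = len(observed - expected)
        if expected:
            score = matches / (len(expected) + 0.5 * private)
        else:
            score = 1.0 if private == 0 else 0.0
        results.append(HgScore(name, score, matches, missing, private, table.depth(name)))
    results.sort(key=lambda s: (-s.score, -s.depth, s.haplogroup))
    return results
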