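"""Tissue-contrast source classification and pedigree segregation checks.

The decisive observation separating a nuclear insert from genuine mtDNA
heteroplasmy is the contrast across cell classes: nucleated cells carry both
nuclear and mitochondrial genomes, anucleate cells (thrombocytes, hair
shafts) carry essentially only mtDNA, and mtDNA-depleted (rho0) cells carry
only nuclear DNA.  A minor mitotype component that vanishes in anucleate
cells and is the *only* signal in rho0 cells is nuclear; one that persists in
anucleate cells at the tissue fraction is mitochondrial in origin (which
covers both heteroplasmy and paternal leakage — they are not distinguishable
here).

A nuclear insert must additionally segregate through the pedigree as an
autosomal dominant allele, independent of the matriline along which genuine
mtDNA travels; both checks are implemented below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .mitotype import Mitotype

__all__ = [
    "Observation", "SourceCall", "Pedigree", "SegregationReport",
    "NUCLEAR_NUMT", "MT_HETEROPLASMY", "INCONCLUSIVE", "CONTAMINATION_SUSPECTED",
    "classify_minor_source", "check_segregation", "check_matriline",
]

NUCLEAR_NUMT = "NUCLEAR_NUMT"
MT_HETEROPLASMY = "MT_HETEROPLASMY"
INCONCLUSIVE = "INCONCLUSIVE"
CONTAMINATION_SUSPECTED = "CONTAMINATION_SUSPECTED"

CARRIER = "carrier"
NON_CARRIER = "non_carrier"
UNKNOWN = "unknown"

TISSUES = ("blood", "buccal", "bone", "intestinal", "hair_root", "hair_shaft",
           "thrombocyte", "pbmc", "rho0_fibroblast", "other")
ASSAYS = ("direct_sanger", "clone", "single_cell", "mps")
CALLS = ("major_only", "minor_only", "mixed", "none")

#: Fixed tissue -> cell-class lookup.  Thrombocytes lack nuclei entirely and
#: hair shafts retain only trace degraded nDNA; both behave as mtDNA-only.
TISSUE_CELL_CLASS: dict[str, str] = {
    **{t: "nucleated" for t in TISSUES},
    "thrombocyte": "anucleate",
    "hair_shaft": "anucleate",
    "rho0_fibroblast": "mtDNA_depleted",
}


class EvidenceError(ValueError):
    """Raised for invalid observation sets or pedigrees."""


@dataclass(frozen=True)
class Observation:
    """One sequencing observation; ``n`` > 1 denotes a batch of identical calls."""

    individual_id: str
    tissue: str
    assay: str
    call: str
    n: int = 1
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.tissue not in TISSUE_CELL_CLASS:
            raise EvidenceError(f"unknown tissue {self.tissue!r}")
        if self.assay not in ASSAYS:
            raise EvidenceError(f"unknown assay {self.assay!r}")
        if self.call not in CALLS:
            raise EvidenceError(f"unknown call {self.call!r}")
        if self.n < 1:
            raise EvidenceError("n must be >= 1")

    @property
    def cell_class(self) -> str:
        return TISSUE_CELL_CLASS[self.tissue]


@dataclass(frozen=True)
class SourceCall:
    verdict: str
    evidence: tuple[dict, ...]
    note: str = ""

    def as_dict(self) -> dict:
        return {"verdict": self.verdict, "evidence": list(self.evidence), "note": self.note}


def classify_minor_source(
    observations: Sequence[Observation],
    min_anucleate: int = 10,
    anucleate_mixed_tolerance: float = 0.05,
) -> SourceCall:
    """Classify the cellular source of the minor mitotype component.

    Rules, in order:

    R0  any negative-control observation with a call other than ``none``
        voids the run (CONTAMINATION_SUSPECTED);
    R1  nucleated tissues show the mixture, at least ``min_anucleate``
        anucleate observations exist, the fraction of anucleate observations
        showing the minor component is within tolerance (allowing e.g. a
        single hair shaft with nuclear remnants), and any mtDNA-depleted
        observations show *only* the minor component -> NUCLEAR_NUMT;
    R2  anucleate observations carry the minor component above tolerance
        -> MT_HETEROPLASMY (mitochondrial in origin; heteroplasmy and
        paternal leakage are confounded at this level);
    otherwise INCONCLUSIVE.

    Nucleated tissues "show the mixture" if any call is ``mixed`` or if
    count-based assays (clones, single cells) yield both major-only and
    minor-only calls.
    """
    obs = list(observations)
    if not obs:
        raise EvidenceError("at least one observation is required")
    evidence: list[dict] = []

    contaminated = sum(o.n for o in obs if o.is_control and o.call != "none")
    evidence.append({"rule": "R0_controls_clean", "satisfied": contaminated == 0,
                     "contaminated_controls": contaminated})
    if contaminated:
        return SourceCall(CONTAMINATION_SUSPECTED, tuple(evidence),
                          note="negative controls yielded sequence; rerun required")

    samples = [o for o in obs if not o.is_control]
    nucleated = [o for o in samples if o.cell_class == "nucleated"]
    if not nucleated:
        raise EvidenceError("no nucleated-tissue observations: mixture status undeterminable")

    n_mixed_nuc = sum(o.n for o in nucleated if o.call == "mixed")
    has_both_counts = (any(o.call == "major_only" for o in nucleated)
                       and any(o.call == "minor_only" for o in nucleated))
    nucleated_mixture = n_mixed_nuc > 0 or has_both_counts
    evidence.append({"rule": "R1_nucleated_mixture", "satisfied": nucleated_mixture,
                     "mixed_calls": n_mixed_nuc})

    anucleate = [o for o in samples if o.cell_class == "anucleate"]
    n_anuc = sum(o.n for o in anucleate)
    n_anuc_minor = sum(o.n for o in anucleate if o.call in ("mixed", "minor_only"))
    frac = n_anuc_minor / n_anuc if n_anuc else None
    evidence.append({"rule": "R1_anucleate_contrast",
                     "satisfied": n_anuc >= min_anucleate and frac is not None
                     and frac <= anucleate_mixed_tolerance,
                     "n_anucleate": n_anuc, "n_anucleate_minor": n_anuc_minor,
                     "fraction": frac})

    depleted = [o for o in samples if o.cell_class == "mtDNA_depleted"]
    depleted_ok = all(o.call == "minor_only" for o in depleted)
    evidence.append({"rule": "R1_depleted_minor_only",
                     "satisfied": depleted_ok,
                     "n_depleted": sum(o.n for o in depleted)})

    if (nucleated_mixture and n_anuc >= min_anucleate
            and frac is not None and frac <= anucleate_mixed_tolerance and depleted_ok):
        return SourceCall(NUCLEAR_NUMT, tuple(evidence),
                          note="minor component absent from anucleate cells"
                          + ("; exclusive in mtDNA-depleted cells" if depleted else ""))
    if frac is not None and frac > anucleate_mixed_tolerance:
        evidence.append({"rule": "R2_anucleate_minor", "satisfied": True, "fraction": frac})
        return SourceCall(MT_HETEROPLASMY, tuple(evidence),
                          note="minor component persists in anucleate cells; "
                          "mitochondrial origin (heteroplasmy or paternal leakage)")
    return SourceCall(INCONCLUSIVE, tuple(evidence),
                      note="insufficient anucleate evidence for a source call")


@dataclass(frozen=True)
class Individual:
    sex: str | None = None  # "M" | "F" | None
    mother: str | None = None
    father: str | None = None


@dataclass
class Pedigree:
    """Individuals with parent links and per-individual carrier status for a
    candidate autosomal (nuclear-insert) allele."""

    individuals: dict[str, Individual] = field(default_factory=dict)
    carrier_status: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for iid, ind in self.individuals.items():
            for parent, want_sex in ((ind.mother, "F"), (ind.father, "M")):
                if parent is None:
                    continue
                if parent not in self.individuals:
                    raise EvidenceError(f"{iid}: unknown parent {parent!r}")
                psex = self.individuals[parent].sex
                if psex is not None and psex != want_sex:
                    raise EvidenceError(f"{iid}: parent {parent!r} has sex {psex}, expected {want_sex}")
        for iid, status in self.carrier_status.items():
            if iid not in self.individuals:
                raise EvidenceError(f"status for unknown individual {iid!r}")
            if status not in (CARRIER, NON_CARRIER, UNKNOWN):
                raise EvidenceError(f"invalid carrier status {status!r}")
        # parent links must be acyclic
        g = nx.DiGraph()
        g.add_nodes_from(self.individuals)
        for iid, ind in self.individuals.items():
            for parent in (ind.mother, ind.father):
                if parent is not None:
                    g.add_edge(parent, iid)
        if not nx.is_directed_acyclic_graph(g):
            raise EvidenceError("pedigree parent links contain a cycle")

    def status(self, iid: str) -> str:
        return self.carrier_status.get(iid, UNKNOWN)

    def children(self, iid: str) -> list[str]:
        return [c for c, ind in self.individuals.items() if iid in (ind.mother, ind.father)]

    def relationship_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.individuals)
        for iid, ind in self.individuals.items():
            for parent in (ind.mother, ind.father):
                if parent is not None:
                    g.add_edge(parent, iid)
        return g


@dataclass(frozen=True)
class SegregationReport:
    consistent: bool
    conflicts: tuple[dict, ...]
    obligate_carriers: tuple[str, ...]
    transmissions: tuple[int, int]  # (transmitted, opportunities)

    def as_dict(self) -> dict:
        return {"consistent": self.consistent, "conflicts": list(self.conflicts),
                "obligate_carriers": list(self.obligate_carriers),
                "transmissions": {"transmitted": self.transmissions[0],
                                  "opportunities": self.transmissions[1]}}


def check_segregation(p: Pedigree) -> SegregationReport:
    """Check autosomal-dominant segregation of the insert allele.

    A conflict is a typed carrier whose parents are *both* present and typed
    non-carrier (unknown status never counts as non-carrier).  Obligate
    carriers are unknown-status individuals lying on every relationship path
    between two typed carriers.  The transmission tally counts
    carrier-parent -> typed-child pairs and how many transmitted.
    """
    conflicts: list[dict] = []
    for iid, ind in p.individuals.items():
        if p.status(iid) != CARRIER:
            continue
        if ind.mother is None or ind.father is None:
            continue
        if p.status(ind.mother) == NON_CARRIER and p.status(ind.father) == NON_CARRIER:
            conflicts.append({"individual": iid,
                              "mother": ind.mother, "father": ind.father,
                              "reason": "carrier child of two typed non-carrier parents"})

    carriers = [i for i in p.individuals if p.status(i) == CARRIER]
    g = p.relationship_graph()
    obligate: list[str] = []
    for iid in sorted(p.individuals):
        if p.status(iid) != UNKNOWN:
            continue
        h = g.copy()
        h.remove_node(iid)
        for a, b in ((a, b) for i, a in enumerate(carriers) for b in carriers[i + 1:]):
            if nx.has_path(g, a, b) and not nx.has_path(h, a, b):
                obligate.append(iid)
                break

    transmitted = opportunities = 0
    for iid, ind in p.individuals.items():
        if p.status(iid) == UNKNOWN:
            continue
        for parent in (ind.mother, ind.father):
            if parent is not None and p.status(parent) == CARRIER:
                opportunities += 1
                if p.status(iid) == CARRIER:
                    transmitted += 1
    return SegregationReport(not conflicts, tuple(conflicts), tuple(obligate),
                             (transmitted, opportunities))


def check_matriline(
    p: Pedigree,
    true_mitotypes: Mapping[str, Mitotype],
) -> list[dict]:
    """Violations of strict maternal mtDNA inheritance: every individual whose
    (unambiguous) mitotype differs from their mother's.  Individuals with a
    missing mother or missing mitotype are skipped."""
    violations: list[dict] = []
    for iid in sorted(p.individuals):
        mother = p.individuals[iid].mother
        if mother is None:
            continue
        child_mt, mother_mt = true_mitotypes.get(iid), true_mitotypes.get(mother)
        if child_mt is None or mother_mt is None:
            continue
        if child_mt.is_ambiguous or mother_mt.is_ambiguous:
            raise EvidenceError(f"matriline check requires unambiguous mitotypes ({iid}/{mother})")
        if child_mt != mother_mt:
            violations.append({"individual": iid, "mother": mother,
                               "individual_mitotype": str(child_mt),
                               "mother_mitotype": str(mother_mt)})
    return violations
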