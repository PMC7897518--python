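"""Quantification targets, digital/real-time PCR copy estimation and the
template-topology amplification test.

The tandem copy number of a Mega-NUMT is estimated from mtDNA-depleted (rho0)
cells, where every mtDNA-like template is nuclear: the ratio of an mtDNA-like
target concentration to a single-copy autosomal target concentration, times
the ploidy of the cells, gives mitogenome copies per (heterozygous) insert.
ddPCR concentrations follow the standard Poisson estimator on the negative
droplet fraction, lambda = -ln(1 - p_positive).

The insert's physical size follows as copies x 16,569 bp, and the topology
test formalises the long-range PCR argument: two overlapping amplicons that
jointly wrap the circle can both amplify from a circular template or a tandem
repeat of the full mitogenome, but never both from a single linearised unit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from statistics import mean, stdev
from typing import Iterable, Mapping, Sequence

from .mitotype import CircularInterval, circular_length
from .reference import MT_LENGTH

__all__ = [
    "QuantTarget", "DropletAssay", "QuantRecord", "CopyEstimate",
    "CircularTemplate", "LinearSingleUnit", "TandemRepeat",
    "default_targets", "ddpcr_lambda", "ddpcr_concentration",
    "copies_per_numt", "aggregate_copies", "copies_from_quant_records",
    "insert_size", "template_supports",
]

MT_LIKE = "mt_like"
SINGLE_COPY_AUTOSOMAL = "single_copy_autosomal"
MULTI_COPY_AUTOSOMAL = "multi_copy_autosomal"


class QuantError(ValueError):
    """Raised for invalid quantification inputs."""


@dataclass(frozen=True)
class QuantTarget:
    """One amplification target.  mtDNA-like targets use circular chrM
    coordinates; autosomal targets are linear.  Multi-copy autosomal targets
    (Alu, RNU2) support relative quantification only."""

    name: str
    chromosome: str
    start: int | None = None
    end: int | None = None
    copy_class: str = MT_LIKE
    note: str = ""

    def __post_init__(self) -> None:
        if self.copy_class not in (MT_LIKE, SINGLE_COPY_AUTOSOMAL, MULTI_COPY_AUTOSOMAL):
            raise QuantError(f"unknown copy class {self.copy_class!r}")
        if self.copy_class == MT_LIKE and self.chromosome != "chrM":
            raise QuantError("mt_like targets must lie on chrM")

    @property
    def length(self) -> int | None:
        """Inclusive amplicon length in bp (None if coordinates unknown)."""
        if self.start is None or self.end is None:
            return None
        if self.chromosome == "chrM":
            return circular_length(CircularInterval(self.start, self.end))
        return self.end - self.start + 1

    @property
    def interval(self) -> CircularInterval | None:
        if self.chromosome != "chrM" or self.start is None:
            return None
        return CircularInterval(self.start, self.end)


def default_targets() -> dict[str, QuantTarget]:
    """The packaged assay-target registry: four mtDNA-like amplicons, the
    single-copy autosomal reference ND14 and two multi-copy autosomal
    targets used for relative gDNA quantification."""
    targets = [
        QuantTarget("ND1", "chrM", 3485, 3553, MT_LIKE),
        QuantTarget("KAV", "chrM", 13288, 13392, MT_LIKE),
        QuantTarget("BATZ", "chrM", 8446, 8524, MT_LIKE),
        QuantTarget("AND", "chrM", 8294, 8436, MT_LIKE,
                    note="co-amplified with a chr1:633463-633605 companion site"),
        QuantTarget("ND14", "chr14", 94841905, 94842013, SINGLE_COPY_AUTOSOMAL),
        QuantTarget("RNU2", "chr17", None, None, MULTI_COPY_AUTOSOMAL),
        QuantTarget("AluYb8", "genome-wide", None, None, MULTI_COPY_AUTOSOMAL,
                    note="~71 bp consensus amplicon"),
    ]
    return {t.name: t for t in targets}


@dataclass(frozen=True)
class DropletAssay:
    """One ddPCR well: droplet partition counts for a single target."""

    target: QuantTarget
    n_droplets: int
    n_positive: int
    droplet_volume_nl: float = 0.85
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise QuantError("n_droplets must be positive")
        if not 0 <= self.n_positive <= self.n_droplets:
            raise QuantError("need 0 <= n_positive <= n_droplets")
        if self.droplet_volume_nl <= 0 or self.dilution <= 0:
            raise QuantError("droplet volume and dilution must be positive")


def ddpcr_lambda(assay: DropletAssay) -> float:
    """Mean template copies per droplet via the Poisson estimator.

    A fully positive well is saturated and carries no upper bound on the
    concentration; it is an error rather than an estimate.
    """
    if assay.n_positive == assay.n_droplets:
        raise QuantError("all droplets positive: assay saturated, dilute and repeat")
    p = assay.n_positive / assay.n_droplets
    return -math.log1p(-p)


def ddpcr_concentration(assay: DropletAssay) -> float:
    """Template concentration in the undiluted sample, copies per nL."""
    return ddpcr_lambda(assay) / assay.droplet_volume_nl * assay.dilution


def copies_per_numt(
    ratio_mt_to_autosomal: float,
    ploidy: int = 2,
    residual_mt_fraction: float = 0.0,
) -> float:
    """Mitogenome copies per insert allele from one mt:autosomal ratio.

    The single-copy autosomal target counts one copy per haploid genome, so a
    heterozygous carrier's ratio is multiplied by the ploidy.  If a known
    fraction of the mt-like signal stems from residual genuine mtDNA in an
    imperfect rho0 preparation, it is removed first.
    """
    if ratio_mt_to_autosomal < 0:
        raise QuantError("ratio must be non-negative")
    if ploidy < 1:
        raise QuantError("ploidy must be >= 1")
    if not 0.0 <= residual_mt_fraction < 1.0:
        raise QuantError("residual_mt_fraction must lie in [0, 1)")
    return ratio_mt_to_autosomal * (1.0 - residual_mt_fraction) * ploidy


@dataclass(frozen=True)
class CopyEstimate:
    copies_per_numt: float
    sd: float
    n: int
    per_target: Mapping[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "copies_per_numt": round(self.copies_per_numt, 4),
            "sd": round(self.sd, 4), "n": self.n,
            "per_target": {k: round(v, 4) for k, v in self.per_target.items()},
        }


def aggregate_copies(
    replicate_ratios: Sequence[float],
    ploidy: int = 2,
    residual_mt_fraction: float = 0.0,
    per_target: Mapping[str, float] | None = None,
) -> CopyEstimate:
    """Per-replicate copy values summarised as mean +/- sample SD (ddof 1).

    Copies are computed replicate by replicate and then averaged, so the
    reported SD is the replicate scatter, not a propagated error.
    """
    ratios = list(replicate_ratios)
    if not ratios:
        raise QuantError("at least one replicate ratio is required")
    copies = [copies_per_numt(r, ploidy, residual_mt_fraction) for r in ratios]
    if len(copies) == 1:
        warnings.warn("single replicate: SD reported as 0.0", stacklevel=2)
        sd = 0.0
    else:
        sd = stdev(copies)
    return CopyEstimate(mean(copies), sd, len(copies), dict(per_target or {}))


@dataclass(frozen=True)
class QuantRecord:
    """One quantification measurement for one sample/target/replicate.

    Exactly one of ``concentration`` (any consistent unit), ``droplet_assay``
    or ``mt_autosomal_ratio`` (pre-computed ratio) is set.
    """

    sample_id: str
    target: QuantTarget
    replicate: int
    method: str  # "ddpcr" | "qpcr"
    concentration: float | None = None
    droplet_assay: DropletAssay | None = None
    mt_autosomal_ratio: float | None = None

    def value(self) -> float:
        if self.droplet_assay is not None:
            return ddpcr_concentration(self.droplet_assay)
        if self.concentration is not None:
            return self.concentration
        if self.mt_autosomal_ratio is not None:
            return self.mt_autosomal_ratio
        raise QuantError("record carries no measurement")


def copies_from_quant_records(
    records: Iterable[QuantRecord],
    method: str,
    ploidy: int = 2,
    residual_mt_fraction: float = 0.0,
) -> CopyEstimate:
    """Copy estimate for one method from a set of quantification records.

    Pre-computed mt:autosomal ratios are used directly; otherwise each
    (mt-like target, replicate) concentration is divided by the single-copy
    autosomal concentration of the same replicate.  Multi-copy autosomal
    targets are never accepted as denominator.
    """
    recs = [r for r in records if r.method == method]
    if not recs:
        raise QuantError(f"no records for method {method!r}")

    ratios: list[float] = []
    per_target: dict[str, list[float]] = {}
    direct = [r for r in recs if r.mt_autosomal_ratio is not None]
    if direct:
        for r in direct:
            ratios.append(r.mt_autosomal_ratio)
            per_target.setdefault(r.target.name, []).append(r.mt_autosomal_ratio)
    else:
        auto = {}
        for r in recs:
            if r.target.copy_class == SINGLE_COPY_AUTOSOMAL:
                auto[r.replicate] = r.value()
            elif r.target.copy_class == MULTI_COPY_AUTOSOMAL:
                raise QuantError(
                    f"target {r.target.name!r} is multi-copy autosomal and cannot "
                    "serve as a copies-per-insert denominator")
        if not auto:
            raise QuantError("no single-copy autosomal records to normalise against")
        for r in recs:
            if r.target.copy_class == MT_LIKE and r.replicate in auto:
                ratio = r.value() / auto[r.replicate]
                ratios.append(ratio)
                per_target.setdefault(r.target.name, []).append(ratio)
    per_target_mean = {k: mean(v) for k, v in per_target.items()}
    return aggregate_copies(ratios, ploidy, residual_mt_fraction, per_target_mean)


def insert_size(copies: float, unit_length: int = MT_LENGTH) -> float:
    """Physical insert size in bp of a tandem repeat of full mitogenome units."""
    if copies < 0:
        raise QuantError("copies must be non-negative")
    return copies * unit_length


@dataclass(frozen=True)
class CircularTemplate:
    """A circular mitogenome (genuine mtDNA)."""


@dataclass(frozen=True)
class LinearSingleUnit:
    """A single linearised mtDNA stretch covering one contiguous circular run."""

    span: CircularInterval = CircularInterval(1, MT_LENGTH)


@dataclass(frozen=True)
class TandemRepeat:
    """n >= 2 complete mitogenome units joined head-to-tail."""

    n_units: int = 2

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise QuantError("a tandem repeat needs at least 2 units")


Template = CircularTemplate | LinearSingleUnit | TandemRepeat


def template_supports(template: Template, amplicon: CircularInterval) -> bool:
    """Can a PCR amplicon (chrM coordinates, possibly origin-spanning) be
    amplified from the given template topology?

    A circular template supports any amplicon.  A single linear unit supports
    an amplicon only if it occurs as a contiguous sub-run of the unit's
    position walk — an origin-spanning amplicon is never contained in a
    single 1..16569 run.  A tandem repeat of full units realises every wrap
    across a unit junction and supports everything.
    """
    if isinstance(template, CircularTemplate):
        return True
    if isinstance(template, TandemRepeat):
        return True
    off = template.span.offset(amplicon.start)
    if off is None:
        return False
    return off + amplicon.length <= template.span.length
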