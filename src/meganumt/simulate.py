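"""Seeded generative model for pedigrees segregating a multi-copy Mega-NUMT.

The simulator produces exactly the statistical structure the analysis
assumes: genuine mtDNA follows the strict matriline; a heterozygous nuclear
insert allele of C tandem mitogenome copies drops through the pedigree
Mendelianly; within each nucleated cell the insert contributes A*C
mtDNA-like templates against m_tissue genuine mtDNA copies, so the expected
minor fraction is

    f = A*C / (A*C + m_tissue)

(A = insert allele count).  The default per-cell mtDNA numbers (blood 84,
buccal 1080, hair root 5000) are back-solved from the clone fractions the
default copy number C = 45 should produce (blood ~35%, buccal ~4%); they are
simulation configuration, not measured biology.  Direct Sanger calls apply a
~20% minor-fraction detection limit; clones are Bernoulli(f) template draws;
anucleate cells carry f = 0 except for rare hair shafts with nuclear
remnants; rho0 cells retain only the insert.  ddPCR droplet counts are
binomial with Poisson-complement positive probability at a per-target
dilution targeting ~0.8 copies/droplet; qPCR quantities are lognormal around
truth.

A ``heteroplasmy`` mode places the minor haplotype in the mitochondrial pool
instead (present in anucleate cells at the same fraction, absent from rho0
cells), giving the contrast the evidence engine must distinguish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .copy_number import DropletAssay, QuantRecord, default_targets
from .evidence import Individual, Observation, Pedigree
from .fixtures import HV0_COMPONENT, U4C1_COMPONENT
from .io import (
    write_mitotype_table, write_observations, write_pedigree, write_quant_records,
)
from .mitotype import CONTROL_REGION, Mitotype, Variant, mix, parse_mitotype
from .reference import load_reference

__all__ = ["SimConfig", "SimResult", "simulate_pedigree_dataset", "write_dataset"]

NUMT_MODE = "numt"
HETEROPLASMY_MODE = "heteroplasmy"

DDPCR_MT_TARGETS = ("ND1", "KAV", "BATZ", "AND")
QPCR_MT_TARGETS = ("ND1", "AND")


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.  ``seed`` is mandatory."""

    seed: int
    generations: int = 3
    sibship: int = 3
    mode: str = NUMT_MODE
    founder_numt_copies: float = 45.0      # C, tandem mitogenome units
    founder_numt_alleles: int = 1          # heterozygous carrier
    chromosome_label: str = "chr14"
    heteroplasmy_fraction: float = 0.35
    mt_copies_per_cell: dict[str, float] = field(default_factory=lambda: {
        "blood": 84.0, "buccal": 1080.0, "hair_root": 5000.0})
    sanger_lod: float = 0.20
    n_clones: int = 100                    # blood clones per individual
    n_single_cells: int = 100              # PBMCs per individual
    n_thrombocytes: int = 113              # focal individual only
    n_hair_shafts: int = 6
    hair_shaft_contamination_p: float = 1.0 / 56.0
    rho0_residual_mt_fraction: float = 0.0
    ddpcr_droplets: int = 20000
    ddpcr_replicates: int = 5              # per mt target (x4 targets = 20)
    ddpcr_target_lambda: float = 0.8
    qpcr_replicates: int = 38              # per mt target (x2 targets = 76)
    qpcr_cv: float = 0.15
    qpcr_efficiency: float = 0.95          # generative detail, reported in truth log

    def __post_init__(self) -> None:
        if self.mode not in (NUMT_MODE, HETEROPLASMY_MODE):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.founder_numt_copies < 0 or self.founder_numt_alleles < 0:
            raise ValueError("copy and allele counts must be non-negative")
        for name in ("heteroplasmy_fraction", "sanger_lod",
                     "hair_shaft_contamination_p", "rho0_residual_mt_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_clones", "n_single_cells", "n_thrombocytes",
                     "n_hair_shafts", "ddpcr_droplets", "ddpcr_replicates",
                     "qpcr_replicates"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimResult:
    pedigree: Pedigree
    true_mitotypes: dict[str, Mitotype]       # genuine mtDNA haplotype per individual
    numt_alleles: dict[str, int]
    observed_mitotypes: dict[str, Mitotype]   # direct-Sanger blood call
    observations: list[Observation]
    quant_records: list[QuantRecord]
    truth_log: dict


def _random_haplotype(rng: np.random.Generator, ref: str, label: str) -> Mitotype:
    """A distinct control-region haplotype: the near-universal 263G/315.1C
    plus 2-4 random private substitutions."""
    n = int(rng.integers(2, 5))
    pool = np.fromiter((p for p in CONTROL_REGION.positions() if p != 263), dtype=int)
    positions = rng.choice(pool, size=n, replace=False)
    variants = [Variant(263, "G"), Variant(315, "C", 1)]
    for pos in sorted(int(p) for p in positions):
        refbase = ref[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != refbase]))
        variants.append(Variant(pos, alt))
    return Mitotype(tuple(variants), (CONTROL_REGION,), label)


def _build_pedigree(cfg: SimConfig, rng: np.random.Generator) -> Pedigree:
    individuals: dict[str, Individual] = {
        "g1.1": Individual(sex="M"), "g1.2": Individual(sex="F"),
    }
    couples = [("g1.1", "g1.2")]
    for gen in range(2, cfg.generations + 1):
        next_couples = []
        k = 0
        for father, mother in couples:
            for _ in range(cfg.sibship):
                k += 1
                cid = f"g{gen}.{k}"
                sex = "F" if rng.random() < 0.5 else "M"
                individuals[cid] = Individual(sex=sex, mother=mother, father=father)
                if gen < cfg.generations:
                    sid = f"{cid}s"
                    individuals[sid] = Individual(sex="M" if sex == "F" else "F")
                    next_couples.append((cid, sid) if sex == "M" else (sid, cid))
        couples = next_couples
    return Pedigree(individuals, {})


def _minor_fraction(cfg: SimConfig, alleles: int, tissue: str, heteroplasmic: bool) -> float:
    if cfg.mode == HETEROPLASMY_MODE:
        return cfg.heteroplasmy_fraction if heteroplasmic else 0.0
    m = cfg.mt_copies_per_cell.get(tissue, cfg.mt_copies_per_cell["blood"])
    load = alleles * cfg.founder_numt_copies
    return load / (load + m) if load > 0 else 0.0


def simulate_pedigree_dataset(cfg: SimConfig) -> SimResult:
    """Generate one complete dataset (pedigree, haplotypes, observations,
    quantification records, truth log).  Identical config and seed give an
    identical dataset."""
    rng = np.random.default_rng(cfg.seed)
    ref = load_reference()
    pedigree = _build_pedigree(cfg, rng)

    founder_mother = "g1.2"
    mt_hap: dict[str, Mitotype] = {}
    for iid, ind in pedigree.individuals.items():
        if ind.mother is None:
            mt_hap[iid] = (HV0_COMPONENT.with_label(iid) if iid == founder_mother
                           else _random_haplotype(rng, ref, iid))
    # matrilineal transmission, generation order guarantees mothers come first
    for iid, ind in pedigree.individuals.items():
        if ind.mother is not None:
            mt_hap[iid] = mt_hap[ind.mother].with_label(iid)

    matriline = {iid for iid, m in mt_hap.items() if m == HV0_COMPONENT}

    alleles: dict[str, int] = {}
    for iid, ind in pedigree.individuals.items():
        if ind.mother is None:
            alleles[iid] = cfg.founder_numt_alleles if iid == founder_mother else 0
        else:
            inherited = sum(int(rng.binomial(min(alleles[p], 2), 0.5))
                            for p in (ind.mother, ind.father))
            alleles[iid] = min(inherited, 2)

    pedigree.carrier_status = {
        iid: ("carrier" if a > 0 else "non_carrier") for iid, a in alleles.items()}
    if cfg.mode == HETEROPLASMY_MODE:
        # the "carrier" concept tracks whoever shows the minor component
        pedigree.carrier_status = {
            iid: ("carrier" if iid in matriline else "non_carrier") for iid in alleles}

    numt_hap = U4C1_COMPONENT
    carriers_by_depth = sorted(
        (iid for iid, a in alleles.items() if a > 0),
        key=lambda i: (-int(i.split(".")[0][1:]), i))
    focal = carriers_by_depth[0] if carriers_by_depth else founder_mother
    rho0_id = focal

    observations: list[Observation] = []
    observed_mt: dict[str, Mitotype] = {}

    def sanger(call_fraction: float) -> str:
        return "mixed" if call_fraction >= cfg.sanger_lod else "major_only"

    for iid in pedigree.individuals:
        het = iid in matriline
        a = alleles[iid]
        # direct Sanger on blood, buccal and hair roots
        for tissue in ("blood", "buccal", "hair_root"):
            f = _minor_fraction(cfg, a, tissue, het)
            call = sanger(f)
            observations.append(Observation(iid, tissue, "direct_sanger", call))
            if tissue == "blood":
                observed_mt[iid] = (mix(mt_hap[iid], numt_hap, ref)
                                    if call == "mixed" else mt_hap[iid])
        # blood clones: Bernoulli(f) template sampling
        f_blood = _minor_fraction(cfg, a, "blood", het)
        if cfg.n_clones:
            k = int(rng.binomial(cfg.n_clones, f_blood))
            if k:
                observations.append(Observation(iid, "blood", "clone", "minor_only", n=k))
            if cfg.n_clones - k:
                observations.append(Observation(iid, "blood", "clone", "major_only",
                                                n=cfg.n_clones - k))
        # single PBMCs: every nucleated cell of a carrier contains the insert
        if cfg.n_single_cells:
            call = sanger(f_blood)
            observations.append(Observation(iid, "pbmc", "single_cell", call,
                                            n=cfg.n_single_cells))
        # hair shafts: anucleate except for rare nuclear remnants
        if cfg.n_hair_shafts:
            if cfg.mode == NUMT_MODE:
                contaminated = int(rng.binomial(
                    cfg.n_hair_shafts, cfg.hair_shaft_contamination_p)) \
                    if a and cfg.founder_numt_copies > 0 else 0
                clean = cfg.n_hair_shafts - contaminated
                if contaminated:
                    observations.append(Observation(iid, "hair_shaft", "direct_sanger",
                                                    "mixed", n=contaminated))
                if clean:
                    observations.append(Observation(iid, "hair_shaft", "direct_sanger",
                                                    "major_only", n=clean))
            else:
                call = sanger(cfg.heteroplasmy_fraction if het else 0.0)
                observations.append(Observation(iid, "hair_shaft", "direct_sanger",
                                                call, n=cfg.n_hair_shafts))

    # thrombocytes for the focal individual
    if cfg.n_thrombocytes:
        if cfg.mode == NUMT_MODE:
            call = "major_only"
        else:
            call = sanger(cfg.heteroplasmy_fraction if focal in matriline else 0.0)
        observations.append(Observation(focal, "thrombocyte", "single_cell", call,
                                        n=cfg.n_thrombocytes))

    # rho0 fibroblasts: only nuclear templates survive depletion
    if cfg.mode == NUMT_MODE and alleles[rho0_id] > 0 and cfg.founder_numt_copies > 0:
        call = "minor_only" if cfg.rho0_residual_mt_fraction == 0 else "mixed"
        observations.append(Observation(rho0_id, "rho0_fibroblast", "direct_sanger",
                                        call, n=3))
    else:
        observations.append(Observation(rho0_id, "rho0_fibroblast", "direct_sanger",
                                        "none", n=3))

    observations.append(Observation("extraction_blank", "other", "direct_sanger",
                                    "none", is_control=True))

    quant = _simulate_quant(cfg, rng, alleles[rho0_id], rho0_id)

    truth_log = {
        "config": {k: v for k, v in asdict(cfg).items()},
        "numt_alleles": dict(alleles),
        "matriline": sorted(matriline),
        "focal_individual": focal,
        "rho0_individual": rho0_id,
        "numt_haplotype": str(numt_hap),
        "mt_haplotypes": {k: str(v) for k, v in mt_hap.items()},
        "expected_minor_fraction_blood": _minor_fraction(
            cfg, cfg.founder_numt_alleles, "blood", True),
    }
    return SimResult(pedigree, mt_hap, alleles, observed_mt,
                     observations, quant, truth_log)


def _simulate_quant(cfg: SimConfig, rng: np.random.Generator,
                    alleles: int, sample_id: str) -> list[QuantRecord]:
    """ddPCR droplet counts and qPCR concentrations for rho0-cell DNA.

    True per-cell template counts: mt-like = A*C (insert only; any residual
    genuine mtDNA inflates this by 1/(1-r)), autosomal single-copy = 2.
    Each target is read at a dilution aiming at ~0.8 copies/droplet; the
    dilution factor is recorded so concentrations can be recovered.
    """
    targets = default_targets()
    records: list[QuantRecord] = []
    r = cfg.rho0_residual_mt_fraction
    load = alleles * cfg.founder_numt_copies if cfg.mode == NUMT_MODE else 0.0
    conc_mt = (load / (1.0 - r)) if r < 1 else load  # copies per cell-volume unit
    conc_auto = 2.0
    vol = 0.85

    def droplet_record(target_name: str, conc: float, rep: int) -> QuantRecord:
        if conc > 0:
            dilution = conc * vol / cfg.ddpcr_target_lambda
            lam = cfg.ddpcr_target_lambda
        else:
            dilution, lam = 1.0, 0.0
        p = 1.0 - math.exp(-lam)
        n_pos = int(rng.binomial(cfg.ddpcr_droplets, p))
        n_pos = min(n_pos, cfg.ddpcr_droplets - 1)  # saturation guard
        assay = DropletAssay(targets[target_name], cfg.ddpcr_droplets, n_pos,
                             droplet_volume_nl=vol, dilution=dilution)
        return QuantRecord(sample_id, targets[target_name], rep, "ddpcr",
                           droplet_assay=assay)

    rep = 0
    for tname in DDPCR_MT_TARGETS:
        for _ in range(cfg.ddpcr_replicates):
            records.append(droplet_record(tname, conc_mt, rep))
            records.append(droplet_record("ND14", conc_auto, rep))
            rep += 1

    sigma = math.sqrt(math.log(1.0 + cfg.qpcr_cv ** 2))
    rep = 0
    for tname in QPCR_MT_TARGETS:
        for _ in range(cfg.qpcr_replicates):
            noisy_mt = conc_mt * float(rng.lognormal(-sigma ** 2 / 2, sigma))
            noisy_auto = conc_auto * float(rng.lognormal(-sigma ** 2 / 2, sigma))
            records.append(QuantRecord(sample_id, targets[tname], rep, "qpcr",
                                       concentration=noisy_mt))
            records.append(QuantRecord(sample_id, targets["ND14"], rep, "qpcr",
                                       concentration=noisy_auto))
            rep += 1
    return records


def write_dataset(result: SimResult, out_dir: str | Path) -> Path:
    """Write a simulated dataset in the TSV formats the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pedigree(out / "pedigree.tsv", result.pedigree)
    rows = [{"sample_id": f"{iid}_blood", "individual_id": iid, "tissue": "blood",
             "mitotype": m} for iid, m in sorted(result.observed_mitotypes.items())]
    write_mitotype_table(out / "mitotypes.tsv", rows)
    write_observations(out / "observations.tsv", result.observations)
    write_quant_records(out / "quant.tsv", result.quant_records)
    import json
    (out / "truth.json").write_text(json.dumps(result.truth_log, indent=2, sort_keys=True))
    return out
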