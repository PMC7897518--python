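"""Reading and writing the tabular dataset formats.

A dataset directory holds up to four TSV files:

``mitotypes.tsv``     sample_id, individual_id, tissue, range, mitotype
``pedigree.tsv``      id, father, mother, sex, status  (PED-like; 0 = missing)
``observations.tsv``  individual_id, tissue, assay, call, n, is_control
``quant.tsv``         sample_id, method, target, replicate, value_type, value,
                      dilution  (value_type: concentration |
                      droplets_pos_total with value "pos/total" |
                      mt_autosomal_ratio)

Lines starting with ``#`` are comments.  Optional exports: FASTA of
unambiguous haplotypes and a simple chrM VCF.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .copy_number import DropletAssay, QuantRecord, QuantTarget, default_targets
from .evidence import Individual, Observation, Pedigree
from .mitotype import (
    CONTROL_REGION, FULL_GENOME, CircularInterval, Mitotype,
    apply_to_reference, parse_mitotype, serialize_mitotype,
)

__all__ = [
    "parse_range", "read_mitotype_table", "write_mitotype_table",
    "read_pedigree", "write_pedigree", "read_observations", "write_observations",
    "read_quant_records", "write_quant_records",
    "write_fasta", "write_vcf",
]

_RANGE_ALIASES = {"CR": CONTROL_REGION, "control_region": CONTROL_REGION,
                  "full": FULL_GENOME, "full_genome": FULL_GENOME}


def parse_range(text: str) -> tuple[CircularInterval, ...]:
    """Parse a covered-range field: 'CR', 'full' or 'start-end[,start-end...]'."""
    text = text.strip()
    if text in _RANGE_ALIASES:
        return (_RANGE_ALIASES[text],)
    out = []
    for part in text.split(","):
        start, _, end = part.partition("-")
        out.append(CircularInterval(int(start), int(end)))
    return tuple(out)


def format_range(covered: Sequence[CircularInterval]) -> str:
    if tuple(covered) == (CONTROL_REGION,):
        return "CR"
    if tuple(covered) == (FULL_GENOME,):
        return "full"
    return ",".join(f"{iv.start}-{iv.end}" for iv in covered)


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_mitotype_table(path: str | Path) -> pd.DataFrame:
    """Mitotype table with a parsed ``Mitotype`` object column added."""
    df = _read_tsv(Path(path))
    required = {"sample_id", "range", "mitotype"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: mitotype table needs columns {sorted(required)}")
    df["mitotype_obj"] = [
        parse_mitotype(row.mitotype, parse_range(row.range), label=row.sample_id)
        for row in df.itertuples()
    ]
    return df


def write_mitotype_table(path: str | Path, rows: Sequence[dict]) -> None:
    """Rows: dicts with sample_id, individual_id, tissue and a Mitotype under
    'mitotype' (object or string)."""
    out = []
    for r in rows:
        m = r["mitotype"]
        if isinstance(m, Mitotype):
            out.append({**{k: v for k, v in r.items() if k != "mitotype"},
                        "range": format_range(m.covered_range),
                        "mitotype": serialize_mitotype(m)})
        else:
            out.append(dict(r))
    pd.DataFrame(out).to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    df = _read_tsv(Path(path))
    required = {"id", "father", "mother", "sex"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: pedigree needs columns {sorted(required)}")
    individuals, status = {}, {}
    for row in df.itertuples():
        individuals[row.id] = Individual(
            sex=row.sex if row.sex in ("M", "F") else None,
            mother=row.mother if row.mother not in ("", "0") else None,
            father=row.father if row.father not in ("", "0") else None,
        )
        if "status" in df.columns and row.status:
            status[row.id] = row.status
    return Pedigree(individuals, status)


def write_pedigree(path: str | Path, p: Pedigree) -> None:
    rows = [{"id": iid, "father": ind.father or "0", "mother": ind.mother or "0",
             "sex": ind.sex or "0", "status": p.status(iid)}
            for iid, ind in p.individuals.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_observations(path: str | Path) -> list[Observation]:
    df = _read_tsv(Path(path))
    required = {"individual_id", "tissue", "assay", "call"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: observations need columns {sorted(required)}")
    obs = []
    for row in df.itertuples():
        obs.append(Observation(
            individual_id=row.individual_id, tissue=row.tissue, assay=row.assay,
            call=row.call, n=int(getattr(row, "n", "1") or 1),
            is_control=str(getattr(row, "is_control", "0")) in ("1", "true", "True"),
        ))
    return obs


def write_observations(path: str | Path, observations: Sequence[Observation]) -> None:
    rows = [{"individual_id": o.individual_id, "tissue": o.tissue, "assay": o.assay,
             "call": o.call, "n": o.n, "is_control": int(o.is_control)}
            for o in observations]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_quant_records(
    path: str | Path,
    targets: Mapping[str, QuantTarget] | None = None,
) -> list[QuantRecord]:
    targets = dict(targets or default_targets())
    df = _read_tsv(Path(path))
    required = {"sample_id", "method", "target", "replicate", "value_type", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: quant table needs columns {sorted(required)}")
    records = []
    for row in df.itertuples():
        name = row.target
        target = targets.get(name, QuantTarget(name, "chrM")) if name != "combined" \
            else QuantTarget("combined", "chrM")
        kwargs: dict = {}
        if row.value_type == "concentration":
            kwargs["concentration"] = float(row.value)
        elif row.value_type == "mt_autosomal_ratio":
            kwargs["mt_autosomal_ratio"] = float(row.value)
        elif row.value_type == "droplets_pos_total":
            pos, _, total = row.value.partition("/")
            dilution = float(getattr(row, "dilution", "1") or 1)
            kwargs["droplet_assay"] = DropletAssay(
                target, n_droplets=int(total), n_positive=int(pos), dilution=dilution)
        else:
            raise ValueError(f"{path}: unknown value_type {row.value_type!r}")
        records.append(QuantRecord(
            sample_id=row.sample_id, target=target, replicate=int(row.replicate),
            method=row.method, **kwargs))
    return records


def write_quant_records(path: str | Path, records: Sequence[QuantRecord]) -> None:
    rows = []
    for r in records:
        if r.droplet_assay is not None:
            value_type = "droplets_pos_total"
            value = f"{r.droplet_assay.n_positive}/{r.droplet_assay.n_droplets}"
            dilution = r.droplet_assay.dilution
        elif r.mt_autosomal_ratio is not None:
            value_type, value, dilution = "mt_autosomal_ratio", repr(r.mt_autosomal_ratio), 1
        else:
            value_type, value, dilution = "concentration", repr(r.concentration), 1
        rows.append({"sample_id": r.sample_id, "method": r.method, "target": r.target.name,
                     "replicate": r.replicate, "value_type": value_type,
                     "value": value, "dilution": dilution})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fasta(path: str | Path, mitotypes: Mapping[str, Mitotype],
                reference: str | None = None) -> None:
    """Export unambiguous haplotypes as FASTA over their covered ranges."""
    with open(path, "w") as fh:
        for name, m in mitotypes.items():
            seq = apply_to_reference(m, reference)
            fh.write(f">{name} {format_range(m.covered_range)}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_vcf(path: str | Path, m: Mitotype, sample: str = "sample",
              reference: str | None = None) -> None:
    """Minimal chrM VCF export: one record per variant, insertions anchored."""
    from .reference import load_reference
    ref = reference if reference is not None else load_reference()
    lines = ["##fileformat=VCFv4.2",
             f"##contig=<ID=chrM,length={len(ref)}>",
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    by_pos: dict[int, dict] = {}
    for v in m.variants:
        rec = by_pos.setdefault(v.position, {"ref": ref[v.position - 1], "ins": [], "sub": None})
        if v.insertion_index:
            rec["ins"].append(v)
        else:
            rec["sub"] = v
    for pos in sorted(by_pos):
        rec = by_pos[pos]
        refbase = rec["ref"]
        if rec["ins"]:
            inserted = "".join(x.observed for x in sorted(rec["ins"], key=lambda x: x.insertion_index))
            base = rec["sub"].observed if rec["sub"] and rec["sub"].kind == "substitution" else refbase
            lines.append(f"chrM\t{pos}\t.\t{refbase}\t{base}{inserted}\t.\t.\t.")
        elif rec["sub"] is not None and rec["sub"].kind == "deletion":
            prev = ref[pos - 2] if pos > 1 else ref[-1]
            lines.append(f"chrM\t{pos - 1}\t.\t{prev}{refbase}\t{prev}\t.\t.\t.")
        elif rec["sub"] is not None:
            lines.append(f"chrM\t{pos}\t.\t{refbase}\t{rec['sub'].observed}\t.\t.\t.")
    Path(path).write_text("\n".join(lines) + "\n")
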