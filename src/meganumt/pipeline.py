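"""End-to-end analysis: deconvolve -> assign -> classify -> segregate ->
copy number, producing one JSON-serializable report for a dataset directory
or the bundled case fixture."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

from .copy_number import QuantError, QuantRecord, copies_from_quant_records, insert_size
from .deconvolution import deconvolve_two_source
from .evidence import (
    Observation, Pedigree, check_matriline, check_segregation, classify_minor_source,
)
from .haplogroups import MotifTable, assign_haplogroup, builtin_motif_table
from .io import read_mitotype_table, read_observations, read_pedigree, read_quant_records
from .mitotype import Mitotype, serialize_mitotype

__all__ = ["PipelineError", "build_report", "run_pipeline", "run_case_pipeline"]


class PipelineError(RuntimeError):
    """Raised for missing inputs or schema violations, with file context."""


def build_report(
    mitotypes: Mapping[str, Mitotype],
    pedigree: Pedigree,
    observations: Sequence[Observation],
    quant_records: Sequence[QuantRecord] = (),
    true_mitotypes: Mapping[str, Mitotype] | None = None,
    motif_table: MotifTable | None = None,
    ploidy: int = 2,
    residual_mt_fraction: float = 0.0,
) -> dict:
    """Assemble the full report from in-memory objects.

    ``mitotypes`` maps individual id -> observed (possibly mixed) mitotype.
    If the pedigree carries no carrier statuses they are derived from the
    observed mitotypes (mixed call = carrier).  The matriline check uses
    ``true_mitotypes`` when given, otherwise only unambiguous observed calls.
    """
    table = motif_table or builtin_motif_table()

    deconv_cache: dict[str, dict] = {}
    mito_report: dict[str, dict] = {}
    for iid in sorted(mitotypes):
        m = mitotypes[iid]
        entry: dict = {"observed": serialize_mitotype(m), "mixed": m.is_ambiguous}
        if m.is_ambiguous:
            key = serialize_mitotype(m)
            if key not in deconv_cache:
                deconv_cache[key] = deconvolve_two_source(m, table).as_dict()
            entry["deconvolution"] = deconv_cache[key]
        else:
            entry["haplogroup"] = assign_haplogroup(m, table)[0].as_dict()
        mito_report[iid] = entry

    source = classify_minor_source(list(observations))

    if not any(s != "unknown" for s in pedigree.carrier_status.values()):
        derived = {}
        for iid in pedigree.individuals:
            if iid in mitotypes:
                derived[iid] = "carrier" if mitotypes[iid].is_ambiguous else "non_carrier"
        pedigree = Pedigree(pedigree.individuals, derived)
    segregation = check_segregation(pedigree)

    if true_mitotypes is None:
        true_mitotypes = {i: m for i, m in mitotypes.items() if not m.is_ambiguous}
    matriline = check_matriline(pedigree, true_mitotypes)

    copy_report: dict = {}
    methods = sorted({r.method for r in quant_records})
    for method in methods:
        est = copies_from_quant_records(quant_records, method, ploidy, residual_mt_fraction)
        copy_report[method] = {**est.as_dict(),
                               "insert_size_bp": round(insert_size(est.copies_per_numt), 1)}
    if copy_report:
        lo = min(v["copies_per_numt"] for v in copy_report.values())
        hi = max(v["copies_per_numt"] for v in copy_report.values())
        copy_report["copies_range"] = [lo, hi]
        copy_report["insert_size_range_bp"] = [round(insert_size(lo), 1),
                                               round(insert_size(hi), 1)]

    return {
        "verdict": source.verdict,
        "source_evidence": list(source.evidence),
        "source_note": source.note,
        "mitotypes": mito_report,
        "segregation": segregation.as_dict(),
        "matriline_violations": matriline,
        "copy_number": copy_report,
        "n_individuals": len(pedigree.individuals),
        "carriers": sorted(i for i, s in pedigree.carrier_status.items() if s == "carrier"),
    }


def run_pipeline(
    data_dir: str | Path,
    out_path: str | Path | None = None,
    motifs_path: str | Path | None = None,
    ploidy: int = 2,
    residual_mt_fraction: float = 0.0,
) -> dict:
    """Run the full analysis on a dataset directory (see :mod:`meganumt.io`
    for the file formats).  ``mitotypes.tsv``, ``pedigree.tsv`` and
    ``observations.tsv`` are required; ``quant.tsv`` is optional."""
    d = Path(data_dir)
    for name in ("mitotypes.tsv", "pedigree.tsv", "observations.tsv"):
        if not (d / name).exists():
            raise PipelineError(f"{d / name}: required input file missing")
    try:
        mito_df = read_mitotype_table(d / "mitotypes.tsv")
        pedigree = read_pedigree(d / "pedigree.tsv")
        observations = read_observations(d / "observations.tsv")
        quant = read_quant_records(d / "quant.tsv") if (d / "quant.tsv").exists() else []
    except (ValueError, KeyError) as exc:
        raise PipelineError(f"{d}: {exc}") from exc

    mitotypes: dict[str, Mitotype] = {}
    id_col = "individual_id" if "individual_id" in mito_df.columns else "sample_id"
    for row in mito_df.itertuples():
        mitotypes.setdefault(getattr(row, id_col), row.mitotype_obj)

    table = None
    if motifs_path is not None:
        from .haplogroups import load_motif_table
        table = load_motif_table(motifs_path)
    report = build_report(mitotypes, pedigree, observations, quant,
                          motif_table=table, ploidy=ploidy,
                          residual_mt_fraction=residual_mt_fraction)
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def run_case_pipeline(out_path: str | Path | None = None) -> dict:
    """Run the full analysis on the bundled case dataset."""
    from .fixtures import load_case_fixture

    fx = load_case_fixture()
    report = build_report(fx.mitotypes, fx.pedigree, fx.observations,
                          fx.quant_records, true_mitotypes=fx.true_mitotypes)
    report["metadata"] = fx.metadata
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
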