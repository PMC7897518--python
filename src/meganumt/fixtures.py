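"""Bundled case dataset: a four-generation family segregating a chromosome-14
tandem multi-copy Mega-NUMT.

Eight maternally related members of the family show a mixed control-region
mitotype (hg HV0/V mtDNA superposed with a hg U4c1 nuclear insert); three
matriline members and all married-in relatives are single-source.  The
bundled tables transcribe the published narrative: the pedigree with carrier
status, per-individual control-region mitotypes, tissue observations
(113 single-source thrombocytes, 55 of 56 hair shafts, 249 bone clones from
the great-grandmother, rho0 fibroblasts yielding only the insert haplotype)
and replicate-level quantification ratios.

The quantification table is a *synthetic reconstruction*: the replicate-level
raw data behind the published summary (ddPCR 45.00 +/- 5.27, n = 20; qPCR
56.16 +/- 4.35, n = 76 mitogenome copies per insert) are not public, so
``quant_synthetic.tsv`` contains deterministic replicate ratios affine-scaled
to reproduce exactly those means and sample SDs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

from .copy_number import QuantRecord
from .evidence import Observation, Pedigree
from .mitotype import CONTROL_REGION, Mitotype, parse_mitotype

__all__ = [
    "MIXED_MITOTYPE_STR", "HV0_COMPONENT_STR", "U4C1_COMPONENT_STR",
    "MIXED_MITOTYPE", "HV0_COMPONENT", "U4C1_COMPONENT",
    "CaseFixture", "load_case_fixture",
]

#: Direct-Sanger blood call of the reference individual (IV.3): IUPAC mixed
#: bases at every position where the insert and the genuine mtDNA differ.
MIXED_MITOTYPE_STR = ("16179Y 16298Y 16356Y 16512Y 16519Y 72Y 73R 189R 195Y "
                      "200R 263G 315.1C 499R")
#: The genuine mtDNA haplotype of the matriline (hg HV0, nesting hg V).
HV0_COMPONENT_STR = "16298C 72C 200G 263G 315.1C"
#: The nuclear-insert haplotype (hg U4c1).
U4C1_COMPONENT_STR = ("16179T 16356C 16512C 16519C 73G 189G 195C 263G "
                      "315.1C 499A")

MIXED_MITOTYPE = parse_mitotype(MIXED_MITOTYPE_STR, (CONTROL_REGION,), "IV.3_blood")
HV0_COMPONENT = parse_mitotype(HV0_COMPONENT_STR, (CONTROL_REGION,), "HV0")
U4C1_COMPONENT = parse_mitotype(U4C1_COMPONENT_STR, (CONTROL_REGION,), "U4c1")


@dataclass
class CaseFixture:
    pedigree: Pedigree
    mitotypes: dict[str, Mitotype]        # individual -> observed CR call (main sample)
    true_mitotypes: dict[str, Mitotype]   # individual -> genuine mtDNA haplotype
    observations: list[Observation]
    quant_records: list[QuantRecord]
    metadata: dict

    @property
    def carriers(self) -> list[str]:
        return sorted(i for i, s in self.pedigree.carrier_status.items() if s == "carrier")


def _data_path(name: str):
    return resources.as_file(resources.files("meganumt.data.fixture").joinpath(name))


@lru_cache(maxsize=1)
def load_case_fixture() -> CaseFixture:
    """Load the packaged case dataset (cached; treat as read-only)."""
    from .io import read_mitotype_table, read_observations, read_pedigree, read_quant_records

    with _data_path("pedigree.tsv") as p:
        pedigree = read_pedigree(p)
    with _data_path("mitotypes.tsv") as p:
        mito_df = read_mitotype_table(p)
    with _data_path("observations.tsv") as p:
        observations = read_observations(p)
    with _data_path("quant_synthetic.tsv") as p:
        quant = read_quant_records(p)

    mitotypes: dict[str, Mitotype] = {}
    for row in mito_df.itertuples():
        # first listed sample per individual is the reporting sample
        mitotypes.setdefault(row.individual_id, row.mitotype_obj)

    matriline = {"I.2", "II.2", "III.2", "III.4", "III.6",
                 "IV.1", "IV.3", "IV.4", "IV.5", "IV.6", "IV.7"}
    true_mt: dict[str, Mitotype] = {}
    for iid, observed in mitotypes.items():
        true_mt[iid] = HV0_COMPONENT.with_label(iid) if iid in matriline \
            else observed.with_label(iid)

    metadata = {
        "numt_chromosome": "14q31",
        "numt_haplogroup": "U4c1",
        "mtdna_haplogroup": "V (HV0)",
        "matriline": sorted(matriline),
        "rho0_individual": "III.4",
        "reference_individual": "IV.3",
        "quant_note": "replicate ratios are a synthetic reconstruction matching "
                      "the published summary statistics",
    }
    return CaseFixture(pedigree, mitotypes, true_mt, observations, quant, metadata)
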