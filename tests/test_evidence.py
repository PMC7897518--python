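"""Tissue-contrast source classification and pedigree checks."""

import pytest

from meganumt.evidence import (
    CONTAMINATION_SUSPECTED, INCONCLUSIVE, MT_HETEROPLASMY, NUCLEAR_NUMT,
    EvidenceError, Individual, Observation, Pedigree, check_matriline,
    check_segregation, classify_minor_source,
)
from meganumt.mitotype import parse_mitotype


def obs(individual="X", tissue="blood", assay="direct_sanger", call="mixed",
        n=1, is_control=False):
    return Observation(individual, tissue, assay, call, n, is_control)


class TestObservation:
    def test_cell_class_lookup(self):
        assert obs(tissue="thrombocyte", assay="single_cell",
                   call="major_only").cell_class == "anucleate"
        assert obs(tissue="hair_shaft").cell_class == "anucleate"
        assert obs(tissue="rho0_fibroblast", call="minor_only").cell_class == "mtDNA_depleted"
        assert obs(tissue="blood").cell_class == "nucleated"

    @pytest.mark.parametrize("kwargs", [
        {"tissue": "muscle"}, {"assay": "nanopore"}, {"call": "maybe"}, {"n": 0},
    ])
    def test_validation(self, kwargs):
        with pytest.raises(EvidenceError):
            obs(**kwargs)


class TestClassification:
    def test_case_fixture_is_called_nuclear(self, case):
        call = classify_minor_source(case.observations)
        assert call.verdict == NUCLEAR_NUMT
        assert any(e["rule"] == "R1_anucleate_contrast" and e["satisfied"]
                   for e in call.evidence)

    def test_minor_in_anucleate_cells_is_heteroplasmy(self):
        observations = [
            obs(call="mixed"),
            obs(tissue="thrombocyte", assay="single_cell", call="mixed", n=50),
            obs(tissue="hair_shaft", call="mixed", n=10),
        ]
        assert classify_minor_source(observations).verdict == MT_HETEROPLASMY

    def test_no_anucleate_evidence_is_inconclusive(self):
        assert classify_minor_source([obs(call="mixed")]).verdict == INCONCLUSIVE

    def test_too_few_anucleate_observations_is_inconclusive(self):
        observations = [obs(call="mixed"),
                        obs(tissue="thrombocyte", assay="single_cell",
                            call="major_only", n=5)]
        assert classify_minor_source(observations).verdict == INCONCLUSIVE

    def test_positive_negative_control_voids_run(self, case):
        dirty = list(case.observations) + [obs(individual="blank", tissue="other",
                                               call="mixed", is_control=True)]
        assert classify_minor_source(dirty).verdict == CONTAMINATION_SUSPECTED

    def test_depleted_cells_with_major_component_block_numt_call(self, case):
        tweaked = [o for o in case.observations if o.cell_class != "mtDNA_depleted"]
        tweaked.append(obs(individual="III.4", tissue="rho0_fibroblast", call="mixed"))
        assert classify_minor_source(tweaked).verdict != NUCLEAR_NUMT

    def test_tolerance_allows_single_contaminated_hair_shaft(self):
        observations = [
            obs(call="mixed"),
            obs(tissue="thrombocyte", assay="single_cell", call="major_only", n=113),
            obs(tissue="hair_shaft", call="major_only", n=55),
            obs(tissue="hair_shaft", call="mixed", n=1),
        ]
        assert classify_minor_source(observations).verdict == NUCLEAR_NUMT

    def test_permutation_invariance(self, case, rng):
        base = classify_minor_source(case.observations)
        shuffled = list(case.observations)
        rng.shuffle(shuffled)
        again = classify_minor_source(shuffled)
        assert again.verdict == base.verdict

    def test_requires_nucleated_observations(self):
        with pytest.raises(EvidenceError, match="nucleated"):
            classify_minor_source([obs(tissue="thrombocyte", assay="single_cell",
                                       call="major_only")])

    @pytest.mark.parametrize("mode,expected", [
        ("numt", NUCLEAR_NUMT), ("heteroplasmy", MT_HETEROPLASMY),
    ])
    def test_simulated_datasets_classified_correctly(self, mode, expected):
        from meganumt.simulate import SimConfig, simulate_pedigree_dataset
        hits = 0
        for seed in range(30):
            res = simulate_pedigree_dataset(SimConfig(seed=seed, mode=mode))
            hits += classify_minor_source(res.observations).verdict == expected
        assert hits == 30


class TestSegregation:
    def test_case_fixture_single_founder_conflict(self, case):
        report = check_segregation(case.pedigree)
        assert not report.consistent
        assert len(report.conflicts) == 1
        assert report.conflicts[0]["individual"] == "II.2"
        assert {report.conflicts[0]["mother"], report.conflicts[0]["father"]} == {"I.1", "I.2"}

    def test_case_fixture_transmission_tally(self, case):
        transmitted, opportunities = check_segregation(case.pedigree).transmissions
        # oracle: hand count over the bundled pedigree (II.2 -> 2/3,
        # III.2 -> 2/2, III.4 -> 3/3, IV.1 -> 0/1 typed children)
        assert (transmitted, opportunities) == (7, 9)

    def test_single_carrier_founder_is_consistent(self):
        p = Pedigree({"A": Individual(sex="F")}, {"A": "carrier"})
        report = check_segregation(p)
        assert report.consistent and report.conflicts == ()

    def test_unknown_parent_status_never_counts_as_non_carrier(self):
        p = Pedigree(
            {"M": Individual(sex="F"), "F": Individual(sex="M"),
             "C": Individual(sex="F", mother="M", father="F")},
            {"M": "unknown", "F": "non_carrier", "C": "carrier"})
        assert check_segregation(p).consistent

    def test_obligate_carrier_on_path_between_carriers(self):
        p = Pedigree(
            {"GM": Individual(sex="F"), "GF": Individual(sex="M"),
             "P": Individual(sex="F", mother="GM", father="GF"),
             "S": Individual(sex="M"),
             "C": Individual(sex="M", mother="P", father="S")},
            {"GM": "carrier", "C": "carrier", "S": "non_carrier"})
        report = check_segregation(p)
        assert "P" in report.obligate_carriers

    def test_mendelian_simulations_never_conflict(self):
        from meganumt.simulate import SimConfig, simulate_pedigree_dataset
        for seed in range(25):
            res = simulate_pedigree_dataset(SimConfig(seed=seed))
            assert check_segregation(res.pedigree).consistent

    def test_corrupting_carrier_parents_always_flags(self):
        from meganumt.simulate import SimConfig, simulate_pedigree_dataset
        flagged = 0
        for seed in range(25):
            res = simulate_pedigree_dataset(SimConfig(seed=seed))
            p = res.pedigree
            carrier_child = next(
                (i for i, ind in p.individuals.items()
                 if p.status(i) == "carrier" and ind.mother and ind.father), None)
            if carrier_child is None:
                continue
            ind = p.individuals[carrier_child]
            corrupted = dict(p.carrier_status)
            corrupted[ind.mother] = corrupted[ind.father] = "non_carrier"
            report = check_segregation(Pedigree(p.individuals, corrupted))
            assert len(report.conflicts) >= 1
            flagged += 1
        assert flagged > 10

    def test_pedigree_validation(self):
        with pytest.raises(EvidenceError, match="unknown parent"):
            Pedigree({"C": Individual(mother="nobody")}, {})
        with pytest.raises(EvidenceError, match="sex"):
            Pedigree({"M": Individual(sex="M"),
                      "C": Individual(mother="M")}, {})


class TestMatriline:
    def test_case_fixture_has_no_violations(self, case):
        assert check_matriline(case.pedigree, case.true_mitotypes) == []

    def test_child_differing_from_mother_is_flagged(self):
        p = Pedigree({"M": Individual(sex="F"),
                      "C": Individual(sex="F", mother="M")}, {})
        mts = {"M": parse_mitotype("263G"), "C": parse_mitotype("263G 16093C")}
        violations = check_matriline(p, mts)
        assert len(violations) == 1 and violations[0]["individual"] == "C"

    def test_missing_mother_or_mitotype_skipped(self):
        p = Pedigree({"M": Individual(sex="F"),
                      "C": Individual(sex="F", mother="M")}, {})
        assert check_matriline(p, {"C": parse_mitotype("263G")}) == []

    def test_ambiguous_mitotype_rejected(self, case, mixed_mitotype):
        p = Pedigree({"M": Individual(sex="F"),
                      "C": Individual(sex="F", mother="M")}, {})
        mts = {"M": mixed_mitotype, "C": mixed_mitotype}
        with pytest.raises(EvidenceError, match="unambiguous"):
            check_matriline(p, mts)
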