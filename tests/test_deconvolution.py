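"""Two-source deconvolution, fraction estimation and the Sanger call model."""

import itertools

import numpy as np
import pytest
from scipy.stats import beta

from meganumt.deconvolution import (
    DeconvolutionError, deconvolve_two_source, detect_mixed_positions,
    estimate_fraction, sanger_call,
)
from meganumt.fixtures import HV0_COMPONENT_STR, U4C1_COMPONENT_STR
from meganumt.haplogroups import DEFAULT_HOTSPOTS, MotifTable, assign_haplogroup
from meganumt.mitotype import (
    CONTROL_REGION, Mitotype, Variant, mix, parse_mitotype, serialize_mitotype,
)
from meganumt.reference import load_reference


def brute_force_deconvolve(m, table):
    """Independent oracle: enumerate all 2^k assignments without symmetry
    collapse; best unordered pair by (pair score, smaller serialization)."""
    ref = load_reference()
    amb = list(m.ambiguous_variants)
    fixed = [v for v in m.variants if not v.is_ambiguous]
    best_key, best_pair = None, None
    for alleles in itertools.product(*[sorted(v.bases) for v in amb]):
        comp_a_vars = list(fixed)
        comp_b_vars = list(fixed)
        for v, allele in zip(amb, alleles):
            other = next(iter(v.bases - {allele}))
            for out, al in ((comp_a_vars, allele), (comp_b_vars, other)):
                if v.insertion_index:
                    out.append(Variant(v.position, al, v.insertion_index))
                elif al != ref[v.position - 1]:
                    out.append(Variant(v.position, al))
        a = Mitotype(tuple(comp_a_vars), m.covered_range)
        b = Mitotype(tuple(comp_b_vars), m.covered_range)
        score = (assign_haplogroup(a, table)[0].score
                 + assign_haplogroup(b, table)[0].score)
        names = sorted([serialize_mitotype(a), serialize_mitotype(b)])
        key = (-score, names[0], names[1])
        if best_key is None or key < best_key:
            best_key, best_pair = key, frozenset({a, b})
    return best_pair


class TestDetectMixed:
    def test_mixed_blood_call_has_eleven_sites(self, mixed_mitotype):
        assert len(detect_mixed_positions(mixed_mitotype)) == 11

    def test_unambiguous_has_none(self, hv0):
        assert detect_mixed_positions(hv0) == []

    def test_single_mixed_site(self):
        m = parse_mitotype("73R")
        assert [v.token() for v in detect_mixed_positions(m)] == ["73R"]


class TestDeconvolution:
    def test_case_mixture_resolves_to_printed_components(self, mixed_mitotype, motifs):
        r = deconvolve_two_source(mixed_mitotype, motifs)
        assert serialize_mitotype(r.component_a) == HV0_COMPONENT_STR
        assert serialize_mitotype(r.component_b) == U4C1_COMPONENT_STR
        assert r.hg_b.haplogroup == "U4c1"
        assert r.n_ambiguous == 11 and r.n_candidates_evaluated == 2 ** 10
        assert mix(r.component_a, r.component_b) == mixed_mitotype

    def test_unambiguous_input_returns_itself_twice(self, hv0, motifs):
        r = deconvolve_two_source(hv0, motifs)
        assert r.component_a == r.component_b == hv0
        assert r.hg_a == r.hg_b

    def test_single_site_matches_brute_force(self, motifs):
        m = parse_mitotype("73R")
        r = deconvolve_two_source(m, motifs)
        assert {r.component_a, r.component_b} == brute_force_deconvolve(m, motifs)

    def test_matches_brute_force_up_to_ten_sites(self, motifs, rng):
        ref = load_reference()
        hv0_vars = [v for v in motifs.cumulative_motif("HV0")]
        u_vars = [v for v in motifs.cumulative_motif("U4c1") if v.position != 4580]
        for k_target in (2, 3, 5, 8, 10):
            ka = min(k_target // 2 + 1, len(hv0_vars))
            kb = min(k_target - k_target // 2 + 3, len(u_vars))
            a = Mitotype(tuple(hv0_vars[:ka]), (CONTROL_REGION,))
            b = Mitotype(tuple(u_vars[:kb]), (CONTROL_REGION,))
            m = mix(a, b, ref)
            if not m.ambiguous_variants:
                continue
            r = deconvolve_two_source(m, motifs)
            assert {r.component_a, r.component_b} == brute_force_deconvolve(m, motifs)

    def test_round_trip_recovery_rate(self, motifs, rng):
        """mix -> deconvolve on random clade haplotypes with <= 2 private
        variants per component: the re-mix identity holds on every run, the
        clade motifs are partitioned correctly in >= 95% of seeded trials,
        and recovery is exact whenever the pair is identifiable (a private
        variant yields the same mixed string whichever component carries it,
        so its attachment is inherently ambiguous)."""
        ref = load_reference()
        hv0 = sorted(motifs.cumulative_motif("HV0"), key=lambda v: v.position)
        u4c1 = sorted((v for v in motifs.cumulative_motif("U4c1") if v.position != 4580),
                      key=lambda v: v.position)
        motif_keys = {v.key for v in hv0} | {v.key for v in u4c1}
        used = {v.position for v in hv0 + u4c1} | DEFAULT_HOTSPOTS
        free = [p for p in CONTROL_REGION.positions() if p not in used]
        partition_ok = exact_eligible = exact_ok = 0
        trials = 200
        for _ in range(trials):
            parts, n_private = {}, 0
            for name, motif in (("a", hv0), ("b", u4c1)):
                extra = []
                for i in rng.choice(len(free), size=int(rng.integers(0, 3)), replace=False):
                    pos = free[int(i)]
                    alt = "ACGT"[("ACGT".index(ref[pos - 1]) + 1) % 4]
                    extra.append(Variant(pos, alt))
                n_private += len(extra)
                parts[name] = Mitotype(tuple(motif + extra), (CONTROL_REGION,))
            mixed = mix(parts["a"], parts["b"], ref)
            r = deconvolve_two_source(mixed, motifs)
            assert mix(r.component_a, r.component_b, ref) == mixed
            got = {frozenset(v.key for v in c.variants if v.key in motif_keys)
                   for c in (r.component_a, r.component_b)}
            want = {frozenset(v.key for v in c.variants if v.key in motif_keys)
                    for c in parts.values()}
            partition_ok += got == want
            if n_private == 0:
                exact_eligible += 1
                exact_ok += ({r.component_a, r.component_b}
                             == {parts["a"], parts["b"]})
        assert partition_ok / trials >= 0.95
        assert exact_eligible > 5 and exact_ok == exact_eligible

    def test_three_allele_code_rejected(self, motifs):
        with pytest.raises(DeconvolutionError, match="3 bases"):
            deconvolve_two_source(parse_mitotype("73D"), motifs)

    def test_site_cap_enforced(self, mixed_mitotype, motifs):
        with pytest.raises(DeconvolutionError, match="cap"):
            deconvolve_two_source(mixed_mitotype, motifs, max_ambiguous=5)

    def test_empty_motif_table_rejected(self, mixed_mitotype):
        with pytest.raises(DeconvolutionError, match="empty motif table"):
            deconvolve_two_source(mixed_mitotype, MotifTable({}))


class TestFractionEstimate:
    def test_zero_count_upper_bound_closed_form(self):
        # oracle: 1 - (alpha/2)^(1/n) for zero successes
        est = estimate_fraction(0, 249)
        assert est.point == 0.0 and est.ci_low == 0.0
        assert est.ci_high == pytest.approx(1 - 0.025 ** (1 / 249), abs=1e-9)
        assert est.ci_high == pytest.approx(0.0146, abs=5e-4)

    def test_full_count(self):
        est = estimate_fraction(30, 30)
        assert est.point == 1.0 and est.ci_high == 1.0
        assert est.ci_low == pytest.approx(0.025 ** (1 / 30), abs=1e-9)

    def test_blood_clone_fraction(self):
        est = estimate_fraction(35, 100)
        assert est.point == 0.35
        assert est.ci_low <= 0.35 <= est.ci_high

    @pytest.mark.parametrize("minor,total", [(-1, 10), (11, 10), (0, 0)])
    def test_invalid_counts(self, minor, total):
        with pytest.raises(ValueError):
            estimate_fraction(minor, total)

    def test_coverage_close_to_nominal(self, rng):
        p, n, reps = 0.3, 50, 2000
        hits = 0
        draws = rng.binomial(n, p, size=reps)
        for k in draws:
            est = estimate_fraction(int(k), n)
            hits += est.ci_low <= p <= est.ci_high
        # Clopper-Pearson is exact-or-conservative
        assert 0.94 <= hits / reps <= 1.0


class TestSangerCall:
    def test_above_lod_shows_mixture(self, hv0, u4c1, mixed_mitotype):
        call = sanger_call((hv0, u4c1), minor_fraction=0.35)
        assert call == mixed_mitotype
        assert len(call.ambiguous_variants) == 11

    def test_below_lod_shows_major_only(self, hv0, u4c1):
        assert sanger_call((hv0, u4c1), minor_fraction=0.0) == hv0
        assert sanger_call((hv0, u4c1), minor_fraction=0.19) == hv0

    def test_threshold_is_inclusive(self, hv0, u4c1, mixed_mitotype):
        assert sanger_call((hv0, u4c1), minor_fraction=0.20) == mixed_mitotype

    def test_invalid_fraction(self, hv0, u4c1):
        with pytest.raises(ValueError):
            sanger_call((hv0, u4c1), minor_fraction=1.5)
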