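"""Two-source deconvolution of mixed mitotypes and mixture-fraction estimation.

A multi-copy Mega-NUMT co-amplified with genuine mtDNA produces Sanger calls
with IUPAC ambiguity codes at every position where the nuclear insert and the
authentic mtDNA differ.  Assuming exactly two contributing sequences, each
ambiguous site assigns one allele to each component; the phylogenetically
plausible resolution is found by exhaustive enumeration of the 2^(k-1)
assignments (swap symmetry collapsed) scored against a haplogroup motif
table.  An allele equal to the reference base means the component simply
carries no variant at that position.

Mixture proportions (e.g. fractions of cloned amplicons carrying the minor
haplotype) are estimated with exact binomial (Clopper-Pearson) intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as _beta

from .haplogroups import DEFAULT_HOTSPOTS, HgScore, MotifTable, assign_haplogroup
from .mitotype import (
    Mitotype, MitotypeError, Variant, mix, serialize_mitotype,
)
from .reference import load_reference

__all__ = [
    "DeconvolutionResult", "FractionEstimate",
    "detect_mixed_positions", "deconvolve_two_source",
    "estimate_fraction", "sanger_call",
]


class DeconvolutionError(MitotypeError):
    """Raised when a mixture is not amenable to two-source deconvolution."""


@dataclass(frozen=True)
class DeconvolutionResult:
    component_a: Mitotype
    component_b: Mitotype
    hg_a: HgScore
    hg_b: HgScore
    pair_score: float
    n_ambiguous: int
    n_candidates_evaluated: int

    def as_dict(self) -> dict:
        return {
            "component_a": serialize_mitotype(self.component_a),
            "component_b": serialize_mitotype(self.component_b),
            "hg_a": self.hg_a.as_dict(),
            "hg_b": self.hg_b.as_dict(),
            "pair_score": round(self.pair_score, 6),
            "n_ambiguous": self.n_ambiguous,
            "n_candidates_evaluated": self.n_candidates_evaluated,
        }


@dataclass(frozen=True)
class FractionEstimate:
    """Point estimate and exact 95% CI for a minor-component count fraction."""

    n_minor: int
    n_total: int
    point: float
    ci_low: float
    ci_high: float

    def as_dict(self) -> dict:
        return {
            "n_minor": self.n_minor, "n_total": self.n_total,
            "point": round(self.point, 6),
            "ci_low": round(self.ci_low, 6), "ci_high": round(self.ci_high, 6),
        }


def detect_mixed_positions(m: Mitotype) -> list[Variant]:
    """The ambiguous (IUPAC mixed-base) variants of a mitotype, canonical order."""
    return list(m.ambiguous_variants)


def _resolve_component(
    m: Mitotype, amb: list[Variant], alleles: list[str], ref: str
) -> Mitotype:
    """Build one component: shared unambiguous variants plus the assigned
    allele at each mixed site; reference alleles become absence-of-variant."""
    variants = [v for v in m.variants if not v.is_ambiguous]
    for v, allele in zip(amb, alleles):
        if v.insertion_index:
            variants.append(Variant(v.position, allele, v.insertion_index))
        elif allele != ref[v.position - 1]:
            variants.append(Variant(v.position, allele))
    return Mitotype(tuple(variants), m.covered_range)


def deconvolve_two_source(
    m: Mitotype,
    table: MotifTable,
    hotspot_mask: frozenset[int] | set[int] = DEFAULT_HOTSPOTS,
    reference: str | None = None,
    max_ambiguous: int = 20,
) -> DeconvolutionResult:
    """Resolve a mixed mitotype into its two most plausible haplotypes.

    Every ambiguous code must denote exactly two bases (three-or-more-allele
    codes imply more than two sources and are rejected).  All 2^(k-1) allele
    assignments are enumerated — component_a is anchored to the alphabetically
    first allele of the first mixed site — and the pair maximising the sum of
    the two top haplogroup scores wins; ties break on the lexicographically
    smaller serialization of component_a.  The winning pair always satisfies
    ``mix(component_a, component_b) == m``.
    """
    if len(table) == 0:
        raise DeconvolutionError("empty motif table: no phylogenetic constraint available")
    ref = reference if reference is not None else load_reference()
    amb = list(m.ambiguous_variants)
    for v in amb:
        if len(v.bases) != 2:
            raise DeconvolutionError(
                f"variant {v.token()} denotes {len(v.bases)} bases; "
                "only two-contributor mixtures are supported")
    k = len(amb)
    if k > max_ambiguous:
        raise DeconvolutionError(f"{k} ambiguous sites exceed the cap of {max_ambiguous}")

    if k == 0:
        top = assign_haplogroup(m, table, hotspot_mask)[0]
        return DeconvolutionResult(m, m, top, top, 2 * top.score, 0, 1)

    site_bases = [sorted(v.bases) for v in amb]
    n_candidates = 2 ** (k - 1)

    # Vectorised exhaustive search: for each haplogroup the match and private
    # counts are additive over the per-site allele choices, so every
    # candidate's score is computed with two small matrix products.
    mask = frozenset(hotspot_mask)
    names = table.names()
    expected = {
        name: frozenset(
            v for v in table.cumulative_motif(name)
            if v.position not in mask and any(v.position in iv for iv in m.covered_range))
        for name in names
    }
    fixed_obs = frozenset(
        v for v in m.variants if not v.is_ambiguous and v.position not in mask)

    # per site and allele: the variant each component would carry (None when
    # the allele equals the reference base, i.e. absence-of-variant)
    site_variant: list[list[Variant | None]] = []
    for v in amb:
        pair: list[Variant | None] = []
        for base in site_bases[len(site_variant)]:
            if v.insertion_index:
                pair.append(Variant(v.position, base, v.insertion_index))
            elif base != ref[v.position - 1]:
                pair.append(Variant(v.position, base))
            else:
                pair.append(None)
        site_variant.append(pair)

    H = len(names)
    e_size = np.array([len(expected[n]) for n in names], dtype=float)
    base_m = np.array([len(expected[n] & fixed_obs) for n in names], dtype=float)
    base_p = len(fixed_obs) - base_m
    am = np.zeros((H, k, 2))
    ap = np.zeros((H, k, 2))
    for i, v in enumerate(amb):
        for c in range(2):
            var = site_variant[i][c]
            if var is None or var.position in mask:
                continue
            for h, name in enumerate(names):
                if var in expected[name]:
                    am[h, i, c] = 1.0
                else:
                    ap[h, i, c] = 1.0

    # allele-choice bit matrix; the first site is anchored to component_a
    bits = np.zeros((n_candidates, k))
    if k > 1:
        bits[:, 1:] = (np.arange(n_candidates)[:, None] >> np.arange(k - 1)) & 1

    def _top_scores(choice: np.ndarray) -> np.ndarray:
        matches = base_m[:, None] + am[:, :, 0] @ (1 - choice).T + am[:, :, 1] @ choice.T
        private = base_p[:, None] + ap[:, :, 0] @ (1 - choice).T + ap[:, :, 1] @ choice.T
        with np.errstate(divide="ignore", invalid="ignore"):
            score = matches / (e_size[:, None] + 0.5 * private)
        vacuous = e_size[:, None] == 0
        score = np.where(vacuous, (private == 0).astype(float), score)
        return score.max(axis=0)

    pair_scores = _top_scores(bits) + _top_scores(1 - bits)
    best_score = pair_scores.max()
    tie_codes = np.nonzero(pair_scores == best_score)[0]

    def _components(code: int) -> tuple[Mitotype, Mitotype]:
        alleles_a = [site_bases[i][int(bits[code, i])] for i in range(k)]
        alleles_b = [site_bases[i][1 - int(bits[code, i])] for i in range(k)]
        return (_resolve_component(m, amb, alleles_a, ref),
                _resolve_component(m, amb, alleles_b, ref))

    best_pair = min((_components(int(c)) for c in tie_codes),
                    key=lambda pair: serialize_mitotype(pair[0]))
    comp_a, comp_b = best_pair
    top_a = assign_haplogroup(comp_a, table, hotspot_mask)[0]
    top_b = assign_haplogroup(comp_b, table, hotspot_mask)[0]
    result = DeconvolutionResult(comp_a, comp_b, top_a, top_b,
                                 top_a.score + top_b.score, k, n_candidates)
    if mix(result.component_a, result.component_b, ref) != m:
        raise AssertionError("internal error: deconvolved pair does not re-mix to the input")
    return result


def estimate_fraction(n_minor: int, n_total: int, confidence: float = 0.95) -> FractionEstimate:
    """Minor-component fraction with an exact Clopper-Pearson interval."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_minor <= n_total:
        raise ValueError("need 0 <= n_minor <= n_total")
    alpha = 1.0 - confidence
    k, n = n_minor, n_total
    low = 0.0 if k == 0 else float(_beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(_beta.ppf(1 - alpha / 2, k + 1, n - k))
    return FractionEstimate(k, n, k / n, low, high)


def sanger_call(
    true_pair: tuple[Mitotype, Mitotype],
    minor_fraction: float,
    lod: float = 0.20,
    reference: str | None = None,
) -> Mitotype:
    """Simulated direct-Sanger call of a two-haplotype mixture.

    ``true_pair`` is (major, minor).  At or above the detection threshold
    *lod* the call is the IUPAC superposition of both haplotypes; below it
    only the major haplotype is seen.  The ~20% default reflects the typical
    minor-component detection limit of fluorescent Sanger traces.
    """
    if not 0.0 <= minor_fraction <= 1.0:
        raise ValueError("minor_fraction must lie in [0, 1]")
    major, minor = true_pair
    if minor_fraction >= lod:
        return mix(major, minor, reference)
    return major
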