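# Methods

## Coordinate model and nomenclature

Positions are 1-based inclusive on the circular 16,569 bp mtDNA reference
(rCRS numbering). Intervals may span the origin; the control region (CR) is
16024–576 with inclusive length 1122. Mitotypes use forensic EMPOP-style
tokens: substitutions `263G`, insertions `315.1C` (k-th base inserted after
the position), deletions `249DEL` (accepted as `249-` on input). Canonical
listing order follows the circular walk of the covered range, so CR strings
begin in the 16024–16569 arc; full-genome mitotypes therefore list in plain
numeric order. Inclusive counting is used for every interval length,
including the quantification amplicons; mixed counting conventions sometimes
seen in print (lengths computed as end − start) are deliberately not
reproduced.

The packaged reference is a **synthetic stand-in**: the true rCRS allele is
guaranteed only at the curated positions listed in
`meganumt.reference.CURATED_BASES` (every position touched by the bundled
haplotypes, the common CR hotspots and the 303–315 C-tract); all other
positions are deterministic pseudo-random bases. Each curated allele is
pinned by the bundled data themselves — an IUPAC mixed call together with its
two resolved components fixes the reference base (e.g. 73R resolving to 73G
in one component and no record in the other implies reference A) — or is a
universally documented hotspot. All bundled analyses and simulations touch
curated positions only. Real-data analyses should pass the genuine rCRS
through the `reference` arguments.

## Mixing and two-source deconvolution

A mixture of two resolved haplotypes is superposed site-wise: where the
haplotypes differ, the IUPAC code covering both alleles is emitted, the
reference base standing in for absence-of-variant. Reference alleles are
"absence of variant" in the other direction too: when an ambiguous site
resolves to the reference base for one component, that component simply has
no record there. Indels private to one component cannot be written on a
single sequence string and raise an explicit error; the bundled data share
their indels (263G, 315.1C) across both components, and the simulator draws
private variants as substitutions only.

Deconvolution assumes **exactly two contributors** (three-plus-allele IUPAC
codes are rejected) and enumerates all 2^(k−1) allele assignments for k
ambiguous sites, component A anchored to the alphabetically first allele of
the first site. Each candidate component is scored against a haplogroup
motif table; the pair maximising the sum of the two top scores wins, ties
broken by the lexicographically smaller serialization of component A. The
search is vectorised (match and private counts are additive over per-site
allele choices), and equality with naive 2^k enumeration is asserted in the
tests. The winning pair always re-mixes exactly to the input; this identity
is checked on every call. The default cap of 20 ambiguous sites bounds the
enumeration at ~half a million candidates.

**Identifiability caveat.** A private variant (present in one component,
absent from the motif table) produces the identical mixed string whichever
component carries it, so its attachment is not recoverable from the mixture
by any method; the score then prefers attaching it to the clade with the
larger motif (smaller relative penalty). The tests therefore assert exact
recovery only for private-free pairs, and correct clade-motif partitioning
in general.

## Haplogroup score

For a clade with cumulative motif E (restricted to the covered range, with
hotspot positions 263, 309, 310, 315 masked) and observed variant set O:

    score = |E ∩ O| / (|E| + 0.5 · |O ∖ E|)

A clade with empty E scores 1 on an empty O (vacuous match, so the root
ranks first for a reference-identical mitotype) and 0 otherwise. The score
is monotone — adding a motif variant never lowers it, adding a private
variant never raises it — and is a deliberately simple, reproducible choice,
not a reimplementation of any published haplogrouping tool. 16519 is *not*
masked by default because the bundled U4c1 motif uses it; the mask is a
parameter. Ranking ties prefer the deeper (more derived) clade, then the
alphabetically first name. The packaged motif table contains root, HV0, V
(child of HV0 with its coding-region defining variant 4580A, which range
masking removes for CR-only data) and U4c1, transcribed from the bundled
component haplotypes minus hotspots; a fuller phylogeny can be loaded from
TSV.

## Sanger detection model and fractions

Direct Sanger sequencing reports the IUPAC superposition when the minor
fraction is at or above the limit of detection (default 0.20, applied as ≥),
otherwise the major haplotype alone. The threshold is configurable because
real traces are reported down to a few percent in favourable assays.
Count-based fractions (clones, single cells) use exact binomial
(Clopper–Pearson) 95 % intervals; the interval is exact-or-conservative, so
empirical coverage in the tests is allowed in [0.94, 1].

## Evidence engine

Cell classes are fixed by tissue: thrombocytes and hair shafts are
anucleate, ρ° fibroblasts are mtDNA-depleted, everything else nucleated.
Rules, in order: any non-clean negative control voids the run
(CONTAMINATION_SUSPECTED); if nucleated tissues show the mixture, at least
`min_anucleate` (default 10) anucleate observations exist, the fraction of
anucleate observations showing the minor component is within
`anucleate_mixed_tolerance` (default 0.05 — this absorbs occasional hair
shafts with nuclear remnants without failing the nuclear call), and any
mtDNA-depleted observations show *only* the minor component, the verdict is
NUCLEAR_NUMT; if anucleate observations carry the minor component above
tolerance, MT_HETEROPLASMY; otherwise INCONCLUSIVE. "Mitochondrial in
origin" deliberately does not distinguish heteroplasmy from paternal
leakage — without a nuclear-insert exclusion they are confounded — and the
verdict carries a note saying so. Nucleated tissues count as "showing the
mixture" on any mixed call or when count-based assays yield both major-only
and minor-only calls.

## Pedigree checks

Segregation: a conflict is a typed carrier both of whose parents are present
and typed non-carrier; unknown status never counts as non-carrier (a
degraded sample must not generate conflicts). Obligate carriers are
estimated as unknown-status individuals whose removal disconnects two typed
carriers in the relationship graph (articulation-point criterion — an
approximation that is exact for the tree-like pedigrees treated here). The
transmission tally counts typed children of carrier parents. The matriline
check flags any individual whose (unambiguous) mtDNA haplotype differs from
their mother's; missing mothers or haplotypes are skipped.

On the bundled pedigree the checker reports exactly one conflict: the
carrier grandmother against the two founder-generation non-carriers. The
bundled data encode both founders as non-carrier as typed, so the conflict
is *flagged, not resolved* — the package takes no position on which founder
actually carried the insert.

## Copy number and insert size

ddPCR: λ = −ln(1 − n₊/n) copies per droplet; concentration =
λ/volume × dilution. Droplet volume defaults to 0.85 nL and cancels from all
ratios; a fully positive well is an error, not an estimate. Copies per
insert = (mt-like : single-copy-autosomal concentration ratio) × ploidy
(default 2, heterozygous carrier in diploid cells), with an optional known
residual-mtDNA fraction removed first (default 0). Replicate ratios are
converted to per-replicate copy values and summarised as mean ± sample SD
(ddof 1), so the reported SD is replicate scatter, not propagated error; a
single replicate reports SD 0 with a warning. Multi-copy autosomal targets
(RNU2, AluYb8) are registered for relative quantification only and are
rejected as copies-per-insert denominators. When both ddPCR and qPCR data
are present the pipeline reports each method and their range, never a pooled
value. Insert size is copies × 16,569 bp, i.e. a tandem repeat of complete
units.

Template topology: a circular template supports any amplicon; a single
linearised unit spanning one contiguous circular run supports an amplicon
only if it is a contiguous sub-run (an origin-spanning amplicon never is,
for a unit linearised at the origin); a tandem repeat of ≥ 2 complete units
realises every junction-spanning amplicon. Hence two long-range products
that jointly wrap the origin exclude the single-linear-unit hypothesis.

## Synthetic data generator

The generator emulates the study design, not arbitrary biology:

- Pedigree: founder couple plus `generations` × `sibship` descendants with
  married-in spouses; genuine mtDNA follows the matriline; a heterozygous
  insert allele in the founding mother drops Mendelianly (p = ½ per parent
  allele).
- Minor fraction in nucleated cells: f = A·C/(A·C + m_tissue) with allele
  count A, tandem copies C (default 45) and per-cell mtDNA numbers
  m(blood) = 84, m(buccal) = 1080, m(hair root) = 5000. These m values are
  back-solved so the defaults reproduce the bundled clone fractions
  (blood ≈ 35 %, buccal ≈ 4 %); they are configuration, not measured
  biology.
- Clones are Bernoulli(f) template draws; single nucleated cells call mixed
  at f ≥ LOD; thrombocytes carry f = 0; hair shafts are clean except for
  nuclear remnants with probability 1/56 per shaft (matching the single
  contaminated shaft in the bundled data); ρ° cells of a carrier yield only
  the insert haplotype.
- ddPCR: each target is read at a dilution targeting λ ≈ 0.8 (recorded, and
  divided back out by the estimator; a 22.5 : 1 mt:autosomal ratio at a
  single dilution would saturate the mt wells), droplet counts
  ~ Binomial(20,000, 1 − e^(−λ)). qPCR concentrations are lognormal around
  truth with CV 0.15. Defaults give n = 20 ddPCR and n = 76 qPCR replicate
  ratios, the bundled reporting shape.
- A `heteroplasmy` mode places the minor haplotype in the mitochondrial pool
  of the matriline instead (fraction 0.35 in all tissues including anucleate
  cells; ρ° cells then yield nothing), providing the contrast the evidence
  engine must distinguish.

Identical seed and configuration produce byte-identical datasets. What the
simulations do **not** model: electropherogram peak heights, read-level
errors, per-cell variation in mtDNA content, PCR efficiency differences
between mitotypes, or NUMT-internal sequence divergence — so passing tests
show the inference chain is correct under its stated model, not that the
model captures every feature of real traces.

## Problem sizes and numerical choices

The statistical guarantees run at deliberately modest sizes chosen to make
sampling error negligible relative to the asserted tolerances: copy-number
recovery over 50 seeds per true value (2-SE criterion), verdict rates over
200 seeds per mode (≥ 99 %), the ddPCR estimator against a 50-replicate
Monte-Carlo partitioning oracle (2 %), Mendelian transmission over ≥ 2000
parent-child pairs (binomial test), CI coverage over 2000 draws.
Deconvolution brute-force equivalence is checked exhaustively for k ≤ 10.
Score ties are resolved deterministically (lexicographic serialization);
all float score comparisons involve exact small-rational arithmetic, so
tie detection is exact.

## Known limitations

- The bundled non-matriline mitotypes and several batch counts are plausible
  placeholders, and the bundled quantification table is a synthetic
  replicate-level reconstruction matching published summary statistics
  (files and docstrings say so); only the counts and haplotypes printed in
  the narrative are authoritative.
- The two quantification methods disagree (45.0 vs 56.2 copies); the package
  reports both and their implied insert-size range, offering no
  reconciliation.
- Haplogroup assignment is a plausibility ranking over a user-supplied motif
  table, not a maximum-likelihood placement on the full mtDNA phylogeny.
- Obligate-carrier detection is graph-topological and can under-report in
  pedigrees with inbreeding loops.
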