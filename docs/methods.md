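# Methods

## The model

`crb1kit` scores biallelic *CRB1* genotypes against the gene's three
retinal transcripts. The model is deliberately simple and rule-based — a
bookkeeping of expression points rather than a probabilistic calibration:

1. **Allele share.** Each of the two alleles accounts for 50 of the 100
   expression points of every isoform (`allele_share`, default 50).
2. **Expression retention.** A variant scales its allele's output by a
   class-specific fraction `f_e`: truncating (nonsense/frameshift) 0,
   canonical splice site 0.05, missense and in-frame 1. The 5% splice
   residual reflects the small wild-type transcript fraction canonical
   ±1..3 sites typically leak; by default it is read as 5% of the
   affected allele's output (2.5 points of 50). An alternative reading —
   5 absolute points of the 100-point total —
   is available as `splice_residual_mode: absolute_points`.
3. **Pathogenic fraction.** Independently of expression, each variant
   carries a pathogenic fraction `p`: truncating 1; splice site
   `1 − f_e = 0.95`; in-frame indel 0.2 (`in_frame_fraction`, the
   hypomorphic-allele reduction); missense `combine(m, s)` with `m`
   binned by the damaging-predictor count `d` out of 15 consulted tools
   (6–10 → 0.5, 11–12 → 0.7, 13–14 → 0.8) and `s = 0.2` per
   splice-prediction tool (of 4) calling a gain or loss, directions
   weighted identically. `d < 6` scores 0 and `d = 15` clamps to 0.8,
   both with a logged warning, since the bins are defined only on 6..14.
4. **Combination.** `combine` is clamped-additive by default,
   `min(1, Σ)`, applied both to `m + s` within a missense variant and
   across variants in cis on one allele (expression losses combine the
   same way on the loss scale). A `multiplicative` alternative,
   `1 − Π(1 − f)`, is configurable; the additive default is the choice
   under which the bundled cohort reproduces the observed group
   separation (most CRD totals above the CD threshold).
5. **Isoform restriction.** A variant contributes to isoform *I* only if
   its exon belongs to *I*'s transcript. Per isoform, expression is
   `Σ_alleles 50 × f_e` and pathogenicity `Σ_alleles 50 × p`, clamped to
   [0, 100].
6. **Total and classification.** Total pathogenicity is the mean over
   A, B, C (equivalently the sum as a percentage of the 300-point
   maximum); `sum_over_affected` (mean over isoforms with nonzero load)
   is the configurable alternative. Severity: CRB1-A pathogenicity ≥ 85
   (`lca_a_loss_threshold`) → LCA; else total ≥ 50 (`cd_total_threshold`)
   → CRD; else total > 0 → CD; else none. Checking the LCA rule first is
   a design choice; the two thresholds are observational bounds, not
   fitted parameters.

Scores are kept at full floating precision internally; reports round to
one decimal.

## Isoform exon model

Published references enumerate exon membership of *CRB1-B* and *CRB1-C*
only schematically; the default model is the unique simple contiguous
assignment consistent with exon 6 being the only exon shared by all
three transcripts and with A spanning all 12 exons:
`A = {1..12}`, `B = {6..12}`, `C = {1..6}`. It ships in the config file
and is overridable (`isoform_model:`); validation enforces the two
structural invariants (exon 6 common to all, A a superset of B and C).
Users with a different transcript annotation — real *CRB1-B/C* structures
may share more exons — can substitute their own map without touching
code.

## Phasing

Clinical tables list zygosity per variant, not phased haplotypes.
Homozygous variants are placed on both alleles — so a proband with two
homozygous variants carries them in cis on each allele — and two
heterozygous variants are placed in trans, one per allele, the standard
compound-heterozygote reading for a recessive disease. More than two
heterozygous variants cannot be phased and are rejected.

## Handled degenerate inputs and numerical choices

- Intronic offsets beyond ±3 raise an unsupported-variant error rather
  than guessing a class; no genomic-coordinate arithmetic is attempted
  (intronic variants take the exon listed in the table).
- A missense variant without a damaging-predictor count is a scoring
  error naming the variant (silently assuming 0 would understate load).
- Deletion/duplication lengths are cross-checked against the stated
  sequence; mismatches are parse errors.
- MAF, ages, and visual-acuity tokens (LP/NLP/HM) are carried through as
  data but never enter the score.

## qPCR quantification

Relative expression uses the efficiency-corrected ratio
`E_t^ΔCq(target) / E_r^ΔCq(ref)` with per-primer amplification
efficiencies `E = 10^(−1/slope)` fitted by least squares on a standard
dilution series (≥ 3 points; perfect doubling corresponds to slope
−3.32). Isoform shares within a sample are efficiency-corrected
quantities of the A/B/C amplicons relative to the total-CRB1 amplicon,
normalized to sum to 1 — the anchor cancels under normalization, so
shares are invariant to a constant Cq shift and to whether the total
amplicon or the isoform sum is used as denominator. Replicates are
averaged on the Cq scale; a Cq at/above 40 cycles counts as undetected
(quantity 0). Efficiencies are constrained to (1, 2.2], doubling plus
tolerance.

## Synthetic cohorts

The generator emulates the statistical structure of the bundled clinical
fixture, not retinal biology: consequence-class mixture
(missense 0.45, in-frame 0.25, truncating 0.20, splice 0.10), exon
weights concentrated on the exon-2/exon-9 hotspots (0.38/0.35),
homozygosity probability 0.3, and damaging-count / splice-token
distributions matching the annotation table — all taken once from the
fixture's empirical frequencies. Variant strings are synthesized in valid
nomenclature on a uniform pseudo-CDS (360 nt per exon) so they survive
the parser round-trip; recurrent draws of the same cDNA string reuse the
same annotated allele, as recurrent alleles do in a real cohort. Truth
labels are defined by the scoring rules themselves applied to the
generated genotype before optional label noise — the generator is a
closed-loop test harness, not an independent disease model, so 100%
agreement at zero label noise verifies pipeline consistency
(parse → phase → score → classify), not clinical validity. Features of
real data it does not emulate: linkage between variant class and family
structure, age/acuity covariates, population allele frequencies, and
genuine diagnostic label noise; passing closed-loop tests therefore says
nothing about classifier accuracy on real patients. qPCR helpers add
optional Gaussian Cq jitter only.

All randomness flows from a single `numpy.random.Generator` seeded via
the simulation config, making every table reproducible from
(config, seed).

## Problem sizes

The bundled fixture (25 probands, 18 variants) runs in well under a
second; property suites use up to 1000 simulated probands, keeping the
full test run in the tens of seconds on one CPU.

## Known limitations

- The score is a heuristic point system; thresholds (85, 50) are
  observational bounds from one cohort and are not calibrated
  probabilities.
- Under the default rules some severe CRD genotypes also exceed the
  CRB1-A LCA threshold, so CRD/LCA separation is imperfect by
  construction; concordance for CRD is reported, not asserted.
- How missense and splice evidence for one variant should interact is
  not identifiable from group-level bounds alone; both combination rules
  are kept configurable.
- The exon model for isoforms B and C is a modeling convention (see
  above), not a measured annotation.
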