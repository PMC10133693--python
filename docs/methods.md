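# Methods

## Problem and estimand

For a gene causing a fully dominant disease, the *genetic prevalence* is
the fraction of a population carrying at least one disease-causing allele.
Population sequencing databases publish, per variant, the alternate allele
count (AC), sometimes the number of genotyped alleles (AN), and the number
of homozygous individuals. From those summaries alone the package
estimates prevalence per 100,000 — the quantity a registry would estimate
by case counting, but without ascertainment bias.

## Inclusion rules

Two curated filters define the disease-causing set:

1. **Missense only.** The target disease mechanism is misfolding of the
   full-length protein, so protein-truncating classes are excluded:
   stop-gain, frameshift, splice, intronic, non-coding (UTR) and
   synonymous variants are dropped, each with a logged reason. Consequence
   classes are inferred from the HGVS notation: a frameshift marker or
   stop-gain in the protein change wins; UTR syntax (`c.-12…`, `c.*34…`)
   is non-coding; an intronic offset within ±2 bases of an exon boundary
   is splice (the canonical splice-site definition; the window is
   configurable since summary tables rarely state one), deeper offsets
   intronic; otherwise ref≠alt amino acids make a missense. Start-loss
   (codon 1 Met substituted) removes the start codon rather than altering
   the folded chain, so it is classed `other`, not missense.
2. **ACMG pathogenic or likely pathogenic.** Classification is a curated
   input (the five-tier ACMG labels), not computed: no evidence-code
   combining is performed. Variants with no curated entry default to
   `uncertain_significance` — and are therefore excluded — which is the
   conservative choice; a strict mode errors instead.

## Estimator

With ΣAC alleles and Σhom homozygotes over the disease-causing set in N
sequenced individuals:

- carriers = ΣAC − Σhom (a homozygote is two alleles, one person); for
  databases that report carrier individuals directly, the count is used
  unchanged — the unit travels with the table so the two are never mixed;
- aggregate disease-allele frequency q = (ΣAC − Σhom)/(2N);
- prevalence per 100,000 = 10⁵ · f · carriers/N, penetrance f ∈ (0,1].

The denominator is the cohort-level N from database metadata (2N alleles),
not per-site AN, because gene-level summary tables typically print no AN;
a per-site AN mode exists for VCF input. The homozygote adjustment in q is
an inference from the arithmetic of the reference analysis (it is the
unique simple rule consistent with both the published aggregate frequency
and the published prevalence); it is exposed as such, not hidden.

Penetrance defaults to 1 — every carrier a prospective case — because
penetrance for the reference gene could not be determined from these data;
the scalar is exposed so sensitivity analyses can rescale linearly
(estimates are exactly linear in f).

An alternative estimator treats q under Hardy–Weinberg equilibrium:
prevalence = 10⁵ · f · (1 − (1 − q)²). The two differ by the q² term only
(relative gap ≤ q), which is negligible at rare-disease frequencies; both
are exposed for transparency.

**Compound heterozygotes.** Summary data cannot see that one individual
carries two different pathogenic variants; `carriers = ΣAC − Σhom` counts
such a person twice. The simulator quantifies the gap (at q ≈ 0.002 it is
a fraction of a percent of carriers; see
`analysis/04_simulation_validation.py`).

**Uncertainty.** A Wilson score interval on carriers/N (default 95%),
scaled per 100,000. Wilson was chosen over the exact Clopper–Pearson
interval for its better average coverage at small counts; the tests pin
the Wilson endpoints against a Clopper–Pearson oracle computed from Beta
quantiles (upper endpoints agree within ~1–3%, lower endpoints within a
few per 100,000 at the counts arising here).

**Cross-database interval.** Databases differ in design (general
population vs clinical referrals), so estimates are not pooled; the
reported interval is the min–max envelope of the point estimates.

## Stratification

A subpopulation's complement within a cohort is the exact elementwise
difference of (variants, AC, hom, N), and conservation (sub + complement =
total) holds by construction. Published splits need not satisfy this: in
the bundled reference data the African/African-American split (402 alleles
in 12,487 exomes) leaves a derived complement of 68 alleles, while the
source reports 65 in 113,261 — evidence of undocumented extra exclusions.
The pipeline computes the faithful complement, warns about the mismatch,
and uses the reported numbers for the headline non-African estimate. The
reported non-African allele frequency is computed as 65/(2·113,261) =
0.000287 (the source's printed value drops a decimal place).

## HGVS handling and protein numbering

The in-package HGVS support covers exactly the shapes that occur in
gene-level summary tables: cDNA single-nucleotide substitutions with UTR
prefixes and intronic offsets, and protein substitutions, identity, stop
gains and frameshift markers (1-letter and 3-letter codes, predicted
changes in parentheses). The canonical internal form is 1-letter. Embedded
whitespace and a missing cDNA reference base (`c.148 > A`) are tolerated
because published tables contain both. Deletions/insertions, duplications
and repeat syntax are out of scope. Genomic keys for substitution rows are
completed from the cDNA alleles, which assumes a plus-strand gene (true
for *TTR*); rows without a resolvable genomic key join on transcript +
cDNA instead.

Legacy *TTR* literature numbers residues on the mature protein (V30M);
databases use the full precursor (V50M). `convert_numbering` shifts codons
by the 20-residue signal peptide in either direction and refuses to assign
a mature number inside the signal peptide.

## Synthetic cohorts

The simulator draws diploid genotypes per individual and variant under
Hardy–Weinberg equilibrium at specified per-population allele frequencies,
with variants unlinked — adequate for validating an estimator that itself
ignores phase. A single global seed expands into independent substreams
per (population, variant) via SHA-256 hashing into a `SeedSequence`, so
identical specs give byte-identical summaries and adding a variant leaves
the other columns' draws untouched.

Bundled cohort shapes mirror the three reference databases: a
multi-ancestry exome cohort of 125,748 individuals across 8 populations
(the African/African-American size fixed at the reported 12,487; the other
seven are realistic relative sizes chosen once to reach the total) with
the six disease-causing variants on a frequency ladder from 4×10⁻⁶ to
1.7×10⁻³, the V142I variant at 0.016 in African ancestry and rare
elsewhere, plus benign/synonymous context rows; a single-population cohort
of 10,588 with two singleton pathogenic variants; and a referral cohort of
45,392 with fifteen rare pathogenic variants (expected ≈34 carriers).

What the simulator does *not* emulate: relatedness, linkage/haplotype
structure, sequencing error, site-level missingness (AN is exactly 2N),
and referral bias in clinical cohorts. Passing validation therefore shows
the estimator is correct *given* faithful summary counts under HWE; it
says nothing about ascertainment artifacts in real databases.

Problem sizes in the validation suite — 200 replicates at N = 10,000,
p = 0.001 for estimator consistency, and tens of replicates at the full
125,748-individual scale for allele-count calibration — were chosen so the
Monte-Carlo standard error is a few per 100,000, small relative to the
effects under test.

## Numerical and design notes

- Display rounding (prevalence to 1 decimal, frequencies to 3 significant
  figures) is applied only when rendering; computation always proceeds at
  full float precision, and reports carry both.
- The Wilson lower bound is clamped to exactly 0 at zero successes.
- Penetrance multiplies the f = 1 estimate exactly (no re-association of
  the floating-point product), so linearity is bit-exact.
- Count invariants are enforced at construction: AC ≤ AN, hom ≤ AC/2,
  AN ≤ 2N, subpopulation sums never exceed the pooled count.
- Mixed count units (alleles vs individuals) refuse to aggregate.
- `aggregate` takes N from cohort metadata; the reference analysis uses
  the locus-average 125,780 exomes for the pooled estimate and the cohort
  total 125,748 (12,487 African + 113,261 non-African) for stratification,
  exactly as the source data are published.

## Known limitations

- Penetrance is an external scalar; age- or sex-structured penetrance and
  onset modelling are out of scope.
- Carrier counts from summaries overcount compound heterozygotes (bounded
  and quantified, not corrected).
- ACMG classifications are trusted inputs; reclassification over time
  changes the estimates.
- Clinical referral cohorts are not population samples; their estimate is
  an envelope bound, not an unbiased population prevalence.
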