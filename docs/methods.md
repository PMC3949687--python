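# Methods

## The diagnostic problem

Usher syndrome type 1 (USH1) is an autosomal recessive disorder combining
congenital profound hearing loss, absent vestibular function and
prepubertal retinitis pigmentosa (RP).  Molecular diagnosis screens a
nine-gene amplicon panel (*MYO7A*, *USH1C*, *CDH23*, *PCDH15*, *USH1G*,
*USH2A*, *GPR98*, *DFNB31*, *CLRN1*) and must turn a noisy per-patient
variant callset into one of a small set of categorical genotype diagnoses:
**solved biallelic** (homozygous, or compound heterozygous in trans, in
one gene), **digenic** (one heterozygous pathogenic variant in each of two
genes), **monoallelic** (a single heterozygous finding), or **unsolved** —
optionally with **modifier candidates**, rare damaging missense variants
in a second USH1 gene that plausibly shift RP onset without being causal.

`usherdx` implements that decision chain as composable stages plus a
simulator that generates cohorts with known planted diagnoses, so each
stage has a ground-truth recovery test without external data.

## Filtering and zygosity

A call survives QC iff mean base quality ≥ 25 (Phred), depth ≥ 10 reads,
and its alternate-allele fraction lies in the heterozygous band
[0.40, 0.60] or the homozygous band [0.80, 1.00].  Both band bounds are
inclusive at both ends — the bands are stated as closed ranges, and the
boundary values 0.40/0.60/0.80/1.00 are accepted.  Fractions in the gap
(0.60, 0.80) are rejected outright rather than flagged as mosaic: on a
germline amplicon panel they indicate artifacts.  Rejection logging uses
a fixed predicate order (depth, quality, band, consequence class, rarity)
so each removed call carries exactly one primary reason and logs are
deterministic.

## Annotation

Consequence is classified from the HGVS strings alone (the panel works in
transcript space; no genome projection).  The coding grammar is a
deliberately small hand-rolled subset — substitutions with optional
intronic offsets, del/dup/ins with optional ranges — and anything outside
it raises a parse error naming the token instead of guessing.  Splice
means an intronic offset within the canonical ±2 dinucleotides; frameshift
means `fs` in the protein change or a length change that is not a multiple
of three; nonsense a substitution ending in a stop; missense a
single-residue substitution.

Rarity requires allele frequency < 1% in each of three sources (1000
Genomes, the 5400-exome set, and an in-house control panel of 384
alleles); an unknown frequency passes, since novel variants are absent
from every catalog.  Tiering is categorical: truncating classes
(nonsense/frameshift/splice) are *pathogenic*; rare missense variants are
*probable pathogenic* iff SIFT ≤ 0.05 **or** PolyPhen-2 ≥ 0.5 (the OR
rule is needed because tolerated-by-SIFT scores of 0.09 and 0.19 co-occur
with PolyPhen scores near 1 among accepted variants), otherwise
*uncertain*; common variants are *excluded*.  Prediction scores and
population frequencies are inputs, never computed here.

## Diagnosis

Decision order per patient, over pathogenic/probable-pathogenic variants:

1. a gene with a homozygous qualifying variant, or two heterozygous ones
   in trans or undetermined phase → solved biallelic (two heterozygous
   qualifying variants without family data are *assumed* biallelic);
2. else exactly one qualifying heterozygous variant in each of exactly two
   genes → digenic, requiring trans when a pedigree exists; a cis pair is
   downgraded to independent monoallelic findings;
3. else exactly one qualifying heterozygous variant → monoallelic; with no
   qualifying variant at all, a single surviving rare heterozygous variant
   of uncertain significance is still reported as monoallelic (a weak
   single finding is what triggers orthogonal follow-up in practice);
4. else unsolved.

Phase comes from parental genotypes: trans iff exactly one variant traces
to each parent; Mendelian consistency is checked strictly over all
genotyped members (de novo is not assumed).  Modifier candidates attach to
solved patients only: damaging missense variants in a *different* USH1
gene, gated on predictor damage alone — rarity is reported but not
applied, because an established modifier allele can be common (the cohort
contains one at 26% control frequency).  Monoallelic and unsolved patients
form the Sanger fallback list: the amplicon platform cannot see variants
outside its design (~3% of target exons) or indels in homopolymer runs, so
those cases are re-sequenced orthogonally.

## Cohort report and the onset comparison

The summary counts patients with ≥ 1 non-excluded variant (the yield),
per-gene biallelic frequencies over all patients, distinct causal variants
by canonical key (gene + case-folded HGVS), novel variants (absent from
the previously-reported catalog), platform-detectable variants (no
detectability flag), and the digenic/modifier tallies.  Percentages are
rendered to one decimal with round-half-away-from-zero.

The modifier/onset comparison contrasts night-blindness onset in
biallelic patients carrying a modifier candidate against biallelic
patients without one; patients with unknown onset are excluded (onset is
undefined for them), and the digenic patient is excluded by default (an
`include_digenic` switch adds them).  Two tests are reported side by side:
Welch's unequal-variance t (statistic and Welch–Satterthwaite df
implemented from the formulas; two-sided p from the t distribution) and an
exact permutation test enumerating all C(n, n₁) group assignments of the
pooled onsets with |Δmean| as statistic.  On the packaged cohort the two
give p ≈ 0.007 and p = 4/84 ≈ 0.048 respectively — within an order of
magnitude, which is what small-sample t p-values against exact tests
typically achieve; both are reported rather than reconciled.  Tests
cross-check the Welch implementation against `scipy.stats.ttest_ind` and
against direct numerical integration of the t density, and the permutation
p against an independent brute-force enumeration.

## The simulator

`simulate_cohort` emulates the statistical structure of the amplicon
sequencing regime, not its signal chain (no reads, flow-space model or
alignment):

| parameter | default | why |
|---|---|---|
| `mean_depth` | 314.2× | the panel's reported mean target coverage |
| `depth_dispersion` | 8 (negative-binomial size) | amplicon coverage is strongly overdispersed relative to Poisson; only the mean is reported, so the dispersion is configuration |
| `mean_base_quality`, `base_quality_sd` | Q30 ± 2 | comfortably above the Q25 filter, with a realistic tail below it |
| `error_rate` ε | 0.01 | typical semiconductor-sequencing substitution regime; homozygous allele fraction is 1 − ε |
| `covered_fraction` | 0.97 | fraction of target exons designable; a planted variant is invisible with probability 0.03 |
| `homopolymer_fraction` / `homopolymer_miss_prob` | 0.2 / 0.5 | share of planted indels sitting in homopolymer runs, and the chance the chemistry misses them (modelled as *non-detection*, the platform's observed failure mode, never as a miscall) |
| `background_polymorphism_rate` | 2 per patient | common variants (frequency ≥ 5%) the rarity filter must remove |
| `diagnosis_mix` | 8:4:1:3:1 /17 | biallelic : biallelic-with-modifier : digenic : monoallelic : unsolved, the composition of a 17-patient USH1 screening cohort |

Depth is NegBin(mean, size); the alternate-read count is Binomial(depth,
p) with p = 0.5 (het) or 1 − ε (hom), so heterozygous fractions
concentrate in 40–60% and homozygous ones in 80–100% exactly as the
filter assumes.  Trio pedigrees with phase-consistent parental genotypes
accompany digenic and compound-heterozygous probands.  HGVS labels are
synthetic (codon indices drawn from a wide range to keep cohort-level
variant keys unique); they are syntactically valid and classified by the
real grammar.  All randomness flows from one seed; patient *i* draws from
the child stream `[seed, i]`, making cohorts byte-identical across runs.

What the simulator does **not** model: mapping artifacts, strand bias,
systematic amplicon dropout correlated across patients, miscalls in
homopolymers (only non-detection), population structure in the background
variants, and variant co-occurrence (every planted variant is
independent).  Passing recovery tests therefore demonstrate the decision
chain's correctness under the stated noise model, not robustness to
artifacts the model omits.

## Recovery oracles and numerical choices

Two analytic oracles back the recovery tests.  Detectability: a planted
variant is seen with probability `covered_fraction`, times
`1 − homopolymer_miss_prob` if it is a homopolymer indel; the empirical
detection fraction over 10⁵ planted variants must sit within 3 standard
errors.  Category: given which qualifying calls actually survived
measurement, the expected diagnosis follows by direct enumeration (a lost
compound-het allele degrades to monoallelic, a lost homozygote to
unsolved, a surviving het pair across two genes reads as digenic); the
pipeline must agree exactly, per patient, across seeded cohorts.  Recovery
is conditioned on *measurement* survival because binomial allele-fraction
tails at low depth, and base-quality draws below Q25, legitimately remove
a call — that is data loss, not a classification error.

Degenerate inputs raise rather than guess: empty cohorts, overlapping
zygosity bands, mixture weights not summing to one, HGVS outside the
grammar, variants absent from a pedigree's genotype map.  Ties in rule 1
(two genes each qualifying for biallelic, which does not occur in the
packaged cohort) break deterministically: genes with a homozygous variant
first, then alphabetically; variant lists are canonically sorted so the
diagnosis is invariant to input order.

## Fixture conventions

The packaged cohort tables are plain-TSV transcriptions of a published
17-patient USH1 screening study.  Three transcription decisions matter:
per-call depth/quality/allele-fraction values are *synthetic nominal*
(314×, Q30, 0.50/0.99) because the study prints none — chosen to
represent its reported regime and pass default QC; the one second allele
printed only at protein level (p.Arg962Cys) is encoded with a coding
position derived arithmetically from its codon number and carries no
predictor scores, so it tiers as uncertain and the distinct-variant count
stays exact; and one modifier printed in `c.C719T` style is normalised to
standard `c.719C>T`.  A homozygote is stored once with zygosity `hom` and
counts as two alleles.

## Known limitations

* HGVS handling is intentionally narrow; unsupported forms (inversions,
  extensions, complex delins with ranges and offsets) raise.
* The pathogenicity rules are categorical, not probabilistic — no ACMG
  scoring, no Bayesian integration of evidence.
* Phase inference uses parental carrier status only; it does not attempt
  read-backed phasing or more distant relatives.
* The Welch p-value on three-versus-six observations is fragile by
  nature; the exact permutation p is the defensible number and is always
  reported alongside.
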