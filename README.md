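# usherdx

Diagnostic pipeline for multi-gene **Usher syndrome type 1 (USH1)**
sequencing panels: QC/zygosity filtering of amplicon variant calls,
three-database rarity and categorical pathogenicity annotation,
per-patient genotype diagnosis with family segregation, cohort-level
yield reporting, and a synthetic amplicon-cohort simulator with planted
ground truth.

USH1 is an autosomal recessive disorder (congenital profound hearing
loss, absent vestibular responses, prepubertal retinitis pigmentosa).  A
targeted amplicon panel screens the nine Usher genes; the diagnostic
question per patient is whether one gene carries two pathogenic alleles.
`usherdx` encodes the full decision chain:

* **filter** — a call survives iff mean base quality ≥ 25, depth ≥ 10,
  and alternate-allele fraction ∈ [0.40, 0.60] (heterozygous) or
  [0.80, 1.00] (homozygous);
* **annotate** — consequence from the HGVS c./p. strings (missense /
  nonsense / frameshift / splice), rarity `< 1%` in each of three allele
  frequency sources, tier: truncating ⇒ *pathogenic*; rare missense with
  SIFT ≤ 0.05 **or** PolyPhen-2 ≥ 0.5 ⇒ *probable pathogenic*;
* **diagnose** — solved biallelic (hom, or compound het in trans) ≻
  digenic (one het in each of two genes, trans when a pedigree exists) ≻
  monoallelic ≻ unsolved; rare damaging missense variants in a second
  USH1 gene attach to solved patients as *modifier candidates*;
  monoallelic/unsolved patients form the Sanger fallback list;
* **report** — diagnostic yield, per-gene biallelic frequencies, novel
  variant counts, and a modifier-vs-onset comparison (Welch's t from the
  formulas plus an exact permutation test);
* **simulate** — overdispersed depths, Binomial(depth, p) allele
  fractions (p = 0.5 het, 1 − ε hom), amplicon-design dropout and
  homopolymer indel misses, trio pedigrees consistent with planted phase.

The package ships a plain-text transcription of a published 17-patient
USH1 cohort (19 variants, four modifier candidates, one digenic family)
as its worked example and regression fixture.

## Worked example

```python
from usherdx import run_fixture_pipeline

result = run_fixture_pipeline()
print(result.summary.render_text())
```

prints

```
Patients screened:                17
Patients with >=1 mutation:       16 (94.1%)
Patients with two pathogenic:     13
Digenic diagnoses:                1
Patients with modifier candidate: 4
Distinct causal variants:         19 (14 novel, 17 MPS-detectable)
Biallelic diagnoses per gene:
  CDH23     3 (17.6%)
  MYO7A     7 (41.2%)
  PCDH15    2 (11.8%)
```

Sixteen of seventeen patients carry at least one qualifying variant
(94.1% diagnostic yield); *MYO7A* is the most frequent gene (7/17
biallelic, 41.2%).  Nineteen distinct variants are tiered pathogenic or
probable-pathogenic, fourteen of them absent from the previously-reported
catalog; seventeen are visible to the sequencing platform itself, while
two (a homopolymer-region frameshift and a splice variant outside the
amplicon design) require orthogonal Sanger sequencing.  The onset
comparison on the same run:

```python
oc = result.onset_comparison
print(round(oc.p_welch, 3), oc.p_permutation)   # 0.007 0.047619...
```

Biallelic patients carrying a modifier candidate (onsets 5, 5, 6 years)
developed night blindness earlier than biallelic patients without one
(onsets 6–13 years): Welch two-sided p = 0.007; the exact 84-assignment
permutation test gives p = 4/84 ≈ 0.048.

The same stages are exposed as a CLI whose subcommands compose
(`usherdx simulate | filter | annotate | diagnose | report | run`):

```bash
usherdx run --fixtures --outdir out/           # end-to-end on the packaged cohort
usherdx simulate --n-patients 50 --seed 7 --outdir sim/   # synthetic cohort (VCF + truth)
```

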