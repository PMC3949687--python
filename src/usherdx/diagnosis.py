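"""Per-patient genotype diagnosis and family segregation analysis.

For an autosomal recessive disease, a patient is molecularly *solved* when
one gene carries two pathogenic alleles: a homozygous variant, or two
heterozygous variants in trans (one per parental haplotype).  The decision
procedure, applied to a patient's filtered, annotated variants:

1. **solved_biallelic** — some gene has a homozygous
   pathogenic/probable-pathogenic variant, or two heterozygous ones whose
   phase is trans or undetermined;
2. **digenic** — otherwise, exactly one heterozygous qualifying variant in
   each of exactly two genes, in trans when a family is available;
3. **monoallelic** — otherwise, exactly one qualifying heterozygous
   variant; failing that, no qualifying variant but exactly one surviving
   rare heterozygous variant of uncertain significance (a single weak
   finding is still a finding the clinic follows up);
4. **unsolved** — none of the above.

Independently of the primary diagnosis, a solved patient may carry a rare
damaging missense variant in a *second* USH1 gene; such variants are
attached as **modifier candidates** (they plausibly modulate retinal
phenotype onset, not causation), gated on predictor damage only — the
rarity filter is reported but deliberately not applied here.

Phase is established from parental genotypes when a pedigree exists
(:func:`check_segregation`); two heterozygous variants traced to different
parents are trans, to a single parent cis.  Monoallelic and unsolved
patients form the Sanger fallback list — the set re-sequenced by an
orthogonal method to catch what the amplicon panel cannot see.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .annotation import MissensePolicy, is_damaging
from .models import (
    ASSUMED,
    CONFIRMED_CIS,
    CONFIRMED_TRANS,
    DIGENIC,
    HET,
    HOM,
    INCONSISTENT,
    MISSENSE,
    MONOALLELIC,
    NOT_TESTED,
    PATHOGENIC,
    PROBABLE_PATHOGENIC,
    SOLVED_BIALLELIC,
    UNCERTAIN,
    UNSOLVED,
    USH1_GENES,
    AnnotatedVariant,
    DiagnosticCall,
    PatientCase,
    Pedigree,
    UsherdxError,
)

__all__ = [
    "SegregationResult",
    "SegregationError",
    "check_segregation",
    "diagnose_patient",
    "diagnose_cohort",
    "sanger_fallback_list",
]

CAUSAL_TIERS = frozenset({PATHOGENIC, PROBABLE_PATHOGENIC})


class SegregationError(UsherdxError):
    """A requested variant is absent from the pedigree's genotype map."""


@dataclass(frozen=True)
class SegregationResult:
    """Phase and Mendelian consistency of two proband variants in a family."""

    variant_pair: tuple[str, str]
    phase: str  # "trans" | "cis" | "undetermined"
    consistent: bool


def _carrier(genotype: Optional[str]) -> Optional[bool]:
    """True/False carrier status, or None when the genotype is unrecorded."""
    if genotype is None:
        return None
    return genotype in (HET, HOM)


def _mendelian_consistent(ped: Pedigree) -> bool:
    """Strict transmission check over every genotyped parent/child trio.

    A child genotype is impossible when: homozygous with a non-carrier
    parent; heterozygous with both parents non-carriers (de novo is not
    assumed) or both parents homozygous; reference with a homozygous
    parent.
    """
    keys = {key for (_, key) in ped.genotypes}
    for member in ped.members:
        if member.father_id is None or member.mother_id is None:
            continue
        for key in keys:
            child = ped.genotype(member.individual_id, key)
            father = ped.genotype(member.father_id, key)
            mother = ped.genotype(member.mother_id, key)
            if child is None or father is None or mother is None:
                continue
            if child == HOM and (father == "ref" or mother == "ref"):
                return False
            if child == HET and father == "ref" and mother == "ref":
                return False
            if child == HET and father == HOM and mother == HOM:
                return False
            if child == "ref" and (father == HOM or mother == HOM):
                return False
    return True


def check_segregation(
    proband_variants: Sequence["AnnotatedVariant | str"],
    ped: Pedigree,
) -> SegregationResult:
    """Phase two heterozygous proband variants against parental genotypes.

    Trans requires exactly one variant carried by the mother and the other
    by the father; both traced to a single parent is cis; a missing or
    uninformative parent leaves the phase undetermined.  Consistency is the
    Mendelian check over all genotyped family members.
    """
    if len(proband_variants) != 2:
        raise ValueError("check_segregation expects exactly two variants")
    keys = tuple(
        v if isinstance(v, str) else v.key for v in proband_variants
    )
    genotyped_keys = {key for (_, key) in ped.genotypes}
    for key in keys:
        if key not in genotyped_keys:
            raise SegregationError(
                f"variant {key} absent from pedigree {ped.pedigree_id} genotypes"
            )
    proband = ped.proband_id
    member = ped.member(proband)
    consistent = _mendelian_consistent(ped)

    father, mother = member.father_id, member.mother_id
    if father is None or mother is None:
        return SegregationResult(keys, "undetermined", consistent)

    origins = []
    for key in keys:
        from_father = _carrier(ped.genotype(father, key))
        from_mother = _carrier(ped.genotype(mother, key))
        if from_father is None or from_mother is None:
            origins.append("unknown")
        elif from_father and not from_mother:
            origins.append("father")
        elif from_mother and not from_father:
            origins.append("mother")
        else:
            origins.append("ambiguous")  # both carriers, or neither (de novo)

    if set(origins) == {"father", "mother"}:
        phase = "trans"
    elif origins[0] == origins[1] and origins[0] in ("father", "mother"):
        phase = "cis"
    else:
        phase = "undetermined"
    return SegregationResult(keys, phase, consistent)


def _sorted_variants(variants: Iterable[AnnotatedVariant]) -> list[AnnotatedVariant]:
    # canonical order makes the diagnosis invariant to input ordering
    return sorted(variants, key=lambda v: (v.gene, v.key))


def _segregation_for_pair(
    pair: Sequence[AnnotatedVariant], ped: Optional[Pedigree]
) -> Optional[SegregationResult]:
    if ped is None:
        return None
    try:
        return check_segregation(pair, ped)
    except SegregationError:
        return None  # family not genotyped at these sites -> uninformative


def diagnose_patient(
    case: PatientCase,
    pedigrees: Optional[Mapping[str, Pedigree]] = None,
    modifier_genes: Sequence[str] = USH1_GENES,
    missense_policy: MissensePolicy = MissensePolicy(),
) -> DiagnosticCall:
    """Classify one patient's genotype; see the module docstring for rules."""
    ped = None
    if pedigrees and case.pedigree_id:
        ped = pedigrees.get(case.pedigree_id)

    variants = _sorted_variants(case.variants)
    causal = [v for v in variants if v.tier in CAUSAL_TIERS]
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in causal:
        by_gene.setdefault(v.gene, []).append(v)

    call: Optional[DiagnosticCall] = None

    # Rule 1: one gene carrying two pathogenic alleles.
    for gene in sorted(by_gene, key=lambda g: (not any(v.zygosity == HOM for v in by_gene[g]), g)):
        vs = by_gene[gene]
        homs = [v for v in vs if v.zygosity == HOM]
        hets = [v for v in vs if v.zygosity == HET]
        if homs:
            call = DiagnosticCall(
                patient_id=case.patient_id,
                category=SOLVED_BIALLELIC,
                primary_genes=(gene,),
                causal_variants=[homs[0]],
                segregation_status=NOT_TESTED,
            )
            break
        if len(hets) >= 2:
            pair = hets[:2]
            seg = _segregation_for_pair(pair, ped)
            if seg is not None and seg.phase == "cis":
                continue  # same haplotype: not biallelic in this gene
            status = CONFIRMED_TRANS if seg is not None and seg.phase == "trans" else ASSUMED
            if seg is not None and not seg.consistent:
                status = INCONSISTENT
            call = DiagnosticCall(
                patient_id=case.patient_id,
                category=SOLVED_BIALLELIC,
                primary_genes=(gene,),
                causal_variants=pair,
                segregation_status=status,
            )
            break

    # Rule 2: exactly one het qualifying variant in each of two genes.
    if call is None and len(by_gene) == 2:
        counts = {g: vs for g, vs in by_gene.items()}
        if all(len(vs) == 1 and vs[0].zygosity == HET for vs in counts.values()):
            pair = [vs[0] for _, vs in sorted(counts.items())]
            seg = _segregation_for_pair(pair, ped)
            if seg is not None and seg.phase == "cis":
                call = DiagnosticCall(
                    patient_id=case.patient_id,
                    category=MONOALLELIC,
                    primary_genes=tuple(sorted(counts)),
                    causal_variants=pair,
                    segregation_status=CONFIRMED_CIS,
                    notes="two het variants on one haplotype: "
                    "downgraded to independent monoallelic findings",
                )
            else:
                if seg is None:
                    status = ASSUMED
                elif seg.phase == "trans":
                    status = CONFIRMED_TRANS if seg.consistent else INCONSISTENT
                else:
                    status = ASSUMED if seg.consistent else INCONSISTENT
                call = DiagnosticCall(
                    patient_id=case.patient_id,
                    category=DIGENIC,
                    primary_genes=tuple(sorted(counts)),
                    causal_variants=pair,
                    segregation_status=status,
                )

    # Rule 3: a single qualifying het variant — or, with no qualifying
    # variant at all, a single surviving rare het variant of uncertain
    # significance.
    if call is None:
        het_causal = [v for v in causal if v.zygosity == HET]
        if len(het_causal) == 1 and not any(v.zygosity == HOM for v in causal):
            v = het_causal[0]
            call = DiagnosticCall(
                patient_id=case.patient_id,
                category=MONOALLELIC,
                primary_genes=(v.gene,),
                causal_variants=[v],
                segregation_status=NOT_TESTED,
            )
        elif not causal:
            uncertain = [
                v for v in variants if v.tier == UNCERTAIN and v.zygosity == HET
            ]
            if len(uncertain) == 1:
                call = DiagnosticCall(
                    patient_id=case.patient_id,
                    category=MONOALLELIC,
                    primary_genes=(uncertain[0].gene,),
                    causal_variants=[uncertain[0]],
                    segregation_status=NOT_TESTED,
                    notes="single rare variant without predictor support",
                )

    # Rule 4: unsolved.
    if call is None:
        call = DiagnosticCall(
            patient_id=case.patient_id,
            category=UNSOLVED,
            segregation_status=NOT_TESTED,
        )

    # Modifier candidates: solved patients only; predictor damage gates,
    # rarity is reported (in the variant record) but not applied.
    if call.category == SOLVED_BIALLELIC:
        primary = set(call.primary_genes)
        causal_keys = {v.key for v in call.causal_variants}
        call.modifier_candidates = [
            v
            for v in variants
            if v.key not in causal_keys
            and v.consequence == MISSENSE
            and v.gene not in primary
            and v.gene in modifier_genes
            and is_damaging(v.sift, v.polyphen, missense_policy)
        ]
    return call


def diagnose_cohort(
    cases: Iterable[PatientCase],
    pedigrees: Optional[Mapping[str, Pedigree]] = None,
    modifier_genes: Sequence[str] = USH1_GENES,
    missense_policy: MissensePolicy = MissensePolicy(),
) -> list[DiagnosticCall]:
    """Diagnose every patient in a cohort."""
    return [
        diagnose_patient(case, pedigrees, modifier_genes, missense_policy)
        for case in cases
    ]


def sanger_fallback_list(calls: Iterable[DiagnosticCall]) -> list[str]:
    """Patients flagged for orthogonal confirmation sequencing.

    Monoallelic and unsolved patients are fully re-sequenced by Sanger:
    the second allele may sit outside the amplicon design or inside a
    homopolymer run where the platform misses indels.
    """
    return [c.patient_id for c in calls if c.category in (MONOALLELIC, UNSOLVED)]
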