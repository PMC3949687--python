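"""Genotype classification and segregation analysis."""

import random

import pytest

from usherdx.diagnosis import (
    SegregationError,
    check_segregation,
    diagnose_cohort,
    diagnose_patient,
    sanger_fallback_list,
)
from usherdx.models import (
    AnnotatedVariant,
    PatientCase,
    Pedigree,
    PedigreeMember,
    VariantCall,
)
from usherdx.pipeline import run_fixture_pipeline


def _annotated(gene, hgvs_c, zygosity="het", tier="pathogenic",
               consequence="nonsense", sift=None, polyphen=None, pid="p1"):
    call = VariantCall(patient_id=pid, gene=gene, hgvs_c=hgvs_c,
                       depth=300, mean_base_quality=30.0,
                       alt_fraction=0.5 if zygosity == "het" else 0.99)
    return AnnotatedVariant(call=call, zygosity=zygosity, consequence=consequence,
                            sift=sift, polyphen=polyphen, tier=tier)


def _trio(genotypes):
    """Trio pedigree; genotypes: {(individual, key): geno}."""
    members = [
        PedigreeMember("fa", None, None, "M", False),
        PedigreeMember("mo", None, None, "F", False),
        PedigreeMember("kid", "fa", "mo", "M", True),
    ]
    return Pedigree("FAM", members, dict(genotypes))


KEY_A, KEY_B = "MYO7A:c.2311g>t", "PCDH15:c.158-1g>a"


class TestCheckSegregation:
    def test_printed_family_is_trans_and_consistent(self, tables):
        ped = tables.pedigrees["FAM4"]
        result = check_segregation([KEY_A, KEY_B], ped)
        assert result.phase == "trans"
        assert result.consistent

    def test_single_parental_origin_is_cis(self):
        ped = _trio({
            ("kid", KEY_A): "het", ("kid", KEY_B): "het",
            ("fa", KEY_A): "het", ("fa", KEY_B): "het",
            ("mo", KEY_A): "ref", ("mo", KEY_B): "ref",
        })
        assert check_segregation([KEY_A, KEY_B], ped).phase == "cis"

    def test_missing_parent_genotype_is_undetermined(self):
        ped = _trio({
            ("kid", KEY_A): "het", ("kid", KEY_B): "het",
            ("fa", KEY_A): "het", ("fa", KEY_B): "ref",
            ("mo", KEY_B): "het",  # KEY_A unrecorded in the mother
        })
        assert check_segregation([KEY_A, KEY_B], ped).phase == "undetermined"

    def test_mendelian_impossibility_flagged(self):
        # child homozygous for an allele absent from both parents
        ped = _trio({
            ("kid", KEY_A): "hom", ("kid", KEY_B): "het",
            ("fa", KEY_A): "ref", ("fa", KEY_B): "het",
            ("mo", KEY_A): "ref", ("mo", KEY_B): "ref",
        })
        assert not check_segregation([KEY_A, KEY_B], ped).consistent

    def test_unknown_variant_raises(self):
        ped = _trio({("kid", KEY_A): "het", ("fa", KEY_A): "het", ("mo", KEY_A): "ref"})
        with pytest.raises(SegregationError):
            check_segregation([KEY_A, "CDH23:c.1g>a"], ped)


EXPECTED_CATEGORIES = {
    "1": ("solved_biallelic", ("MYO7A",)),
    "2": ("solved_biallelic", ("MYO7A",)),
    "3": ("solved_biallelic", ("PCDH15",)),
    "4": ("digenic", ("MYO7A", "PCDH15")),
    "5": ("solved_biallelic", ("MYO7A",)),
    "6": ("solved_biallelic", ("MYO7A",)),
    "7": ("solved_biallelic", ("CDH23",)),
    "8": ("solved_biallelic", ("MYO7A",)),
    "9": ("solved_biallelic", ("CDH23",)),
    "10": ("monoallelic", ("PCDH15",)),
    "11": ("solved_biallelic", ("MYO7A",)),
    "12": ("monoallelic", ("PCDH15",)),
    "13": ("monoallelic", ("PCDH15",)),
    "14": ("unsolved", ()),
    "15": ("solved_biallelic", ("CDH23",)),
    "16": ("solved_biallelic", ("PCDH15",)),
    "17": ("solved_biallelic", ("MYO7A",)),
}


class TestCohortDiagnoses:
    @pytest.mark.parametrize("pid", sorted(EXPECTED_CATEGORIES, key=int))
    def test_every_patient_classified_as_printed(self, diagnoses_by_id, pid):
        category, genes = EXPECTED_CATEGORIES[pid]
        call = diagnoses_by_id[pid]
        assert (call.category, call.primary_genes) == (category, genes)

    def test_category_tallies(self, fixture_result):
        tally = {}
        for d in fixture_result.diagnoses:
            tally[d.category] = tally.get(d.category, 0) + 1
        assert tally == {
            "solved_biallelic": 12, "digenic": 1, "monoallelic": 3, "unsolved": 1,
        }

    def test_exactly_four_modifier_carriers(self, fixture_result):
        carriers = {
            d.patient_id for d in fixture_result.diagnoses if d.modifier_candidates
        }
        assert carriers == {"3", "5", "8", "15"}

    def test_common_but_damaging_modifier_retained(self, diagnoses_by_id):
        """The 26%-frequency CDH23 missense stays a modifier candidate:
        rarity is reported, not gating, for modifier candidacy."""
        mods = diagnoses_by_id["5"].modifier_candidates
        assert [v.key for v in mods] == ["CDH23:c.719c>t"]
        assert mods[0].tier == "excluded" and mods[0].freq_inhouse == 0.26

    def test_digenic_case_confirmed_trans(self, diagnoses_by_id):
        assert diagnoses_by_id["4"].segregation_status == "confirmed_trans"

    def test_diagnosis_invariant_to_variant_order(self, tables):
        rng = random.Random(0)
        for case in tables.patients:
            baseline = diagnose_patient(case, tables.pedigrees)
            for _ in range(3):
                shuffled = PatientCase(
                    patient_id=case.patient_id,
                    variants=rng.sample(case.variants, k=len(case.variants)),
                    pedigree_id=case.pedigree_id,
                )
                result = diagnose_patient(shuffled, tables.pedigrees)
                assert (result.category, result.primary_genes) == (
                    baseline.category, baseline.primary_genes,
                )
                assert [v.key for v in result.causal_variants] == [
                    v.key for v in baseline.causal_variants
                ]


class TestRuleEdges:
    def test_cis_digenic_pair_downgraded_to_monoallelic(self):
        a = _annotated("MYO7A", "c.100C>T", pid="kid")
        b = _annotated("PCDH15", "c.200C>T", pid="kid")
        ped = _trio({
            ("kid", a.key): "het", ("kid", b.key): "het",
            ("fa", a.key): "het", ("fa", b.key): "het",
            ("mo", a.key): "ref", ("mo", b.key): "ref",
        })
        case = PatientCase(patient_id="kid", variants=[a, b], pedigree_id="FAM")
        call = diagnose_patient(case, {"FAM": ped})
        assert call.category == "monoallelic"
        assert call.segregation_status == "confirmed_cis"

    def test_digenic_without_pedigree_is_assumed(self):
        a = _annotated("MYO7A", "c.100C>T")
        b = _annotated("PCDH15", "c.200C>T")
        case = PatientCase(patient_id="p1", variants=[a, b])
        call = diagnose_patient(case, None)
        assert (call.category, call.segregation_status) == ("digenic", "assumed")

    def test_compound_het_without_pedigree_is_assumed_biallelic(self):
        a = _annotated("MYO7A", "c.100C>T")
        b = _annotated("MYO7A", "c.200C>T")
        call = diagnose_patient(PatientCase(patient_id="p1", variants=[a, b]), None)
        assert (call.category, call.segregation_status) == (
            "solved_biallelic", "assumed",
        )

    def test_uncertain_single_het_is_monoallelic_finding(self):
        v = _annotated("PCDH15", "c.2884C>T", tier="uncertain", consequence="missense")
        call = diagnose_patient(PatientCase(patient_id="p1", variants=[v]), None)
        assert call.category == "monoallelic"

    def test_excluded_variants_never_causal(self):
        v = _annotated("CDH23", "c.719C>T", zygosity="hom", tier="excluded",
                       consequence="missense")
        call = diagnose_patient(PatientCase(patient_id="p1", variants=[v]), None)
        assert call.category == "unsolved"


class TestSangerFallback:
    def test_full_cohort_fallback(self, fixture_result):
        assert sorted(sanger_fallback_list(fixture_result.diagnoses), key=int) == [
            "10", "12", "13", "14",
        ]

    def test_platform_only_callset_flags_the_sanger_rescued_cases(self):
        result = run_fixture_pipeline(mps_detectable_only=True)
        fallback = sorted(sanger_fallback_list(result.diagnoses), key=int)
        assert fallback == ["8", "9", "10", "12", "13", "14"]
        by_id = {d.patient_id: d for d in result.diagnoses}
        # each is rescued by the variant the platform cannot see
        assert by_id["8"].category == "monoallelic"
        assert by_id["9"].category == "monoallelic"

    def test_all_solved_yields_empty_list(self):
        v = _annotated("MYO7A", "c.100C>T", zygosity="hom")
        calls = diagnose_cohort([PatientCase(patient_id="p1", variants=[v])])
        assert sanger_fallback_list(calls) == []
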