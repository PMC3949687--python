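"""Simulator: determinism, sampling model, dropout and recovery."""

import dataclasses

import numpy as np
import pytest

from usherdx.filtering import apply_qc_filters
from usherdx.pipeline import run_simulated_pipeline
from usherdx.simulate import (
    CohortTruth,
    PatientTruth,
    PlantedVariant,
    SimulationConfig,
    draw_depth_and_fraction,
    expected_observable_category,
    planted_detectability,
    simulate_cohort,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"n_patients": 0},
            {"mean_depth": -1.0},
            {"diagnosis_mix": {"unsolved": 0.5}},  # does not sum to 1
            {"diagnosis_mix": {"bogus": 1.0}},
            {"covered_fraction": 1.5},
        ],
    )
    def test_bad_configs_rejected(self, overrides):
        with pytest.raises(ValueError):
            SimulationConfig(**overrides)


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        cfg = SimulationConfig(n_patients=12, seed=11)
        assert simulate_cohort(cfg) == simulate_cohort(cfg)

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimulationConfig(n_patients=12, seed=11))
        b = simulate_cohort(SimulationConfig(n_patients=12, seed=12))
        assert a.calls != b.calls


class TestPlanting:
    def test_all_unsolved_no_background_means_no_calls(self):
        cfg = SimulationConfig(
            n_patients=10, seed=1, diagnosis_mix={"unsolved": 1.0},
            background_polymorphism_rate=0.0,
        )
        sim = simulate_cohort(cfg)
        assert all(not calls for calls in sim.calls.values())
        assert all(p.category == "unsolved" for p in sim.truth.patients)

    def test_digenic_truth_spans_two_genes_in_trans(self):
        cfg = SimulationConfig(
            n_patients=20, seed=5, diagnosis_mix={"digenic": 1.0},
            background_polymorphism_rate=0.0,
        )
        sim = simulate_cohort(cfg)
        for patient in sim.truth.patients:
            causal = [v for v in patient.variants if v.role == "causal"]
            assert len({v.gene for v in causal}) == 2
            assert {v.parent_origin for v in causal} == {"father", "mother"}
            assert patient.pedigree_id is not None

    def test_background_polymorphisms_are_common(self):
        cfg = SimulationConfig(
            n_patients=10, seed=2, diagnosis_mix={"unsolved": 1.0},
            background_polymorphism_rate=3.0,
        )
        sim = simulate_cohort(cfg)
        background = [
            v for p in sim.truth.patients for v in p.variants if v.role == "background"
        ]
        assert background
        for v in background:
            ann = sim.annotations[v.key]
            assert ann.freq_1000g >= 0.05


class TestAlleleFractionModel:
    def test_het_mean_fraction_within_three_se_of_half(self):
        """1e4 heterozygous draws at the default depth regime."""
        cfg = SimulationConfig(seed=0)
        rng = np.random.default_rng(1234)
        fractions = np.array(
            [draw_depth_and_fraction(rng, cfg, "het")[1] for _ in range(10_000)]
        )
        se = fractions.std(ddof=1) / np.sqrt(len(fractions))
        assert abs(fractions.mean() - 0.5) < 3 * se

    def test_hom_fraction_tracks_error_rate(self):
        rng = np.random.default_rng(7)
        cfg = SimulationConfig(seed=0, error_rate=0.05)
        fractions = np.array(
            [draw_depth_and_fraction(rng, cfg, "hom")[1] for _ in range(2_000)]
        )
        assert fractions.mean() == pytest.approx(0.95, abs=0.01)

    def test_hom_band_detection_monotone_in_error_rate(self):
        """Raising the per-base error pushes homozygotes out of the 80-100%
        acceptance band; detection never increases with the error rate."""
        rates = []
        for eps in (0.01, 0.1, 0.2, 0.3, 0.45):
            rng = np.random.default_rng(99)
            cfg = SimulationConfig(seed=0, error_rate=eps)
            in_band = 0
            n = 3_000
            for _ in range(n):
                _, f = draw_depth_and_fraction(rng, cfg, "hom")
                in_band += 0.80 <= f <= 1.00
            rates.append(in_band / n)
        assert all(a >= b - 0.01 for a, b in zip(rates, rates[1:]))
        assert rates[0] > 0.99 and rates[-1] < 0.05


class TestDetectability:
    def test_fully_covered_panel_detects_everything(self):
        cfg = SimulationConfig(
            n_patients=5, seed=3, covered_fraction=1.0, homopolymer_miss_prob=0.0,
            diagnosis_mix={"monoallelic": 1.0}, background_polymorphism_rate=0.0,
        )
        sim = simulate_cohort(cfg)
        assert planted_detectability(sim.truth, cfg) == 1.0

    def test_homopolymer_indel_expectation_is_the_product(self):
        cfg = SimulationConfig(covered_fraction=0.97, homopolymer_miss_prob=0.5)
        truth = CohortTruth(patients=(
            PatientTruth(
                patient_id="S1", category="monoallelic",
                variants=(PlantedVariant(
                    patient_id="S1", gene="MYO7A", hgvs_c="c.100dup",
                    hgvs_p="p.Lys34GlnfsX5", zygosity="het",
                    consequence="frameshift", role="causal", homopolymer=True,
                ),),
            ),
        ))
        assert planted_detectability(truth, cfg) == pytest.approx(0.485)

    def test_empirical_detection_tracks_analytic_expectation(self):
        cfg = SimulationConfig(
            n_patients=4_000, seed=17, diagnosis_mix={"monoallelic": 1.0},
            background_polymorphism_rate=0.0, homopolymer_miss_prob=0.4,
        )
        sim = simulate_cohort(cfg)
        planted = [v for p in sim.truth.patients for v in p.variants]
        expected = planted_detectability(sim.truth, cfg)
        detected = np.array([v.dropped is None for v in planted], dtype=float)
        se = detected.std(ddof=1) / np.sqrt(len(detected))
        assert abs(detected.mean() - expected) < 3 * se


class TestRecovery:
    def test_covered_variants_survive_filtering_with_true_zygosity(self):
        """>=99% of planted, covered variants at depth >= 30 pass QC and
        receive their planted zygosity."""
        cfg = SimulationConfig(
            n_patients=800, seed=21, covered_fraction=1.0,
            homopolymer_miss_prob=0.0, background_polymorphism_rate=0.0,
        )
        sim = simulate_cohort(cfg)
        truth_zyg = {
            (p.patient_id, v.key): v.zygosity
            for p in sim.truth.patients
            for v in p.variants
        }
        total = correct = 0
        for pid, calls in sim.calls.items():
            eligible = [c for c in calls if c.depth >= 30]
            total += len(eligible)
            surviving = dict(apply_qc_filters(eligible))
            for call in eligible:
                zyg = surviving.get(call)
                if zyg is not None and zyg == truth_zyg[(pid, call.key)]:
                    correct += 1
        assert total > 1_000
        assert correct / total >= 0.99

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_diagnosis_recovers_planted_categories(self, seed):
        """Exact category agreement with the enumeration oracle for every
        patient, given which qualifying calls survived measurement."""
        cfg = SimulationConfig(n_patients=25, seed=seed)
        sim = simulate_cohort(cfg)
        cases, diagnoses = run_simulated_pipeline(sim)
        by_id = {d.patient_id: d for d in diagnoses}
        truth_by_id = {p.patient_id: p for p in sim.truth.patients}
        for case in cases:
            truth = truth_by_id[case.patient_id]
            planted = {v.key: v for v in truth.variants}
            surviving = [
                (v.gene, v.zygosity)
                for v in case.variants
                if v.tier in ("pathogenic", "probable_pathogenic")
                and v.key in planted
                and planted[v.key].role in ("causal", "modifier")
            ]
            assert by_id[case.patient_id].category == expected_observable_category(
                surviving
            )

    def test_modifier_patients_recovered_with_candidate_attached(self):
        cfg = SimulationConfig(
            n_patients=15, seed=8, diagnosis_mix={"modifier": 1.0},
            covered_fraction=1.0, homopolymer_miss_prob=0.0,
            background_polymorphism_rate=0.0,
        )
        sim = simulate_cohort(cfg)
        cases, diagnoses = run_simulated_pipeline(sim)
        by_id = {d.patient_id: d for d in diagnoses}
        truth_by_id = {p.patient_id: p for p in sim.truth.patients}
        n_full = 0
        for case in cases:
            truth = truth_by_id[case.patient_id]
            surviving_keys = {v.key for v in case.variants}
            all_survived = all(v.key in surviving_keys for v in truth.variants)
            if not all_survived:
                continue  # QC loss (e.g. low base quality) degrades the call
            n_full += 1
            d = by_id[case.patient_id]
            assert d.category == "solved_biallelic"
            assert d.modifier_candidates
        assert n_full >= 10  # QC loss is the rare exception, not the rule
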