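"""Pipeline orchestration: filter → annotate → diagnose → report.

Stages are plain functions over in-memory objects; file-based entry points
(:func:`run_pipeline`, the CLI) are thin wrappers that read the standard
formats, call the stages and write TSV/JSON artifacts.  Given the same
inputs the pipeline is deterministic: reports are written with sorted keys
and no timestamps, so reruns are byte-identical.

Every variant removed on the way to a causal diagnosis is logged with
exactly one primary reason, in a fixed predicate order: read depth, base
quality, zygosity band, consequence class, rarity.  Variants failing only
the rarity test are logged but retained on the patient — a common damaging
missense in a second gene is still a modifier candidate (rarity is
reported, not gating, for modifier candidacy).
"""
from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .annotation import MissensePolicy, RarityPolicy, annotate_call
from .diagnosis import diagnose_cohort, sanger_fallback_list
from .filtering import FilterThresholds, apply_qc_filters, rejection_reason
from .fixtures import (
    fixture_path,
    load_annotation_source,
    load_fixture_tables,
    load_known_catalog,
)
from .models import (
    EXCLUDED,
    OTHER,
    USH1_GENES,
    AnnotatedVariant,
    DiagnosticCall,
    PatientCase,
    Pedigree,
    UsherdxError,
    VariantCall,
    make_variant_key,
)
from .report import (
    CohortSummary,
    OnsetComparison,
    compare_onset_by_modifier,
    summarize_cohort,
)
from .simulate import SimulatedCohort
from .vcfio import read_ped, read_ped_genotypes, read_variant_table

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "filter_stage",
    "annotate_stage",
    "build_cases",
    "run_pipeline",
    "run_fixture_pipeline",
    "load_annotation_table",
    "load_patient_metadata",
    "write_diagnoses_tsv",
    "write_rejections_tsv",
    "cases_from_simulation",
    "run_simulated_pipeline",
]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def filter_stage(
    calls: Iterable[VariantCall], thresholds: FilterThresholds = FilterThresholds()
) -> tuple[list[tuple[VariantCall, str]], list[tuple[VariantCall, str]]]:
    """QC-filter calls; returns (surviving (call, zygosity), rejections)."""
    calls = list(calls)
    kept = apply_qc_filters(calls, thresholds)
    rejections = [
        (c, reason)
        for c in calls
        if (reason := rejection_reason(c, thresholds)) is not None
    ]
    return kept, rejections


def annotate_stage(
    kept: Iterable[tuple[VariantCall, str]],
    annotations: Mapping[str, Mapping[str, Optional[float]]],
    known_catalog: Iterable[str] = (),
    rarity: RarityPolicy = RarityPolicy(),
    missense: MissensePolicy = MissensePolicy(),
) -> tuple[list[AnnotatedVariant], list[tuple[VariantCall, str]]]:
    """Annotate QC survivors; returns (retained variants, removals).

    Variants of consequence class *other* are removed outright (the screen
    selects missense/nonsense/frameshift/splice).  Variants failing the
    rarity filter are logged as removed-from-causal-consideration but stay
    attached to the patient with tier ``excluded``.
    """
    catalog = set(known_catalog)
    retained: list[AnnotatedVariant] = []
    removed: list[tuple[VariantCall, str]] = []
    for call, zygosity in kept:
        ann = annotations.get(call.key, {})
        variant = annotate_call(
            call,
            zygosity,
            freq_1000g=ann.get("freq_1000g"),
            freq_exome=ann.get("freq_exome"),
            freq_inhouse=ann.get("freq_inhouse"),
            sift=ann.get("sift"),
            polyphen=ann.get("polyphen"),
            known_catalog=catalog,
            rarity=rarity,
            missense=missense,
        )
        if variant.consequence == OTHER:
            removed.append((call, "consequence class 'other' (not selected)"))
            continue
        if variant.tier == EXCLUDED:
            removed.append(
                (call, f"population frequency >= {rarity.max_frequency:g} (rarity)")
            )
        retained.append(variant)
    return retained, removed


def build_cases(
    variants: Iterable[AnnotatedVariant],
    metadata: Optional[Mapping[str, Mapping]] = None,
) -> list[PatientCase]:
    """Group annotated variants into per-patient cases.

    ``metadata`` maps patient id to optional fields (age, sex,
    inheritance_label, onset_night_blindness, pedigree_id) and also fixes
    the patient universe — patients with zero surviving variants still
    get a case (they are the unsolved candidates).
    """
    by_patient: dict[str, list[AnnotatedVariant]] = {}
    for v in variants:
        by_patient.setdefault(v.call.patient_id, []).append(v)
    ids = sorted(metadata) if metadata is not None else sorted(by_patient)
    cases = []
    for pid in ids:
        meta = dict(metadata.get(pid, {})) if metadata else {}
        cases.append(
            PatientCase(
                patient_id=pid,
                age=meta.get("age"),
                sex=meta.get("sex", ""),
                inheritance_label=meta.get("inheritance_label", ""),
                onset_night_blindness=meta.get("onset_night_blindness"),
                variants=by_patient.get(pid, []),
                pedigree_id=meta.get("pedigree_id"),
            )
        )
    return cases


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """File-level configuration for an end-to-end run."""

    variant_tables: list[str] = field(default_factory=list)
    dialect: str = "tsv"
    patients_path: Optional[str] = None
    annotations_path: Optional[str] = None
    catalog_path: Optional[str] = None
    ped_paths: list[str] = field(default_factory=list)
    ped_genotype_paths: list[str] = field(default_factory=list)
    outdir: str = "usherdx_out"
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    rarity: RarityPolicy = field(default_factory=RarityPolicy)
    missense: MissensePolicy = field(default_factory=MissensePolicy)
    modifier_genes: tuple[str, ...] = USH1_GENES
    include_digenic_in_onset: bool = False

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs = dict(raw)
        for key, klass in (
            ("thresholds", FilterThresholds),
            ("rarity", RarityPolicy),
            ("missense", MissensePolicy),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                section = kwargs[key]
                for band in ("het_band", "hom_band"):
                    if band in section:
                        section[band] = tuple(section[band])
                kwargs[key] = klass(**section)
        if "modifier_genes" in kwargs:
            kwargs["modifier_genes"] = tuple(kwargs["modifier_genes"])
        return cls(**kwargs)


def load_annotation_table(path: "str | Path") -> dict[str, dict[str, Optional[float]]]:
    """Read a generic annotation TSV (gene, hgvs_c, frequencies, scores)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, dict[str, Optional[float]]] = {}
    for _, row in frame.iterrows():
        key = make_variant_key(str(row["gene"]), str(row["hgvs_c"]))
        entry: dict[str, Optional[float]] = {}
        for col in ("freq_1000g", "freq_exome", "freq_inhouse", "sift", "polyphen"):
            raw = row.get(col)
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                entry[col] = None
                continue
            text = str(raw).strip()
            entry[col] = None if not text or text.upper() in ("N/A", "NAN") else float(text)
        out[key] = entry
    return out


def load_patient_metadata(path: "str | Path") -> dict[str, dict]:
    """Read patient metadata TSV (table-2 style columns)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    meta: dict[str, dict] = {}
    for _, row in frame.iterrows():
        pid = str(row["patient_id"])
        onset = str(row.get("onset_night_blindness", "")).strip().lower()
        ped = row.get("pedigree_id")
        ped = None if ped is None or str(ped) in ("", "nan") else str(ped)
        meta[pid] = {
            "age": int(row["age"]) if str(row.get("age", "")).strip().isdigit() else None,
            "sex": str(row.get("sex", "") or ""),
            "inheritance_label": str(
                row.get("hereditary_form", row.get("inheritance_label", "")) or ""
            ),
            "onset_night_blindness": int(onset) if onset.isdigit() else None,
            "pedigree_id": ped,
        }
    return meta


# ---------------------------------------------------------------------------
# end-to-end runs
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    cases: list[PatientCase]
    diagnoses: list[DiagnosticCall]
    summary: CohortSummary
    onset_comparison: Optional[OnsetComparison]
    rejections: list[tuple[VariantCall, str]]

    def report_dict(self) -> dict:
        return {
            "summary": self.summary.to_dict(),
            "onset_comparison": (
                self.onset_comparison.to_dict() if self.onset_comparison else None
            ),
            "sanger_fallback": sorted(sanger_fallback_list(self.diagnoses)),
            "diagnoses": [
                {
                    "patient_id": d.patient_id,
                    "category": d.category,
                    "primary_genes": list(d.primary_genes),
                    "causal_variants": [v.key for v in d.causal_variants],
                    "modifier_candidates": [v.key for v in d.modifier_candidates],
                    "segregation_status": d.segregation_status,
                }
                for d in sorted(self.diagnoses, key=lambda d: d.patient_id)
            ],
        }


def write_rejections_tsv(
    rejections: Iterable[tuple[VariantCall, str]], path: "str | Path"
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["patient_id", "gene", "hgvs_c", "reason"])
        for call, reason in rejections:
            writer.writerow([call.patient_id, call.gene, call.hgvs_c, reason])


def write_diagnoses_tsv(diagnoses: Iterable[DiagnosticCall], path: "str | Path") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "patient_id",
                "category",
                "primary_genes",
                "causal_variants",
                "modifier_candidates",
                "segregation_status",
                "notes",
            ]
        )
        for d in sorted(diagnoses, key=lambda d: d.patient_id):
            writer.writerow(
                [
                    d.patient_id,
                    d.category,
                    ",".join(d.primary_genes),
                    ",".join(v.key for v in d.causal_variants),
                    ",".join(v.key for v in d.modifier_candidates),
                    d.segregation_status,
                    d.notes,
                ]
            )


def _write_artifacts(result: PipelineResult, outdir: "str | Path") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_rejections_tsv(result.rejections, outdir / "rejections.tsv")
    write_diagnoses_tsv(result.diagnoses, outdir / "diagnoses.tsv")
    (outdir / "report.json").write_text(
        json.dumps(result.report_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    (outdir / "report.txt").write_text(result.summary.render_text() + "\n", encoding="utf-8")


def _run(
    calls: list[VariantCall],
    annotations: Mapping[str, Mapping[str, Optional[float]]],
    catalog: Iterable[str],
    metadata: Optional[Mapping[str, Mapping]],
    pedigrees: Optional[Mapping[str, Pedigree]],
    thresholds: FilterThresholds,
    rarity: RarityPolicy,
    missense: MissensePolicy,
    modifier_genes: Sequence[str],
    include_digenic_in_onset: bool,
    outdir: Optional["str | Path"],
) -> PipelineResult:
    kept, qc_rejections = filter_stage(calls, thresholds)
    variants, ann_removed = annotate_stage(kept, annotations, catalog, rarity, missense)
    cases = build_cases(variants, metadata)
    diagnoses = diagnose_cohort(cases, pedigrees, modifier_genes, missense)
    summary = summarize_cohort(diagnoses, cases)
    try:
        onset = compare_onset_by_modifier(cases, diagnoses, include_digenic_in_onset)
    except UsherdxError:
        onset = None  # a group is empty or onsets unknown
    result = PipelineResult(
        cases=cases,
        diagnoses=diagnoses,
        summary=summary,
        onset_comparison=onset,
        rejections=qc_rejections + ann_removed,
    )
    if outdir is not None:
        _write_artifacts(result, outdir)
    return result


def run_pipeline(cfg: PipelineConfig, outdir: Optional["str | Path"] = None) -> PipelineResult:
    """Execute filter → annotate → diagnose → report from files on disk."""
    if not cfg.variant_tables:
        raise UsherdxError("pipeline stage 'read': no variant tables configured")
    calls: list[VariantCall] = []
    for path in cfg.variant_tables:
        calls.extend(read_variant_table(path, cfg.dialect))
    annotations = (
        load_annotation_table(cfg.annotations_path) if cfg.annotations_path else {}
    )
    catalog: set[str] = set()
    if cfg.catalog_path:
        frame = pd.read_csv(cfg.catalog_path, sep="\t", dtype=str)
        catalog = {
            make_variant_key(str(r["gene"]), str(r["hgvs_c"])) for _, r in frame.iterrows()
        }
    metadata = load_patient_metadata(cfg.patients_path) if cfg.patients_path else None
    pedigrees: dict[str, Pedigree] = {}
    for path in cfg.ped_paths:
        pedigrees.update(read_ped(path))
    for path in cfg.ped_genotype_paths:
        read_ped_genotypes(path, pedigrees)
    return _run(
        calls,
        annotations,
        catalog,
        metadata,
        pedigrees or None,
        cfg.thresholds,
        cfg.rarity,
        cfg.missense,
        cfg.modifier_genes,
        cfg.include_digenic_in_onset,
        outdir if outdir is not None else cfg.outdir,
    )


def run_fixture_pipeline(
    outdir: Optional["str | Path"] = None,
    thresholds: FilterThresholds = FilterThresholds(),
    rarity: RarityPolicy = RarityPolicy(),
    missense: MissensePolicy = MissensePolicy(),
    mps_detectable_only: bool = False,
) -> PipelineResult:
    """Run the full pipeline on the packaged 17-patient cohort fixtures.

    With ``mps_detectable_only`` the two Sanger-rescued variants (outside
    the amplicon design / in a homopolymer run) are withheld, reproducing
    what the sequencing platform alone would report.
    """
    calls = read_variant_table(fixture_path("patient_calls.tsv"), dialect="tsv")
    if mps_detectable_only:
        calls = [c for c in calls if not c.detectability_flags]
    annotations = load_annotation_source()
    catalog = load_known_catalog()
    metadata = load_patient_metadata(fixture_path("table2_patients.tsv"))
    pedigrees = load_fixture_tables(thresholds, rarity, missense).pedigrees
    return _run(
        calls,
        annotations,
        catalog,
        metadata,
        pedigrees,
        thresholds,
        rarity,
        missense,
        USH1_GENES,
        False,
        outdir,
    )


# ---------------------------------------------------------------------------
# simulated cohorts
# ---------------------------------------------------------------------------


def cases_from_simulation(
    sim: SimulatedCohort,
    thresholds: FilterThresholds = FilterThresholds(),
    rarity: RarityPolicy = RarityPolicy(),
    missense: MissensePolicy = MissensePolicy(),
) -> tuple[list[PatientCase], list[tuple[VariantCall, str]]]:
    """Filter and annotate a simulated cohort into patient cases."""
    all_calls = [c for patient in sorted(sim.calls) for c in sim.calls[patient]]
    annotations = {
        key: {
            "freq_1000g": ann.freq_1000g,
            "freq_exome": ann.freq_exome,
            "freq_inhouse": ann.freq_inhouse,
            "sift": ann.sift,
            "polyphen": ann.polyphen,
        }
        for key, ann in sim.annotations.items()
    }
    kept, qc_rej = filter_stage(all_calls, thresholds)
    variants, ann_removed = annotate_stage(kept, annotations, (), rarity, missense)
    metadata = {
        p.patient_id: {"pedigree_id": p.pedigree_id} for p in sim.truth.patients
    }
    return build_cases(variants, metadata), qc_rej + ann_removed


def run_simulated_pipeline(
    sim: SimulatedCohort,
    thresholds: FilterThresholds = FilterThresholds(),
    rarity: RarityPolicy = RarityPolicy(),
    missense: MissensePolicy = MissensePolicy(),
) -> tuple[list[PatientCase], list[DiagnosticCall]]:
    """Diagnose a simulated cohort with its trio pedigrees."""
    cases, _ = cases_from_simulation(sim, thresholds, rarity, missense)
    pedigrees = {p.pedigree_id: p for p in sim.pedigrees}
    return cases, diagnose_cohort(cases, pedigrees, USH1_GENES, missense)
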