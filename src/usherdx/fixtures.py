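"""Packaged cohort fixtures: the 17-patient USH1 study transcribed to TSV.

The package ships, under ``usherdx/data/``, plain-text transcriptions of a
published 17-patient Usher type 1 screening cohort:

* ``table1_variants.tsv`` — the 19 distinct probable pathogenic variants
  (gene, HGVS, consequence label, in-house control frequency in 384
  alleles, SIFT/PolyPhen scores, literature reference);
* ``table2_patients.tsv`` — per-patient phenotype and inheritance data;
* ``patient_calls.tsv`` — one row per observed variant per patient.  Depth,
  mean base quality and allele fraction are *synthetic nominal* values
  (314x, Q30, 0.50 het / 0.99 hom) standing in for unpublished raw caller
  output; they represent the reported sequencing regime and pass the
  default QC thresholds;
* ``table3_modifiers.tsv`` — the four second-gene missense candidates
  carried by biallelic patients (Cases #3, #5, #8, #15);
* ``family_case4.ped`` / ``family_case4_genotypes.tsv`` — the digenic
  Case #4 trio-plus-siblings family;
* ``known_variants.tsv`` — the previously-reported variant catalog used to
  mark novelty.

Notes on transcription: Case #10's second printed allele (p.Arg962Cys) has
no published nucleotide change; it is encoded as c.2884C>T, derived
arithmetically from the codon number, and carries no predictor scores, so
it tiers as *uncertain*.  The Case #5 modifier is printed in
``c.C719T``-style notation and is normalized to ``c.719C>T``.
"""
from __future__ import annotations

import math
from importlib import resources
from typing import NamedTuple, Optional

import pandas as pd

from .annotation import MissensePolicy, RarityPolicy, annotate_call
from .filtering import FilterThresholds, apply_qc_filters
from .models import (
    AnnotatedVariant,
    PatientCase,
    Pedigree,
    UsherdxError,
    VariantCall,
    make_variant_key,
)
from .vcfio import read_ped, read_ped_genotypes, read_variant_table

__all__ = [
    "FixtureError",
    "FixtureTables",
    "load_fixture_tables",
    "load_known_catalog",
    "load_annotation_source",
    "fixture_path",
]


class FixtureError(UsherdxError):
    """A packaged fixture table is missing or corrupt."""


class FixtureTables(NamedTuple):
    """The loaded cohort: variant list, patients, pedigrees."""

    variants: list[AnnotatedVariant]
    patients: list[PatientCase]
    pedigrees: dict[str, Pedigree]


def fixture_path(name: str):
    """Filesystem path of a packaged data file."""
    path = resources.files("usherdx.data").joinpath(name)
    if not path.is_file():
        raise FixtureError(f"fixture table {name!r} is missing from the package")
    return path


def _read_table(name: str) -> pd.DataFrame:
    try:
        return pd.read_csv(fixture_path(name), sep="\t", dtype=str)
    except Exception as exc:  # corrupt file
        if isinstance(exc, FixtureError):
            raise
        raise FixtureError(f"fixture table {name!r} is corrupt: {exc}") from exc


def _opt_float(raw: object) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if not text or text.upper() == "N/A" or text.lower() == "nan":
        return None
    return float(text)


def load_known_catalog() -> set[str]:
    """Previously-reported variants as canonical keys."""
    frame = _read_table("known_variants.tsv")
    return {
        make_variant_key(str(row["gene"]), str(row["hgvs_c"]))
        for _, row in frame.iterrows()
    }


def load_annotation_source() -> dict[str, dict[str, Optional[float]]]:
    """Per-variant annotation inputs keyed by canonical variant key.

    Merges the cohort variant list and the modifier table into one map of
    ``{key: {freq_inhouse, sift, polyphen}}``.  1000 Genomes / exome
    frequencies are unreported for these variants (all are rare or absent
    there) and stay ``None``.
    """
    table1 = _read_table("table1_variants.tsv")
    table3 = _read_table("table3_modifiers.tsv")
    source: dict[str, dict[str, Optional[float]]] = {}
    for frame, gene_col in ((table1, "gene"), (table3, "modifier_gene")):
        for _, row in frame.iterrows():
            key = make_variant_key(str(row[gene_col]), str(row["hgvs_c"]))
            source[key] = {
                "freq_inhouse": _opt_float(row.get("control_freq")),
                "sift": _opt_float(row.get("sift")),
                "polyphen": _opt_float(row.get("polyphen")),
            }
    return source


def _load_pedigrees() -> dict[str, Pedigree]:
    peds = read_ped(fixture_path("family_case4.ped"))
    read_ped_genotypes(fixture_path("family_case4_genotypes.tsv"), peds)
    ped = peds.get("FAM4")
    if ped is None:
        raise FixtureError("fixture table 'family_case4.ped' lacks family FAM4")
    members = {m.individual_id for m in ped.members}
    if not {"4", "father4", "mother4", "brother4a", "brother4b"} <= members:
        raise FixtureError("fixture table 'family_case4.ped' is incomplete")
    return peds


def load_fixture_tables(
    thresholds: FilterThresholds = FilterThresholds(),
    rarity: RarityPolicy = RarityPolicy(),
    missense: MissensePolicy = MissensePolicy(),
) -> FixtureTables:
    """Load and annotate the packaged cohort.

    The per-patient calls are run through the real QC-filter and annotation
    stages (fixtures are inputs, not precomputed outputs), so the returned
    objects reflect the pipeline's own decisions.

    Returns the 19-variant cohort list (in printed table order), the 17
    patients with their annotated variants attached, and the Case #4
    pedigree.
    """
    table1 = _read_table("table1_variants.tsv")
    table2 = _read_table("table2_patients.tsv")
    catalog = load_known_catalog()
    annotations = load_annotation_source()

    try:
        calls = read_variant_table(fixture_path("patient_calls.tsv"), dialect="tsv")
    except ValueError as exc:
        raise FixtureError(f"fixture table 'patient_calls.tsv' is corrupt: {exc}") from exc

    annotated_by_patient: dict[str, list[AnnotatedVariant]] = {}
    annotated_by_key: dict[str, AnnotatedVariant] = {}
    for call, zygosity in apply_qc_filters(calls, thresholds):
        ann = annotations.get(call.key, {})
        variant = annotate_call(
            call,
            zygosity,
            freq_inhouse=ann.get("freq_inhouse"),
            sift=ann.get("sift"),
            polyphen=ann.get("polyphen"),
            known_catalog=catalog,
            rarity=rarity,
            missense=missense,
        )
        annotated_by_patient.setdefault(call.patient_id, []).append(variant)
        annotated_by_key[call.key] = variant

    patients: list[PatientCase] = []
    for _, row in table2.iterrows():
        pid = str(row["patient_id"])
        onset = row.get("onset_night_blindness")
        onset_val = None if str(onset).strip().lower() in ("unknown", "nan", "") else int(onset)
        ped_id = row.get("pedigree_id")
        ped_id = None if ped_id is None or str(ped_id) in ("", "nan") else str(ped_id)
        patients.append(
            PatientCase(
                patient_id=pid,
                age=int(row["age"]),
                sex=str(row["sex"]),
                inheritance_label=str(row["hereditary_form"]),
                onset_night_blindness=onset_val,
                variants=annotated_by_patient.get(pid, []),
                pedigree_id=ped_id,
            )
        )
    if len(patients) != len({p.patient_id for p in patients}):
        raise FixtureError("fixture table 'table2_patients.tsv' has duplicate patients")

    variants: list[AnnotatedVariant] = []
    for _, row in table1.iterrows():
        key = make_variant_key(str(row["gene"]), str(row["hgvs_c"]))
        variant = annotated_by_key.get(key)
        if variant is None:
            raise FixtureError(
                f"fixture table 'table1_variants.tsv' row {key} has no carrier "
                "in 'patient_calls.tsv'"
            )
        variants.append(variant)

    return FixtureTables(variants=variants, patients=patients, pedigrees=_load_pedigrees())
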