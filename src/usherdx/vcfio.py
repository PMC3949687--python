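"""File-format adapters: variant tables (TSV / minimal VCF 4.2) and PED.

Two variant-table dialects are supported:

* ``tsv`` — tab-delimited with header, one call per row, columns
  ``patient_id  gene  hgvs_c  [hgvs_p  location]  depth
  mean_base_quality  alt_fraction  [flags]`` (flags comma-separated);
* ``vcf`` — minimal VCF 4.2 with one sample per file.  CHROM carries the
  gene symbol (variant identity lives in transcript space), INFO carries
  ``GENE``/``HGVSC``/``HGVSP``/``FLAGS`` and FORMAT carries ``DP``, ``AD``
  (ref,alt read counts) and ``QV`` (mean base quality).  The alternate
  allele fraction is derived from AD when not given explicitly.

Reading VCF goes through :mod:`pysam`; writing emits the minimal dialect
directly.  Malformed rows are reported with their line numbers.
"""
from __future__ import annotations

import csv
import math
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .models import Pedigree, PedigreeMember, VariantCall, make_variant_key

__all__ = [
    "read_variant_table",
    "write_variant_tsv",
    "write_vcf",
    "read_ped",
    "read_ped_genotypes",
]

_TSV_REQUIRED = ("patient_id", "gene", "hgvs_c", "depth", "mean_base_quality", "alt_fraction")


def _parse_flags(raw: object) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return frozenset()
    text = str(raw).strip()
    if not text or text.lower() == "nan":
        return frozenset()
    return frozenset(p.strip() for p in text.split(",") if p.strip())


def _opt_str(raw: object) -> str:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return ""
    return str(raw)


def _read_tsv_calls(path: Path) -> list[VariantCall]:
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file without header") from exc
    missing = [c for c in _TSV_REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    calls: list[VariantCall] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            calls.append(
                VariantCall(
                    patient_id=str(row["patient_id"]),
                    gene=str(row["gene"]),
                    hgvs_c=str(row["hgvs_c"]),
                    hgvs_p=_opt_str(row.get("hgvs_p", "")),
                    location=_opt_str(row.get("location", "")),
                    depth=int(float(row["depth"])),
                    mean_base_quality=float(row["mean_base_quality"]),
                    alt_fraction=float(row["alt_fraction"]),
                    detectability_flags=_parse_flags(row.get("flags", "")),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line_no}: {exc}")
    if errors:
        raise ValueError(f"{path}: malformed rows — " + "; ".join(errors))
    return calls


def _read_vcf_calls(path: Path) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            info = rec.info
            gene = str(info.get("GENE", rec.chrom))
            hgvs_c = str(info.get("HGVSC", ""))
            if not hgvs_c:
                raise ValueError(f"{path}: record at {rec.chrom}:{rec.pos} lacks INFO/HGVSC")
            hgvs_p = str(info.get("HGVSP", "") or "")
            flags = _parse_flags(",".join(info.get("FLAGS", ()) or ()))
            for sample in samples:
                fmt = rec.samples[sample]
                ad = fmt.get("AD")
                dp = fmt.get("DP")
                if ad is not None and len(ad) >= 2 and ad[0] is not None:
                    total = sum(a for a in ad if a is not None)
                    depth = int(dp if dp is not None else total)
                    alt_fraction = (ad[1] / total) if total > 0 else 0.0
                else:
                    depth = int(dp or 0)
                    alt_fraction = float(fmt.get("AF", 0.0) or 0.0)
                qv = fmt.get("QV")
                calls.append(
                    VariantCall(
                        patient_id=sample,
                        gene=gene,
                        hgvs_c=hgvs_c,
                        hgvs_p="" if hgvs_p == "." else hgvs_p,
                        depth=depth,
                        mean_base_quality=float(qv if qv is not None else 0.0),
                        alt_fraction=alt_fraction,
                        detectability_flags=flags,
                    )
                )
    return calls


def read_variant_table(path: "str | Path", dialect: str = "tsv") -> list[VariantCall]:
    """Read per-patient variant calls from a TSV or minimal-VCF file."""
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv_calls(path)
    if dialect == "vcf":
        return _read_vcf_calls(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'vcf')")


def write_variant_tsv(calls: Iterable[VariantCall], path: "str | Path") -> None:
    """Write calls in the package's TSV dialect (UTF-8, header required)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "patient_id",
                "gene",
                "hgvs_c",
                "hgvs_p",
                "location",
                "depth",
                "mean_base_quality",
                "alt_fraction",
                "flags",
            ]
        )
        for c in calls:
            writer.writerow(
                [
                    c.patient_id,
                    c.gene,
                    c.hgvs_c,
                    c.hgvs_p,
                    c.location,
                    c.depth,
                    repr(c.mean_base_quality),
                    repr(c.alt_fraction),
                    ",".join(sorted(c.detectability_flags)),
                ]
            )


_POS_RE = re.compile(r"c\.(\d+)")


def _vcf_pos(hgvs_c: str) -> int:
    m = _POS_RE.search(hgvs_c)
    return int(m.group(1)) if m else 1


def write_vcf(
    calls: Sequence[VariantCall],
    path: "str | Path",
    sample: Optional[str] = None,
    contigs: Optional[Sequence[str]] = None,
) -> None:
    """Write one sample's calls as minimal VCF 4.2 text.

    POS is the first coding coordinate of the HGVS string (pass-through
    metadata; identity is INFO/GENE + INFO/HGVSC).  REF/ALT use the actual
    bases for substitutions and ``N`` placeholders for indels.
    """
    calls = list(calls)
    if sample is None:
        samples = {c.patient_id for c in calls}
        if len(samples) > 1:
            raise ValueError("write_vcf writes one sample per file")
        sample = samples.pop() if samples else "SAMPLE"
    if contigs is None:
        contigs = sorted({c.gene for c in calls})
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=HGVSC,Number=1,Type=String,Description="Coding HGVS change">',
        '##INFO=<ID=HGVSP,Number=1,Type=String,Description="Protein HGVS change">',
        '##INFO=<ID=FLAGS,Number=.,Type=String,Description="Detectability flags">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt read depths">',
        '##FORMAT=<ID=QV,Number=1,Type=Float,Description="Mean base quality">',
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for c in sorted(calls, key=lambda v: (v.gene, _vcf_pos(v.hgvs_c), v.key)):
        m = re.match(r"^c\.\d+(?:[+-]\d+)?([ACGT])>([ACGT])$", "".join(c.hgvs_c.split()), re.I)
        ref, alt = (m.group(1).upper(), m.group(2).upper()) if m else ("N", "NN")
        info = f"GENE={c.gene};HGVSC={c.hgvs_c}"
        if c.hgvs_p:
            info += f";HGVSP={c.hgvs_p}"
        if c.detectability_flags:
            info += ";FLAGS=" + ",".join(sorted(c.detectability_flags))
        alt_reads = round(c.alt_fraction * c.depth)
        fmt = f"{c.depth}:{c.depth - alt_reads},{alt_reads}:{c.mean_base_quality:.2f}"
        lines.append(
            f"{c.gene}\t{_vcf_pos(c.hgvs_c)}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tDP:AD:QV\t{fmt}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_ped(path: "str | Path") -> dict[str, Pedigree]:
    """Read standard 6-column PED into pedigrees keyed by family id.

    Columns: family, individual, father (0 = founder), mother, sex
    (1 = male, 2 = female), phenotype (2 = affected).
    """
    families: dict[str, list[PedigreeMember]] = {}
    for line_no, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise ValueError(f"{path}: line {line_no}: expected 6 PED columns")
        fam, ind, father, mother, sex, pheno = parts[:6]
        families.setdefault(fam, []).append(
            PedigreeMember(
                individual_id=ind,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex={"1": "M", "2": "F"}.get(sex, ""),
                affected=pheno == "2",
            )
        )
    return {fam: Pedigree(pedigree_id=fam, members=members) for fam, members in families.items()}


def read_ped_genotypes(
    path: "str | Path", pedigrees: dict[str, Pedigree]
) -> dict[str, Pedigree]:
    """Attach family genotypes (TSV: individual_id, gene, hgvs_c, genotype)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    member_to_fam = {
        m.individual_id: fam for fam, ped in pedigrees.items() for m in ped.members
    }
    for idx, row in frame.iterrows():
        ind = str(row["individual_id"])
        fam = member_to_fam.get(ind)
        if fam is None:
            raise ValueError(
                f"{path}: line {int(idx) + 2}: individual {ind!r} not in any pedigree"
            )
        key = make_variant_key(str(row["gene"]), str(row["hgvs_c"]))
        pedigrees[fam].genotypes[(ind, key)] = str(row["genotype"])
    return pedigrees
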