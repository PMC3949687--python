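"""Core domain types for a multi-gene Usher syndrome (USH1) sequencing panel.

Usher syndrome type 1 (USH1) is an autosomal recessive disorder (congenital
profound hearing loss, absent vestibular responses, prepubertal retinitis
pigmentosa).  A targeted amplicon panel screens the nine known Usher genes;
variant calls flow from raw caller output (:class:`VariantCall`) through
annotation (:class:`AnnotatedVariant`) to a per-patient genotype diagnosis
(:class:`DiagnosticCall`): biallelic, digenic, monoallelic or unsolved, with
optional modifier candidates in a second gene.

Variant identity throughout the package is gene symbol + coding HGVS string
(transcript space); genomic coordinates are pass-through metadata only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

HET = "het"
HOM = "hom"
REJECTED = "rejected"
ZYGOSITIES = frozenset({HET, HOM})

MISSENSE = "missense"
NONSENSE = "nonsense"
FRAMESHIFT = "frameshift"
SPLICE = "splice"
OTHER = "other"
CONSEQUENCES = frozenset({MISSENSE, NONSENSE, FRAMESHIFT, SPLICE, OTHER})

#: consequence classes that are pathogenic per se (truncating / splice-disrupting)
TRUNCATING = frozenset({NONSENSE, FRAMESHIFT, SPLICE})

PATHOGENIC = "pathogenic"
PROBABLE_PATHOGENIC = "probable_pathogenic"
UNCERTAIN = "uncertain"
EXCLUDED = "excluded"
TIERS = frozenset({PATHOGENIC, PROBABLE_PATHOGENIC, UNCERTAIN, EXCLUDED})

SOLVED_BIALLELIC = "solved_biallelic"
DIGENIC = "digenic"
MONOALLELIC = "monoallelic"
UNSOLVED = "unsolved"
CATEGORIES = frozenset({SOLVED_BIALLELIC, DIGENIC, MONOALLELIC, UNSOLVED})

CONFIRMED_TRANS = "confirmed_trans"
CONFIRMED_CIS = "confirmed_cis"
ASSUMED = "assumed"
NOT_TESTED = "not_tested"
INCONSISTENT = "inconsistent"

HOMOPOLYMER_REGION = "homopolymer_region"
OUTSIDE_DESIGN = "outside_design"
DETECTABILITY_FLAGS = frozenset({HOMOPOLYMER_REGION, OUTSIDE_DESIGN})

#: genes implicated in USH1 — the default search space for causal and
#: modifier variants.
USH1_GENES = ("MYO7A", "USH1C", "CDH23", "PCDH15", "USH1G")


class UsherdxError(Exception):
    """Base class for package errors."""


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenePanel:
    """The screened gene set with transcript accessions.

    Parameters
    ----------
    genes:
        ``(symbol, refseq_accession)`` pairs; symbols must be unique.
    covered_fraction:
        Proportion of target exons for which amplicons could be designed
        (unitless, in [0, 1]).  Variants falling in the remaining fraction
        are invisible to the panel.
    """

    genes: tuple[tuple[str, str], ...]
    covered_fraction: float = 0.97

    def __post_init__(self) -> None:
        symbols = [g for g, _ in self.genes]
        if len(set(symbols)) != len(symbols):
            raise ValueError("gene symbols must be unique")
        if not 0.0 <= self.covered_fraction <= 1.0:
            raise ValueError("covered_fraction must lie in [0, 1]")

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.genes)


#: The nine-gene Usher panel with its RefSeq transcripts.
DEFAULT_PANEL = GenePanel(
    genes=(
        ("MYO7A", "NM_000260.3"),
        ("USH1C", "NM_153676.3"),
        ("CDH23", "NM_022124.5"),
        ("PCDH15", "NM_033056.3"),
        ("USH1G", "NM_173477.2"),
        ("USH2A", "NM_206933.2"),
        ("GPR98", "NM_032119.3"),
        ("DFNB31", "NM_015404.3"),
        ("CLRN1", "NM_174878.2"),
    ),
    covered_fraction=0.97,
)


# ---------------------------------------------------------------------------
# Variant identity
# ---------------------------------------------------------------------------


def make_variant_key(gene: str, hgvs_c: str) -> str:
    """Canonical identifier for a variant: gene + normalized coding HGVS.

    Keys are equal iff the gene symbols match (case-insensitively) and the
    coding HGVS strings match after stripping all whitespace and folding
    case.
    """
    if not hgvs_c or not hgvs_c.strip():
        raise ValueError("hgvs_c must be non-empty")
    return f"{gene.strip().upper()}:{''.join(hgvs_c.split()).lower()}"


def variant_key(v: "VariantCall | AnnotatedVariant") -> str:
    """Canonical identifier for a call or annotated variant."""
    if isinstance(v, AnnotatedVariant):
        v = v.call
    return make_variant_key(v.gene, v.hgvs_c)


# ---------------------------------------------------------------------------
# Calls and annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantCall:
    """One observed variant site in one patient, before any filtering.

    ``detectability_flags`` marks sites the amplicon platform cannot see:
    ``outside_design`` (no amplicon covers the exon) or
    ``homopolymer_region`` (indel inside a homopolymer run, where
    semiconductor sequencing is unreliable); such variants reach a callset
    only through orthogonal Sanger sequencing.
    """

    patient_id: str
    gene: str
    hgvs_c: str
    hgvs_p: str = ""
    location: str = ""
    depth: int = 0
    mean_base_quality: float = 0.0
    alt_fraction: float = 0.0
    detectability_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.hgvs_c or not self.hgvs_c.strip():
            raise ValueError("hgvs_c must be non-empty")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValueError("alt_fraction must lie in [0, 1]")
        unknown = self.detectability_flags - DETECTABILITY_FLAGS
        if unknown:
            raise ValueError(f"unknown detectability flags: {sorted(unknown)}")

    @property
    def key(self) -> str:
        return make_variant_key(self.gene, self.hgvs_c)


@dataclass(frozen=True)
class AnnotatedVariant:
    """A surviving call with zygosity, consequence, rarity and tier.

    Population frequencies are allele frequencies in [0, 1]; ``None`` means
    the variant is absent from (or unreported in) that source, which the
    rarity filter treats as passing — novel variants are by definition in
    no catalog.  ``tier`` encodes the categorical pathogenicity rule:
    truncating consequences (nonsense / frameshift / canonical splice) are
    ``pathogenic``; rare missense changes with damaging predictor support
    are ``probable_pathogenic``; rare variants without support are
    ``uncertain``; common variants are ``excluded``.
    """

    call: VariantCall
    zygosity: str
    consequence: str
    freq_1000g: Optional[float] = None
    freq_exome: Optional[float] = None
    freq_inhouse: Optional[float] = None
    sift: Optional[float] = None
    polyphen: Optional[float] = None
    tier: str = UNCERTAIN
    novel: bool = True

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"zygosity must be het or hom, got {self.zygosity!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.tier == PATHOGENIC and self.consequence not in TRUNCATING:
            raise ValueError(
                "tier=pathogenic is reserved for nonsense/frameshift/splice"
            )
        for name in ("freq_1000g", "freq_exome", "freq_inhouse", "sift", "polyphen"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1] when present")

    @property
    def key(self) -> str:
        return self.call.key

    @property
    def gene(self) -> str:
        return self.call.gene

    @property
    def n_alleles(self) -> int:
        """Allele count contributed by this variant (a homozygote counts 2)."""
        return 2 if self.zygosity == HOM else 1


# ---------------------------------------------------------------------------
# Patients and pedigrees
# ---------------------------------------------------------------------------


@dataclass
class PatientCase:
    """Patient metadata plus the variants that survived filtering."""

    patient_id: str
    age: Optional[int] = None
    sex: str = ""
    inheritance_label: str = ""  # "AR" or "sporadic"
    onset_night_blindness: Optional[int] = None  # years; None = unknown
    variants: list[AnnotatedVariant] = field(default_factory=list)
    pedigree_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.onset_night_blindness is not None and self.onset_night_blindness < 0:
            raise ValueError("onset_night_blindness must be >= 0 when known")


@dataclass(frozen=True)
class PedigreeMember:
    individual_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str = ""  # "M" / "F" / ""
    affected: bool = False


@dataclass
class Pedigree:
    """A family with per-individual genotypes at the proband's variants.

    ``genotypes`` maps ``(individual_id, variant_key)`` to one of
    ``{"ref", "het", "hom"}``.  Parent references must resolve within the
    family or be founders, and at least one affected member (the proband)
    must be present.
    """

    pedigree_id: str
    members: list[PedigreeMember]
    genotypes: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {m.individual_id for m in self.members}
        for m in self.members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in ids:
                    raise ValueError(
                        f"pedigree {self.pedigree_id}: parent {parent!r} of "
                        f"{m.individual_id!r} does not resolve"
                    )
        if not any(m.affected for m in self.members):
            raise ValueError(f"pedigree {self.pedigree_id}: no affected proband")
        for (_, _), geno in self.genotypes.items():
            if geno not in {"ref", HET, HOM}:
                raise ValueError(f"invalid genotype {geno!r}")

    @property
    def proband_id(self) -> str:
        return next(m.individual_id for m in self.members if m.affected)

    def member(self, individual_id: str) -> PedigreeMember:
        for m in self.members:
            if m.individual_id == individual_id:
                return m
        raise KeyError(individual_id)

    def genotype(self, individual_id: str, key: str) -> Optional[str]:
        """Genotype of an individual at a variant, or None if unrecorded."""
        return self.genotypes.get((individual_id, key))


# ---------------------------------------------------------------------------
# Diagnosis
# ---------------------------------------------------------------------------


@dataclass
class DiagnosticCall:
    """Per-patient genotype classification with supporting evidence."""

    patient_id: str
    category: str
    primary_genes: tuple[str, ...] = ()
    causal_variants: list[AnnotatedVariant] = field(default_factory=list)
    modifier_candidates: list[AnnotatedVariant] = field(default_factory=list)
    segregation_status: str = NOT_TESTED
    notes: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        n_alleles = sum(v.n_alleles for v in self.causal_variants)
        if self.category == SOLVED_BIALLELIC and n_alleles != 2:
            raise ValueError(
                "solved_biallelic requires exactly 2 causal alleles "
                f"(got {n_alleles})"
            )
        if self.category == DIGENIC:
            genes = {v.gene for v in self.causal_variants}
            if (
                len(self.causal_variants) != 2
                or len(genes) != 2
                or any(v.zygosity != HET for v in self.causal_variants)
            ):
                raise ValueError(
                    "digenic requires exactly one het causal variant in each "
                    "of two distinct genes"
                )

    @property
    def n_causal_alleles(self) -> int:
        return sum(v.n_alleles for v in self.causal_variants)
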