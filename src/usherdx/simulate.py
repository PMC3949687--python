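"""Synthetic amplicon-panel cohorts with known planted diagnoses.

The simulator emulates the statistical structure of targeted amplicon
sequencing on the nine-gene Usher panel so that every downstream stage
(QC filtering, annotation, diagnosis, reporting) has a ground-truth
recovery test without any external data:

* per-site read depth is overdispersed around the panel's mean coverage
  (negative binomial; amplicon coverage is far noisier than Poisson);
* the alternate-read count is Binomial(depth, p) with p = 0.5 for
  heterozygotes and p = 1 - eps for homozygotes, where eps is the per-base
  error rate — so heterozygous allele fractions concentrate near 40-60%
  and homozygous ones near 80-100%;
* each planted variant is independently invisible with probability
  1 - covered_fraction (exon not in the amplicon design), and an indel in
  a homopolymer run is additionally missed with ``homopolymer_miss_prob``
  (semiconductor chemistry fails on homopolymers as a *non-detection*,
  not a miscall);
* common background polymorphisms (population frequency >= 5%) are spiked
  in at a Poisson rate per patient — the rarity filter must remove them;
* trio pedigrees with phase-consistent parental genotypes accompany every
  digenic or compound-heterozygous proband.

All randomness derives from a single seed; per-patient child streams are
spawned deterministically, so a cohort is byte-for-byte reproducible.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .models import (
    DIGENIC,
    FRAMESHIFT,
    HET,
    HOM,
    MISSENSE,
    MONOALLELIC,
    NONSENSE,
    OTHER,
    SOLVED_BIALLELIC,
    SPLICE,
    UNSOLVED,
    USH1_GENES,
    DEFAULT_PANEL,
    GenePanel,
    Pedigree,
    PedigreeMember,
    VariantCall,
    make_variant_key,
)

__all__ = [
    "MODIFIER",
    "DEFAULT_DIAGNOSIS_MIX",
    "SimulationConfig",
    "PlantedVariant",
    "PatientTruth",
    "CohortTruth",
    "SiteAnnotation",
    "SimulatedCohort",
    "simulate_cohort",
    "planted_detectability",
    "expected_observable_category",
    "draw_depth_and_fraction",
]

#: extra truth category: biallelic diagnosis plus a second-gene modifier
MODIFIER = "modifier"

_TRUTH_CATEGORIES = (SOLVED_BIALLELIC, DIGENIC, MODIFIER, MONOALLELIC, UNSOLVED)

#: cohort composition of a 17-patient USH1 screening study:
#: 8 biallelic without modifier, 4 biallelic with modifier, 1 digenic,
#: 3 monoallelic, 1 unsolved.
DEFAULT_DIAGNOSIS_MIX: dict[str, float] = {
    SOLVED_BIALLELIC: 8 / 17,
    MODIFIER: 4 / 17,
    DIGENIC: 1 / 17,
    MONOALLELIC: 3 / 17,
    UNSOLVED: 1 / 17,
}

_AA3 = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val"
).split()
_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for a simulated cohort.

    Defaults reproduce the panel's reported sequencing regime: 314.2x mean
    target depth, ~Q30 base quality (above the Q25 filter), 97% of target
    exons designable.  The per-base error rate (0.01) and the depth
    overdispersion are configuration, not measured quantities.
    """

    n_patients: int = 17
    panel: GenePanel = DEFAULT_PANEL
    mean_depth: float = 314.2
    depth_dispersion: float = 8.0  # negative-binomial size; larger = tighter
    mean_base_quality: float = 30.0
    base_quality_sd: float = 2.0
    error_rate: float = 0.01
    covered_fraction: float = 0.97
    homopolymer_fraction: float = 0.2  # P(a planted indel sits in a homopolymer)
    homopolymer_miss_prob: float = 0.5
    background_polymorphism_rate: float = 2.0
    diagnosis_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIAGNOSIS_MIX)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be > 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be > 0")
        for name in (
            "error_rate",
            "covered_fraction",
            "homopolymer_fraction",
            "homopolymer_miss_prob",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.background_polymorphism_rate < 0:
            raise ValueError("background_polymorphism_rate must be >= 0")
        unknown = set(self.diagnosis_mix) - set(_TRUTH_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown diagnosis_mix categories: {sorted(unknown)}")
        total = sum(self.diagnosis_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"diagnosis_mix proportions must sum to 1 (got {total})")


@dataclass(frozen=True)
class PlantedVariant:
    """Ground truth for one planted variant in one patient."""

    patient_id: str
    gene: str
    hgvs_c: str
    hgvs_p: str
    zygosity: str
    consequence: str
    role: str  # "causal" | "modifier" | "background"
    homopolymer: bool = False
    parent_origin: Optional[str] = None  # "father" | "mother" for phased hets
    dropped: Optional[str] = None  # None = emitted as an MPS call

    @property
    def key(self) -> str:
        return make_variant_key(self.gene, self.hgvs_c)


@dataclass(frozen=True)
class PatientTruth:
    patient_id: str
    category: str
    variants: tuple[PlantedVariant, ...]
    pedigree_id: Optional[str] = None


@dataclass(frozen=True)
class CohortTruth:
    patients: tuple[PatientTruth, ...]


@dataclass(frozen=True)
class SiteAnnotation:
    """Annotation inputs the pipeline consumes for one variant site."""

    gene: str
    hgvs_c: str
    hgvs_p: str = ""
    freq_1000g: Optional[float] = None
    freq_exome: Optional[float] = None
    freq_inhouse: Optional[float] = None
    sift: Optional[float] = None
    polyphen: Optional[float] = None


@dataclass(frozen=True)
class SimulatedCohort:
    config: SimulationConfig
    truth: CohortTruth
    calls: dict[str, list[VariantCall]]  # patient_id -> emitted MPS calls
    pedigrees: list[Pedigree]
    annotations: dict[str, SiteAnnotation]  # variant key -> annotation inputs


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------


def draw_depth_and_fraction(
    rng: np.random.Generator, cfg: SimulationConfig, zygosity: str
) -> tuple[int, float]:
    """Sample (depth, alt_fraction) for one site.

    Depth ~ NegBin with mean ``mean_depth`` and size ``depth_dispersion``;
    alt reads ~ Binomial(depth, p), p = 0.5 (het) or 1 - error_rate (hom).
    A zero-depth draw returns fraction 0.
    """
    k, m = cfg.depth_dispersion, cfg.mean_depth
    depth = int(rng.negative_binomial(k, k / (k + m)))
    if depth == 0:
        return 0, 0.0
    p = 0.5 if zygosity == HET else 1.0 - cfg.error_rate
    alt = int(rng.binomial(depth, p))
    return depth, alt / depth


def _draw_quality(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    return float(
        np.clip(rng.normal(cfg.mean_base_quality, cfg.base_quality_sd), 0.0, 45.0)
    )


def _fresh_codon(rng: np.random.Generator, gene: str, used: set[str]) -> int:
    # codon labels are synthetic plumbing; the wide range keys cohort-level
    # uniqueness so annotation lookups stay one-to-one even for huge cohorts
    while True:
        codon = int(rng.integers(10, 30_000))
        if f"{gene}:{codon}" not in used:
            used.add(f"{gene}:{codon}")
            return codon


def _synth_hgvs(
    rng: np.random.Generator, gene: str, consequence: str, used: set[str]
) -> tuple[str, str]:
    """Invent a syntactically valid (hgvs_c, hgvs_p) of the requested class."""
    codon = _fresh_codon(rng, gene, used)
    pos = 3 * codon - 2
    ref, alt = rng.choice(list(_BASES), size=2, replace=False)
    aa_from, aa_to = rng.choice(_AA3, size=2, replace=False)
    if consequence == NONSENSE:
        return f"c.{pos}{ref}>{alt}", f"p.{aa_from}{codon}X"
    if consequence == MISSENSE:
        return f"c.{pos}{ref}>{alt}", f"p.{aa_from}{codon}{aa_to}"
    if consequence == SPLICE:
        offset = int(rng.choice([-2, -1, 1, 2]))
        sign = "+" if offset > 0 else "-"
        return f"c.{3 * codon}{sign}{abs(offset)}{ref}>{alt}", "?"
    if consequence == FRAMESHIFT:
        stop = int(rng.integers(2, 60))
        if rng.random() < 0.5:
            return f"c.{pos}dup", f"p.{aa_from}{codon}{aa_to}fsX{stop}"
        seq = "".join(rng.choice(list(_BASES), size=2))
        return f"c.{pos}_{pos + 1}del{seq}", f"p.{aa_from}{codon}{aa_to}fsX{stop}"
    if consequence == OTHER:
        # deep intronic substitution: parseable, classified as other
        offset = int(rng.integers(8, 40))
        return f"c.{3 * codon}+{offset}{ref}>{alt}", ""
    raise ValueError(f"cannot synthesise consequence {consequence!r}")


_CAUSAL_CLASSES = (NONSENSE, FRAMESHIFT, SPLICE, MISSENSE)
_CAUSAL_WEIGHTS = (0.35, 0.30, 0.10, 0.25)


def _damaging_scores(rng: np.random.Generator) -> tuple[float, float]:
    """SIFT/PolyPhen pair that the OR-rule calls damaging."""
    sift = round(float(rng.uniform(0.0, 0.04)), 3)
    polyphen = round(float(rng.uniform(0.6, 1.0)), 3)
    return sift, polyphen


def _benign_scores(rng: np.random.Generator) -> tuple[float, float]:
    sift = round(float(rng.uniform(0.2, 1.0)), 3)
    polyphen = round(float(rng.uniform(0.0, 0.4)), 3)
    return sift, polyphen


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _plant_patient(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    patient_id: str,
    category: str,
    used: set[str],
    annotations: dict[str, SiteAnnotation],
) -> tuple[list[PlantedVariant], Optional[str]]:
    """Plant the causal/modifier/background variants for one patient."""
    ush1 = [g for g in cfg.panel.symbols if g in USH1_GENES] or list(cfg.panel.symbols)
    planted: list[PlantedVariant] = []
    pedigree_needed = False

    def causal(gene: str, zygosity: str, origin: Optional[str]) -> PlantedVariant:
        consequence = str(rng.choice(_CAUSAL_CLASSES, p=_CAUSAL_WEIGHTS))
        hgvs_c, hgvs_p = _synth_hgvs(rng, gene, consequence, used)
        homopolymer = consequence == FRAMESHIFT and rng.random() < cfg.homopolymer_fraction
        sift = polyphen = None
        if consequence == MISSENSE:
            sift, polyphen = _damaging_scores(rng)
        annotations[make_variant_key(gene, hgvs_c)] = SiteAnnotation(
            gene=gene, hgvs_c=hgvs_c, hgvs_p=hgvs_p,
            freq_inhouse=0.0, sift=sift, polyphen=polyphen,
        )
        return PlantedVariant(
            patient_id=patient_id, gene=gene, hgvs_c=hgvs_c, hgvs_p=hgvs_p,
            zygosity=zygosity, consequence=consequence, role="causal",
            homopolymer=homopolymer, parent_origin=origin,
        )

    if category in (SOLVED_BIALLELIC, MODIFIER):
        gene = str(rng.choice(ush1))
        if rng.random() < 0.5:
            planted.append(causal(gene, HOM, None))
        else:
            planted.append(causal(gene, HET, "father"))
            planted.append(causal(gene, HET, "mother"))
            pedigree_needed = True
        if category == MODIFIER:
            other = str(rng.choice([g for g in ush1 if g != gene]))
            hgvs_c, hgvs_p = _synth_hgvs(rng, other, MISSENSE, used)
            sift, polyphen = _damaging_scores(rng)
            annotations[make_variant_key(other, hgvs_c)] = SiteAnnotation(
                gene=other, hgvs_c=hgvs_c, hgvs_p=hgvs_p,
                freq_inhouse=0.0, sift=sift, polyphen=polyphen,
            )
            planted.append(
                PlantedVariant(
                    patient_id=patient_id, gene=other, hgvs_c=hgvs_c,
                    hgvs_p=hgvs_p, zygosity=HET, consequence=MISSENSE,
                    role="modifier",
                )
            )
    elif category == DIGENIC:
        gene_a, gene_b = (str(g) for g in rng.choice(ush1, size=2, replace=False))
        planted.append(causal(gene_a, HET, "father"))
        planted.append(causal(gene_b, HET, "mother"))
        pedigree_needed = True
    elif category == MONOALLELIC:
        planted.append(causal(str(rng.choice(ush1)), HET, None))
    elif category != UNSOLVED:
        raise ValueError(f"unknown truth category {category!r}")

    # common background polymorphisms across the whole panel
    for _ in range(int(rng.poisson(cfg.background_polymorphism_rate))):
        gene = str(rng.choice(list(cfg.panel.symbols)))
        consequence = str(rng.choice([MISSENSE, OTHER], p=[0.6, 0.4]))
        hgvs_c, hgvs_p = _synth_hgvs(rng, gene, consequence, used)
        sift, polyphen = _benign_scores(rng) if consequence == MISSENSE else (None, None)
        annotations[make_variant_key(gene, hgvs_c)] = SiteAnnotation(
            gene=gene, hgvs_c=hgvs_c, hgvs_p=hgvs_p,
            freq_1000g=round(float(rng.uniform(0.05, 0.5)), 3),
            freq_inhouse=round(float(rng.uniform(0.05, 0.5)), 3),
            sift=sift, polyphen=polyphen,
        )
        planted.append(
            PlantedVariant(
                patient_id=patient_id, gene=gene, hgvs_c=hgvs_c, hgvs_p=hgvs_p,
                zygosity=HET if rng.random() < 0.5 else HOM,
                consequence=consequence, role="background",
            )
        )

    return planted, (f"FAM{patient_id}" if pedigree_needed else None)


def _emit_calls(
    rng: np.random.Generator, cfg: SimulationConfig, planted: list[PlantedVariant]
) -> tuple[list[PlantedVariant], list[VariantCall]]:
    """Apply platform dropout, then sample depth/fraction for survivors."""
    final: list[PlantedVariant] = []
    calls: list[VariantCall] = []
    for pv in planted:
        dropped: Optional[str] = None
        if rng.random() > cfg.covered_fraction:
            dropped = "outside_design"
        elif pv.homopolymer and rng.random() < cfg.homopolymer_miss_prob:
            dropped = "homopolymer_miss"
        else:
            depth, fraction = draw_depth_and_fraction(rng, cfg, pv.zygosity)
            if depth == 0:
                dropped = "no_reads"
            else:
                calls.append(
                    VariantCall(
                        patient_id=pv.patient_id,
                        gene=pv.gene,
                        hgvs_c=pv.hgvs_c,
                        hgvs_p=pv.hgvs_p,
                        depth=depth,
                        mean_base_quality=round(_draw_quality(rng, cfg), 2),
                        alt_fraction=fraction,
                    )
                )
        final.append(pv if dropped is None else dataclasses.replace(pv, dropped=dropped))
    return final, calls


def _trio_pedigree(pedigree_id: str, proband: str, variants: list[PlantedVariant]) -> Pedigree:
    father, mother = f"{proband}.fa", f"{proband}.mo"
    members = [
        PedigreeMember(father, None, None, "M", False),
        PedigreeMember(mother, None, None, "F", False),
        PedigreeMember(proband, father, mother, "", True),
    ]
    genotypes: dict[tuple[str, str], str] = {}
    for pv in variants:
        if pv.role != "causal":
            continue
        if pv.zygosity == HET and pv.parent_origin is not None:
            carrier = father if pv.parent_origin == "father" else mother
            non_carrier = mother if carrier == father else father
            genotypes[(proband, pv.key)] = HET
            genotypes[(carrier, pv.key)] = HET
            genotypes[(non_carrier, pv.key)] = "ref"
        elif pv.zygosity == HOM:
            genotypes[(proband, pv.key)] = HOM
            genotypes[(father, pv.key)] = HET
            genotypes[(mother, pv.key)] = HET
    return Pedigree(pedigree_id=pedigree_id, members=members, genotypes=genotypes)


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort with known planted diagnoses.

    Fully reproducible from ``cfg.seed``: the master stream assigns truth
    categories; patient ``i`` then draws from the child stream seeded
    ``[seed, i]``.
    """
    master = np.random.default_rng(cfg.seed)
    probs = [cfg.diagnosis_mix.get(c, 0.0) for c in _TRUTH_CATEGORIES]
    categories = master.choice(_TRUTH_CATEGORIES, size=cfg.n_patients, p=probs)

    used: set[str] = set()
    annotations: dict[str, SiteAnnotation] = {}
    patients: list[PatientTruth] = []
    calls: dict[str, list[VariantCall]] = {}
    pedigrees: list[Pedigree] = []

    for i, category in enumerate(categories):
        patient_id = f"S{i + 1:03d}"
        rng = np.random.default_rng([cfg.seed, i])
        planted, ped_id = _plant_patient(rng, cfg, patient_id, str(category), used, annotations)
        planted, patient_calls = _emit_calls(rng, cfg, planted)
        calls[patient_id] = patient_calls
        if ped_id is not None:
            pedigrees.append(_trio_pedigree(ped_id, patient_id, planted))
        patients.append(
            PatientTruth(
                patient_id=patient_id,
                category=str(category),
                variants=tuple(planted),
                pedigree_id=ped_id,
            )
        )

    return SimulatedCohort(
        config=cfg,
        truth=CohortTruth(patients=tuple(patients)),
        calls=calls,
        pedigrees=pedigrees,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# analytic expectations (oracles for recovery tests)
# ---------------------------------------------------------------------------


def planted_detectability(truth: CohortTruth, cfg: SimulationConfig) -> float:
    """Expected fraction of planted causal/modifier variants visible to MPS.

    A variant outside a homopolymer is seen iff its exon is covered
    (probability ``covered_fraction``); a homopolymer indel additionally
    survives the chemistry with probability ``1 - homopolymer_miss_prob``.
    """
    planted = [
        pv
        for patient in truth.patients
        for pv in patient.variants
        if pv.role in ("causal", "modifier")
    ]
    if not planted:
        raise ValueError("no planted variants in truth")
    per_variant = [
        cfg.covered_fraction
        * ((1.0 - cfg.homopolymer_miss_prob) if pv.homopolymer else 1.0)
        for pv in planted
    ]
    return float(np.mean(per_variant))


def expected_observable_category(surviving: Sequence[tuple[str, str]]) -> str:
    """Category the diagnosis stage *should* report, by direct enumeration.

    ``surviving`` lists the ``(gene, zygosity)`` of the patient's
    *qualifying* variants that survived measurement — planted causal and
    modifier variants that were emitted and passed QC (rare damaging
    variants are indistinguishable by role once observed).  The expected
    degradation under dropout follows: losing one allele of a compound
    heterozygote leaves a monoallelic finding, losing a homozygote leaves
    the patient unsolved, a surviving het pair split across two genes
    reads as digenic.
    """
    by_gene: dict[str, list[str]] = {}
    for gene, zygosity in surviving:
        by_gene.setdefault(gene, []).append(zygosity)
    for zygosities in by_gene.values():
        if HOM in zygosities or len(zygosities) >= 2:
            return SOLVED_BIALLELIC
    n_het = sum(zs.count(HET) for zs in by_gene.values())
    if n_het == 2 and len(by_gene) == 2:
        return DIGENIC
    if n_het == 1:
        return MONOALLELIC
    return UNSOLVED
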