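"""Rarity filtering, pathogenicity tiering and novelty marking.

The screening algorithm keeps missense, nonsense, frameshift and splice
variants that are rare (<1% allele frequency) in each of three sources —
the 1000 Genomes database, the 5400-exome variant set, and an in-house
control panel of 384 alleles — then tiers them categorically:

* nonsense / frameshift / canonical-splice variants are **pathogenic**;
* rare missense variants are **probable_pathogenic** when either predictor
  calls them damaging (SIFT <= 0.05 or PolyPhen-2 >= 0.5), otherwise
  **uncertain**;
* variants failing the rarity filter are **excluded**.

Prediction scores and population frequencies are *inputs* here (they come
from upstream annotation services); this module only applies the decision
rules.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .hgvs import classify_consequence
from .models import (
    EXCLUDED,
    MISSENSE,
    PATHOGENIC,
    PROBABLE_PATHOGENIC,
    TRUNCATING,
    UNCERTAIN,
    AnnotatedVariant,
    VariantCall,
    make_variant_key,
)

__all__ = [
    "RarityPolicy",
    "MissensePolicy",
    "rarity_filter",
    "tier_pathogenicity",
    "is_damaging",
    "mark_novel",
    "annotate_call",
    "inhouse_frequency",
]


@dataclass(frozen=True)
class RarityPolicy:
    """Maximum allele frequency tolerated in each population source."""

    max_frequency: float = 0.01
    inhouse_alleles: int = 384

    def __post_init__(self) -> None:
        if not 0.0 < self.max_frequency < 1.0:
            raise ValueError("max_frequency must lie in (0, 1)")
        if self.inhouse_alleles < 1:
            raise ValueError("inhouse_alleles must be >= 1")


@dataclass(frozen=True)
class MissensePolicy:
    """Predictor thresholds for calling a missense change damaging.

    The rule is an OR: damaging iff SIFT <= ``sift_damaging_max`` or
    PolyPhen-2 >= ``polyphen_damaging_min``.  A variant with neither score
    available is not damaging.
    """

    sift_damaging_max: float = 0.05
    polyphen_damaging_min: float = 0.5

    def __post_init__(self) -> None:
        for name in ("sift_damaging_max", "polyphen_damaging_min"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def inhouse_frequency(carrier_alleles: int, policy: RarityPolicy = RarityPolicy()) -> float:
    """Allele frequency in the in-house control panel."""
    if carrier_alleles < 0:
        raise ValueError("carrier_alleles must be >= 0")
    return carrier_alleles / policy.inhouse_alleles


def _check_freqs(freqs: Iterable[Optional[float]]) -> list[Optional[float]]:
    out = []
    for f in freqs:
        if f is not None and f < 0:
            raise ValueError(f"negative allele frequency {f}")
        out.append(f)
    return out


def rarity_filter(
    v: "AnnotatedVariant | tuple[Optional[float], Optional[float], Optional[float]]",
    policy: RarityPolicy = RarityPolicy(),
) -> bool:
    """True iff every *known* source frequency is below the cutoff.

    Unknown (None) sources pass: a variant absent from a catalog cannot be
    common in it.  Raising the cutoff never fails a previously passing
    variant (monotonicity).
    """
    if isinstance(v, AnnotatedVariant):
        freqs = (v.freq_1000g, v.freq_exome, v.freq_inhouse)
    else:
        freqs = tuple(v)
    return all(f < policy.max_frequency for f in _check_freqs(freqs) if f is not None)


def is_damaging(
    sift: Optional[float],
    polyphen: Optional[float],
    policy: MissensePolicy = MissensePolicy(),
) -> bool:
    """Apply the OR-rule over the two predictors; absent scores do not vote."""
    if sift is not None and sift <= policy.sift_damaging_max:
        return True
    if polyphen is not None and polyphen >= policy.polyphen_damaging_min:
        return True
    return False


def tier_pathogenicity(
    consequence: str,
    sift: Optional[float] = None,
    polyphen: Optional[float] = None,
    rarity_ok: bool = True,
    policy: MissensePolicy = MissensePolicy(),
) -> str:
    """Categorical pathogenicity tier for an already-classified variant.

    Truncating classes are pathogenic per se; missense needs predictor
    support to rise to probable_pathogenic; everything else is uncertain.
    A variant that failed the rarity filter is excluded regardless of
    consequence — a common variant cannot cause a rare recessive disease.
    Never returns ``pathogenic`` for a missense change.
    """
    if not rarity_ok:
        return EXCLUDED
    if consequence in TRUNCATING:
        return PATHOGENIC
    if consequence == MISSENSE:
        return PROBABLE_PATHOGENIC if is_damaging(sift, polyphen, policy) else UNCERTAIN
    return UNCERTAIN


def mark_novel(gene: str, hgvs_c: str, known_catalog: Iterable[str]) -> bool:
    """True iff the variant is absent from the previously-reported catalog.

    ``known_catalog`` holds canonical variant keys (see
    :func:`usherdx.models.make_variant_key`); an empty catalog marks
    everything novel.
    """
    return make_variant_key(gene, hgvs_c) not in set(known_catalog)


def annotate_call(
    call: VariantCall,
    zygosity: str,
    *,
    freq_1000g: Optional[float] = None,
    freq_exome: Optional[float] = None,
    freq_inhouse: Optional[float] = None,
    sift: Optional[float] = None,
    polyphen: Optional[float] = None,
    known_catalog: Iterable[str] = (),
    rarity: RarityPolicy = RarityPolicy(),
    missense: MissensePolicy = MissensePolicy(),
) -> AnnotatedVariant:
    """Run the full annotation chain on one QC-surviving call."""
    consequence = classify_consequence(call.hgvs_c, call.hgvs_p, call.location)
    rarity_ok = rarity_filter((freq_1000g, freq_exome, freq_inhouse), rarity)
    tier = tier_pathogenicity(consequence, sift, polyphen, rarity_ok, missense)
    return AnnotatedVariant(
        call=call,
        zygosity=zygosity,
        consequence=consequence,
        freq_1000g=freq_1000g,
        freq_exome=freq_exome,
        freq_inhouse=freq_inhouse,
        sift=sift,
        polyphen=polyphen,
        tier=tier,
        novel=mark_novel(call.gene, call.hgvs_c, known_catalog),
    )
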