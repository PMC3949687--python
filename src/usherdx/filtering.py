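"""Variant-call QC filtering and allele-fraction zygosity assignment.

An amplicon-panel caller emits candidate sites with a read depth, a mean
base quality and an alternate-allele fraction.  A call survives iff

* mean base quality >= ``min_mean_base_quality`` (default Phred 25),
* depth >= ``min_depth`` (default 10 reads), and
* the alternate-allele fraction falls in the heterozygous band
  (default 40-60%) or the homozygous band (default 80-100%).

Band bounds are inclusive at both ends.  Fractions between the bands
(e.g. 70%) are rejected outright — on a germline panel they indicate
artifacts rather than mosaicism.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .models import HET, HOM, REJECTED, VariantCall

__all__ = [
    "FilterThresholds",
    "assign_zygosity",
    "apply_qc_filters",
    "rejection_reason",
]


@dataclass(frozen=True)
class FilterThresholds:
    """QC thresholds; defaults match the standard amplicon-panel regime."""

    min_mean_base_quality: float = 25.0
    min_depth: int = 10
    het_band: tuple[float, float] = (0.40, 0.60)
    hom_band: tuple[float, float] = (0.80, 1.00)

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        for name, (lo, hi) in (("het_band", self.het_band), ("hom_band", self.hom_band)):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi <= 1")
        het, hom = self.het_band, self.hom_band
        if not (het[1] < hom[0] or hom[1] < het[0]):
            raise ValueError("het_band and hom_band must not overlap")


def assign_zygosity(alt_fraction: float, thresholds: FilterThresholds = FilterThresholds()) -> str:
    """Assign het / hom / rejected from the alternate-allele fraction.

    The three outcomes partition [0, 1]: the call is *het* iff the fraction
    lies in the (inclusive) heterozygous band, *hom* iff in the homozygous
    band, and *rejected* otherwise.
    """
    if not 0.0 <= alt_fraction <= 1.0:
        raise ValueError(f"alt_fraction must lie in [0, 1], got {alt_fraction}")
    lo, hi = thresholds.het_band
    if lo <= alt_fraction <= hi:
        return HET
    lo, hi = thresholds.hom_band
    if lo <= alt_fraction <= hi:
        return HOM
    return REJECTED


def rejection_reason(
    call: VariantCall, thresholds: FilterThresholds = FilterThresholds()
) -> Optional[str]:
    """First failing QC predicate, or None if the call survives.

    Predicates are evaluated in a fixed order — depth, quality, zygosity
    band — so rejection logs are deterministic and each removed call has
    exactly one primary reason.
    """
    if call.depth < thresholds.min_depth:
        return f"depth {call.depth} < {thresholds.min_depth}"
    if call.mean_base_quality < thresholds.min_mean_base_quality:
        return (
            f"mean_base_quality {call.mean_base_quality:g} < "
            f"{thresholds.min_mean_base_quality:g}"
        )
    if assign_zygosity(call.alt_fraction, thresholds) == REJECTED:
        return f"alt_fraction {call.alt_fraction:g} outside het/hom bands"
    return None


def apply_qc_filters(
    calls: Iterable[VariantCall], thresholds: FilterThresholds = FilterThresholds()
) -> list[tuple[VariantCall, str]]:
    """Filter calls, pairing each survivor with its zygosity.

    Input order is preserved; an empty input yields an empty output.
    Filtering is idempotent: re-filtering the surviving calls removes
    nothing further.
    """
    kept: list[tuple[VariantCall, str]] = []
    for call in calls:
        if rejection_reason(call, thresholds) is None:
            kept.append((call, assign_zygosity(call.alt_fraction, thresholds)))
    return kept
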