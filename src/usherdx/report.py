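"""Cohort-level summaries and the modifier-vs-onset comparison.

The summary reports the quantities a diagnostic-yield study prints:
number of patients carrying at least one mutation (the yield), per-gene
biallelic frequencies, distinct causal variants and how many are novel,
how many were detectable by the sequencing platform itself, and the
digenic / modifier tallies.  Percentages are rendered to one decimal
place with round-half-away-from-zero.

The onset comparison asks whether biallelic patients carrying a
second-gene modifier candidate develop night blindness earlier than
biallelic patients without one.  Two tests are reported side by side:
Welch's unequal-variance t (statistic and Welch–Satterthwaite degrees of
freedom implemented from the formulas, two-sided p from the t
distribution) and an exact permutation test that enumerates every
assignment of the pooled onsets into the two group sizes — the
assumption-free oracle for the small samples involved.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .models import (
    DIGENIC,
    EXCLUDED,
    PATHOGENIC,
    PROBABLE_PATHOGENIC,
    SOLVED_BIALLELIC,
    DiagnosticCall,
    PatientCase,
    UsherdxError,
)

__all__ = [
    "CohortSummary",
    "OnsetComparison",
    "summarize_cohort",
    "compare_onset_by_modifier",
    "welch_t_test",
    "exact_permutation_pvalue",
    "percent",
]

CAUSAL_TIERS = frozenset({PATHOGENIC, PROBABLE_PATHOGENIC})


def percent(numerator: int, denominator: int) -> float:
    """Percentage to one decimal, rounding half away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("empty cohort")
    value = Decimal(numerator * 100) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    n_patients: int
    n_with_any_mutation: int
    yield_percent: float
    per_gene_biallelic_counts: dict[str, int]
    per_gene_biallelic_percent: dict[str, float]
    n_distinct_variants: int
    n_novel: int
    n_detected_by_mps: int
    n_two_pathogenic: int  # patients carrying two pathogenic alleles
    n_digenic: int
    n_modifier_patients: int

    def __post_init__(self) -> None:
        counts = [
            self.n_with_any_mutation,
            self.n_digenic,
            self.n_modifier_patients,
            self.n_two_pathogenic,
        ]
        if any(c < 0 or c > self.n_patients for c in counts):
            raise ValueError("patient counts must lie in [0, n_patients]")

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_with_any_mutation": self.n_with_any_mutation,
            "yield_percent": self.yield_percent,
            "per_gene_biallelic_counts": dict(sorted(self.per_gene_biallelic_counts.items())),
            "per_gene_biallelic_percent": dict(sorted(self.per_gene_biallelic_percent.items())),
            "n_distinct_variants": self.n_distinct_variants,
            "n_novel": self.n_novel,
            "n_detected_by_mps": self.n_detected_by_mps,
            "n_two_pathogenic": self.n_two_pathogenic,
            "n_digenic": self.n_digenic,
            "n_modifier_patients": self.n_modifier_patients,
        }

    def render_text(self) -> str:
        lines = [
            f"Patients screened:                {self.n_patients}",
            f"Patients with >=1 mutation:       {self.n_with_any_mutation} "
            f"({self.yield_percent}%)",
            f"Patients with two pathogenic:     {self.n_two_pathogenic}",
            f"Digenic diagnoses:                {self.n_digenic}",
            f"Patients with modifier candidate: {self.n_modifier_patients}",
            f"Distinct causal variants:         {self.n_distinct_variants} "
            f"({self.n_novel} novel, {self.n_detected_by_mps} MPS-detectable)",
            "Biallelic diagnoses per gene:",
        ]
        for gene in sorted(self.per_gene_biallelic_counts):
            lines.append(
                f"  {gene:<8} {self.per_gene_biallelic_counts[gene]:>2} "
                f"({self.per_gene_biallelic_percent[gene]}%)"
            )
        return "\n".join(lines)


def summarize_cohort(
    calls: Sequence[DiagnosticCall], cases: Sequence[PatientCase]
) -> CohortSummary:
    """Aggregate per-patient diagnoses into the cohort summary.

    Distinct variants are counted by canonical key over the causal
    variants of all diagnostic calls, restricted to the pathogenic /
    probable-pathogenic tiers; the result is stable under patient
    reordering.
    """
    if not calls:
        raise UsherdxError("cannot summarize an empty cohort")
    by_id = {c.patient_id: c for c in cases}
    if set(by_id) != {c.patient_id for c in calls}:
        raise UsherdxError("diagnostic calls and patient cases do not match")

    n_patients = len(calls)
    n_with_any = sum(
        1
        for case in cases
        if any(v.tier != EXCLUDED for v in case.variants)
    )

    causal = {}
    for call in calls:
        for v in call.causal_variants:
            if v.tier in CAUSAL_TIERS:
                causal[v.key] = v
    per_gene_counts: dict[str, int] = {}
    for call in calls:
        if call.category == SOLVED_BIALLELIC:
            for gene in call.primary_genes:
                per_gene_counts[gene] = per_gene_counts.get(gene, 0) + 1

    return CohortSummary(
        n_patients=n_patients,
        n_with_any_mutation=n_with_any,
        yield_percent=percent(n_with_any, n_patients),
        per_gene_biallelic_counts=per_gene_counts,
        per_gene_biallelic_percent={
            g: percent(n, n_patients) for g, n in per_gene_counts.items()
        },
        n_distinct_variants=len(causal),
        n_novel=sum(1 for v in causal.values() if v.novel),
        n_detected_by_mps=sum(
            1 for v in causal.values() if not v.call.detectability_flags
        ),
        n_two_pathogenic=sum(
            1
            for call in calls
            if call.category in (SOLVED_BIALLELIC, DIGENIC)
            and call.n_causal_alleles == 2
        ),
        n_digenic=sum(1 for call in calls if call.category == DIGENIC),
        n_modifier_patients=sum(1 for call in calls if call.modifier_candidates),
    )


# ---------------------------------------------------------------------------
# onset comparison
# ---------------------------------------------------------------------------


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t test, from the formulas.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of freedom

        df = (va/na + vb/nb)^2 / [ (va/na)^2/(na-1) + (vb/nb)^2/(nb-1) ]

    and the two-sided p from the t distribution.
    """
    x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    na, nb = len(x), len(y)
    if na < 2 or nb < 2:
        raise ValueError("Welch's t requires at least two observations per group")
    va, vb = x.var(ddof=1), y.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        raise ValueError("both groups are constant; t statistic undefined")
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


def exact_permutation_pvalue(a: Sequence[float], b: Sequence[float]) -> tuple[float, int]:
    """Exact two-sided permutation p for the difference of group means.

    Enumerates all C(na+nb, na) assignments of the pooled values to a
    group of size ``len(a)``; p is the fraction of assignments whose
    absolute mean difference is at least the observed one.  The observed
    assignment is always counted, so p >= 1 / C(na+nb, na), and the
    result is invariant to which group is labelled first.
    """
    pool = list(a) + list(b)
    na, n = len(a), len(a) + len(b)
    if na == 0 or na == n:
        raise ValueError("both groups must be non-empty")
    total_sum = sum(pool)
    observed = abs(sum(a) / na - (total_sum - sum(a)) / (n - na))
    count = 0
    n_assignments = math.comb(n, na)
    for idx in combinations(range(n), na):
        sa = sum(pool[i] for i in idx)
        diff = abs(sa / na - (total_sum - sa) / (n - na))
        if diff >= observed - 1e-12:
            count += 1
    return count / n_assignments, n_assignments


@dataclass
class OnsetComparison:
    modifier_onsets: list[float]
    comparison_onsets: list[float]
    t_statistic: Optional[float]
    welch_df: Optional[float]
    p_welch: Optional[float]
    p_permutation: float
    n_assignments: int

    def to_dict(self) -> dict:
        return {
            "modifier_onsets": self.modifier_onsets,
            "comparison_onsets": self.comparison_onsets,
            "t_statistic": self.t_statistic,
            "welch_df": self.welch_df,
            "p_welch": self.p_welch,
            "p_permutation": self.p_permutation,
            "n_assignments": self.n_assignments,
        }


def compare_onset_by_modifier(
    cases: Sequence[PatientCase],
    calls: Sequence[DiagnosticCall],
    include_digenic: bool = False,
) -> OnsetComparison:
    """Compare night-blindness onset between modifier carriers and others.

    The modifier group holds biallelic-solved patients carrying at least
    one modifier candidate; the comparison group holds biallelic-solved
    patients without one (optionally also the digenic patient).  Patients
    with unknown onset are excluded — onset is undefined for them.  The
    Welch path needs two observations per group and is reported as None
    below that; the permutation test always runs.
    """
    onset = {c.patient_id: c.onset_night_blindness for c in cases}
    modifier_group: list[float] = []
    comparison_group: list[float] = []
    for call in calls:
        age = onset.get(call.patient_id)
        if age is None:
            continue
        if call.category == SOLVED_BIALLELIC and call.modifier_candidates:
            modifier_group.append(float(age))
        elif call.category == SOLVED_BIALLELIC or (
            include_digenic and call.category == DIGENIC
        ):
            comparison_group.append(float(age))
    if not modifier_group or not comparison_group:
        raise UsherdxError("both onset groups must be non-empty")

    try:
        t, df, p_welch = welch_t_test(modifier_group, comparison_group)
    except ValueError:
        t = df = p_welch = None
    p_perm, n_assignments = exact_permutation_pvalue(modifier_group, comparison_group)
    return OnsetComparison(
        modifier_onsets=modifier_group,
        comparison_onsets=comparison_group,
        t_statistic=t,
        welch_df=df,
        p_welch=p_welch,
        p_permutation=p_perm,
        n_assignments=n_assignments,
    )
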