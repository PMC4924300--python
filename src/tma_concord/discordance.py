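"""Core-to-core discordance, the intratumoral-heterogeneity taxonomy, and the review queue.

A case is discordant when any two of its cores differ in status on the primary
scale (ER/PR dichotomous at 1 %; HER2 three-category). Manual review of
discordant cases is restricted to those where heterogeneity would be clinically
meaningful: ER/PR discordant cases with positive case-level status (discordance
in case-negative tumors reflects random variation around the 1 % threshold),
and HER2 discordant cases with at least one 3+ core (mixtures of 0/1+ and 2+
cores stay within the HER2-negative clinical bin).

Review-eligible cases are categorised by the composition of their core
statuses. ER/PR: cases whose cores span negative (<1 %) and borderline
(>=1 to <10 %) levels only, versus cases with both negative and positive
(>=10 %) cores. HER2: 2+&3+ mixtures, 0/1+&3+ mixtures, and cases carrying all
three categories; the strict definition of HER2 heterogeneity counts only
cases with both a negative (0/1+) and a positive (3+) core.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from tma_concord.classify import (
    CaseClassification,
    ERPR_POSITIVE,
    HER2_EQUIVOCAL2,
    HER2_NEG01,
    HER2_POSITIVE3,
    TRI_BORDERLINE,
    TRI_NEGATIVE,
    TRI_POSITIVE,
)
from tma_concord.datamodel import Marker


class HeterogeneityCategory(str, Enum):
    """Core-status composition of a review-eligible discordant case."""

    NEG_AND_BORDERLINE_ONLY = "neg_and_borderline_only"  # ER/PR: no >=10 % core
    NEG_AND_POSITIVE = "neg_and_positive"  # ER/PR: both <1 % and >=10 % cores
    EQUIV_AND_POS = "equiv_and_pos"  # HER2: 2+ and 3+ cores only
    NEG_AND_POS = "neg_and_pos"  # HER2: 0/1+ and 3+ cores only
    NEG_EQUIV_POS = "neg_equiv_pos"  # HER2: all three categories


@dataclass(frozen=True)
class HeterogeneityCall:
    case_id: str
    marker: Marker
    category: HeterogeneityCategory
    strict_flag: bool  # HER2 only: case contains both 0/1+ and 3+ cores


def detect_discordance(case: CaseClassification, scale: str = "primary") -> bool:
    """True iff any two cores differ in status on the requested scale.

    ``scale="primary"`` uses the dichotomous 1 % rule for ER/PR and the HER2
    three-category rule; ``scale="alternative_10pct"`` dichotomises ER/PR at
    the 10 % exploratory threshold (HER2 is unchanged).
    """
    if case.n_cores < 2:
        raise ValueError("discordance requires at least two cores")
    if scale == "primary":
        labels = {s.primary_label for s in case.core_statuses}
    elif scale == "alternative_10pct":
        if case.marker == Marker.HER2:
            labels = {s.her2_cat for s in case.core_statuses}
        else:
            labels = {s.erpr_tri == TRI_POSITIVE for s in case.core_statuses}
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return len(labels) > 1


def is_review_eligible(case: CaseClassification) -> bool:
    """Whether a case qualifies for manual heterogeneity review."""
    if not case.discordant:
        return False
    if case.marker == Marker.HER2:
        return case.has_positive3_core
    return case.case_status == ERPR_POSITIVE


def build_review_queue(cases: list[CaseClassification]) -> list[CaseClassification]:
    """Review-eligible subset, sorted ascending by case-level expression.

    ER/PR discordant cases enter only when the collapsed case status is
    positive; HER2 discordant cases only when at least one core is 3+. Sorting
    (expression, then case_id for ties) matches the ordering used to plot
    per-case core expression profiles.
    """
    queue = [c for c in cases if is_review_eligible(c)]
    queue.sort(key=lambda c: (c.weighted_expression, c.case_id))
    return queue


def classify_heterogeneity(case: CaseClassification) -> HeterogeneityCall:
    """Assign the composition category for a review-eligible discordant case."""
    if not is_review_eligible(case):
        raise ValueError(
            f"case {case.case_id} ({case.marker.value}) is not review-eligible"
        )
    if case.marker == Marker.HER2:
        present = {s.her2_cat for s in case.core_statuses}
        has_neg, has_eq, has_pos = (
            HER2_NEG01 in present,
            HER2_EQUIVOCAL2 in present,
            HER2_POSITIVE3 in present,
        )
        if not has_pos:  # unreachable for review-eligible cases
            raise ValueError("HER2 heterogeneity requires a 3+ core")
        if has_neg and has_eq:
            category = HeterogeneityCategory.NEG_EQUIV_POS
        elif has_neg:
            category = HeterogeneityCategory.NEG_AND_POS
        elif has_eq:
            category = HeterogeneityCategory.EQUIV_AND_POS
        else:
            raise ValueError(
                f"case {case.case_id}: all cores 3+ cannot be discordant"
            )
        return HeterogeneityCall(case.case_id, case.marker, category, strict_flag=has_neg)

    tri = {s.erpr_tri for s in case.core_statuses}
    if TRI_NEGATIVE not in tri:
        # Discordance on the <1/>=1 scale forces at least one core below 1 %.
        raise ValueError(
            f"case {case.case_id}: ER/PR discordant composition lacks a negative core"
        )
    if TRI_POSITIVE in tri:
        category = HeterogeneityCategory.NEG_AND_POSITIVE
    elif TRI_BORDERLINE in tri:
        category = HeterogeneityCategory.NEG_AND_BORDERLINE_ONLY
    else:
        raise ValueError(f"case {case.case_id}: all cores negative cannot be discordant")
    return HeterogeneityCall(case.case_id, case.marker, category, strict_flag=False)


def summarize_heterogeneity(
    calls: list[HeterogeneityCall],
    cases: list[CaseClassification],
) -> pd.DataFrame:
    """Frequency table of confirmed heterogeneity with the three denominators.

    ``calls`` are the confirmed-heterogeneous cases (manual review on real
    data; the latent truth flag in simulation). Frequencies are reported
    against the review-eligible cases, against all biomarker-positive cases
    (HER2: all cases with at least one 3+ core), and against all cases.
    """
    rows = []
    for marker in Marker:
        mcases = [c for c in cases if c.marker == marker]
        if not mcases:
            continue
        mcalls = [h for h in calls if h.marker == marker]
        n_all = len(mcases)
        n_reviewed = sum(1 for c in mcases if is_review_eligible(c))
        if marker == Marker.HER2:
            n_positive = sum(1 for c in mcases if c.has_positive3_core)
        else:
            n_positive = sum(1 for c in mcases if c.case_status == ERPR_POSITIVE)
        n_conf = len(mcalls)
        n_strict = sum(1 for h in mcalls if h.strict_flag)
        by_cat = {
            cat.value: sum(1 for h in mcalls if h.category == cat)
            for cat in HeterogeneityCategory
            if any(h.category == cat for h in mcalls)
        }
        rows.append(
            {
                "marker": marker.value,
                "n_cases": n_all,
                "n_discordant": sum(1 for c in mcases if c.discordant),
                "n_review_eligible": n_reviewed,
                "n_positive": n_positive,
                "n_confirmed": n_conf,
                "n_confirmed_strict": n_strict if marker == Marker.HER2 else None,
                "pct_of_reviewed": 100.0 * n_conf / n_reviewed if n_reviewed else 0.0,
                "pct_of_positive": 100.0 * n_conf / n_positive if n_positive else 0.0,
                "pct_of_all": 100.0 * n_conf / n_all if n_all else 0.0,
                "pct_strict_of_positive": (
                    100.0 * n_strict / n_positive if n_positive else 0.0
                )
                if marker == Marker.HER2
                else None,
                "categories": by_cat,
            }
        )
    return pd.DataFrame(rows)


def cross_marker_cooccurrence(calls: list[HeterogeneityCall]) -> pd.DataFrame:
    """Counts of cases with confirmed heterogeneity in each pair of markers."""
    by_case: dict[str, set[str]] = {}
    for h in calls:
        by_case.setdefault(h.case_id, set()).add(h.marker.value)
    pairs = [("ER", "PR"), ("ER", "HER2"), ("PR", "HER2")]
    rows = [
        {
            "markers": f"{a}+{b}",
            "n_cases": sum(1 for s in by_case.values() if a in s and b in s),
        }
        for a, b in pairs
    ]
    return pd.DataFrame(rows)
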