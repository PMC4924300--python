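"""Core-level status calls and cellularity-weighted core-to-case collapsing.

Clinical thresholds: ER/PR are positive at >=1 % stained tumor nuclei (with a
borderline band >=1 to <10 % distinguished for the heterogeneity taxonomy and
an exploratory 10 % dichotomy). HER2 is positive (3+) when >=10 % of tumor
cells stain at 3+ intensity, equivocal (2+) when the 3+ fraction is <10 % but
the 2+ fraction is >=10 %, and negative (0/1+) otherwise.

Case-level status is assigned from the cellularity-weighted average: core
weight w_i = n_i / sum_j n_j (n_i = tumor nuclei in core i), and the weighted
expression sum_i w_i p_i is thresholded with the same clinical rules. For HER2
the 3+ and 2+ intensity fractions are each weighted-averaged and the
three-category rule is applied to the weighted fractions.

All threshold comparisons are closed on the positive side (>=); percentages are
kept in floating point with no rounding before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tma_concord.datamodel import CoreMeasurement, Marker

ERPR_NEGATIVE = "negative"
ERPR_POSITIVE = "positive"
TRI_NEGATIVE = "negative"
TRI_BORDERLINE = "borderline"
TRI_POSITIVE = "positive"
HER2_NEG01 = "0/1+"
HER2_EQUIVOCAL2 = "2+"
HER2_POSITIVE3 = "3+"

#: Map HER2 intensity categories onto the clinical-record vocabulary.
HER2_TO_CLINICAL = {
    HER2_NEG01: "negative",
    HER2_EQUIVOCAL2: "equivocal",
    HER2_POSITIVE3: "positive",
}


@dataclass(frozen=True)
class ThresholdConfig:
    """Clinical classification thresholds (percent of tumor cells).

    erpr_positive_cutoff
        ER/PR positivity threshold; cores/cases at or above are positive.
    erpr_high_cutoff
        Lower edge of the "positive" band of the ER/PR tri-status
        (negative < positive_cutoff <= borderline < high_cutoff <= positive).
    her2_cat_cutoff
        Intensity-fraction threshold for the HER2 three-category rule.
    erpr_alternative_cutoff
        Exploratory alternative ER/PR dichotomy (default 10 %).
    """

    erpr_positive_cutoff: float = 1.0
    erpr_high_cutoff: float = 10.0
    her2_cat_cutoff: float = 10.0
    erpr_alternative_cutoff: float = 10.0

    def __post_init__(self):
        if not 0.0 < self.erpr_positive_cutoff <= self.erpr_high_cutoff <= 100.0:
            raise ValueError(
                "require 0 < erpr_positive_cutoff <= erpr_high_cutoff <= 100, got "
                f"{self.erpr_positive_cutoff}, {self.erpr_high_cutoff}"
            )
        if not 0.0 < self.her2_cat_cutoff <= 100.0:
            raise ValueError(f"her2_cat_cutoff {self.her2_cat_cutoff} outside (0, 100]")
        if not 0.0 < self.erpr_alternative_cutoff <= 100.0:
            raise ValueError(
                f"erpr_alternative_cutoff {self.erpr_alternative_cutoff} outside (0, 100]"
            )


@dataclass(frozen=True)
class CoreStatus:
    """Status calls for one core. ER/PR cores fill the erpr fields, HER2 cores her2_cat."""

    marker: Marker
    erpr_binary: str | None = None
    erpr_tri: str | None = None
    her2_cat: str | None = None

    @property
    def primary_label(self) -> str:
        """Label on the primary discordance scale (ER/PR binary; HER2 3-category)."""
        return self.her2_cat if self.marker == Marker.HER2 else self.erpr_binary


def _erpr_status(percent: float, cfg: ThresholdConfig) -> tuple[str, str]:
    if percent >= cfg.erpr_high_cutoff:
        tri = TRI_POSITIVE
    elif percent >= cfg.erpr_positive_cutoff:
        tri = TRI_BORDERLINE
    else:
        tri = TRI_NEGATIVE
    binary = ERPR_NEGATIVE if tri == TRI_NEGATIVE else ERPR_POSITIVE
    return binary, tri


def _her2_status(pct_3: float, pct_2: float, cfg: ThresholdConfig) -> str:
    if pct_3 >= cfg.her2_cat_cutoff:
        return HER2_POSITIVE3
    if pct_2 >= cfg.her2_cat_cutoff:
        return HER2_EQUIVOCAL2
    return HER2_NEG01


def classify_core(core: CoreMeasurement, cfg: ThresholdConfig | None = None) -> CoreStatus:
    """Assign core-level biomarker status with the clinical thresholds."""
    cfg = cfg or ThresholdConfig()
    if core.marker in (Marker.ER, Marker.PR):
        if core.percent_positive is None:
            raise ValueError(f"ER/PR core {core.core_id} lacks percent_positive")
        binary, tri = _erpr_status(core.percent_positive, cfg)
        return CoreStatus(marker=core.marker, erpr_binary=binary, erpr_tri=tri)
    if core.pct_3 is None or core.pct_2 is None:
        raise ValueError(f"HER2 core {core.core_id} lacks intensity fractions")
    return CoreStatus(marker=core.marker, her2_cat=_her2_status(core.pct_3, core.pct_2, cfg))


def core_weights(cores: list[CoreMeasurement]) -> np.ndarray:
    """Cellularity weights w_i = n_i / sum_j n_j over one case's cores for one marker."""
    if len(cores) < 2:
        raise ValueError("core weights require at least two cores")
    n = np.array([c.tumor_nuclei for c in cores], dtype=float)
    if np.any(n < 0) or n.sum() <= 0:
        raise ValueError("tumor nuclei counts must be nonnegative with positive total")
    return n / n.sum()


@dataclass(frozen=True)
class CaseClassification:
    """Collapsed case-level classification with per-core detail.

    ``weighted_expression`` is the cellularity-weighted percent positivity for
    ER/PR; for HER2, ``weighted_intensity`` maps each intensity category to its
    weighted fraction and ``weighted_expression`` carries the weighted 3+
    fraction (the case-level expression axis used for review-queue ordering).
    """

    case_id: str
    marker: Marker
    n_cores: int
    core_weights: tuple[float, ...]
    weighted_expression: float
    case_status: str
    core_statuses: tuple[CoreStatus, ...]
    discordant: bool
    total_nuclei: int
    weighted_intensity: dict[str, float] | None = None
    core_expressions: tuple[float, ...] = field(default=())

    @property
    def has_positive3_core(self) -> bool:
        return self.marker == Marker.HER2 and any(
            s.her2_cat == HER2_POSITIVE3 for s in self.core_statuses
        )


def collapse_case(
    cores: list[CoreMeasurement], cfg: ThresholdConfig | None = None
) -> CaseClassification:
    """Collapse one case's cores (single marker) to a case-level classification.

    The weighted average of percent positivity is the sum over cores of
    percent positivity times core weight; the clinical threshold rule is then
    applied to the weighted value. Discordance is flagged on the primary scale
    (ER/PR dichotomous at 1 %; HER2 three-category).
    """
    cfg = cfg or ThresholdConfig()
    markers = {c.marker for c in cores}
    if len(markers) != 1:
        raise ValueError(f"collapse_case requires a single marker, got {markers}")
    marker = markers.pop()
    case_ids = {c.case_id for c in cores}
    if len(case_ids) != 1:
        raise ValueError(f"collapse_case requires a single case, got {case_ids}")
    w = core_weights(cores)
    statuses = tuple(classify_core(c, cfg) for c in cores)
    labels = [s.primary_label for s in statuses]
    discordant = len(set(labels)) > 1

    if marker in (Marker.ER, Marker.PR):
        p = np.array([c.percent_positive for c in cores], dtype=float)
        weighted = float(np.dot(p, w))
        case_status, _ = _erpr_status(weighted, cfg)
        weighted_intensity = None
        core_expr = tuple(float(x) for x in p)
    else:
        p3 = np.array([c.pct_3 for c in cores], dtype=float)
        p2 = np.array([c.pct_2 for c in cores], dtype=float)
        p01 = np.array([c.pct_01 for c in cores], dtype=float)
        w3, w2, w01 = float(np.dot(p3, w)), float(np.dot(p2, w)), float(np.dot(p01, w))
        case_status = _her2_status(w3, w2, cfg)
        weighted = w3
        weighted_intensity = {HER2_NEG01: w01, HER2_EQUIVOCAL2: w2, HER2_POSITIVE3: w3}
        core_expr = tuple(float(x) for x in p3)

    if not discordant:
        # A convex combination preserves every category's threshold conditions,
        # so concordant cores fix the case status; assigning it directly avoids
        # floating-point flips when all cores sit exactly on a cutoff.
        case_status = labels[0]

    return CaseClassification(
        case_id=case_ids and cores[0].case_id,
        marker=marker,
        n_cores=len(cores),
        core_weights=tuple(float(x) for x in w),
        weighted_expression=weighted,
        case_status=case_status,
        core_statuses=statuses,
        discordant=discordant,
        total_nuclei=int(sum(c.tumor_nuclei for c in cores)),
        weighted_intensity=weighted_intensity,
        core_expressions=core_expr,
    )


def classify_cases(
    analysis_set: dict[Marker, dict[str, list[CoreMeasurement]]],
    cfg: ThresholdConfig | None = None,
) -> dict[Marker, list[CaseClassification]]:
    """Collapse every case in an analysis set, per marker."""
    cfg = cfg or ThresholdConfig()
    out: dict[Marker, list[CaseClassification]] = {}
    for marker, cases in analysis_set.items():
        out[marker] = [
            collapse_case(case_cores, cfg)
            for _, case_cores in sorted(cases.items())
        ]
    return out


def case_status_clinical_scale(case: CaseClassification) -> str:
    """Case status in the clinical-record vocabulary (HER2 categories renamed)."""
    if case.marker == Marker.HER2:
        return HER2_TO_CLINICAL[case.case_status]
    return case.case_status
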