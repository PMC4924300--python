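"""Central-vs-clinical agreement: contingency tables, Cohen's kappa, stratified analysis.

Agreement between the TMA (central) classification and the clinical record is
summarised with percent agreement (100·trace/n) and Cohen's kappa,

    kappa = (po - pe) / (1 - pe),

where po is observed agreement and pe = sum_i p_i. p_.i the chance-expected
agreement from the row and column margins. The 95 % CI uses the asymptotic
large-sample variance of Fleiss, Cohen & Everitt (1969), truncated to [-1, 1].
Analyses are run overall and stratified by core-to-core concordant/discordant
status; the two stratum tables partition the all-cases table cellwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tma_concord.classify import CaseClassification, case_status_clinical_scale
from tma_concord.datamodel import ClinicalRecord, ERPR_LABELS, HER2_LABELS, Marker


class JoinError(KeyError):
    """Central cases without a matching clinical record."""


@dataclass(frozen=True)
class ContingencyTable:
    """k×k cross-tabulation; rows are the central (TMA) call, columns the clinical record."""

    labels: tuple[str, ...]
    counts: np.ndarray  # shape (k, k), nonnegative integers

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError(f"counts must be square, got shape {counts.shape}")
        if counts.shape[0] != len(self.labels):
            raise ValueError("labels length must match table dimension")
        if counts.shape[0] not in (2, 3):
            raise ValueError("expected a 2x2 or 3x3 table")
        if (counts < 0).any():
            raise ValueError("cell counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"central_{l}" for l in self.labels],
            columns=[f"clinical_{l}" for l in self.labels],
        )


@dataclass(frozen=True)
class AgreementResult:
    """Percent agreement and Cohen's kappa with 95 % CI for one (sub)cohort.

    ``kappa`` is NaN (``undefined=True``) when chance agreement pe = 1, i.e.
    all mass sits in a single row and column, or when the table is empty.
    """

    table: ContingencyTable
    stratum: str
    po: float
    pe: float
    percent_agreement: float
    kappa: float
    kappa_se: float
    kappa_ci: tuple[float, float]
    undefined: bool = False

    def summary(self) -> str:
        if self.undefined:
            return f"[{self.stratum}] n={self.table.n}: kappa undefined"
        lo, hi = self.kappa_ci
        return (
            f"[{self.stratum}] n={self.table.n}: agreement "
            f"{self.percent_agreement:.0f} %, kappa {self.kappa:.2f} "
            f"({lo:.2f}-{hi:.2f})"
        )


def marker_labels(marker: Marker) -> tuple[str, ...]:
    return tuple(HER2_LABELS if Marker(marker) == Marker.HER2 else ERPR_LABELS)


def build_table(
    central: list[CaseClassification],
    clinical: list[ClinicalRecord],
    marker: Marker,
) -> ContingencyTable:
    """Cross-tabulate central case status against the clinical record.

    HER2 uses the shared three-category vocabulary (0/1+ -> negative,
    2+ -> equivocal, 3+ -> positive); ER/PR are 2x2.
    """
    marker = Marker(marker)
    labels = marker_labels(marker)
    clin = {r.case_id: r for r in clinical}
    missing = [c.case_id for c in central if c.case_id not in clin]
    if missing:
        raise JoinError(
            f"no clinical record for case(s): {', '.join(sorted(missing)[:10])}"
            + ("..." if len(missing) > 10 else "")
        )
    idx = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for case in central:
        if case.marker != marker:
            raise ValueError(f"case {case.case_id} is {case.marker.value}, not {marker.value}")
        counts[idx[case_status_clinical_scale(case)], idx[clin[case.case_id].status(marker)]] += 1
    return ContingencyTable(labels=labels, counts=counts)


def _kappa_variance(p: np.ndarray, po: float, pe: float, n: int) -> float:
    """Fleiss–Cohen–Everitt asymptotic variance of kappa (cell proportions p)."""
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    k = p.shape[0]
    a = sum(
        p[i, i] * ((1 - pe) - (row[i] + col[i]) * (1 - po)) ** 2 for i in range(k)
    )
    b = (1 - po) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(k)
        for j in range(k)
        if i != j
    )
    c = (po * pe - 2 * pe + po) ** 2
    return (a + b - c) / (n * (1 - pe) ** 4)


def cohens_kappa(table: ContingencyTable, stratum: str = "all") -> AgreementResult:
    """Percent agreement and Cohen's kappa with asymptotic 95 % CI.

    po = trace/n; pe = sum_i row_i·col_i / n^2; kappa = (po-pe)/(1-pe). The CI
    is kappa ± 1.96·SE with the Fleiss–Cohen–Everitt large-sample SE,
    truncated to [-1, 1]. Degenerate tables (n = 0 or pe = 1) are flagged
    undefined rather than raising.
    """
    n = table.n
    if n == 0:
        return AgreementResult(
            table, stratum, math.nan, math.nan, math.nan, math.nan, math.nan,
            (math.nan, math.nan), undefined=True,
        )
    p = table.counts / n
    po = float(np.trace(p))
    pe = float(p.sum(axis=1) @ p.sum(axis=0))
    pct = 100.0 * po
    if pe >= 1.0 - 1e-12:
        return AgreementResult(
            table, stratum, po, pe, pct, math.nan, math.nan,
            (math.nan, math.nan), undefined=True,
        )
    kappa = (po - pe) / (1 - pe)
    se = math.sqrt(max(_kappa_variance(p, po, pe, n), 0.0))
    z = stats.norm.ppf(0.975)
    ci = (max(kappa - z * se, -1.0), min(kappa + z * se, 1.0))
    return AgreementResult(table, stratum, po, pe, pct, kappa, se, ci)


def stratified_agreement(
    central: list[CaseClassification],
    clinical: list[ClinicalRecord],
    marker: Marker,
) -> dict[str, AgreementResult]:
    """Agreement overall and within the concordant/discordant core-status strata.

    The concordant and discordant stratum tables sum cellwise to the all-cases
    table by construction.
    """
    marker = Marker(marker)
    cases = [c for c in central if c.marker == marker]
    strata = {
        "all": cases,
        "concordant": [c for c in cases if not c.discordant],
        "discordant": [c for c in cases if c.discordant],
    }
    return {
        name: cohens_kappa(
            build_table(sub, clinical, marker)
            if sub
            else ContingencyTable(
                labels=marker_labels(marker),
                counts=np.zeros((len(marker_labels(marker)),) * 2, dtype=int),
            ),
            stratum=name,
        )
        for name, sub in strata.items()
    }


@dataclass(frozen=True)
class RankSumResult:
    """Two-sided Wilcoxon–Mann–Whitney comparison of group cellularity."""

    statistic: float
    p_value: float
    method: str  # "exact" or "asymptotic"
    median_concordant: float
    iqr_concordant: tuple[float, float]
    median_discordant: float
    iqr_discordant: tuple[float, float]
    n_concordant: int
    n_discordant: int


def _median_iqr(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    return float(np.median(x)), (
        float(np.percentile(x, 25)),
        float(np.percentile(x, 75)),
    )


def cellularity_comparison(
    concordant: np.ndarray | list[float],
    discordant: np.ndarray | list[float],
    exact_max_n: int = 7,
) -> RankSumResult:
    """Compare case-level tumor cellularity between concordance strata.

    Uses the exact Mann–Whitney null distribution when both groups have at
    most ``exact_max_n`` observations and no ties, otherwise the normal
    approximation with continuity and tie correction.
    """
    x = np.asarray(concordant, dtype=float)
    y = np.asarray(discordant, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both concordance strata must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = len(x) <= exact_max_n and len(y) <= exact_max_n and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    med_x, iqr_x = _median_iqr(x)
    med_y, iqr_y = _median_iqr(y)
    return RankSumResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="exact" if exact else "asymptotic",
        median_concordant=med_x,
        iqr_concordant=iqr_x,
        median_discordant=med_y,
        iqr_discordant=iqr_y,
        n_concordant=len(x),
        n_discordant=len(y),
    )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame  # rows: core number; columns: concordant, discordant


def core_number_association(
    table: pd.DataFrame | np.ndarray | None = None,
    *,
    core_numbers: list[int] | None = None,
    discordant: list[bool] | None = None,
) -> ChiSquareResult:
    """Pearson chi-square for discordance rate across 2/3/4-core cases (df = k-1).

    Either pass a prebuilt (core-number × {concordant, discordant}) count
    table, or per-case ``core_numbers`` and ``discordant`` flags. Rows with a
    zero margin are dropped with a warning. No continuity correction.
    """
    if table is None:
        if core_numbers is None or discordant is None:
            raise ValueError("provide a table or core_numbers with discordant flags")
        df = pd.DataFrame({"k": core_numbers, "disc": discordant})
        table = (
            df.groupby("k")["disc"]
            .agg(concordant=lambda s: int((~s).sum()), discordant="sum")
            .astype(int)
        )
    if isinstance(table, np.ndarray):
        table = pd.DataFrame(
            table, index=range(2, 2 + len(table)), columns=["concordant", "discordant"]
        )
    table = table.astype(int)
    keep = table.sum(axis=1) > 0
    if not keep.all():
        warnings.warn(
            f"dropping zero-margin core-number rows: {list(table.index[~keep])}",
            stacklevel=2,
        )
        table = table.loc[keep]
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return ChiSquareResult(statistic=float(chi2), df=int(dof), p_value=float(p), table=table)
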