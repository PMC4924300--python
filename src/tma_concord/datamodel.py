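"""Domain types, validation, and delimited-text I/O for TMA core and clinical tables.

The unit of automated scoring is a 1.0-mm TMA core. ER and PR are nuclear markers
scored as percent of positively staining tumor nuclei; HER2 is a membrane marker
scored as the percent of tumor cells at each staining intensity (0/1+ pooled, 2+,
3+; the intensity-0 remainder is implicit). Each core also carries its tumor-nuclei
count (cellularity), which later serves as the core weight in case-level collapsing.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Minimum tumor cellularity for a core to be evaluable.
MIN_TUMOR_NUCLEI = 50

CORE_COLUMNS = [
    "case_id",
    "core_id",
    "block_id",
    "marker",
    "percent_positive",
    "pct_01",
    "pct_2",
    "pct_3",
    "tumor_nuclei",
]
REQUIRED_CORE_COLUMNS = [c for c in CORE_COLUMNS if c != "block_id"]
CLINICAL_COLUMNS = ["case_id", "er_status", "pr_status", "her2_status"]


class Marker(str, Enum):
    """Immunohistochemistry biomarker."""

    ER = "ER"
    PR = "PR"
    HER2 = "HER2"


ERPR_LABELS = ["negative", "positive"]
HER2_LABELS = ["negative", "equivocal", "positive"]


class TableFormatError(ValueError):
    """Input table is structurally malformed (missing columns, unreadable)."""


class TableValidationError(ValueError):
    """One or more rows violate field invariants; message lists row numbers."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid rows:\n" + "\n".join(self.problems)
        )


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or x == ""


@dataclass(frozen=True)
class CoreMeasurement:
    """One core's automated readout for one marker.

    ER/PR cores carry ``percent_positive`` (and no intensity fractions); HER2
    cores carry ``pct_01``/``pct_2``/``pct_3`` intensity-category percentages
    summing to at most 100 (remainder is intensity 0 within the pooled 0/1+
    convention) and no ``percent_positive``.
    """

    case_id: str
    core_id: str
    marker: Marker
    percent_positive: float | None = None
    pct_01: float | None = None
    pct_2: float | None = None
    pct_3: float | None = None
    tumor_nuclei: int = 0
    block_id: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "marker", Marker(self.marker))
        problems = self.validate()
        if problems:
            raise TableValidationError(problems)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        p: list[str] = []
        tag = f"case={self.case_id} core={self.core_id} marker={self.marker.value}"
        if self.tumor_nuclei < 0:
            p.append(f"{tag}: tumor_nuclei {self.tumor_nuclei} is negative")
        if self.marker in (Marker.ER, Marker.PR):
            if _is_missing(self.percent_positive):
                p.append(f"{tag}: ER/PR row missing percent_positive")
            elif not 0.0 <= self.percent_positive <= 100.0:
                p.append(
                    f"{tag}: percent_positive {self.percent_positive} outside [0, 100]"
                )
            for name in ("pct_01", "pct_2", "pct_3"):
                if not _is_missing(getattr(self, name)):
                    p.append(f"{tag}: ER/PR row carries HER2 intensity field {name}")
        else:
            if not _is_missing(self.percent_positive):
                p.append(f"{tag}: HER2 row carries percent_positive")
            total = 0.0
            for name in ("pct_01", "pct_2", "pct_3"):
                v = getattr(self, name)
                if _is_missing(v):
                    p.append(f"{tag}: HER2 row missing {name}")
                elif not 0.0 <= v <= 100.0:
                    p.append(f"{tag}: {name} {v} outside [0, 100]")
                else:
                    total += v
            if not p and total > 100.0 + 1e-9:
                p.append(f"{tag}: HER2 intensity fractions sum to {total} > 100")
        return p

    @property
    def evaluable(self) -> bool:
        """Whether the core meets the minimum-cellularity requirement."""
        return self.tumor_nuclei >= MIN_TUMOR_NUCLEI


@dataclass(frozen=True)
class ClinicalRecord:
    """Case-level biomarker status abstracted from the medical record."""

    case_id: str
    er: str
    pr: str
    her2: str

    def __post_init__(self):
        problems = []
        for name, value, allowed in (
            ("er", self.er, ERPR_LABELS),
            ("pr", self.pr, ERPR_LABELS),
            ("her2", self.her2, HER2_LABELS),
        ):
            if value not in allowed:
                problems.append(
                    f"case={self.case_id}: clinical {name} status {value!r} "
                    f"not in {allowed}"
                )
        if problems:
            raise TableValidationError(problems)

    def status(self, marker: Marker) -> str:
        return {Marker.ER: self.er, Marker.PR: self.pr, Marker.HER2: self.her2}[
            Marker(marker)
        ]


def _read_delimited(path, delimiter: str, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=delimiter, dtype={"case_id": str, "core_id": str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TableFormatError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    return df


def read_core_table(path, delimiter: str = ",") -> list[CoreMeasurement]:
    """Read and validate a core-level measurement table.

    Rows violating type invariants are collected and reported together with
    their (1-based, header excluded) row numbers in a :class:`TableValidationError`.
    """
    df = _read_delimited(path, delimiter, REQUIRED_CORE_COLUMNS)
    records: list[CoreMeasurement] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        try:
            marker = Marker(d["marker"])
        except ValueError:
            problems.append(f"row {i}: unknown marker {d['marker']!r}")
            continue
        try:
            nuclei = int(d["tumor_nuclei"])
        except (TypeError, ValueError):
            problems.append(f"row {i}: tumor_nuclei {d['tumor_nuclei']!r} not an integer")
            continue

        def _f(name):
            v = d.get(name)
            return None if _is_missing(v) else float(v)

        try:
            records.append(
                CoreMeasurement(
                    case_id=str(d["case_id"]),
                    core_id=str(d["core_id"]),
                    marker=marker,
                    percent_positive=_f("percent_positive"),
                    pct_01=_f("pct_01"),
                    pct_2=_f("pct_2"),
                    pct_3=_f("pct_3"),
                    tumor_nuclei=nuclei,
                    block_id=None
                    if _is_missing(d.get("block_id"))
                    else str(d["block_id"]),
                )
            )
        except TableValidationError as exc:
            problems.extend(f"row {i}: {msg}" for msg in exc.problems)
    if problems:
        raise TableValidationError(problems)
    return records


def cores_to_frame(cores: Iterable[CoreMeasurement]) -> pd.DataFrame:
    rows = []
    for c in cores:
        rows.append(
            {
                "case_id": c.case_id,
                "core_id": c.core_id,
                "block_id": c.block_id,
                "marker": c.marker.value,
                "percent_positive": c.percent_positive,
                "pct_01": c.pct_01,
                "pct_2": c.pct_2,
                "pct_3": c.pct_3,
                "tumor_nuclei": c.tumor_nuclei,
            }
        )
    return pd.DataFrame(rows, columns=CORE_COLUMNS)


def write_core_table(cores: Iterable[CoreMeasurement], path, delimiter: str = ",") -> None:
    cores_to_frame(cores).to_csv(path, sep=delimiter, index=False)


def read_clinical_table(path, delimiter: str = ",") -> list[ClinicalRecord]:
    """Read and validate the clinical-record table (one row per case)."""
    df = _read_delimited(path, delimiter, CLINICAL_COLUMNS)
    records: list[ClinicalRecord] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        if any(_is_missing(d[c]) for c in ("er_status", "pr_status", "her2_status")):
            # Missing clinical status is an upstream exclusion, not a read error;
            # represented by omitting the record.
            continue
        try:
            records.append(
                ClinicalRecord(
                    case_id=str(d["case_id"]),
                    er=str(d["er_status"]),
                    pr=str(d["pr_status"]),
                    her2=str(d["her2_status"]),
                )
            )
        except TableValidationError as exc:
            problems.extend(f"row {i}: {m}" for m in exc.problems)
    if problems:
        raise TableValidationError(problems)
    return records


def write_clinical_table(records: Iterable[ClinicalRecord], path, delimiter=",") -> None:
    df = pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "er_status": r.er,
                "pr_status": r.pr,
                "her2_status": r.her2,
            }
            for r in records
        ],
        columns=CLINICAL_COLUMNS,
    )
    df.to_csv(path, sep=delimiter, index=False)


@dataclass
class ExclusionLog:
    """Per-marker accounting of case exclusions and dropped cores.

    ``|analysis set| + sum(case exclusion reasons) == |input cases|`` holds per
    marker for every run. A case hitting several rules is counted once, under
    the first applicable reason in the order: missing_clinical, multi_block,
    single_core (fewer than two evaluable cores after the cellularity filter).
    """

    n_input_cases: dict[str, int] = field(default_factory=dict)
    n_retained: dict[str, int] = field(default_factory=dict)
    excluded: dict[str, dict[str, int]] = field(default_factory=dict)
    cores_dropped_low_cellularity: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input_cases": self.n_input_cases,
            "n_retained": self.n_retained,
            "excluded": self.excluded,
            "cores_dropped_low_cellularity": self.cores_dropped_low_cellularity,
        }


def apply_exclusions(
    cores: Iterable[CoreMeasurement],
    clinical: Iterable[ClinicalRecord],
    mode: str = "per_marker",
) -> tuple[dict[Marker, dict[str, list[CoreMeasurement]]], ExclusionLog]:
    """Build the analysis set: cases with >=2 evaluable cores and a complete clinical record.

    Cores below the 50-nuclei cellularity floor are dropped; cases whose cores
    span more than one tumor block (when a block column is present) are
    excluded; cases lacking a clinical record are excluded.

    Parameters
    ----------
    mode
        ``"per_marker"`` (default) applies the two-evaluable-core rule within
        each marker independently; ``"global"`` additionally drops a case from
        every marker if it fails the rule for any marker it appears in.

    Returns
    -------
    analysis_set, log
        ``analysis_set[marker][case_id]`` is the list of evaluable cores;
        ``log`` counts exclusions by reason per marker.
    """
    if mode not in ("per_marker", "global"):
        raise ValueError(f"mode must be 'per_marker' or 'global', got {mode!r}")
    clin_by_case = {r.case_id: r for r in clinical}
    by_marker_case: dict[Marker, dict[str, list[CoreMeasurement]]] = defaultdict(
        lambda: defaultdict(list)
    )
    blocks_by_case: dict[str, set[str]] = defaultdict(set)
    for c in cores:
        by_marker_case[c.marker][c.case_id].append(c)
        if c.block_id is not None:
            blocks_by_case[c.case_id].add(c.block_id)

    log = ExclusionLog()
    evaluable: dict[Marker, dict[str, list[CoreMeasurement]]] = {}
    for marker, cases in by_marker_case.items():
        m = marker.value
        log.n_input_cases[m] = len(cases)
        log.excluded[m] = {"missing_clinical": 0, "multi_block": 0, "single_core": 0}
        log.cores_dropped_low_cellularity[m] = 0
        kept: dict[str, list[CoreMeasurement]] = {}
        for case_id, case_cores in cases.items():
            ev = [c for c in case_cores if c.evaluable]
            log.cores_dropped_low_cellularity[m] += len(case_cores) - len(ev)
            if case_id not in clin_by_case:
                log.excluded[m]["missing_clinical"] += 1
            elif len(blocks_by_case.get(case_id, ())) > 1:
                log.excluded[m]["multi_block"] += 1
            elif len(ev) < 2:
                log.excluded[m]["single_core"] += 1
            else:
                kept[case_id] = sorted(ev, key=lambda c: c.core_id)
        evaluable[marker] = kept

    if mode == "global":
        failing: set[str] = set()
        for marker, cases in by_marker_case.items():
            for case_id in cases:
                if case_id not in evaluable[marker]:
                    failing.add(case_id)
        for marker in list(evaluable):
            m = marker.value
            for case_id in list(evaluable[marker]):
                if case_id in failing:
                    del evaluable[marker][case_id]
                    log.excluded[m]["single_core"] += 1

    for marker, kept in evaluable.items():
        log.n_retained[marker.value] = len(kept)
    return dict(evaluable), log
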