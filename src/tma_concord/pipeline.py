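"""End-to-end orchestration: classify -> discordance -> agreement, with report output.

``run_pipeline`` reads (or receives) the core and clinical tables, applies the
exclusion rules, collapses cases, builds the review queue, and writes the
case-level CSV, review-queue CSV, heterogeneity summary, sampling-characteristics
(Table-1-style) and agreement (Table-2-style) reports, plus a run manifest and
exclusion log. Every count in a report is derivable from the emitted case-level
CSV; reruns with the same inputs produce identical reports.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from tma_concord.agreement import (
    cellularity_comparison,
    core_number_association,
    stratified_agreement,
)
from tma_concord.classify import (
    CaseClassification,
    ThresholdConfig,
    classify_cases,
)
from tma_concord.datamodel import (
    ClinicalRecord,
    CoreMeasurement,
    Marker,
    apply_exclusions,
    read_clinical_table,
    read_core_table,
)
from tma_concord.discordance import (
    build_review_queue,
    classify_heterogeneity,
    summarize_heterogeneity,
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    cores_path: str | None
    clinical_path: str | None
    thresholds: ThresholdConfig
    seed: int | None = None
    version: str = "0.1.0"
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )
    exclusions: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "cores_path": self.cores_path,
            "clinical_path": self.clinical_path,
            "thresholds": vars(self.thresholds) if hasattr(self.thresholds, "__dict__")
            else {
                "erpr_positive_cutoff": self.thresholds.erpr_positive_cutoff,
                "erpr_high_cutoff": self.thresholds.erpr_high_cutoff,
                "her2_cat_cutoff": self.thresholds.her2_cat_cutoff,
                "erpr_alternative_cutoff": self.thresholds.erpr_alternative_cutoff,
            },
            "seed": self.seed,
            "version": self.version,
            "timestamp": self.timestamp,
            "exclusions": self.exclusions,
        }
        return json.dumps(d, indent=2, default=str)


def cases_to_frame(classified: dict[Marker, list[CaseClassification]]) -> pd.DataFrame:
    """Case-level output table (one row per case × marker)."""
    rows = []
    for marker, cases in classified.items():
        for c in cases:
            row = {
                "case_id": c.case_id,
                "marker": marker.value,
                "n_cores": c.n_cores,
                "total_nuclei": c.total_nuclei,
                "case_status": c.case_status,
                "discordant": c.discordant,
                "core_statuses": ";".join(s.primary_label for s in c.core_statuses),
            }
            if marker == Marker.HER2:
                row["weighted_pct_3"] = c.weighted_intensity["3+"]
                row["weighted_pct_2"] = c.weighted_intensity["2+"]
            else:
                row["weighted_expression"] = c.weighted_expression
            rows.append(row)
    return pd.DataFrame(rows)


def queue_to_frame(queue: list[CaseClassification]) -> pd.DataFrame:
    rows = []
    for c in queue:
        try:
            call = classify_heterogeneity(c)
            category = call.category.value
        except ValueError:
            category = "unclassified"
        rows.append(
            {
                "case_id": c.case_id,
                "marker": c.marker.value,
                "weighted_expression": c.weighted_expression,
                "core_statuses": ";".join(s.primary_label for s in c.core_statuses),
                "core_expressions": ";".join(f"{x:.3f}" for x in c.core_expressions),
                "composition_category": category,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "case_id",
            "marker",
            "weighted_expression",
            "core_statuses",
            "core_expressions",
            "composition_category",
        ],
    )


def table1_report(classified: dict[Marker, list[CaseClassification]]) -> pd.DataFrame:
    """Sampling characteristics by concordance stratum, per marker.

    Cellularity medians/IQRs with the rank-sum p-value, and the core-number ×
    concordance breakdown with the chi-square p-value.
    """
    rows = []
    for marker, cases in sorted(classified.items(), key=lambda kv: kv[0].value):
        conc = [c.total_nuclei for c in cases if not c.discordant]
        disc = [c.total_nuclei for c in cases if c.discordant]
        if conc and disc:
            rs = cellularity_comparison(conc, disc)
            chi = core_number_association(
                core_numbers=[c.n_cores for c in cases],
                discordant=[c.discordant for c in cases],
            )
            counts = {
                f"n_{k}_cores": int(sum(1 for c in cases if c.n_cores == k))
                for k in (2, 3, 4)
            }
            rows.append(
                {
                    "marker": marker.value,
                    "n_cases": len(cases),
                    "n_concordant": len(conc),
                    "n_discordant": len(disc),
                    "cellularity_median_concordant": rs.median_concordant,
                    "cellularity_iqr_concordant": f"{rs.iqr_concordant[0]:.0f}-{rs.iqr_concordant[1]:.0f}",
                    "cellularity_median_discordant": rs.median_discordant,
                    "cellularity_iqr_discordant": f"{rs.iqr_discordant[0]:.0f}-{rs.iqr_discordant[1]:.0f}",
                    "ranksum_p": rs.p_value,
                    **counts,
                    "core_number_chi2": chi.statistic,
                    "core_number_p": chi.p_value,
                }
            )
    return pd.DataFrame(rows)


def table2_report(
    classified: dict[Marker, list[CaseClassification]],
    clinical: list[ClinicalRecord],
) -> pd.DataFrame:
    """Central-vs-clinical agreement per marker and concordance stratum.

    Display rounding follows clinical-reporting convention: agreement to whole
    percent, kappa to two decimals.
    """
    rows = []
    for marker, cases in sorted(classified.items(), key=lambda kv: kv[0].value):
        strata = stratified_agreement(cases, clinical, marker)
        for name in ("all", "concordant", "discordant"):
            res = strata[name]
            row = {
                "marker": marker.value,
                "stratum": name,
                "n": res.table.n,
                "percent_agreement": round(res.percent_agreement)
                if not res.undefined
                else None,
                "kappa": round(res.kappa, 2) if not res.undefined else None,
                "kappa_ci_low": round(res.kappa_ci[0], 2) if not res.undefined else None,
                "kappa_ci_high": round(res.kappa_ci[1], 2) if not res.undefined else None,
            }
            for i, rl in enumerate(res.table.labels):
                for j, cl in enumerate(res.table.labels):
                    row[f"central_{rl}|clinical_{cl}"] = int(res.table.counts[i, j])
            rows.append(row)
    return pd.DataFrame(rows)


def plot_review_queue(queue: list[CaseClassification], confirmed: set[str] | None, path):
    """Expression-vs-rank plot of review-eligible cases, cores overplotted.

    Cases ordered on the x-axis by case-level expression; case-level values as
    colored points (red negative, blue borderline/equivocal, green positive),
    cores as black dots (confirmed heterogeneous) or X's.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    confirmed = confirmed or set()
    markers = sorted({c.marker for c in queue}, key=lambda m: m.value)
    fig, axes = plt.subplots(1, max(len(markers), 1), figsize=(4 * max(len(markers), 1), 3.5))
    if len(markers) <= 1:
        axes = [axes]
    colors = {"negative": "red", "borderline": "blue", "equivocal": "blue",
              "0/1+": "red", "2+": "blue", "3+": "green", "positive": "green"}
    for ax, marker in zip(axes, markers):
        sub = [c for c in queue if c.marker == marker]
        for x, c in enumerate(sub):
            sym = "ko" if c.case_id in confirmed else "kx"
            ax.plot([x] * len(c.core_expressions), c.core_expressions, sym, ms=3)
            from tma_concord.classify import HER2_TO_CLINICAL

            status = (
                HER2_TO_CLINICAL[c.case_status] if marker == Marker.HER2 else c.case_status
            )
            ax.plot(x, c.weighted_expression, "o", color=colors.get(status, "gray"), ms=4)
        ax.set_title(marker.value)
        ax.set_xlabel("case rank by expression")
        ax.set_ylabel("% positive" if marker != Marker.HER2 else "% 3+")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(
    cores: str | Path | list[CoreMeasurement],
    clinical: str | Path | list[ClinicalRecord],
    out_dir: str | Path,
    thresholds: ThresholdConfig | None = None,
    seed: int | None = None,
    delimiter: str = ",",
    make_plot: bool = False,
    confirmed_heterogeneous: set[tuple[str, str]] | None = None,
) -> RunManifest:
    """Run the full classification → discordance → agreement pipeline.

    ``confirmed_heterogeneous`` optionally supplies (case_id, marker) pairs
    confirmed by review (e.g. the latent truth of a simulation); when absent,
    the heterogeneity summary counts every review-queue case with a defined
    composition category as a candidate, leaving confirmation to the reader of
    the review-queue CSV.
    """
    thresholds = thresholds or ThresholdConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        core_records = (
            cores if isinstance(cores, list) else read_core_table(cores, delimiter)
        )
        clin_records = (
            clinical
            if isinstance(clinical, list)
            else read_clinical_table(clinical, delimiter)
        )
    except Exception as exc:
        raise PipelineError("read", str(exc)) from exc
    if not clin_records:
        raise PipelineError("join", "clinical table is empty")

    analysis_set, log = apply_exclusions(core_records, clin_records)
    classified = classify_cases(analysis_set, thresholds)

    cases_df = cases_to_frame(classified)
    cases_df.to_csv(out / "cases.csv", index=False)

    queue_all: list[CaseClassification] = []
    for marker, cases in classified.items():
        queue_all.extend(build_review_queue(cases))
    queue_to_frame(queue_all).to_csv(out / "review_queue.csv", index=False)

    if confirmed_heterogeneous is not None:
        calls = [
            classify_heterogeneity(c)
            for c in queue_all
            if (c.case_id, c.marker.value) in confirmed_heterogeneous
        ]
    else:
        calls = []
        for c in queue_all:
            try:
                calls.append(classify_heterogeneity(c))
            except ValueError:
                pass
    all_cases = [c for cases in classified.values() for c in cases]
    summarize_heterogeneity(calls, all_cases).to_csv(
        out / "heterogeneity_summary.csv", index=False
    )

    t1 = table1_report(classified)
    t1.to_csv(out / "table1_style.csv", index=False)
    t2 = table2_report(classified, clin_records)
    t2.to_csv(out / "table2_style.csv", index=False)
    (out / "table2_style.md").write_text(t2.to_markdown(index=False))

    if make_plot:
        try:
            plot_review_queue(
                queue_all,
                {c[0] for c in (confirmed_heterogeneous or set())},
                out / "review_queue.png",
            )
        except Exception as exc:  # plotting must never sink a run
            raise PipelineError("plot", str(exc)) from exc

    manifest = RunManifest(
        cores_path=str(cores) if not isinstance(cores, list) else None,
        clinical_path=str(clinical) if not isinstance(clinical, list) else None,
        thresholds=thresholds,
        seed=seed,
        exclusions=log.to_dict(),
    )
    (out / "manifest.json").write_text(manifest.to_json())
    (out / "exclusions.json").write_text(json.dumps(log.to_dict(), indent=2))
    return manifest
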