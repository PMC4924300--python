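"""Synthetic TMA-cohort generator with retained latent truth.

Emulates the statistical structure the concordance analysis assumes for a
population-based breast-cancer TMA cohort: 2–4 cores per case, right-skewed
tumor cellularity, biomarker-positive fractions matching a ~1085-case cohort,
segregated intratumoral heterogeneity (two spatially distinct expression
regions per heterogeneous tumor), binomial core-sampling noise driven by
cellularity, additive contamination of automated scores by benign epithelium /
DCIS, and an imperfect clinical record.

Every case's ground truth (true status, region expression levels, heterogeneity
flag, contaminated cores, clinical flips) is retained so that the
classification pipeline can be validated by parameter recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from tma_concord.classify import ThresholdConfig, classify_cases
from tma_concord.datamodel import (
    ClinicalRecord,
    CoreMeasurement,
    Marker,
    apply_exclusions,
    read_clinical_table,
    read_core_table,
)
from tma_concord.discordance import build_review_queue

MARKERS = ("ER", "PR", "HER2")


def fit_lognormal_to_median_iqr(
    median: float, iqr: tuple[float, float]
) -> tuple[float, float]:
    """Lognormal (mu, sigma) whose median and interquartile range match the inputs.

    mu = ln(median); sigma = (ln q3 - ln q1) / (2 z_{0.75}) with z_{0.75} the
    standard-normal 75th-percentile deviate. The returned distribution
    reproduces the requested median and IQR exactly (up to floating point).
    """
    q1, q3 = iqr
    if not 0 < q1 < median < q3:
        raise ValueError(f"require 0 < q1 < median < q3, got {q1}, {median}, {q3}")
    z75 = stats.norm.ppf(0.75)
    return math.log(median), (math.log(q3) - math.log(q1)) / (2 * z75)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic TMA cohort.

    Defaults describe a ~1085-case population cohort: core-count mix 10/27/63 %
    for 2/3/4 cores; ER/PR positive fractions 784/1085 and 739/1085; a HER2
    3+-expressing component matched to the 148/1085 cases carrying at least one
    3+ core; heterogeneity among biomarker-positive cases at 2 %/7 %/8 % for
    ER/PR/HER2; case-level cellularity lognormal with median 5225 and IQR
    (2846, 8869), scaled down by 0.7 for cases destined to be ER/PR
    heterogeneous (HER2 heterogeneity leaves cellularity unchanged, matching
    the observed absence of a HER2 cellularity shift); 2 % per-core
    contamination adding 1–15 percentage points of spurious positivity; and a
    3 % clinical-record error rate.
    """

    n_cases: int = 1085
    seed: int = 0
    core_count_probs: tuple[float, float, float] = (0.10, 0.27, 0.63)  # P(2/3/4 cores)
    marker_positive_prob: dict = field(
        default_factory=lambda: {"ER": 784 / 1085, "PR": 739 / 1085, "HER2": 148 / 1085}
    )
    her2_equivocal_prob: float = 0.05
    heterogeneity_prob: dict = field(
        default_factory=lambda: {"ER": 0.02, "PR": 0.07, "HER2": 0.08}
    )
    contamination_prob: float = 0.02
    contamination_effect: tuple[float, float] = (1.0, 15.0)
    cellularity_median: float = 5225.0  # case-level total nuclei
    cellularity_iqr: tuple[float, float] = (2846.0, 8869.0)
    discordant_cellularity_shift: dict = field(
        default_factory=lambda: {"ER": 0.7, "PR": 0.7, "HER2": 1.0}
    )
    clinical_error_prob: float = 0.03
    # ER/PR expression components (percent positivity)
    negative_expression_max: float = 0.5  # true negatives: uniform(0, this)
    borderline_prob: float = 0.3  # positive component mass in [1, 10)
    positive_expression_range: tuple[float, float] = (10.0, 95.0)
    borderline_expression_range: tuple[float, float] = (1.0, 10.0)
    # HER2 true intensity-profile components: (pct_3 range, pct_2 range)
    her2_positive_profile: tuple[tuple[float, float], tuple[float, float]] = (
        (15.0, 80.0),
        (5.0, 30.0),
    )
    her2_equivocal_profile: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0, 5.0),
        (15.0, 50.0),
    )
    her2_negative_profile: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0, 2.0),
        (0.0, 6.0),
    )
    her2_het_low_equivocal_prob: float = 0.6  # low region equivocal vs negative
    region_fraction_range: tuple[float, float] = (0.3, 0.7)  # whole-tumor high-region share

    def __post_init__(self):
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        probs = np.asarray(self.core_count_probs, dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("core_count_probs must be a distribution over {2,3,4}")
        for name in ("marker_positive_prob", "heterogeneity_prob"):
            d = getattr(self, name)
            if set(d) != set(MARKERS):
                raise ValueError(f"{name} must have keys {MARKERS}")
            if any(not 0 <= v <= 1 for v in d.values()):
                raise ValueError(f"{name} values must lie in [0, 1]")
        for p in (self.contamination_prob, self.clinical_error_prob,
                  self.her2_equivocal_prob, self.borderline_prob,
                  self.her2_het_low_equivocal_prob):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        fit_lognormal_to_median_iqr(self.cellularity_median, self.cellularity_iqr)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class SyntheticCohort:
    """Simulated core + clinical tables with the latent truth table."""

    cores: list[CoreMeasurement]
    clinical: list[ClinicalRecord]
    truth: pd.DataFrame  # one row per (case, marker)
    config: SimulationConfig

    def write(self, out_dir) -> dict[str, Path]:
        from tma_concord.datamodel import write_clinical_table, write_core_table

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "cores": out / "cores.csv",
            "clinical": out / "clinical.csv",
            "truth": out / "truth.csv",
            "config": out / "sim_config.json",
        }
        write_core_table(self.cores, paths["cores"])
        write_clinical_table(self.clinical, paths["clinical"])
        self.truth.to_csv(paths["truth"], index=False)
        paths["config"].write_text(self.config.to_json())
        return paths


def _uniform(rng, lohi):
    return float(rng.uniform(lohi[0], lohi[1]))


def _region_assignment(rng, k: int) -> np.ndarray:
    """Per-core high-region membership, Bernoulli(1/2) conditioned on both regions sampled.

    Conditioning ensures the cores of a heterogeneous case actually straddle
    the two expression regions, so the latent heterogeneity flag corresponds
    to a detectable signal (a tumor whose sampled cores all hit one region is
    indistinguishable from a homogeneous tumor and carries no flag to recover).
    """
    while True:
        a = rng.random(k) < 0.5
        if a.any() and not a.all():
            return a


def _erpr_positive_expression(rng, cfg: SimulationConfig) -> float:
    if rng.random() < cfg.borderline_prob:
        return _uniform(rng, cfg.borderline_expression_range)
    return _uniform(rng, cfg.positive_expression_range)


def _her2_profile(rng, cfg: SimulationConfig, kind: str) -> tuple[float, float]:
    ranges = {
        "positive": cfg.her2_positive_profile,
        "equivocal": cfg.her2_equivocal_profile,
        "negative": cfg.her2_negative_profile,
    }[kind]
    p3 = _uniform(rng, ranges[0])
    # 2+ fraction is capped so the intensity categories form a valid composition
    p2 = min(_uniform(rng, ranges[1]), 100.0 - p3)
    return p3, p2


def _erpr_true_status(expr: float) -> str:
    return "positive" if expr >= 1.0 else "negative"


def _her2_true_status(p3: float, p2: float) -> str:
    if p3 >= 10.0:
        return "positive"
    if p2 >= 10.0:
        return "equivocal"
    return "negative"


def _flip_erpr(rng, status: str) -> str:
    return "negative" if status == "positive" else "positive"


def _flip_her2(rng, status: str) -> str:
    others = [s for s in ("negative", "equivocal", "positive") if s != status]
    return others[int(rng.integers(len(others)))]


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Generate a cohort of synthetic cases, fully reproducible from ``cfg.seed``.

    Per case: a core count is drawn from the 2/3/4 mix; each marker
    independently receives a true expression state (ER/PR: percent positivity;
    HER2: a 3+/2+ intensity profile). Biomarker-positive cases are
    heterogeneous with the per-marker probability, in which case two regions
    on opposite sides of a classification boundary are created and each core
    is assigned to a region. Core cellularity is lognormal (scaled down for
    marker-heterogeneous cases where configured) and the observed core percent
    is a binomial draw with n = tumor nuclei — so low-cellularity cores are
    noisier. Contaminated cores gain additive spurious positivity. The
    clinical record classifies the region-size-weighted whole-tumor aggregate
    and is flipped with the clinical error probability.

    Randomness uses one seed sequence with deterministically spawned per-case
    substreams, so output is reproducible regardless of generation order.
    """
    mu_case, sigma = fit_lognormal_to_median_iqr(
        cfg.cellularity_median, cfg.cellularity_iqr
    )
    mean_cores = float(np.dot([2, 3, 4], cfg.core_count_probs))
    mu_core = mu_case - math.log(mean_cores)  # per-core log-median

    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_cases)
    width = len(str(cfg.n_cases))

    cores: list[CoreMeasurement] = []
    clinical: list[ClinicalRecord] = []
    truth_rows: list[dict] = []

    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        case_id = f"case{i + 1:0{width}d}"
        k = int(rng.choice([2, 3, 4], p=cfg.core_count_probs))
        clin_status: dict[str, str] = {}

        for marker in MARKERS:
            positive = rng.random() < cfg.marker_positive_prob[marker]
            het = positive and (rng.random() < cfg.heterogeneity_prob[marker])
            region_high_frac = _uniform(rng, cfg.region_fraction_range) if het else 1.0

            if marker == "HER2":
                if positive:
                    high = _her2_profile(rng, cfg, "positive")
                    if het:
                        low_kind = (
                            "equivocal"
                            if rng.random() < cfg.her2_het_low_equivocal_prob
                            else "negative"
                        )
                        low = _her2_profile(rng, cfg, low_kind)
                    else:
                        low = high
                else:
                    kind = (
                        "equivocal"
                        if rng.random()
                        < cfg.her2_equivocal_prob / (1 - cfg.marker_positive_prob[marker])
                        else "negative"
                    )
                    high = low = _her2_profile(rng, cfg, kind)
                agg3 = region_high_frac * high[0] + (1 - region_high_frac) * low[0]
                agg2 = region_high_frac * high[1] + (1 - region_high_frac) * low[1]
                true_status = _her2_true_status(agg3, agg2)
                region_low_expr, region_high_expr = low[0], high[0]
            else:
                if positive:
                    high_expr = _erpr_positive_expression(rng, cfg)
                    low_expr = (
                        float(rng.uniform(0.0, cfg.negative_expression_max))
                        if het
                        else high_expr
                    )
                else:
                    high_expr = low_expr = float(
                        rng.uniform(0.0, cfg.negative_expression_max)
                    )
                agg = region_high_frac * high_expr + (1 - region_high_frac) * low_expr
                true_status = _erpr_true_status(agg)
                region_low_expr, region_high_expr = low_expr, high_expr

            in_high = _region_assignment(rng, k) if het else np.ones(k, dtype=bool)
            shift = cfg.discordant_cellularity_shift[marker] if het else 1.0
            nuclei = np.maximum(
                1,
                np.round(
                    rng.lognormal(mu_core + math.log(shift), sigma, size=k)
                ).astype(int),
            )
            contaminated = rng.random(k) < cfg.contamination_prob
            contam_ids = []

            for j in range(k):
                core_id = f"{case_id}-c{j + 1}"
                n = int(nuclei[j])
                if marker == "HER2":
                    p3, p2 = high if in_high[j] else low
                    # observed intensity fractions: multinomial core sampling
                    draws = rng.multinomial(
                        n, [p3 / 100.0, p2 / 100.0, 1 - (p3 + p2) / 100.0]
                    )
                    obs3 = 100.0 * draws[0] / n
                    obs2 = 100.0 * draws[1] / n
                    if contaminated[j]:
                        obs3 = min(100.0, obs3 + _uniform(rng, cfg.contamination_effect))
                        obs2 = min(obs2, 100.0 - obs3)
                        contam_ids.append(core_id)
                    obs01 = max(0.0, 100.0 - obs3 - obs2)
                    cores.append(
                        CoreMeasurement(
                            case_id=case_id,
                            core_id=core_id,
                            marker=Marker.HER2,
                            pct_01=obs01,
                            pct_2=obs2,
                            pct_3=obs3,
                            tumor_nuclei=n,
                        )
                    )
                else:
                    p = (region_high_expr if in_high[j] else region_low_expr) / 100.0
                    obs = 100.0 * rng.binomial(n, p) / n
                    if contaminated[j]:
                        obs = min(100.0, obs + _uniform(rng, cfg.contamination_effect))
                        contam_ids.append(core_id)
                    cores.append(
                        CoreMeasurement(
                            case_id=case_id,
                            core_id=core_id,
                            marker=Marker(marker),
                            percent_positive=obs,
                            tumor_nuclei=n,
                        )
                    )

            flipped = rng.random() < cfg.clinical_error_prob
            if flipped:
                clin = (
                    _flip_her2(rng, true_status)
                    if marker == "HER2"
                    else _flip_erpr(rng, true_status)
                )
            else:
                clin = true_status
            clin_status[marker] = clin
            truth_rows.append(
                {
                    "case_id": case_id,
                    "marker": marker,
                    "n_cores": k,
                    "true_positive": positive,
                    "true_status": true_status,
                    "heterogeneous": het,
                    "region_low_expression": region_low_expr,
                    "region_high_expression": region_high_expr,
                    "region_high_fraction": region_high_frac,
                    "n_contaminated_cores": len(contam_ids),
                    "contaminated_cores": ";".join(contam_ids),
                    "clinical_flipped": flipped,
                    "clinical_status": clin,
                }
            )

        clinical.append(
            ClinicalRecord(
                case_id=case_id,
                er="positive" if clin_status["ER"] == "positive" else "negative",
                pr="positive" if clin_status["PR"] == "positive" else "negative",
                her2=clin_status["HER2"],
            )
        )

    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(cores=cores, clinical=clinical, truth=truth, config=cfg)


def load_cohort(cores_path, clinical_path, truth_path=None) -> SyntheticCohort:
    """Re-load a written cohort (truth optional)."""
    truth = pd.read_csv(truth_path) if truth_path else pd.DataFrame()
    return SyntheticCohort(
        cores=read_core_table(cores_path),
        clinical=read_clinical_table(clinical_path),
        truth=truth,
        config=SimulationConfig(),
    )


def recover_heterogeneity(
    cohort: SyntheticCohort, thresholds: ThresholdConfig | None = None
) -> pd.DataFrame:
    """Estimate per-marker heterogeneity frequency by running the full pipeline.

    Runs exclusions, classification and review-queue construction on the
    simulated tables; "manual review" is replayed from the latent truth flag
    (a queued case counts as confirmed iff it is truly heterogeneous). Returns
    per-marker estimates against the biomarker-positive denominator (HER2:
    cases with at least one 3+ core) together with the configured truth and
    the Monte-Carlo standard error sqrt(p_hat (1-p_hat) / denominator).
    """
    thresholds = thresholds or ThresholdConfig()
    analysis_set, _ = apply_exclusions(cohort.cores, cohort.clinical)
    classified = classify_cases(analysis_set, thresholds)
    het_flags = {
        (r.case_id, r.marker): bool(r.heterogeneous)
        for r in cohort.truth.itertuples(index=False)
    }
    rows = []
    for marker, cases in classified.items():
        queue = build_review_queue(cases)
        confirmed = sum(
            1 for c in queue if het_flags.get((c.case_id, marker.value), False)
        )
        if marker == Marker.HER2:
            denom = sum(1 for c in cases if c.has_positive3_core)
        else:
            denom = sum(1 for c in cases if c.case_status == "positive")
        est = confirmed / denom if denom else float("nan")
        mc_se = math.sqrt(est * (1 - est) / denom) if denom else float("nan")
        rows.append(
            {
                "marker": marker.value,
                "n_cases": len(cases),
                "n_discordant": sum(1 for c in cases if c.discordant),
                "discordance_frequency": sum(1 for c in cases if c.discordant)
                / len(cases),
                "n_review_eligible": len(queue),
                "n_confirmed": confirmed,
                "denominator_positive": denom,
                "estimated_heterogeneity_freq": est,
                "configured_heterogeneity_prob": cohort.config.heterogeneity_prob[
                    marker.value
                ],
                "mc_se": mc_se,
            }
        )
    return pd.DataFrame(rows).sort_values("marker").reset_index(drop=True)
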