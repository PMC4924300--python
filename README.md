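# tma-concord

Classification of breast-cancer biomarker status from tissue-microarray (TMA)
cores, and analysis of core-to-core discordance and agreement with the clinical
record.

Population-based breast-cancer studies increasingly score estrogen receptor
(ER), progesterone receptor (PR), and HER2 immunohistochemistry on TMAs with
automated image analysis, using two to four 1.0-mm cores per tumor. Because
each core samples a small region, spatial (intratumoral) heterogeneity of
biomarker expression — and technical artifacts such as admixed benign
epithelium or DCIS misread as invasive tumor — can make cores of the same
tumor disagree, which in turn degrades agreement between the central TMA call
and the clinical record. This package provides the full analysis chain for
such studies, plus a synthetic cohort generator for validating it.

## What it computes

**Core-level status.** ER/PR cores are scored by percent positivity *p* and
called negative (*p* < 1 %), borderline (1 % ≤ *p* < 10 %), or positive
(*p* ≥ 10 %); the clinical dichotomy is positive at *p* ≥ 1 %. HER2 cores are
scored by intensity-category fractions and called 3+ (positive) when ≥10 % of
tumor cells stain at 3+, 2+ (equivocal) when the 3+ fraction is <10 % but the
2+ fraction is ≥10 %, and 0/1+ (negative) otherwise.

**Case-level collapsing.** With *n_i* tumor nuclei in core *i*, the core
weight is *w_i = n_i / Σ_j n_j* and the case-level expression is the weighted
average *Σ_i w_i p_i*, to which the same clinical thresholds are applied
(HER2: applied to the weighted 3+ and 2+ fractions).

**Discordance and heterogeneity.** A case is discordant when any two cores
differ on the primary scale (ER/PR <1 %/≥1 %; HER2 three-category). The
manual-review queue keeps discordant ER/PR cases with positive case-level
status and discordant HER2 cases with ≥1 3+ core, and categorises each by its
core-status composition (negative+borderline only vs negative+positive for
ER/PR; 2+&3+, 0/1+&3+, or all three for HER2, with a strict flag when both
0/1+ and 3+ cores are present).

**Agreement.** Central-vs-clinical contingency tables, percent agreement
(100·trace/n) and Cohen's kappa

    kappa = (p_o - p_e) / (1 - p_e),  p_e = sum_i p_i. p_.i

with a 95 % CI from the Fleiss–Cohen–Everitt asymptotic variance, overall and
stratified by core-concordance; rank-sum comparison of cellularity between
strata and a chi-square test of discordance rate by core number.

**Simulation.** `simulate_cohort` generates cohorts with segregated two-region
heterogeneity, cellularity-driven binomial core-sampling noise, additive
benign/DCIS contamination, and clinical-record error, retaining the latent
truth so the pipeline's heterogeneity estimates can be validated by parameter
recovery.

## Worked example

```python
from tma_concord import (SimulationConfig, simulate_cohort, recover_heterogeneity)

cohort = simulate_cohort(SimulationConfig(n_cases=5000, seed=31, contamination_prob=0.0))
print(recover_heterogeneity(cohort)[
    ["marker", "discordance_frequency", "estimated_heterogeneity_freq",
     "configured_heterogeneity_prob"]].to_string(index=False))
```

prints

```
marker  discordance_frequency  estimated_heterogeneity_freq  configured_heterogeneity_prob
    ER                 0.0266                      0.018738                           0.02
  HER2                 0.0112                      0.077253                           0.08
    PR                 0.0590                      0.065770                           0.07
```

i.e., running the full classify → discordance → review-queue pipeline on the
simulated cohort and confirming queued cases against the latent truth recovers
the configured per-marker heterogeneity rates (2 %/7 %/8 % among
biomarker-positive cases) from the observed core data.

Agreement statistics work from any cross-tabulation:

```python
import numpy as np
from tma_concord import ContingencyTable, cohens_kappa

t = ContingencyTable(labels=("negative", "positive"),
                     counts=np.array([[259, 42], [28, 756]]))
print(cohens_kappa(t).summary())
# [all] n=1085: agreement 94 %, kappa 0.84 (0.80-0.87)
```

The same pipeline runs from the shell:

```
tma-concord simulate --n-cases 1085 --seed 0 --out sim/
tma-concord all --cores sim/cores.csv --clinical sim/clinical.csv --out run/
```

writing the case-level CSV, review-queue CSV, heterogeneity summary, and the
sampling-characteristics and agreement reports into `run/`.

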