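# Methods

## Classification model

The unit of measurement is a TMA core scored by automated image analysis.
ER/PR cores carry a percent positivity in [0, 100]; HER2 cores carry percent
of tumor cells per staining-intensity category, with 0 and 1+ pooled (the
classification rule consults only the 2+ and 3+ fractions, so the pooled
representation is sufficient and the intensity-0 remainder is implicit). Cores
with fewer than 50 tumor nuclei are not evaluable and are dropped before any
analysis; a case needs at least two evaluable cores per marker and a complete
clinical record (ER, PR, and HER2 all present) to enter the analysis set, and
is excluded if its cores span more than one tumor block. Exclusions are
counted by the first applicable reason (missing clinical, multi-block, single
core) so that retained + excluded = input cases per marker. The
two-evaluable-core rule is applied per marker by default; a `global` mode
drops a case everywhere if it fails for any marker — the choice matters only
for cases whose core counts differ by marker.

Core status uses the clinical thresholds: ER/PR negative <1 %, borderline
[1, 10) %, positive ≥10 % (dichotomy: positive at ≥1 %; an exploratory 10 %
dichotomy is configurable); HER2 3+ when the 3+ fraction is ≥10 %, else 2+
when the 2+ fraction is ≥10 %, else 0/1+. All comparisons are closed on the
positive side and operate on unrounded floating-point percentages.

Case status comes from cellularity-weighted collapsing: weights
w_i = n_i / Σ n_j over a case's evaluable cores, case expression Σ w_i p_i,
thresholded with the same rules (HER2: the rule applied to the weighted 3+
and 2+ fractions — one collapsing method for all markers, rather than a
majority vote of core categories, because the case rule is stated in terms of
percent of tumor cells, which the weighted fractions estimate). Because every
status category is defined by threshold conditions preserved under convex
combination, concordant cores force the case status; the implementation
assigns the shared status directly in that situation, which also removes
floating-point flips when all cores sit exactly on a cutoff.

## Discordance, review queue, heterogeneity taxonomy

Discordance is any two cores differing on the primary scale (ER/PR <1 %/≥1 %;
HER2 three-category); an alternative scale dichotomises ER/PR at 10 %. The
review queue — the cases a pathologist would re-examine to separate true
spatial heterogeneity from algorithmic misclassification — contains discordant
ER/PR cases with positive case-level status and discordant HER2 cases with at
least one 3+ core, sorted ascending by case-level expression (weighted percent
positivity; weighted 3+ fraction for HER2), ties broken by case id. Each
queued case receives a composition category from the multiset of its core
statuses; for HER2 the strict heterogeneity flag marks cases with both 0/1+
and 3+ cores. Frequencies are reported against three denominators:
review-eligible cases, biomarker-positive cases (HER2: cases with ≥1 3+
core), and all cases. On real data confirmation is a human decision and the
queue is exported for review; in simulation the latent truth flag replays the
reviewer.

## Agreement statistics

Cohen's kappa is computed from the central-vs-clinical cross-tabulation (rows
central, columns clinical; ER/PR 2×2, HER2 3×3 with 0/1+, 2+, 3+ mapped onto
negative/equivocal/positive). The 95 % CI uses the Fleiss–Cohen–Everitt
asymptotic variance

    var = [ Σ_i p_ii ((1-p_e) - (p_i.+p_.i)(1-p_o))²
            + (1-p_o)² Σ_{i≠j} p_ij (p_.i+p_j.)²
            - (p_o p_e - 2p_e + p_o)² ] / (n (1-p_e)⁴)

truncated to [-1, 1]; tables with p_e = 1 (all mass in one row and column) or
n = 0 yield a flagged undefined result rather than an error. The tests verify
the closed form against a first-principles po/pe summation and against an
independent library implementation. Clinical HER2 equivocal is kept as an
irreducible third category (no FISH resolution is modelled). Cellularity is
compared between concordance strata with a two-sided Wilcoxon–Mann–Whitney
test (exact enumeration when both groups have ≤7 untied observations, else
normal approximation with continuity and tie correction), and discordance rate
across 2/3/4-core cases with Pearson chi-square, no continuity correction,
df = k−1 after dropping zero-margin rows. Display rounding: agreement to whole
percent, kappa to two decimals.

## Synthetic cohort generator

The generator's defaults describe a ~1085-case population cohort: core-count
mix 10/27/63 % for 2/3/4 cores; ER/PR positive fractions 784/1085 and
739/1085; a HER2 3+-expressing component at 148/1085 (matching cases with ≥1
3+ core) plus a 5 % equivocal-profile component so all three central HER2
categories are populated; heterogeneity among biomarker-positive cases at
2 %/7 %/8 % (ER/PR/HER2); case-level cellularity lognormal with median 5225
and IQR (2846, 8869), converted to per-core draws by dividing the log-median
by the mean core count (3.53).

Mechanisms, per case and marker:

- **Expression.** True negatives sit near zero (uniform on [0, 0.5] %, bounded
  away from the 1 % cutoff so that pure sampling noise rarely crosses it).
  The positive component mixes a borderline band (30 % mass, uniform on
  [1, 10)) with a positive band (uniform on [10, 95]), so both ER/PR
  heterogeneity compositions (negative+borderline-only and negative+positive)
  arise. HER2 profiles are uniform boxes per category (3+ fraction 15–80 %
  for positive, 2+ fraction 15–50 % for equivocal, both low for negative),
  with the 2+ fraction capped so the composition stays valid.
- **Segregated heterogeneity.** A heterogeneous tumor has exactly two regions:
  a high region drawn from the positive component and a low region drawn from
  the negative component (HER2: equivocal with probability 0.6, else
  negative, reflecting the predominance of 2+&3+ mixtures). The whole-tumor
  high-region share is uniform on [0.3, 0.7]. Core region membership is
  Bernoulli(1/2) **conditioned on both regions being sampled**: a tumor whose
  cores all happen to hit one region carries no recoverable signal, so the
  latent flag is defined as sampled heterogeneity — this makes parameter
  recovery well-posed at the cost of not modelling heterogeneity missed
  entirely by coring (a real phenomenon the generator deliberately leaves
  out, like spatial coordinates and temporal change).
- **Sampling noise.** Per-core cellularity is lognormal (scaled by 0.7 for
  ER/PR-heterogeneous cases, reproducing their lower observed cellularity;
  HER2 heterogeneity leaves cellularity unchanged, matching the absence of a
  HER2 shift). The observed percent is a binomial draw with n = tumor nuclei
  (HER2: multinomial over intensity categories), so low-cellularity cores are
  noisier and borderline tumors near 1 % generate spurious discordance — the
  "random variation around the threshold" that review rejects.
- **Contamination.** Each core is independently contaminated with probability
  0.02, adding uniform [1, 15] percentage points of spurious positivity (HER2:
  to the 3+ fraction, emulating HER2-positive DCIS in a negative background).
  Contamination creates review-queue entries that are not true heterogeneity,
  so the confirmed fraction among discordant cases tracks the mix of the two
  injected mechanisms.
- **Clinical record.** The record classifies the region-share-weighted
  whole-tumor aggregate and is flipped with probability 0.03 (ER/PR: toggled;
  HER2: moved to one of the other two categories uniformly). The rate is a
  free parameter chosen so overall simulated agreement lands in the high-80s
  to mid-90s percent range typical of central-vs-clinical comparisons, not an
  estimate of any particular cohort's record quality.

Marker states are drawn independently across markers; real ER and PR are
correlated, so cross-marker joint frequencies (e.g. co-occurring
heterogeneity) are not calibrated — the package reports them but fits no
dependence model. Randomness uses a root `SeedSequence` with per-case spawned
substreams, so output is byte-reproducible from the seed.

## Validation by parameter recovery

`recover_heterogeneity` runs the full pipeline (exclusions → classification →
review queue) on a simulated cohort and confirms queued cases against the
latent flag; the per-marker estimate uses the biomarker-positive denominator.
The estimator has a small structural downward bias (~5 % relative): truly
heterogeneous cases whose weighted expression collapses below 1 % are excluded
from review by the case-positivity rule itself. With contamination off and
n = 5000 cases this bias sits well inside three Monte-Carlo standard errors of
the configured rates, which is the acceptance band the tests use. Simulation
sizes in the tests (300–5000 cases) were chosen so each stochastic check runs
in seconds while keeping Monte-Carlo error a fraction of the tested margins.

## Known limitations

- The lognormal cellularity fit matches the median and IQR width exactly but
  not both printed quartiles when the log-quantiles are asymmetric (two
  parameters, three constraints); quartiles land within ~5 %.
- Discordance frequencies in a default simulated cohort (~3–6 %) are lower
  than in real cohorts (~9–18 %), because only two artifact mechanisms
  (binomial noise, additive contamination) are modelled; the generator is a
  testbed for the pipeline's logic, not a calibrated digital twin.
- No Allred/H-score systems, no weighted kappa or multi-rater statistics, no
  image-level modelling; automated image-analysis outputs are this package's
  inputs.
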