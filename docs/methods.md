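# Methods

This note documents the models and procedures implemented in
`sepsiswatch`, the parameters that matter, the numerical choices, and
what the synthetic-data results do and do not demonstrate.

## Data model

An *episode* is one encounter: static features (age, sex, weight),
timestamped observations of up to 28 dynamic variables, timed
intervention events (antibiotic, vasopressor, glucocorticoid,
ventilation), a binary sepsis label, and — for septic episodes — an
onset time. All times are hours relative to admission (t = 0), so onset
lives on the same axis as the observations. The *reference time* of an
episode (the prediction anchor) is the onset for septic episodes; for
controls, which have no natural anchor, it is an explicit
`anchor_time_h` chosen by the data source (the synthetic generator
draws it uniformly on the same interval as septic onsets). This control
anchor rule is a stated convention of this package.

Loading rejects only physically impossible values (outside per-variable
*hard* bounds, e.g. negative heart rate); values outside the narrower
*plausible* physiologic ranges produce warnings but are retained, since
no principled outlier rule exists for this setting. Missingness is
episode-level presence/absence: a variable is excluded from modeling
when the fraction of episodes with zero observations of it is
*strictly* above 0.20 (exactly 0.20 is retained; the strictness is
documented and tested).

## CTWH window estimation

Per retained variable:

* **Window size** `W_v` = the q-quantile (default q = 0.70) of the
  pooled within-episode inter-observation gaps, with linear
  interpolation between closest ranks (numpy's `linear` convention,
  frozen for reproducibility). Pooling all gaps is the default; a
  per-patient-median variant is exposed as a config switch.
* **Window count** `N_v`: window means are computed in trailing windows
  `T_k = [anchor − (k+1)W, anchor − kW)` stacked at each episode's
  reference time, and the Pearson correlation between `T_0` and `T_k`
  is taken across episodes over complete pairs (both windows
  non-empty). Counting is *sequential*: `N` is 1 plus the longest run
  of leading lags whose correlation strictly exceeds the threshold
  (default 0.6), so the referenced history has no gaps. `N ≥ 1` always
  (the current window is usable by definition), `N ≤ max_windows`
  (default 4), and fewer than `min_pairs` (default 10) complete pairs
  at lag 1 forces `N = 1` with a warning. The arithmetic mean is the
  within-window summary — chosen for noise robustness, since the
  source material plots window "values" without defining a summary.
* **Span** = `W_v × N_v` exactly, for every entry. When externally
  reported window tables conflict with this identity, the package
  follows the identity and treats such rows as inconsistent rather
  than resolving them.

Fitted lag correlations `r_1 … r_{N−1}` are stored in the window config
and reused as the CTWH estimate weights downstream.

## Multitask GP imputation

The GP operates in z-scored space (population mean/sd per variable).
Covariance between observation (t, variable i) and (s, variable j):

    K = c · B[i,j] · k(|t−s|; ℓ_shared)  +  δ_ij · s² · k(|t−s|; ℓ_i)
        + δ_ij δ_ts · σ_n²

* **Time kernel** `k`: exponential (Ornstein–Uhlenbeck) by default —
  physiologic signals are rough, and OU sample paths are continuous but
  not differentiable; a squared-exponential is available by config.
* **Task structure** `B`: unit-diagonal cross-variable correlation
  estimated from per-episode variable means (pairwise-complete Pearson),
  truncated to its leading `task_rank` = 5 eigencomponents, ridged
  (+0.05 I) and renormalized. This is the "multivariate" coupling: a
  variable with no recent observation borrows strength from correlated
  variables through the shared term.
* **Length scales**: `ℓ_i = W_v` — the CTWH stage's own estimate of
  each variable's temporal coherence — and `ℓ_shared` = their median.
  This deliberately couples the two stages.
* **Magnitudes** `(c, s², σ_n²)` are population-level, fitted by L-BFGS
  on the summed log marginal likelihood of a seeded subsample of
  episodes (default 8, `max_opt_iter` 30, bounds e^−6…e^3 on variances
  and e^−9…1 on noise); per-episode optimization would be slow and
  unstable on sparse episodes. Conditioning is per-episode.
* **Numerics**: noise floor 1e-4; Cholesky jitter starts at 1e-6 and
  escalates ×10 up to 1e-2 before raising an error naming the episode.

Only observations at or before the prediction cutoff *and* within the
variable's span of it condition the posterior. Grid cells further back
than the span are filled with the population median and flagged
`out_of_span` rather than extrapolated — limiting the interpolation
range is the point of the span rule. An episode with zero usable
observations falls back to population medians with a fallback flag.

**Merge rule.** The final grid value is the convex combination
`λ·ctwh + (1−λ)·gp`, where the CTWH estimate is the
lag-correlation-weighted average of the `N_v` window means ending at
the grid time (lag-0 weight 1, weights renormalized over non-empty
windows) and `λ = (fraction of non-empty windows) × fixed_weight`
(default 0.5) in the default correlation mode, or a fixed constant.
The combination functional form is this package's choice; both mode
and weight are exposed in config. When one source is undefined the
other is used as-is; when both are, the population median with an
`out_of_span` flag. Uncertainty (`sd`) is the GP posterior sd — the
window estimate carries no uncertainty model.

## Horizon datasets and leakage

For horizon T ∈ {0…12}, each episode contributes one row with cutoff =
reference − T; the trailing 12 h hourly grid (13 points) ends at the
cutoff and is imputed from pre-cutoff data only. Septic rows answer
"will onset occur T hours after this cutoff?"; controls contribute one
row per horizon at their anchor. Tabular features are
(last, mean, min, max, least-squares slope) per variable — 5·V columns
— plus age, sex, weight and four any-intervention-before-cutoff flags;
the summary set is a package choice ("raw interpolated features" alone
underdetermines it). Sequence mode keeps the 13 × V tensor. Because
every feature derives from pre-cutoff data, perturbing post-cutoff
observations leaves feature matrices bit-identical; this anti-leakage
property is asserted by perturbation tests. Folds are stratified and
episode-disjoint.

## Model bank

13 models, one per horizon. The boosted variant is XGBoost
(logloss, hist trees, single-threaded, seeded); hyperparameters by
stratified 5-fold CV over learning_rate ∈ {0.05, 0.1, 0.3} ×
max_depth ∈ {3, 4, 6} (a package choice) with early stopping at 10
rounds on the held-out fold; the winner refits on all training data at
the mean stopped round count. No class reweighting by default (a
positive-class weight is exposed). The recurrent variant is a
two-layer GRU (64 hidden units each) implemented on numpy, trained
with Adam and early stopping (patience 10 epochs) on a 20% stratified
holdout, restoring the best-epoch weights; training is bit-reproducible
under a seed in single-threaded runs. The hybrid variant feeds the
GRU's final hidden state, concatenated with the static features, to
the boosted stage. Feature-schema hashes are verified at predict time.

## Evaluation

AUROC via the tie-corrected Mann–Whitney rank identity; AUPRC by
step-wise interpolation (average precision — PR conventions differ, so
this is pinned). Threshold metrics use score ≥ threshold ⇒ positive;
the operating threshold maximizes Youden's J on the evaluated scores
unless supplied explicitly. Confidence intervals are percentile
intervals (not BCa, for parity with common practice) over 1,000
class-stratified episode-level resamples; resamples on which a metric
is undefined are redrawn with a cap. Shapley attributions are
interventional with a background sample: exact coalition enumeration
up to 12 features, seeded permutation sampling beyond; both satisfy
local accuracy exactly (permutation marginal contributions telescope).
The indicator-frequency-deviation statistic counts observations per
episode within cumulative windows from admission (2/6/8 h by default)
and differences two cohorts, negative meaning the second cohort
records the indicator more often.

## Alerting

Scheme A maps scores to low [0.5, 0.6), medium [0.6, 0.8), high
[0.8, ∞) — closed below, open above; scheme B is nested thresholds
(tier1 > 0.65, tier2 > 0.80, tier3 > 0.90) resolved to the highest
match. Replay steps hourly (matching the hourly bank) from
reference − 12 h to the reference, re-imputing with data up to each
step and scoring with the horizon-0 model (current-state risk); an
alert fires on each upward tier change. Lead time = onset − first
qualifying alert; the cohort summary reports median, IQR, max and
alert-sensitivity, covering both "median lead" and "up to" readings.
Episode-level κ binarizes as "any qualifying alert at or before the
reference" versus the confirmed label — the binarization is a
documented, configurable choice.

## Synthetic cohorts

The generator emulates the study conditions the pipeline assumes:
default 26.2% septic prevalence with *exact* class counts
(floor(n × prevalence), assigned by seeded permutation), septic onsets
uniform on [18, 60] h so a full trailing window always exists, control
anchors drawn the same way. Per variable: log-normal inter-observation
gaps parameterized by their 70th percentile (σ = 0.6 on the log scale),
a persistent per-episode offset plus a stationary OU component
(τ = 24 h) plus measurement noise, values clipped to plausible ranges,
and episode-level missingness (default 5%). Septic episodes add a
linear deterioration ramp over the final 12 h before onset — lactate,
heart rate, respiratory rate, WBC, temperature, CRP, glucose and base
deficit drift up; blood pressures, pH, SpO₂ and consciousness score
drift down — with slopes sized to roughly 1–4 within-episode noise
standard deviations at onset. Interventions are onset-locked with
fixed probabilities. Everything is deterministic in
(cohort seed, episode index), independent of cohort ordering.

**What passing tests show — and don't.** The generator produces
Gaussian, stationary-plus-ramp signals with log-normal gap times and
exactly the low-rank cross-variable structure the GP assumes. Real
EHR data have informative sampling (sicker children are measured more
often), non-Gaussian labs, age-dependent reference ranges,
documentation artifacts and label noise — none of which are modeled.
Synthetic results therefore validate the *mechanics* (window recovery,
imputation accuracy relative to mean imputation, horizon-decaying
discrimination, leakage freedom, calibration of the bootstrap), not
clinical performance on any real cohort.

## Problem sizes and determinism in the shipped tests

The suite exercises cohorts of 60–220 episodes, horizon subsets
{0, 3, 6, 9, 12}, 20 replicate cohorts of 500 episodes for
window-count recovery, and 200 repetitions × 1,000 replicates for
bootstrap coverage — sizes at which every statistical property checked
is comfortably resolved. All randomness is seeded; hypothesis-based
property tests are derandomized by fixed seeds.

## Known limitations

* Dense GP conditioning is O(m³) per episode in the number of in-span
  observations — appropriate for desk-scale cohorts, not for
  population-scale streaming.
* The merge rule's λ is heuristic; no likelihood combines the window
  estimate with the GP posterior.
* Permutation Shapley beyond 12 features is Monte-Carlo in attribution
  values (local accuracy still exact).
* The replay simulator scores with the horizon-0 model only; a
  deployment could fuse all 13 horizon scores.
* Tabular and sequence variants share imputed grids; no end-to-end
  uncertainty propagation from the GP into the classifier.
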