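# sepsiswatch

Early-warning pipeline for pediatric sepsis from irregular electronic
health record (EHR) time series.

Pediatric sepsis presents heterogeneously and deteriorates quickly;
vital signs are charted every few hours while key labs (lactate,
creatinine, blood gas) may be days apart and frequently missing. This
package implements, as a tested and reusable library + CLI, a complete
forecasting pipeline for that setting:

1. **CTWH window estimation** — for each clinical variable, an
   interpolation *window size* `W_v` is the 70% quantile of its pooled
   within-episode inter-measurement intervals, and a *window count*
   `N_v` is how many successive historical windows remain informative,
   judged by the across-episode Pearson correlation of window means
   staying above r = 0.6. The *span* `W_v × N_v` bounds how far back
   imputation may look for that variable.
2. **Multitask Gaussian-process imputation** — a dense multitask GP
   (low-rank cross-variable covariance, Ornstein–Uhlenbeck time kernel,
   per-variable length scales tied to `W_v`) imputes each episode's
   retained variables onto a regular hourly grid over the trailing 12 h
   window, with posterior uncertainty. Grid values are merged with a
   correlation-weighted window estimate: `λ·ctwh + (1−λ)·gp`.
3. **Horizon model bank** — 13 independent risk models, one per
   forecast horizon T = 0…12 h before onset. Variants: gradient
   boosting (XGBoost) on grid summaries, a two-layer GRU sequence
   classifier, or a hybrid feeding GRU embeddings into the boosted
   stage. Hyperparameters by stratified 5-fold CV with early stopping
   at 10 rounds.
4. **Evaluation** — AUROC (Mann–Whitney identity), AUPRC, sensitivity,
   specificity, accuracy, Youden's J = Se + Sp − 1, Brier score, with
   percentile bootstrap CIs (1,000 class-stratified episode resamples),
   interventional Shapley attributions with exact local accuracy, and a
   cohort indicator-frequency-deviation statistic.
5. **Alert simulation** — hourly retrospective replay using only past
   data, two tier schemes (low/medium/high at 0.5/0.6/0.8, or nested
   tiers at 0.65/0.80/0.90), lead-time statistics (median, IQR, max),
   and Cohen's κ agreement with confirmed episode labels.

Because real pediatric cohorts of this kind are not redistributable,
the package ships a first-class synthetic cohort generator
(`sepsiswatch.synthetic`) reproducing the statistical structure the
pipeline assumes: 26.2% septic prevalence, 28 dynamic variables with
per-variable irregular sampling and missingness, and a pre-onset
deterioration signature (rising lactate/heart rate, falling blood
pressure/pH). All of its randomness is seeded and label balance is
exact by construction.

## Worked example

```python
from sepsiswatch import CohortSpec, generate_cohort, run_pipeline
from sepsiswatch.evaluation import evaluate_bank

cohort = generate_cohort(CohortSpec(n_patients=150, seed=7))
result = run_pipeline(cohort, horizons=(0, 4, 8, 12), seed=0)

for v in ("LAC", "PH", "Cr"):
    w, n, span = result.windows.entries[v]
    print(f"{v}: window {w:.1f} h x {n} -> span {span:.1f} h")

table = evaluate_bank(result.bank, result.test_datasets, b_boot=1000, seed=0)
print(table.to_frame()[["horizon_h", "auroc", "auroc_lo", "auroc_hi",
                        "sensitivity", "specificity", "youden", "brier"]]
      .round(3).to_string(index=False))
```

prints

```
LAC: window 12.1 h x 1 -> span 12.1 h
PH: window 8.9 h x 1 -> span 8.9 h
Cr: window 19.9 h x 3 -> span 59.7 h
 horizon_h  auroc  auroc_lo  auroc_hi  sensitivity  specificity  youden  brier
         0  1.000     1.000     1.000        1.000        1.000   1.000  0.001
         4  0.957     0.856     1.000        0.917        1.000   0.917  0.044
         8  0.610     0.401     0.821        0.500        0.788   0.288  0.188
        12  0.629     0.460     0.785        1.000        0.333   0.333  0.207
```

Sparse labs (Cr) earn long multi-window spans; fast-moving variables
(pH) get short ones. Held-out discrimination is near-perfect at
diagnosis time and decays toward chance at the 12 h horizon — the
synthetic deterioration signal ramps up only over the final 12 h before
onset, so distant cutoffs contain little signal. Confidence intervals
at this cohort size (150 episodes) are wide; the `youden` column always
recomputes exactly from its own `sensitivity`/`specificity` columns.

## Command line

```bash
sepsiswatch synth --n 500 --prevalence 0.262 --seed 7 --out data/
sepsiswatch fit-windows --events data/events.csv --episodes data/episodes.csv --out windows.yaml
sepsiswatch train --events data/events.csv --episodes data/episodes.csv \
    --interventions data/interventions.csv --horizons 0-12 --out metrics.csv
sepsiswatch simulate-alerts --events data/events.csv --episodes data/episodes.csv \
    --scheme A --out alerts.json
```

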