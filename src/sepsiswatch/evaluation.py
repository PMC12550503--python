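"""Metrics, bootstrap confidence intervals, Shapley attributions, and
cohort-comparison statistics.

AUROC is the tie-corrected probability of concordance, computed through
the Mann–Whitney rank identity; AUPRC uses step-wise interpolation (the
average-precision convention, via scikit-learn). Threshold metrics use the convention
score ≥ threshold ⇒ predicted positive. Confidence intervals are
percentile intervals over class-stratified episode-level bootstrap
resamples (default 1,000 replicates).

Shapley attributions are interventional: the value of a coalition S is
the model's expected output with features outside S replaced by
background rows. Exact coalition enumeration is used up to 12 features;
beyond that, permutation sampling — whose attributions still satisfy
local accuracy exactly, because each permutation's marginal
contributions telescope to f(x) − E[f(background)].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, brier_score_loss

from .features import HorizonDataset
from .models import ModelBank


class MetricError(ValueError):
    """Metric undefined for the given inputs (e.g. single-class labels)."""


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve; ties counted half.

    Computed through the Mann–Whitney identity
    AUROC = (R₁ − n₁(n₁+1)/2) / (n₀ n₁) with midranks, which is the
    probability a random positive outscores a random negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise MetricError("AUROC undefined: only one class present")
    r = rankdata(scores)
    u = float(r[labels].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n0 * n1)


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision–recall curve, step-interpolated."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise MetricError("AUPRC undefined: no positives")
    return float(average_precision_score(labels, scores))


def confusion_at(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) at score ≥ threshold ⇒ positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(labels)
    return sens, spec, acc


def youden(sensitivity: float, specificity: float) -> float:
    """Youden's J = sensitivity + specificity − 1."""
    return sensitivity + specificity - 1.0


def brier(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean squared error of probabilities against binary outcomes."""
    scores = np.asarray(scores, dtype=float)
    if np.any((scores < 0) | (scores > 1)):
        raise MetricError("Brier score requires probabilities in [0, 1]")
    return float(brier_score_loss(np.asarray(labels).astype(int), scores))


def youden_optimal_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Operating threshold maximizing Youden's J over observed scores."""
    candidates = np.unique(np.asarray(scores, dtype=float))
    best_t, best_j = 0.5, -np.inf
    for t in candidates:
        s, p, _ = confusion_at(scores, labels, t)
        j = youden(s, p)
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(
    metric_fn,
    scores: np.ndarray,
    labels: np.ndarray,
    b: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    max_redraws: int = 100,
) -> tuple[float, float, float]:
    """Percentile interval over class-stratified episode resamples.

    Resamples on which the metric is undefined are redrawn (capped).
    Deterministic under the seed.
    """
    if b < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    point = metric_fn(scores, labels)
    rng = np.random.default_rng(seed)
    idx_by_class = [np.where(labels == c)[0] for c in (0, 1)]
    stats = np.empty(b)
    redraws = 0
    for i in range(b):
        while True:
            take = np.concatenate(
                [rng.choice(idx, size=len(idx), replace=True) for idx in idx_by_class if len(idx)]
            )
            try:
                stats[i] = metric_fn(scores[take], labels[take])
                break
            except (MetricError, ValueError):
                redraws += 1
                if redraws > max_redraws:
                    raise MetricError("metric undefined on too many bootstrap resamples")
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(point), float(lo), float(hi)


# ---------------------------------------------------------------------------
# Shapley attributions
# ---------------------------------------------------------------------------

@dataclass
class AttributionReport:
    """Per-feature attribution summary plus per-instance values."""

    feature_names: list[str]
    phi: np.ndarray          # instances × features
    base_value: float
    predictions: np.ndarray  # model outputs on the explained instances

    @property
    def mean_abs(self) -> np.ndarray:
        return np.abs(self.phi).mean(axis=0)

    @property
    def mean_signed(self) -> np.ndarray:
        return self.phi.mean(axis=0)

    def ranking(self) -> list[str]:
        order = np.argsort(self.mean_abs)[::-1]
        return [self.feature_names[i] for i in order]

    def local_accuracy_error(self) -> float:
        """max |base + Σφ − f(x)| over the explained instances."""
        recon = self.base_value + self.phi.sum(axis=1)
        return float(np.max(np.abs(recon - self.predictions)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "mean_abs_shap": self.mean_abs,
                "mean_shap": self.mean_signed,
            }
        ).sort_values("mean_abs_shap", ascending=False, ignore_index=True)


def _coalition_value(
    predict_fn, x_row: np.ndarray, background: np.ndarray, mask: np.ndarray
) -> float:
    """E_b[f(x_S, b_{\\S})]: background rows with coalition features set to x."""
    data = background.copy()
    data[:, mask] = x_row[mask]
    return float(np.mean(predict_fn(data)))


def shapley_attributions(
    predict_fn,
    x: np.ndarray,
    background: np.ndarray,
    feature_names: list[str] | None = None,
    n_permutations: int = 64,
    exact_max_features: int = 12,
    seed: int = 0,
) -> AttributionReport:
    """Interventional Shapley values for each row of ``x``.

    ``predict_fn`` maps an (n, M) array to n scalar outputs (for a
    classifier, pass the positive-class probability). Exact coalition
    enumeration when M ≤ ``exact_max_features``; seeded permutation
    sampling otherwise.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    n, m = x.shape
    if background.shape[1] != m:
        raise ValueError("background feature count differs from x")
    names = feature_names or [f"f{j}" for j in range(m)]
    if len(names) != m:
        raise ValueError("feature_names length differs from x columns")
    base = float(np.mean(predict_fn(background)))
    phi = np.zeros((n, m))
    rng = np.random.default_rng(seed)

    from math import factorial

    for i in range(n):
        row = x[i]
        cache: dict[int, float] = {}

        def value(mask_bits: int) -> float:
            if mask_bits not in cache:
                mask = np.array([(mask_bits >> j) & 1 for j in range(m)], dtype=bool)
                cache[mask_bits] = _coalition_value(predict_fn, row, background, mask)
            return cache[mask_bits]

        if m <= exact_max_features:
            for j in range(m):
                others = [k for k in range(m) if k != j]
                total = 0.0
                for size in range(m):
                    w = factorial(size) * factorial(m - size - 1) / factorial(m)
                    for subset in combinations(others, size):
                        bits = sum(1 << k for k in subset)
                        total += w * (value(bits | (1 << j)) - value(bits))
                phi[i, j] = total
        else:
            for _ in range(n_permutations):
                order = rng.permutation(m)
                bits = 0
                prev = value(0)
                for j in order:
                    bits |= 1 << int(j)
                    cur = value(bits)
                    phi[i, j] += (cur - prev) / n_permutations
                    prev = cur
    preds = np.asarray(predict_fn(x), dtype=float)
    return AttributionReport(names, phi, base, preds)


# ---------------------------------------------------------------------------
# cohort-comparison statistic
# ---------------------------------------------------------------------------

def indicator_frequency_deviation(
    cohort_a,
    cohort_b,
    cumulative_windows_h: tuple[float, ...] = (2.0, 6.0, 8.0),
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Per-indicator cumulative-frequency difference between two cohorts.

    freq(v, w) = total observation count of variable v within the first
    w hours of each episode / number of episodes; the deviation is
    freq_a − freq_b (negative ⇒ cohort b records the indicator more
    often). Rows: variables; columns: one per cumulative window.
    """
    if not cohort_a or not cohort_b:
        raise ValueError("both cohorts must be non-empty")

    def freq(cohort, variable, w):
        total = sum(
            int(np.sum(ep.times_values(variable)[0] <= w)) for ep in cohort
        )
        return total / len(cohort)

    if variables is None:
        seen = set()
        for cohort in (cohort_a, cohort_b):
            for ep in cohort:
                seen.update(o.variable for o in ep.observations)
        variables = sorted(seen)
    rows = {
        v: [freq(cohort_a, v, w) - freq(cohort_b, v, w) for w in cumulative_windows_h]
        for v in variables
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"{w:g}h" for w in cumulative_windows_h]
    )


# ---------------------------------------------------------------------------
# per-horizon evaluation table
# ---------------------------------------------------------------------------

@dataclass
class MetricsTable:
    """Per-horizon metrics with bootstrap confidence intervals."""

    rows: list[dict] = field(default_factory=list)
    n_boot: int = 1000

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float | None = None,
    b_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """All headline metrics for one score vector, CIs for the rank metrics."""
    thr = youden_optimal_threshold(scores, labels) if threshold is None else threshold
    sens, spec, acc = confusion_at(scores, labels, thr)
    au, au_lo, au_hi = bootstrap_ci(auroc, scores, labels, b=b_boot, seed=seed)
    ap, ap_lo, ap_hi = bootstrap_ci(auprc, scores, labels, b=b_boot, seed=seed + 1)
    return {
        "auroc": au, "auroc_lo": au_lo, "auroc_hi": au_hi,
        "auprc": ap, "auprc_lo": ap_lo, "auprc_hi": ap_hi,
        "accuracy": acc, "sensitivity": sens, "specificity": spec,
        "youden": youden(sens, spec),
        "brier": brier(scores, labels),
        "threshold": thr,
        "n": int(len(labels)),
    }


def evaluate_bank(
    bank: ModelBank,
    datasets: dict[int, HorizonDataset],
    strata: dict[str, np.ndarray] | None = None,
    b_boot: int = 1000,
    seed: int = 0,
    thresholds: dict[int, float] | None = None,
) -> MetricsTable:
    """Full per-horizon table on held-out datasets.

    The operating threshold per horizon maximizes Youden's J on the
    evaluated scores unless explicit thresholds are supplied. Optional
    ``strata`` maps stratum name → boolean episode mask; strata with one
    class are skipped with a warning.
    """
    table = MetricsTable(n_boot=b_boot)
    for t in bank.horizons:
        if t not in datasets:
            continue
        ds = datasets[t]
        scores = bank.models[t].predict(ds)
        thr = thresholds.get(t) if thresholds else None
        row = {"horizon_h": t, "stratum": "all"}
        row.update(evaluate_scores(scores, ds.labels, thr, b_boot, seed + t))
        table.rows.append(row)
        for name, mask in (strata or {}).items():
            sub_labels = ds.labels[mask]
            if len(np.unique(sub_labels)) < 2:
                warnings.warn(f"stratum {name!r} at horizon {t} has one class; skipped",
                              stacklevel=2)
                continue
            row = {"horizon_h": t, "stratum": name}
            row.update(evaluate_scores(scores[mask], sub_labels, thr, b_boot, seed + t))
            table.rows.append(row)
    return table
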