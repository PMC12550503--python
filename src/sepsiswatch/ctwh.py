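"""Continuous time-window histogram (CTWH) window estimation.

Irregularly sampled clinical variables differ wildly in how often they
are recorded, so a single interpolation horizon misfits most of them.
This stage sizes a per-variable interpolation window from the data:

1. ``window_size`` — the 70% quantile (configurable) of the pooled
   within-episode inter-measurement intervals; a variable measured every
   few hours gets a short window, a sparse lab a long one.
2. ``window_count`` — how many successive historical windows remain
   informative about the current one, judged by the Pearson correlation
   of across-episode window means: counting stops at the first lag whose
   correlation drops to the threshold (default 0.6) or below.
3. ``interpolation_span`` — window size × window count, the maximum
   look-back the imputation stage may use for that variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ehr import Episode
from .panel import CtwhConfig, FeaturePanel


class WindowEstimationError(ValueError):
    """Raised when a variable has too little data to size a window."""


@dataclass
class IntervalHistogram:
    """Pooled within-episode inter-observation gaps for one variable."""

    variable: str
    intervals_h: np.ndarray
    quantile_q: float = 0.70

    @property
    def quantile_value_h(self) -> float:
        return window_size(self, self.quantile_q)


@dataclass
class WindowCorrelation:
    """Across-episode correlation of window means, per lag."""

    variable: str
    r_by_lag: dict[int, float]
    n_pairs_by_lag: dict[int, int]


@dataclass
class WindowConfig:
    """Per-variable (window size, window count, span) — the machine form
    of the fitted interpolation-window table."""

    entries: dict[str, tuple[float, int, float]] = field(default_factory=dict)
    exclusions: dict[str, str] = field(default_factory=dict)
    # fitted lag correlations r_1..r_{N-1} per variable (lag-0 weight is 1)
    correlations: dict[str, list[float]] = field(default_factory=dict)

    def window_size_h(self, variable: str) -> float:
        return self.entries[variable][0]

    def n_windows(self, variable: str) -> int:
        return self.entries[variable][1]

    def span_h(self, variable: str) -> float:
        return self.entries[variable][2]

    def __contains__(self, variable: str) -> bool:
        return variable in self.entries

    def to_dict(self) -> dict:
        out = {}
        for v, (w, n, s) in sorted(self.entries.items()):
            out[v] = {"window_size_h": w, "n_windows": n, "span_h": s}
            if v in self.correlations:
                out[v]["correlations"] = [float(r) for r in self.correlations[v]]
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "WindowConfig":
        entries = {
            v: (float(e["window_size_h"]), int(e["n_windows"]), float(e["span_h"]))
            for v, e in d.items()
        }
        correlations = {
            v: [float(r) for r in e["correlations"]]
            for v, e in d.items()
            if "correlations" in e
        }
        return cls(entries=entries, correlations=correlations)


def interval_histogram(
    episodes: list[Episode],
    variable: str,
    per_patient: bool = False,
) -> IntervalHistogram:
    """Pool consecutive within-episode observation gaps for ``variable``.

    Episodes with fewer than two observations of the variable contribute
    nothing. With ``per_patient=True`` each episode contributes its
    median gap instead of all gaps (an alternative reading of the
    per-patient quantile plots).
    """
    pooled: list[float] = []
    for ep in episodes:
        t, _ = ep.times_values(variable)
        if len(t) < 2:
            continue
        gaps = np.diff(t)
        gaps = gaps[gaps > 0]
        if len(gaps) == 0:
            continue
        if per_patient:
            pooled.append(float(np.median(gaps)))
        else:
            pooled.extend(gaps.tolist())
    if not pooled:
        raise WindowEstimationError(
            f"cannot estimate window for {variable!r}: no episode has >=2 observations"
        )
    return IntervalHistogram(variable, np.asarray(pooled, dtype=float))


def window_size(hist: IntervalHistogram, q: float = 0.70) -> float:
    """q-quantile of the interval histogram, linear between closest ranks."""
    if len(hist.intervals_h) == 0:
        raise WindowEstimationError(f"{hist.variable}: empty interval set")
    w = float(np.quantile(hist.intervals_h, q, method="linear"))
    if w <= 0:
        raise WindowEstimationError(f"{hist.variable}: non-positive window size")
    return w


def window_means(
    episode: Episode,
    variable: str,
    anchor_h: float,
    window_size_h: float,
    n_windows: int,
) -> np.ndarray:
    """Mean observation value in each trailing window T_k, k = 0..n-1.

    Window T_k covers [anchor − (k+1)·W, anchor − k·W); empty windows
    yield NaN.
    """
    t, v = episode.times_values(variable)
    out = np.full(n_windows, np.nan)
    for k in range(n_windows):
        hi = anchor_h - k * window_size_h
        lo = anchor_h - (k + 1) * window_size_h
        mask = (t >= lo) & (t < hi)
        if mask.any():
            out[k] = float(np.mean(v[mask]))
    return out


def window_correlation(
    episodes: list[Episode],
    variable: str,
    window_size_h: float,
    cfg: CtwhConfig,
) -> WindowCorrelation:
    """Pearson correlation between the current window mean (T0) and each
    successive window mean (T_k), paired across episodes, complete pairs
    only."""
    if window_size_h <= 0:
        raise WindowEstimationError(f"{variable}: window size must be > 0")
    means = np.array(
        [
            window_means(ep, variable, ep.reference_time_h, window_size_h, cfg.max_windows + 1)
            for ep in episodes
        ]
    )
    r_by_lag: dict[int, float] = {}
    n_by_lag: dict[int, int] = {}
    for lag in range(1, cfg.max_windows + 1):
        pair = means[:, [0, lag]]
        ok = ~np.isnan(pair).any(axis=1)
        n = int(ok.sum())
        n_by_lag[lag] = n
        if n >= 2 and np.std(pair[ok, 0]) > 0 and np.std(pair[ok, 1]) > 0:
            r_by_lag[lag] = float(np.corrcoef(pair[ok, 0], pair[ok, 1])[0, 1])
        else:
            r_by_lag[lag] = float("nan")
    return WindowCorrelation(variable, r_by_lag, n_by_lag)


def window_count(
    episodes: list[Episode],
    variable: str,
    window_size_h: float,
    cfg: CtwhConfig | None = None,
) -> tuple[int, WindowCorrelation]:
    """Number of referenced windows: 1 + the longest run of leading lags
    whose correlation strictly exceeds the threshold.

    The current window is always usable, so N >= 1; counting is
    sequential (stops at the first lag at or below the threshold) so the
    referenced history has no gaps. With fewer than ``cfg.min_pairs``
    complete pairs at lag 1 the estimate falls back to N = 1.
    """
    cfg = cfg or CtwhConfig()
    corr = window_correlation(episodes, variable, window_size_h, cfg)
    if corr.n_pairs_by_lag.get(1, 0) < cfg.min_pairs:
        return 1, corr
    n = 1
    for lag in range(1, cfg.max_windows + 1):
        r = corr.r_by_lag.get(lag, float("nan"))
        if np.isnan(r) or r <= cfg.r_threshold:
            break
        n = lag + 1
    return min(n, cfg.max_windows), corr


def interpolation_span(window_size_h: float, n_windows: int) -> float:
    """span = window size × window count (hours)."""
    if window_size_h <= 0 or n_windows <= 0:
        raise ValueError("window size and count must be positive")
    return window_size_h * n_windows


def build_window_config(
    episodes: list[Episode],
    panel: FeaturePanel,
    cfg: CtwhConfig | None = None,
    variables: list[str] | None = None,
) -> WindowConfig:
    """Fit (W, N, span) for every retained variable of the panel.

    Variables whose intervals cannot be estimated are excluded with a
    reason instead of failing the whole fit.
    """
    cfg = cfg or CtwhConfig()
    out = WindowConfig()
    for code in variables if variables is not None else panel.dynamic_codes:
        try:
            hist = interval_histogram(episodes, code, per_patient=cfg.per_patient_quantile)
            w = window_size(hist, cfg.quantile_q)
            n, corr = window_count(episodes, code, w, cfg)
            out.entries[code] = (w, n, interpolation_span(w, n))
            if n > 1:
                out.correlations[code] = [corr.r_by_lag[lag] for lag in range(1, n)]
        except WindowEstimationError as err:
            out.exclusions[code] = str(err)
    return out
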