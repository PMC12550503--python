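"""Tiered alerts, retrospective replay, lead time and agreement statistics.

Two preset tier schemes ship, reflecting the two deployment descriptions
the framework supports:

* ``scheme_A`` — low [0.5, 0.6), medium [0.6, 0.8), high [0.8, ∞):
  half-open intervals, closed below.
* ``scheme_B`` — Tier 1 (P > 0.65), Tier 2 (P > 0.80), Tier 3
  (P > 0.90): nested thresholds resolved to the highest matching tier.

The replay simulator walks an episode hour by hour, re-imputes the
trailing grid using only data up to the replay time, scores it with the
horizon-0 model, and emits an alert whenever the mapped tier rises.
Lead time is onset minus the first qualifying alert time; agreement
with confirmed labels uses Cohen's κ on an episode-level binarization
(any qualifying alert at or before onset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ctwh import WindowConfig
from .ehr import Episode
from .features import assemble_horizon
from .mgp import MgpConfig, MgpHyperparameters, impute_episode
from .models import ModelBank
from .panel import FeaturePanel

NO_ALERT = "none"


@dataclass
class TierScheme:
    """Ordered score intervals; higher tiers win on overlap."""

    name: str
    tiers: list[tuple[str, float, float]]  # (label, lower, upper); upper may be inf

    def __post_init__(self) -> None:
        lowers = [lo for _, lo, _ in self.tiers]
        if lowers != sorted(lowers) or len(set(lowers)) != len(lowers):
            raise ValueError(f"{self.name}: tier lower bounds must be strictly increasing")
        for label, lo, hi in self.tiers:
            if not lo < hi:
                raise ValueError(f"{self.name}/{label}: lower bound must be < upper bound")

    @property
    def labels(self) -> list[str]:
        return [label for label, _, _ in self.tiers]

    def level(self, tier: str) -> int:
        """Ordinal level of a tier label; none = 0."""
        if tier == NO_ALERT:
            return 0
        return self.labels.index(tier) + 1


SCHEME_A = TierScheme(
    "scheme_A",
    [("low", 0.5, 0.6), ("medium", 0.6, 0.8), ("high", 0.8, float("inf"))],
)
SCHEME_B = TierScheme(
    "scheme_B",
    [("tier1", 0.65, float("inf")), ("tier2", 0.80, float("inf")), ("tier3", 0.90, float("inf"))],
)
PRESETS = {"A": SCHEME_A, "B": SCHEME_B}


def map_tier(score: float, scheme: TierScheme) -> str:
    """Highest tier whose interval contains the score (closed below,
    open above); scores below every lower bound map to ``none``."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score must lie in [0, 1], got {score}")
    matched = NO_ALERT
    for label, lo, hi in scheme.tiers:
        if lo <= score < hi:
            matched = label
    return matched


@dataclass
class AlertEvent:
    episode_id: str
    time_h: float
    tier: str
    score: float


@dataclass
class AlertTrace:
    """Hourly scores and upward tier-change alerts for one episode replay."""

    episode_id: str
    times_h: list[float] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    tiers: list[str] = field(default_factory=list)
    alerts: list[AlertEvent] = field(default_factory=list)


def simulate_alerts(
    bank: ModelBank,
    episodes: list[Episode],
    panel: FeaturePanel,
    windows: WindowConfig,
    scheme: TierScheme = SCHEME_A,
    mgp_cfg: MgpConfig | None = None,
    hypers: MgpHyperparameters | None = None,
    step_h: float = 1.0,
    start_offset_h: float = 12.0,
    horizon: int = 0,
) -> dict[str, AlertTrace]:
    """Replay each episode hourly from ``reference − start_offset`` to the
    reference time, scoring with the horizon model using only data up to
    each step. An alert is emitted whenever the tier rises."""
    if horizon not in bank.models:
        raise ValueError(f"bank has no model for horizon {horizon}")
    traces: dict[str, AlertTrace] = {}
    for ep in episodes:
        trace = AlertTrace(ep.episode_id)
        current_level = 0
        t = ep.reference_time_h - start_offset_h
        while t <= ep.reference_time_h + 1e-9:
            grid = impute_episode(
                ep, panel, windows, mgp_cfg, hypers, cutoff_h=t, grid_hours=12.0
            )
            ds = assemble_horizon_at(ep, grid, horizon)
            score = float(bank.models[horizon].predict(ds)[0])
            tier = map_tier(score, scheme)
            trace.times_h.append(float(t))
            trace.scores.append(score)
            trace.tiers.append(tier)
            level = scheme.level(tier)
            if level > current_level:
                trace.alerts.append(AlertEvent(ep.episode_id, float(t), tier, score))
            current_level = level
            t += step_h
        traces[ep.episode_id] = trace
    return traces


def assemble_horizon_at(ep: Episode, grid, horizon: int):
    """Single-episode dataset built from one already-imputed grid."""
    return assemble_horizon([ep_with_reference(ep, grid.cutoff_h + horizon)],
                            {(ep.episode_id, horizon): grid}, horizon)


def ep_with_reference(ep: Episode, reference_h: float) -> Episode:
    """Copy of an episode with its anchor moved (replay bookkeeping)."""
    from dataclasses import replace

    if ep.septic:
        return replace(ep, onset_time_h=reference_h)
    return replace(ep, anchor_time_h=reference_h)


@dataclass
class LeadTimeSummary:
    median_h: float
    iqr_h: tuple[float, float]
    max_h: float
    alert_sensitivity: float
    lead_times_h: dict[str, float]


def lead_time(
    trace: AlertTrace,
    onset_time_h: float,
    scheme: TierScheme,
    qualifying_tier: str,
) -> float | None:
    """Onset time minus first alert at or above the qualifying tier."""
    min_level = scheme.level(qualifying_tier)
    for ev in trace.alerts:
        if scheme.level(ev.tier) >= min_level:
            return onset_time_h - ev.time_h
    return None


def lead_time_summary(
    traces: dict[str, AlertTrace],
    episodes: list[Episode],
    scheme: TierScheme,
    qualifying_tier: str,
) -> LeadTimeSummary:
    """Cohort lead-time statistics over septic episodes."""
    septic = [ep for ep in episodes if ep.septic]
    if not septic:
        raise ValueError("lead time requires septic episodes with onsets")
    leads: dict[str, float] = {}
    for ep in septic:
        lt = lead_time(traces[ep.episode_id], ep.onset_time_h, scheme, qualifying_tier)
        if lt is not None:
            leads[ep.episode_id] = lt
    values = np.array(sorted(leads.values()))
    if len(values) == 0:
        return LeadTimeSummary(float("nan"), (float("nan"), float("nan")),
                               float("nan"), 0.0, leads)
    return LeadTimeSummary(
        median_h=float(np.median(values)),
        iqr_h=(float(np.quantile(values, 0.25)), float(np.quantile(values, 0.75))),
        max_h=float(values.max()),
        alert_sensitivity=len(values) / len(septic),
        lead_times_h=leads,
    )


def episode_alert_labels(
    traces: dict[str, AlertTrace],
    episodes: list[Episode],
    scheme: TierScheme,
    qualifying_tier: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Episode-level binarization for agreement: predicted positive iff
    any qualifying alert at or before the reference time; confirmed
    positive iff the episode is septic."""
    predicted, confirmed = [], []
    min_level = scheme.level(qualifying_tier)
    for ep in episodes:
        trace = traces[ep.episode_id]
        any_alert = any(scheme.level(ev.tier) >= min_level for ev in trace.alerts)
        predicted.append(int(any_alert))
        confirmed.append(int(ep.septic))
    return np.asarray(predicted), np.asarray(confirmed)


def cohens_kappa(predicted: np.ndarray, confirmed: np.ndarray) -> float:
    """Chance-corrected agreement κ = (p_o − p_e) / (1 − p_e)."""
    predicted = np.asarray(predicted).astype(int)
    confirmed = np.asarray(confirmed).astype(int)
    if predicted.shape != confirmed.shape or predicted.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d label vectors")
    n = len(predicted)
    p_o = float(np.mean(predicted == confirmed))
    p_e = 0.0
    for c in (0, 1):
        p_e += float(np.mean(predicted == c)) * float(np.mean(confirmed == c))
    if abs(1.0 - p_e) < 1e-12:
        raise ValueError("kappa undefined: both raters are constant")
    return (p_o - p_e) / (1.0 - p_e)


def outcome_contrast(rate_a: float, rate_b: float) -> tuple[float, float]:
    """Absolute and relative reduction between two percentage rates.

    absolute = rate_a − rate_b; relative = 100 × absolute / rate_a.
    """
    for r in (rate_a, rate_b):
        if not 0.0 <= r <= 100.0:
            raise ValueError("rates must be percentages in [0, 100]")
    absolute = rate_a - rate_b
    if rate_a == 0.0:
        raise ValueError("relative reduction undefined for zero baseline rate")
    return absolute, 100.0 * absolute / rate_a
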