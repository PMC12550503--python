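"""Seeded synthetic pediatric EHR cohorts.

Real cohorts behind the pipeline (a tertiary pediatric emergency
department and a pediatric ICU subset of a public critical-care
database) are not redistributable, so this module generates cohorts
with the statistical structure the pipeline assumes:

* two classes with exact septic prevalence (default 26.2%), labels
  assigned by permutation rather than Bernoulli draws;
* 28 dynamic variables with irregular, per-variable sampling — gap
  lengths are log-normal, parameterized by their 70th-percentile so the
  window-estimation stage has a known target to recover;
* per-variable episode-level missingness;
* a latent Ornstein–Uhlenbeck component plus a persistent per-episode
  offset, giving the across-episode window correlations the window-count
  stage estimates;
* a pre-onset deterioration signature in septic episodes — lactate,
  heart rate, respiratory rate, white cells and temperature ramp up
  while blood pressure, pH and SpO₂ ramp down over the final hours
  before onset — so predictive signal decays with forecast horizon;
* onset-locked intervention events (antibiotics, vasopressors,
  glucocorticoids, ventilation).

Everything is deterministic given the cohort seed, and episode content
depends only on (seed, episode index), never on cohort ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .ehr import CONTROL, SEPTIC, Episode, Observation
from .panel import FeaturePanel, default_panel

_Z70 = 0.5244005127080409  # standard normal 70% quantile


@dataclass(frozen=True)
class VariableProfile:
    """Generative parameters of one dynamic variable.

    ``interval_q70_h`` is the 70th percentile of the log-normal
    inter-observation gap distribution; ``drift_slope`` is the per-hour
    mean shift in septic episodes over the ``drift_duration_h`` hours
    ending at onset (sign encodes direction of deterioration).
    """

    baseline: float
    ou_sd: float
    meas_sd: float
    offset_sd: float
    interval_q70_h: float
    interval_sigma: float = 0.6
    tau_h: float = 24.0
    drift_slope: float = 0.0
    drift_duration_h: float = 12.0
    missing_rate: float = 0.05

    @property
    def interval_mu(self) -> float:
        """Log-scale location giving the requested 70% gap quantile."""
        return math.log(self.interval_q70_h) - self.interval_sigma * _Z70


# baseline, ou_sd, meas_sd, offset_sd, q70 gap (h), drift slope (/h)
_DEFAULT_PROFILE_TABLE: dict[str, tuple[float, float, float, float, float, float]] = {
    "T":    (37.2, 0.30, 0.15, 0.30, 5.0,  +0.10),
    "R":    (28.0, 3.0,  2.0,  3.0,  4.0,  +1.0),
    "HR":   (120.0, 8.0, 4.0,  8.0,  4.0,  +3.0),
    "MAP":  (65.0, 5.0,  3.0,  5.0,  10.0, -1.3),
    "DBP":  (50.0, 5.0,  3.0,  5.0,  10.0, -1.2),
    "SBP":  (95.0, 6.0,  3.0,  6.0,  9.0,  -1.8),
    "INR":  (1.1,  0.10, 0.05, 0.10, 24.0, +0.03),
    "WBC":  (9.5,  1.5,  0.8,  2.0,  26.0, +0.8),
    "TB":   (12.0, 2.0,  1.0,  3.0,  22.0, 0.0),
    "Cr":   (45.0, 6.0,  3.0,  10.0, 32.0, +2.0),
    "LAC":  (1.5,  0.30, 0.15, 0.30, 14.0, +0.35),
    "PLT":  (250.0, 25.0, 10.0, 40.0, 28.0, 0.0),
    "CRP":  (20.0, 6.0,  3.0,  8.0,  3.0,  +1.5),
    "SO2":  (97.0, 1.0,  0.5,  1.0,  14.0, -0.15),
    "ALB":  (38.0, 2.0,  1.0,  3.0,  20.0, 0.0),
    "HCT":  (33.0, 1.5,  0.8,  2.0,  4.0,  0.0),
    "PCO2": (40.0, 3.0,  1.5,  3.0,  22.0, 0.0),
    "ALP":  (180.0, 20.0, 10.0, 30.0, 21.0, 0.0),
    "HGB":  (110.0, 5.0, 3.0,  8.0,  3.0,  0.0),
    "K":    (4.1,  0.25, 0.10, 0.20, 15.0, 0.0),
    "BSD":  (2.0,  1.0,  0.5,  1.0,  22.0, +0.3),
    "AC":   (0.2,  0.15, 0.10, 0.10, 20.0, 0.0),
    "GCS":  (14.0, 0.5,  0.3,  0.5,  19.0, -0.15),
    "DBIL": (4.0,  1.0,  0.5,  1.0,  22.0, 0.0),
    "FIB":  (3.0,  0.30, 0.15, 0.40, 24.0, 0.0),
    "AST":  (35.0, 8.0,  4.0,  10.0, 27.0, 0.0),
    "PH":   (7.38, 0.020, 0.010, 0.020, 10.3, -0.008),
    "BG":   (5.5,  0.80, 0.40, 0.80, 12.0, +0.2),
}


def default_profiles() -> dict[str, VariableProfile]:
    return {
        code: VariableProfile(
            baseline=b, ou_sd=ou, meas_sd=ms, offset_sd=off,
            interval_q70_h=q70, drift_slope=slope,
        )
        for code, (b, ou, ms, off, q70, slope) in _DEFAULT_PROFILE_TABLE.items()
    }


# (code, probability, offset-range in hours relative to onset)
_SEPTIC_INTERVENTIONS: list[tuple[str, float, tuple[float, float]]] = [
    ("antibiotic", 0.50, (-6.0, 0.0)),
    ("vasopressor", 0.35, (-4.0, 0.0)),
    ("glucocorticoid", 0.25, (-3.0, 1.0)),
    ("ventilation", 0.20, (-2.0, 2.0)),
]
_CONTROL_INTERVENTIONS: list[tuple[str, float, tuple[float, float]]] = [
    ("antibiotic", 0.10, (-12.0, 0.0)),
    ("glucocorticoid", 0.05, (-12.0, 0.0)),
]


@dataclass
class CohortSpec:
    """Study conditions for a generated cohort."""

    n_patients: int = 200
    sepsis_prevalence: float = 0.262
    horizon_h: float = 12.0
    seed: int = 0
    profiles: dict[str, VariableProfile] = field(default_factory=default_profiles)
    onset_low_h: float = 18.0
    onset_high_h: float = 60.0
    drift_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0.0 <= self.sepsis_prevalence <= 1.0:
            raise ValueError("sepsis_prevalence must lie in [0, 1]")
        for code, p in self.profiles.items():
            if p.ou_sd <= 0 or p.meas_sd <= 0:
                raise ValueError(f"{code}: noise sds must be > 0")


def _episode_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, index)))


def _ou_path(rng: np.random.Generator, times: np.ndarray, sd: float, tau: float) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck samples at irregular times."""
    x = np.empty(len(times))
    if len(times) == 0:
        return x
    x[0] = rng.normal(0.0, sd)
    for k in range(1, len(times)):
        dt = times[k] - times[k - 1]
        rho = math.exp(-dt / tau)
        x[k] = rho * x[k - 1] + rng.normal(0.0, sd * math.sqrt(max(0.0, 1.0 - rho * rho)))
    return x


def generate_episode(
    spec: CohortSpec,
    index: int,
    septic: bool,
    panel: FeaturePanel | None = None,
) -> Episode:
    """Generate one episode; deterministic in (spec.seed, index, septic)."""
    panel = panel or default_panel()
    unknown = set(spec.profiles) - set(panel.codes)
    if unknown:
        raise ValueError(f"profile variables not in panel: {sorted(unknown)}")
    rng = _episode_rng(spec.seed, index)
    reference = rng.uniform(spec.onset_low_h, spec.onset_high_h)

    observations: list[Observation] = []
    for code in panel.dynamic_codes:
        if code not in spec.profiles:
            continue
        p = spec.profiles[code]
        # episode-level missingness: the variable was simply never ordered
        if rng.random() < p.missing_rate:
            continue
        times = []
        t = rng.uniform(0.0, p.interval_q70_h)
        while t <= reference:
            times.append(t)
            t += rng.lognormal(p.interval_mu, p.interval_sigma)
        times_arr = np.asarray(times)
        if len(times_arr) == 0:
            continue
        offset = rng.normal(0.0, p.offset_sd)
        ou = _ou_path(rng, times_arr, p.ou_sd, p.tau_h)
        noise = rng.normal(0.0, p.meas_sd, size=len(times_arr))
        values = p.baseline + offset + ou + noise
        if septic and p.drift_slope != 0.0:
            ramp_start = reference - p.drift_duration_h
            ramp = np.clip(times_arr - ramp_start, 0.0, p.drift_duration_h)
            values = values + spec.drift_scale * p.drift_slope * ramp
        vspec = panel[code]
        values = np.clip(values, vspec.plausible_low, vspec.plausible_high)
        observations.extend(
            Observation(float(tt), code, float(vv)) for tt, vv in zip(times_arr, values)
        )

    interventions: list[tuple[float, str]] = []
    table = _SEPTIC_INTERVENTIONS if septic else _CONTROL_INTERVENTIONS
    for code, prob, (lo, hi) in table:
        if rng.random() < prob:
            interventions.append((float(reference + rng.uniform(lo, hi)), code))

    return Episode(
        episode_id=f"ep{index:05d}",
        age_years=float(round(rng.uniform(0.1, 17.5), 2)),
        sex="male" if rng.random() < 0.648 else "female",
        weight_kg=float(round(max(2.5, rng.normal(11.6, 3.4)), 2)),
        label=SEPTIC if septic else CONTROL,
        onset_time_h=float(reference) if septic else None,
        anchor_time_h=None if septic else float(reference),
        observations=observations,
        interventions=interventions,
    )


def generate_cohort(spec: CohortSpec, panel: FeaturePanel | None = None) -> list[Episode]:
    """Generate a cohort with exactly ``floor(n × prevalence)`` septic episodes.

    Septic indices are a seeded permutation of the episode indices, so
    the class split is exact by construction (floor convention).
    """
    panel = panel or default_panel()
    n = spec.n_patients
    n_septic = int(math.floor(n * spec.sepsis_prevalence))
    label_rng = np.random.default_rng(np.random.SeedSequence(entropy=(spec.seed, 0xC0F0E7)))
    septic_idx = set(label_rng.permutation(n)[:n_septic].tolist())
    return [generate_episode(spec, i, i in septic_idx, panel) for i in range(n)]


def inject_missingness(
    episode: Episode,
    rates: dict[str, float],
    seed: int,
) -> Episode:
    """Drop each variable from the episode entirely with its stated rate.

    Models episode-level missingness (the panel exclusion rule's unit):
    either a variable was measured for a patient or it never was.
    Deterministic in (seed, episode_id).
    """
    for code, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{code}: missingness rate must lie in [0, 1]")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(seed, abs(hash_id(episode.episode_id))))
    )
    dropped = {code for code, rate in rates.items() if rng.random() < rate}
    if not dropped:
        return episode
    return replace(
        episode,
        observations=[o for o in episode.observations if o.variable not in dropped],
    )


def hash_id(episode_id: str) -> int:
    """Stable (non-salted) 32-bit hash of an episode id."""
    import zlib

    return zlib.crc32(episode_id.encode("utf-8"))
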