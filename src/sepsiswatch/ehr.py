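"""Domain types and long-format CSV I/O for clinical episodes.

File schema (comma-separated, UTF-8, '.' decimal):

* ``events.csv``: ``episode_id,time_h,variable,value`` — one row per
  timestamped observation.
* ``episodes.csv``: ``episode_id,age_years,sex,weight_kg,label,onset_time_h``
  — one row per encounter; ``onset_time_h`` empty for controls.
* ``interventions.csv``: ``episode_id,time_h,code`` — timed binary
  therapeutic events (antibiotic, vasopressor, glucocorticoid, ventilation).

Times are hours relative to the episode anchor (admission = 0), so the
sepsis onset time lives on the same axis as the observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import FeaturePanel

SEPTIC = "septic"
CONTROL = "control"

EVENTS_COLUMNS = ["episode_id", "time_h", "variable", "value"]
EPISODES_COLUMNS = ["episode_id", "age_years", "sex", "weight_kg", "label", "onset_time_h"]
INTERVENTIONS_COLUMNS = ["episode_id", "time_h", "code"]


class SchemaError(ValueError):
    """A required column is missing or a file-level contract is broken."""


class ValidationError(ValueError):
    """An episode violates a domain invariant."""


@dataclass(frozen=True)
class Observation:
    """A single timestamped measurement of one panel variable."""

    time_h: float
    variable: str
    value: float


@dataclass
class Episode:
    """One patient encounter: static features, observations, interventions.

    ``reference_time_h`` is the prediction anchor — the sepsis onset for
    septic episodes and a stated convention for controls. Observations
    are kept sorted non-decreasing in time.
    """

    episode_id: str
    age_years: float
    sex: str
    weight_kg: float
    label: str
    onset_time_h: float | None = None
    observations: list[Observation] = field(default_factory=list)
    interventions: list[tuple[float, str]] = field(default_factory=list)
    anchor_time_h: float | None = None

    def __post_init__(self) -> None:
        if self.label not in (SEPTIC, CONTROL):
            raise ValidationError(f"{self.episode_id}: label must be septic/control")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"{self.episode_id}: sex must be male/female")
        if self.age_years < 0:
            raise ValidationError(f"{self.episode_id}: age_years must be >= 0")
        if self.weight_kg <= 0:
            raise ValidationError(f"{self.episode_id}: weight_kg must be > 0")
        if self.label == SEPTIC and self.onset_time_h is None:
            raise ValidationError(f"{self.episode_id}: septic episode lacks onset_time_h")
        if self.label == CONTROL and self.onset_time_h is not None:
            raise ValidationError(f"{self.episode_id}: control episode has onset_time_h")
        self.sort_observations()

    @property
    def septic(self) -> bool:
        return self.label == SEPTIC

    @property
    def reference_time_h(self) -> float:
        """Prediction anchor: onset for septic episodes, anchor for controls."""
        if self.septic:
            assert self.onset_time_h is not None
            return self.onset_time_h
        if self.anchor_time_h is None:
            raise ValidationError(f"{self.episode_id}: control episode lacks anchor_time_h")
        return self.anchor_time_h

    def sort_observations(self) -> None:
        """Stable sort by (time, variable); idempotent."""
        self.observations.sort(key=lambda o: (o.time_h, o.variable))
        self.interventions.sort(key=lambda iv: (iv[0], iv[1]))

    def times_values(self, variable: str) -> tuple[np.ndarray, np.ndarray]:
        """Times and values of one variable, sorted ascending."""
        pairs = [(o.time_h, o.value) for o in self.observations if o.variable == variable]
        if not pairs:
            return np.empty(0), np.empty(0)
        t, v = zip(*pairs)
        return np.asarray(t, dtype=float), np.asarray(v, dtype=float)


@dataclass
class RejectedRow:
    """A row dropped at load time, with the reason."""

    row_index: int
    episode_id: str
    reason: str


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


def read_events(
    events_path: str | Path,
    episodes_path: str | Path,
    panel: FeaturePanel,
    interventions_path: str | Path | None = None,
    collect_rejects: bool = False,
) -> list[Episode] | tuple[list[Episode], list[RejectedRow]]:
    """Load and validate a cohort from long-format CSV files.

    Rows whose variable is not in the panel, whose value is non-numeric,
    or whose value falls outside the variable's hard physical bounds are
    dropped and reported; values outside the plausible range only warn.
    Pass ``collect_rejects=True`` to also receive the rejected-row report.
    """
    events = pd.read_csv(
        events_path, dtype={"episode_id": str, "variable": str},
        float_precision="round_trip",
    )
    _require_columns(events, EVENTS_COLUMNS, "events")
    meta = pd.read_csv(episodes_path, dtype={"episode_id": str}, float_precision="round_trip")
    _require_columns(meta, EPISODES_COLUMNS[:-1], "episodes")

    interventions: dict[str, list[tuple[float, str]]] = {}
    if interventions_path is not None and Path(interventions_path).exists():
        iv = pd.read_csv(interventions_path, dtype={"episode_id": str, "code": str})
        _require_columns(iv, INTERVENTIONS_COLUMNS, "interventions")
        for _, row in iv.iterrows():
            interventions.setdefault(row["episode_id"], []).append(
                (float(row["time_h"]), row["code"])
            )

    rejects: list[RejectedRow] = []
    obs_by_episode: dict[str, list[Observation]] = {}
    n_implausible = 0
    for idx, row in events.iterrows():
        eid = row["episode_id"]
        var = row["variable"]
        if var not in panel:
            rejects.append(RejectedRow(int(idx), eid, f"unknown variable {var!r}"))
            continue
        try:
            t = float(row["time_h"])
            val = float(row["value"])
        except (TypeError, ValueError):
            rejects.append(RejectedRow(int(idx), eid, "non-numeric time or value"))
            continue
        if not (np.isfinite(t) and np.isfinite(val)):
            rejects.append(RejectedRow(int(idx), eid, "non-finite time or value"))
            continue
        spec = panel[var]
        if not (spec.hard_low <= val <= spec.hard_high):
            rejects.append(
                RejectedRow(int(idx), eid, f"{var}={val} outside hard bounds")
            )
            continue
        if not (spec.plausible_low <= val <= spec.plausible_high):
            n_implausible += 1
        obs_by_episode.setdefault(eid, []).append(Observation(t, var, val))
    if n_implausible:
        warnings.warn(
            f"{n_implausible} observation(s) outside plausible ranges (retained)",
            stacklevel=2,
        )

    episodes: list[Episode] = []
    for _, row in meta.iterrows():
        eid = row["episode_id"]
        onset = row.get("onset_time_h")
        onset = None if pd.isna(onset) else float(onset)
        anchor = row.get("anchor_time_h") if "anchor_time_h" in meta.columns else None
        anchor = None if anchor is None or pd.isna(anchor) else float(anchor)
        episodes.append(
            Episode(
                episode_id=eid,
                age_years=float(row["age_years"]),
                sex=str(row["sex"]),
                weight_kg=float(row["weight_kg"]),
                label=str(row["label"]),
                onset_time_h=onset,
                anchor_time_h=anchor,
                observations=obs_by_episode.get(eid, []),
                interventions=interventions.get(eid, []),
            )
        )
    if collect_rejects:
        return episodes, rejects
    return episodes


def write_events(
    episodes: list[Episode],
    events_path: str | Path,
    episodes_path: str | Path | None = None,
    interventions_path: str | Path | None = None,
) -> None:
    """Write a cohort back to long-format CSV.

    Row order is deterministic: (episode_id, time_h, variable).
    """
    rows = [
        {"episode_id": ep.episode_id, "time_h": o.time_h, "variable": o.variable, "value": o.value}
        for ep in episodes
        for o in ep.observations
    ]
    events = pd.DataFrame(rows, columns=EVENTS_COLUMNS)
    events = events.sort_values(["episode_id", "time_h", "variable"], kind="stable")
    events.to_csv(events_path, index=False)

    if episodes_path is not None:
        meta = pd.DataFrame(
            [
                {
                    "episode_id": ep.episode_id,
                    "age_years": ep.age_years,
                    "sex": ep.sex,
                    "weight_kg": ep.weight_kg,
                    "label": ep.label,
                    "onset_time_h": ep.onset_time_h,
                    "anchor_time_h": ep.anchor_time_h,
                }
                for ep in episodes
            ],
            columns=EPISODES_COLUMNS + ["anchor_time_h"],
        ).sort_values("episode_id", kind="stable")
        meta.to_csv(episodes_path, index=False)

    if interventions_path is not None:
        iv_rows = [
            {"episode_id": ep.episode_id, "time_h": t, "code": code}
            for ep in episodes
            for t, code in ep.interventions
        ]
        iv = pd.DataFrame(iv_rows, columns=INTERVENTIONS_COLUMNS)
        iv = iv.sort_values(["episode_id", "time_h", "code"], kind="stable")
        iv.to_csv(interventions_path, index=False)


@dataclass
class MissingnessReport:
    """Episode-level missingness per variable plus the retention verdict."""

    fraction_missing: dict[str, float]
    retained: list[str]
    excluded: list[str]
    threshold: float


def validate_panel(episodes: list[Episode], panel: FeaturePanel) -> MissingnessReport:
    """Episode-level missingness per panel variable.

    A variable is "missing" for an episode when the episode has zero
    observations of it; variables with a missing fraction *strictly*
    above the panel threshold are flagged for exclusion (exactly at the
    threshold is retained).
    """
    if not episodes:
        raise ValidationError("cannot compute missingness on an empty cohort")
    n = len(episodes)
    fraction: dict[str, float] = {}
    for code in panel.codes:
        n_missing = sum(1 for ep in episodes if not any(o.variable == code for o in ep.observations))
        fraction[code] = n_missing / n
    thr = panel.missingness_threshold
    retained = [c for c in panel.codes if fraction[c] <= thr]
    excluded = [c for c in panel.codes if fraction[c] > thr]
    return MissingnessReport(fraction, retained, excluded, thr)
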