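"""Supervised datasets for each forecast horizon T = 0…12 h.

For horizon ``T`` the prediction cutoff of an episode is
``reference_time − T`` (onset for septic episodes, the stated anchor for
controls); every feature is computed from the imputed trailing 12-h grid
ending at that cutoff, plus static features and intervention indicators
observed at or before it. Nothing after the cutoff may influence the
row — the imputation itself conditions only on pre-cutoff observations,
so perturbing later data leaves the feature matrix bit-identical.

Tabular mode summarizes each variable's 13-point hourly series as
(last, mean, min, max, least-squares slope); sequence mode keeps the
full 13 × V tensor for the recurrent encoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .ctwh import WindowConfig
from .ehr import Episode
from .mgp import ImputedGrid, MgpConfig, MgpHyperparameters, impute_episode
from .panel import INTERVENTION_CODES, FeaturePanel

HORIZONS = tuple(range(13))
STATIC_FEATURES = ["age_years", "sex_male", "weight_kg"]
SUMMARIES = ["last", "mean", "min", "max", "slope"]


@dataclass
class HorizonDataset:
    """One-row-per-episode design matrix for a single forecast horizon."""

    horizon_h: int
    mode: str  # "tabular" or "sequence"
    feature_names: list[str]
    X: np.ndarray | None          # episodes × features (tabular)
    sequences: np.ndarray | None  # episodes × 13 × V   (sequence)
    static: np.ndarray | None     # episodes × (statics + interventions)
    labels: np.ndarray            # binary, 1 = septic
    groups: list[str]             # episode ids

    @property
    def n_episodes(self) -> int:
        return len(self.groups)


def compute_grids(
    episodes: list[Episode],
    panel: FeaturePanel,
    windows: WindowConfig,
    cfg: MgpConfig | None = None,
    hypers: MgpHyperparameters | None = None,
    horizons: tuple[int, ...] = HORIZONS,
    grid_hours: float = 12.0,
) -> dict[tuple[str, int], ImputedGrid]:
    """Impute the trailing grid of every episode at every horizon cutoff."""
    grids: dict[tuple[str, int], ImputedGrid] = {}
    for ep in episodes:
        for t in horizons:
            cutoff = ep.reference_time_h - t
            grids[(ep.episode_id, t)] = impute_episode(
                ep, panel, windows, cfg, hypers, cutoff_h=cutoff, grid_hours=grid_hours
            )
    return grids


def _slope(times: np.ndarray, values: np.ndarray) -> float:
    """Ordinary least-squares slope of values against time."""
    tc = times - times.mean()
    denom = float(tc @ tc)
    if denom == 0.0:
        return 0.0
    return float(tc @ (values - values.mean()) / denom)


def _static_vector(ep: Episode, cutoff: float) -> np.ndarray:
    iv_flags = [
        float(any(iv_code == c and t <= cutoff for t, iv_code in ep.interventions))
        for c in INTERVENTION_CODES
    ]
    return np.array(
        [ep.age_years, 1.0 if ep.sex == "male" else 0.0, ep.weight_kg] + iv_flags
    )


def assemble_horizon(
    episodes: list[Episode],
    grids: dict[tuple[str, int], ImputedGrid],
    horizon_h: int,
    mode: str = "tabular",
) -> HorizonDataset:
    """Build the supervised dataset for one horizon from precomputed grids."""
    if horizon_h not in HORIZONS:
        raise ValueError(f"horizon must be an integer in 0..12, got {horizon_h}")
    if mode not in ("tabular", "sequence"):
        raise ValueError("mode must be tabular or sequence")
    if not episodes:
        raise ValueError("empty cohort")

    first = grids[(episodes[0].episode_id, horizon_h)]
    variables = first.variables
    n_grid = len(first.grid_times_h)
    if first.grid_times_h[-1] - first.grid_times_h[0] < 12.0 - 1e-9:
        raise ValueError("grids must cover a full trailing 12 h window")

    static_names = STATIC_FEATURES + [f"any_{c}" for c in INTERVENTION_CODES]
    labels = np.array([1 if ep.septic else 0 for ep in episodes], dtype=int)
    groups = [ep.episode_id for ep in episodes]

    static = np.stack(
        [_static_vector(ep, ep.reference_time_h - horizon_h) for ep in episodes]
    )

    if mode == "sequence":
        seq = np.empty((len(episodes), n_grid, len(variables)))
        for i, ep in enumerate(episodes):
            g = grids[(ep.episode_id, horizon_h)]
            seq[i] = g.values.T
        names = [f"{v}@t{k}" for k in range(n_grid) for v in variables]
        return HorizonDataset(horizon_h, mode, names, None, seq, static, labels, groups)

    names = [f"{v}_{s}" for v in variables for s in SUMMARIES] + static_names
    x = np.empty((len(episodes), 5 * len(variables) + static.shape[1]))
    for i, ep in enumerate(episodes):
        g = grids[(ep.episode_id, horizon_h)]
        t = g.grid_times_h
        row = []
        for j in range(len(variables)):
            vals = g.values[j]
            row.extend([vals[-1], vals.mean(), vals.min(), vals.max(), _slope(t, vals)])
        x[i] = np.concatenate([row, static[i]])
    return HorizonDataset(horizon_h, mode, names, x, None, static, labels, groups)


def make_folds(dataset: HorizonDataset, k: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified, episode-disjoint fold assignment (0..k-1 per episode)."""
    counts = np.bincount(dataset.labels, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= {k} episodes for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(dataset.n_episodes, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(dataset.n_episodes), dataset.labels)):
        assignment[test_idx] = fold
    return assignment
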