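"""End-to-end orchestration: windows → hyperparameters → grids →
horizon datasets → model bank → per-horizon scores.

Glue for the common experiment: fit the CTWH window config and the
population GP hyperparameters on a training split, impute per-horizon
grids for both splits, train the bank on the training split and score
the held-out split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ctwh import WindowConfig, build_window_config
from .ehr import Episode
from .features import HorizonDataset, assemble_horizon, compute_grids
from .mgp import MgpConfig, MgpHyperparameters, fit_hyperparameters
from .models import ModelBank, ModelConfig, build_bank
from .panel import CtwhConfig, FeaturePanel, default_panel


def split_episodes(
    episodes: list[Episode], test_fraction: float = 0.3, seed: int = 0
) -> tuple[list[Episode], list[Episode]]:
    """Stratified episode-level train/test split, deterministic in seed."""
    rng = np.random.default_rng(seed)
    train: list[Episode] = []
    test: list[Episode] = []
    for septic in (False, True):
        group = [ep for ep in episodes if ep.septic == septic]
        order = rng.permutation(len(group))
        n_test = int(round(test_fraction * len(group)))
        test_idx = set(order[:n_test].tolist())
        for i, ep in enumerate(group):
            (test if i in test_idx else train).append(ep)
    return train, test


@dataclass
class PipelineResult:
    windows: WindowConfig
    hypers: MgpHyperparameters
    bank: ModelBank
    train_datasets: dict[int, HorizonDataset]
    test_datasets: dict[int, HorizonDataset]
    test_scores: dict[int, np.ndarray] = field(default_factory=dict)

    def test_auroc(self) -> dict[int, float]:
        from .evaluation import auroc

        return {
            t: auroc(self.test_scores[t], self.test_datasets[t].labels)
            for t in sorted(self.test_scores)
        }


def run_pipeline(
    episodes: list[Episode],
    panel: FeaturePanel | None = None,
    horizons: tuple[int, ...] = tuple(range(13)),
    model_cfg: ModelConfig | None = None,
    mgp_cfg: MgpConfig | None = None,
    ctwh_cfg: CtwhConfig | None = None,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> PipelineResult:
    """Run the full training/evaluation pipeline on one cohort."""
    panel = panel or default_panel()
    model_cfg = model_cfg or ModelConfig()
    mgp_cfg = mgp_cfg or MgpConfig()
    train, test = split_episodes(episodes, test_fraction, seed)

    from .ehr import validate_panel

    report = validate_panel(train, panel)
    windows = build_window_config(train, panel, ctwh_cfg, variables=report.retained)
    hypers = fit_hyperparameters(train, panel, windows, mgp_cfg, seed=seed)

    mode = "tabular" if model_cfg.variant == "tabular_boosted" else "sequence"
    train_grids = compute_grids(train, panel, windows, mgp_cfg, hypers, horizons)
    test_grids = compute_grids(test, panel, windows, mgp_cfg, hypers, horizons)
    train_ds = {t: assemble_horizon(train, train_grids, t, mode) for t in horizons}
    test_ds = {t: assemble_horizon(test, test_grids, t, mode) for t in horizons}

    bank = build_bank(train_ds, model_cfg)
    result = PipelineResult(windows, hypers, bank, train_ds, test_ds)
    for t in horizons:
        result.test_scores[t] = bank.models[t].predict(test_ds[t])
    return result
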