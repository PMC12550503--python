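"""Horizon-specific risk models: GRU encoder + gradient-boosted classifier.

Thirteen independent models are trained, one per forecast horizon
T = 0…12 h before onset. Three variants are supported:

* ``tabular_boosted`` — gradient boosting (XGBoost) on the per-variable
  grid summaries;
* ``sequence_recurrent`` — the GRU sequence classifier alone;
* ``hybrid_embedding`` — GRU encoder embeddings concatenated with the
  static features, fed to the boosted classifier.

Boosted hyperparameters are chosen by stratified 5-fold cross-validation
over a small grid with early stopping at 10 rounds; the winner is refit
on all training data. Training is seeded and single-threaded so a rerun
reproduces the same model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .features import HorizonDataset
from .gru import GruClassifier, GruConfig

VARIANTS = ("tabular_boosted", "sequence_recurrent", "hybrid_embedding")


@dataclass
class BoostedConfig:
    n_rounds_max: int = 200
    early_stopping_rounds: int = 10
    cv_folds: int = 5
    learning_rates: tuple[float, ...] = (0.05, 0.1, 0.3)
    max_depths: tuple[int, ...] = (3, 4, 6)
    scale_pos_weight: float = 1.0
    seed: int = 0


@dataclass
class ModelConfig:
    variant: str = "tabular_boosted"
    recurrent: GruConfig = field(default_factory=GruConfig)
    boosted: BoostedConfig = field(default_factory=BoostedConfig)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


@dataclass
class TrainingReport:
    variant: str
    chosen_params: dict
    cv_auc: float
    fold_aucs: list[float]
    stopping_rounds: list[int]
    n_rounds_final: int
    seed: int
    encoder_stopped_epoch: int | None = None


def schema_hash(feature_names: list[str]) -> str:
    return hashlib.sha256("\x1f".join(feature_names).encode()).hexdigest()[:16]


def _new_booster(lr: float, depth: int, cfg: BoostedConfig, n_rounds: int,
                 early_stopping: int | None) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=n_rounds,
        learning_rate=lr,
        max_depth=depth,
        scale_pos_weight=cfg.scale_pos_weight,
        eval_metric="logloss",
        early_stopping_rounds=early_stopping,
        n_jobs=1,
        random_state=cfg.seed,
        tree_method="hist",
        verbosity=0,
    )


def train_boosted(
    x: np.ndarray, y: np.ndarray, cfg: BoostedConfig | None = None
) -> tuple[XGBClassifier, TrainingReport]:
    """Grid-searched, cross-validated, early-stopped boosted classifier."""
    cfg = cfg or BoostedConfig()
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    best = None
    for lr in cfg.learning_rates:
        for depth in cfg.max_depths:
            aucs, rounds = [], []
            for tr, va in skf.split(x, y):
                model = _new_booster(lr, depth, cfg, cfg.n_rounds_max, cfg.early_stopping_rounds)
                model.fit(x[tr], y[tr], eval_set=[(x[va], y[va])], verbose=False)
                p = model.predict_proba(x[va])[:, 1]
                aucs.append(roc_auc_score(y[va], p) if len(np.unique(y[va])) > 1 else 0.5)
                rounds.append(int(getattr(model, "best_iteration", cfg.n_rounds_max) or 0) + 1)
            mean_auc = float(np.mean(aucs))
            if best is None or mean_auc > best[0]:
                best = (mean_auc, lr, depth, aucs, rounds)
    mean_auc, lr, depth, aucs, rounds = best
    n_final = max(1, int(round(np.mean(rounds))))
    final = _new_booster(lr, depth, cfg, n_final, None)
    final.fit(x, y, verbose=False)
    report = TrainingReport(
        variant="boosted",
        chosen_params={"learning_rate": lr, "max_depth": depth},
        cv_auc=mean_auc,
        fold_aucs=[float(a) for a in aucs],
        stopping_rounds=rounds,
        n_rounds_final=n_final,
        seed=cfg.seed,
    )
    return final, report


def train_recurrent_encoder(
    dataset: HorizonDataset, cfg: GruConfig | None = None
) -> tuple[GruClassifier, np.ndarray]:
    """Train the GRU on a sequence dataset; return it with the
    per-episode embeddings (final hidden state of the last layer)."""
    if dataset.mode != "sequence":
        raise ValueError("recurrent encoder requires a sequence-mode dataset")
    encoder = GruClassifier(cfg or GruConfig()).fit(dataset.sequences, dataset.labels)
    return encoder, encoder.transform(dataset.sequences)


@dataclass
class HorizonModel:
    horizon_h: int
    variant: str
    schema: str
    booster: XGBClassifier | None
    encoder: GruClassifier | None
    report: TrainingReport

    def predict(self, dataset: HorizonDataset) -> np.ndarray:
        if self.variant == "sequence_recurrent":
            return self.encoder.predict_proba(dataset.sequences)
        if self.variant == "hybrid_embedding":
            emb = self.encoder.transform(dataset.sequences)
            x = np.hstack([emb, dataset.static])
        else:
            if schema_hash(dataset.feature_names) != self.schema:
                raise ValueError(
                    f"feature schema mismatch at horizon {self.horizon_h}"
                )
            x = dataset.X
        return self.booster.predict_proba(x)[:, 1]


@dataclass
class ModelBank:
    """One trained model per configured horizon."""

    models: dict[int, HorizonModel] = field(default_factory=dict)
    variant: str = "tabular_boosted"

    @property
    def horizons(self) -> list[int]:
        return sorted(self.models)

    def __len__(self) -> int:
        return len(self.models)


def train_horizon_model(
    dataset: HorizonDataset,
    cfg: ModelConfig,
    sequence_dataset: HorizonDataset | None = None,
) -> HorizonModel:
    if cfg.variant == "tabular_boosted":
        booster, report = train_boosted(dataset.X, dataset.labels, cfg.boosted)
        report.variant = cfg.variant
        return HorizonModel(
            dataset.horizon_h, cfg.variant, schema_hash(dataset.feature_names),
            booster, None, report,
        )
    seq = sequence_dataset or dataset
    if seq.mode != "sequence":
        raise ValueError(f"{cfg.variant} requires a sequence-mode dataset")
    encoder, embeddings = train_recurrent_encoder(seq, cfg.recurrent)
    if cfg.variant == "sequence_recurrent":
        report = TrainingReport(
            variant=cfg.variant, chosen_params={}, cv_auc=float("nan"),
            fold_aucs=[], stopping_rounds=[], n_rounds_final=0,
            seed=cfg.recurrent.seed, encoder_stopped_epoch=encoder.stopped_epoch,
        )
        return HorizonModel(seq.horizon_h, cfg.variant, schema_hash(seq.feature_names),
                            None, encoder, report)
    x = np.hstack([embeddings, seq.static])
    booster, report = train_boosted(x, seq.labels, cfg.boosted)
    report.variant = cfg.variant
    report.encoder_stopped_epoch = encoder.stopped_epoch
    return HorizonModel(seq.horizon_h, cfg.variant, schema_hash(seq.feature_names),
                        booster, encoder, report)


def build_bank(
    datasets: dict[int, HorizonDataset],
    cfg: ModelConfig | None = None,
    sequence_datasets: dict[int, HorizonDataset] | None = None,
    horizons: tuple[int, ...] | None = None,
) -> ModelBank:
    """Train the full bank: exactly one model per requested horizon."""
    cfg = cfg or ModelConfig()
    horizons = tuple(sorted(datasets)) if horizons is None else horizons
    missing = [t for t in horizons if t not in datasets]
    if missing:
        raise ValueError(f"missing dataset(s) for horizon(s) {missing}")
    bank = ModelBank(variant=cfg.variant)
    for t in horizons:
        seq = sequence_datasets.get(t) if sequence_datasets else None
        bank.models[t] = train_horizon_model(datasets[t], cfg, seq)
    return bank


def predict_risk(
    bank: ModelBank,
    datasets: dict[int, HorizonDataset],
) -> dict[int, np.ndarray]:
    """Score every horizon's dataset with its model; probabilities in [0,1]."""
    out: dict[int, np.ndarray] = {}
    for t, model in bank.models.items():
        if t in datasets:
            p = model.predict(datasets[t])
            if np.any((p < 0) | (p > 1)):
                raise RuntimeError("model produced scores outside [0, 1]")
            out[t] = p
    return out
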