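"""Minimal gated-recurrent-unit sequence classifier on numpy.

A small, deterministic GRU (two layers of 64 hidden units by default)
trained with Adam and early stopping on a stratified holdout, used both
as a standalone sequence classifier and as the encoder whose final
hidden state feeds the gradient-boosted stage. The cohort sizes this
package targets are desk-scale, so dense numpy forward/backward passes
are entirely adequate and keep the training bit-reproducible under a
seed in single-threaded runs.

Gate equations per layer (update z, reset r, candidate c):

    z_t = sigmoid(x_t Wxz + h_{t-1} Whz + bz)
    r_t = sigmoid(x_t Wxr + h_{t-1} Whr + br)
    c_t = tanh(x_t Wxc + (r_t ∘ h_{t-1}) Whc + bc)
    h_t = (1 - z_t) ∘ h_{t-1} + z_t ∘ c_t
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class GruLayerParams:
    wx: dict[str, np.ndarray]
    wh: dict[str, np.ndarray]
    b: dict[str, np.ndarray]


@dataclass
class GruConfig:
    n_layers: int = 2
    hidden_units: int = 64
    learning_rate: float = 1e-2
    max_epochs: int = 100
    batch_size: int = 32
    early_stopping_patience: int = 10
    validation_fraction: float = 0.2
    l2: float = 1e-5
    seed: int = 0


_GATES = ("z", "r", "c")


class GruClassifier:
    """Two-layer GRU + logistic head; ``transform`` exposes embeddings."""

    def __init__(self, cfg: GruConfig | None = None):
        self.cfg = cfg or GruConfig()
        self.layers: list[GruLayerParams] = []
        self.w_out: np.ndarray | None = None
        self.b_out: float = 0.0
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        self.stopped_epoch: int | None = None
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    # ---- initialization -------------------------------------------------
    def _init_params(self, n_features: int, rng: np.random.Generator) -> None:
        h = self.cfg.hidden_units
        self.layers = []
        d_in = n_features
        for _ in range(self.cfg.n_layers):
            scale_x = 1.0 / np.sqrt(d_in)
            scale_h = 1.0 / np.sqrt(h)
            self.layers.append(
                GruLayerParams(
                    wx={g: rng.normal(0, scale_x, (d_in, h)) for g in _GATES},
                    wh={g: rng.normal(0, scale_h, (h, h)) for g in _GATES},
                    b={g: np.zeros(h) for g in _GATES},
                )
            )
            d_in = h
        self.w_out = rng.normal(0, 1.0 / np.sqrt(h), h)
        self.b_out = 0.0

    # ---- forward --------------------------------------------------------
    def _forward(self, x: np.ndarray, cache: bool = False):
        """x: batch × T × d. Returns final hidden state (batch × H) and,
        when caching, the per-layer per-step activations for backprop."""
        caches = []
        seq = x
        for lp in self.layers:
            n, t_len, _ = seq.shape
            h = np.zeros((n, self.cfg.hidden_units))
            hs, zs, rs, cs, xs, h_prevs = [], [], [], [], [], []
            for t in range(t_len):
                xt = seq[:, t, :]
                h_prev = h
                z = _sigmoid(xt @ lp.wx["z"] + h_prev @ lp.wh["z"] + lp.b["z"])
                r = _sigmoid(xt @ lp.wx["r"] + h_prev @ lp.wh["r"] + lp.b["r"])
                c = np.tanh(xt @ lp.wx["c"] + (r * h_prev) @ lp.wh["c"] + lp.b["c"])
                h = (1.0 - z) * h_prev + z * c
                if cache:
                    xs.append(xt); h_prevs.append(h_prev)
                    zs.append(z); rs.append(r); cs.append(c)
                hs.append(h)
            if cache:
                caches.append((xs, h_prevs, zs, rs, cs))
            seq = np.stack(hs, axis=1)
        final = seq[:, -1, :]
        return (final, seq, caches) if cache else (final, seq, None)

    def _scores(self, final: np.ndarray) -> np.ndarray:
        return _sigmoid(final @ self.w_out + self.b_out)

    # ---- backward -------------------------------------------------------
    def _backward(self, x, y, final, seq_out, caches):
        n = len(y)
        p = self._scores(final)
        # dL/dlogit for mean BCE
        dlogit = (p - y) / n
        grads_out = (final.T @ dlogit, float(dlogit.sum()))
        d_seq = np.zeros_like(seq_out)  # grad wrt last layer's output sequence
        d_seq[:, -1, :] = np.outer(dlogit, self.w_out)

        layer_grads = []
        for li in range(self.cfg.n_layers - 1, -1, -1):
            lp = self.layers[li]
            xs, h_prevs, zs, rs, cs = caches[li]
            t_len = len(xs)
            gwx = {g: np.zeros_like(lp.wx[g]) for g in _GATES}
            gwh = {g: np.zeros_like(lp.wh[g]) for g in _GATES}
            gb = {g: np.zeros_like(lp.b[g]) for g in _GATES}
            d_in_seq = np.zeros((n, t_len, lp.wx["z"].shape[0]))
            dh_next = np.zeros((n, self.cfg.hidden_units))
            for t in range(t_len - 1, -1, -1):
                dh = dh_next + d_seq[:, t, :]
                z, r, c, h_prev, xt = zs[t], rs[t], cs[t], h_prevs[t], xs[t]
                dz = dh * (c - h_prev)
                dc = dh * z
                dh_prev = dh * (1.0 - z)
                dpre_c = dc * (1.0 - c * c)
                gwx["c"] += xt.T @ dpre_c
                gwh["c"] += (r * h_prev).T @ dpre_c
                gb["c"] += dpre_c.sum(axis=0)
                drh = dpre_c @ lp.wh["c"].T
                dr = drh * h_prev
                dh_prev += drh * r
                dpre_r = dr * r * (1.0 - r)
                gwx["r"] += xt.T @ dpre_r
                gwh["r"] += h_prev.T @ dpre_r
                gb["r"] += dpre_r.sum(axis=0)
                dh_prev += dpre_r @ lp.wh["r"].T
                dpre_z = dz * z * (1.0 - z)
                gwx["z"] += xt.T @ dpre_z
                gwh["z"] += h_prev.T @ dpre_z
                gb["z"] += dpre_z.sum(axis=0)
                dh_prev += dpre_z @ lp.wh["z"].T
                d_in_seq[:, t, :] = (
                    dpre_z @ lp.wx["z"].T + dpre_r @ lp.wx["r"].T + dpre_c @ lp.wx["c"].T
                )
                dh_next = dh_prev
            layer_grads.append((gwx, gwh, gb))
            d_seq = d_in_seq
        layer_grads.reverse()
        return grads_out, layer_grads

    # ---- parameter vector utilities ------------------------------------
    def _param_list(self):
        out = []
        for lp in self.layers:
            for g in _GATES:
                out.extend([lp.wx[g], lp.wh[g], lp.b[g]])
        return out

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for p in self._param_list():
            h.update(np.ascontiguousarray(p).tobytes())
        h.update(np.ascontiguousarray(self.w_out).tobytes())
        h.update(np.float64(self.b_out).tobytes())
        return h.hexdigest()

    # ---- training -------------------------------------------------------
    @staticmethod
    def _bce(p: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))

    def fit(self, x: np.ndarray, y: np.ndarray) -> "GruClassifier":
        cfg = self.cfg
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        if not np.all(np.isfinite(x)):
            raise ValueError("sequence tensor must be complete (no NaN/inf)")
        rng = np.random.default_rng(cfg.seed)
        # per-feature standardization over (episode, time)
        flat = x.reshape(-1, x.shape[-1])
        self._mu = flat.mean(axis=0)
        self._sd = np.clip(flat.std(axis=0), 1e-8, None)
        x = (x - self._mu) / self._sd

        # stratified early-stopping holdout
        val_idx = []
        for cls in (0, 1):
            idx = np.where(y == cls)[0]
            n_val = max(1, int(round(cfg.validation_fraction * len(idx))))
            val_idx.extend(rng.permutation(idx)[:n_val].tolist())
        val_mask = np.zeros(len(y), dtype=bool)
        val_mask[val_idx] = True
        x_tr, y_tr = x[~val_mask], y[~val_mask]
        x_va, y_va = x[val_mask], y[val_mask]
        if len(np.unique(y_tr)) < 2:
            raise ValueError("training split lost a class; need more episodes")

        self._init_params(x.shape[-1], rng)
        params = self._param_list() + [self.w_out]
        m = [np.zeros_like(p) for p in params] + [0.0]
        v = [np.zeros_like(p) for p in params] + [0.0]
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_state = None
        patience = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(y_tr))
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                xb, yb = x_tr[batch], y_tr[batch]
                final, seq_out, caches = self._forward(xb, cache=True)
                (gw_out, gb_out), layer_grads = self._backward(xb, yb, final, seq_out, caches)
                flat_params = []
                flat_grads = []
                for lp, (gwx, gwh, gb) in zip(self.layers, layer_grads):
                    for g in _GATES:
                        flat_params.extend([lp.wx[g], lp.wh[g], lp.b[g]])
                        flat_grads.extend(
                            [gwx[g] + cfg.l2 * lp.wx[g], gwh[g] + cfg.l2 * lp.wh[g], gb[g]]
                        )
                flat_params.append(self.w_out)
                flat_grads.append(gw_out + cfg.l2 * self.w_out)
                step += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - b2**step) / (1 - b1**step)
                for i, (p, g) in enumerate(zip(flat_params, flat_grads)):
                    m[i] = b1 * m[i] + (1 - b1) * g
                    v[i] = b2 * v[i] + (1 - b2) * g * g
                    p -= lr_t * m[i] / (np.sqrt(v[i]) + eps)
                m[-1] = b1 * m[-1] + (1 - b1) * gb_out
                v[-1] = b2 * v[-1] + (1 - b2) * gb_out * gb_out
                self.b_out -= lr_t * m[-1] / (np.sqrt(v[-1]) + eps)

            p_tr = self._scores(self._forward(x_tr)[0])
            p_va = self._scores(self._forward(x_va)[0])
            tr_loss = self._bce(p_tr, y_tr)
            va_loss = self._bce(p_va, y_va)
            if not (np.isfinite(tr_loss) and np.isfinite(va_loss)):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            self.history["train_loss"].append(tr_loss)
            self.history["val_loss"].append(va_loss)
            if va_loss < best_val - 1e-6:
                best_val = va_loss
                best_state = self._snapshot()
                patience = 0
            else:
                patience += 1
                if patience >= cfg.early_stopping_patience:
                    break
        if best_state is not None:
            self._restore(best_state)
        self.stopped_epoch = int(np.argmin(self.history["val_loss"]))
        return self

    def _snapshot(self):
        return (
            [
                {k: {g: a.copy() for g, a in d.items()} for k, d in
                 (("wx", lp.wx), ("wh", lp.wh), ("b", lp.b))}
                for lp in self.layers
            ],
            self.w_out.copy(),
            self.b_out,
        )

    def _restore(self, state):
        layers_state, w_out, b_out = state
        for lp, st in zip(self.layers, layers_state):
            lp.wx, lp.wh, lp.b = st["wx"], st["wh"], st["b"]
        self.w_out = w_out
        self.b_out = b_out

    # ---- inference ------------------------------------------------------
    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self._mu) / self._sd

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        final, _, _ = self._forward(self._standardize(x))
        return self._scores(final)

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Final hidden state of the last layer — the episode embedding."""
        final, _, _ = self._forward(self._standardize(x))
        return final
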