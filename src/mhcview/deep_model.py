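"""Stage-two classifier: BiLSTM + multi-head attention + SELU head.

The reduced feature vector (default 224-dim) is reshaped into a short
multivariate sequence of T timesteps x d features (T*d = input_dim), run
through a bidirectional LSTM whose per-timestep forward/backward states
are concatenated, refined by multi-head self-attention over timesteps,
mean-pooled, and classified by a two-linear-layer head with a scaled
exponential linear unit (SELU) between the layers.  The output is the
positive-class probability; the decision threshold is 0.5.

Three ablation variants accompany the full model: V1 drops the BiLSTM
(attention acts on the reshaped input), V2 drops the attention (the
BiLSTM final states feed the head), V3 keeps only the head on the flat
input.

The network and its backpropagation are implemented directly in NumPy
(float64, single-threaded deterministic given the seed), trained with
Adam on binary cross-entropy and early stopping on validation loss with
best-epoch weight restoration.  Gradients are exercised against finite
differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


class ModelVariant(str, Enum):
    FULL = "FULL"
    V1_NO_BILSTM = "V1_NO_BILSTM"
    V2_NO_ATTN = "V2_NO_ATTN"
    V3_HEAD_ONLY = "V3_HEAD_ONLY"


def _default_timesteps(input_dim: int) -> int:
    """Largest divisor of input_dim not exceeding sqrt(input_dim)."""
    best = 1
    for t in range(1, int(np.sqrt(input_dim)) + 1):
        if input_dim % t == 0:
            best = t
    return best


@dataclass(frozen=True)
class NetConfig:
    input_dim: int = 224
    timesteps: int | None = None  # None → largest divisor <= sqrt(input_dim)
    lstm_hidden: int = 64
    lstm_layers: int = 1
    attn_heads: int = 4
    attn_dim: int = 128  # attention model width (divisible by attn_heads)
    head_hidden: int = 64
    dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        T = self.resolved_timesteps
        if self.input_dim % T != 0:
            raise ValueError(
                f"timesteps={T} does not divide input_dim={self.input_dim}"
            )
        if self.attn_dim % self.attn_heads != 0:
            raise ValueError(
                f"attn_dim={self.attn_dim} not divisible by attn_heads={self.attn_heads}"
            )
        if self.lstm_layers < 1:
            raise ValueError("lstm_layers must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def resolved_timesteps(self) -> int:
        return self.timesteps if self.timesteps is not None else _default_timesteps(self.input_dim)

    @property
    def step_dim(self) -> int:
        return self.input_dim // self.resolved_timesteps


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _selu(x: np.ndarray) -> np.ndarray:
    return _SELU_SCALE * np.where(x > 0, x, _SELU_ALPHA * (np.exp(x) - 1.0))


def _selu_grad(x: np.ndarray) -> np.ndarray:
    return _SELU_SCALE * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(x))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


# ---------------------------------------------------------------------------
# building blocks (pure-function forward/backward pairs over a params dict)

class _LSTMDirection:
    """One direction of an LSTM layer; gate order i, f, g, o."""

    def __init__(self, prefix: str, input_dim: int, hidden: int):
        self.prefix, self.input_dim, self.hidden = prefix, input_dim, hidden

    def init(self, rng: np.random.Generator, params: dict) -> None:
        H = self.hidden
        params[f"{self.prefix}.Wx"] = _glorot(rng, self.input_dim, 4 * H)
        params[f"{self.prefix}.Wh"] = _glorot(rng, H, 4 * H)
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # forget-gate bias init
        params[f"{self.prefix}.b"] = b

    def forward(self, params: dict, X: np.ndarray) -> tuple[np.ndarray, dict]:
        B, T, _ = X.shape
        H = self.hidden
        Wx, Wh, b = (params[f"{self.prefix}.{n}"] for n in ("Wx", "Wh", "b"))
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.zeros((B, T, H))
        cache: dict = {"X": X, "steps": []}
        for t in range(T):
            a = X[:, t] @ Wx + h @ Wh + b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = _sigmoid(a[:, 3 * H:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tanh_c = np.tanh(c)
            h = o * tanh_c
            hs[:, t] = h
            cache["steps"].append((i, f, g, o, c_prev, h_prev, tanh_c))
        return hs, cache

    def backward(self, params: dict, cache: dict, dhs: np.ndarray,
                 grads: dict) -> np.ndarray:
        X = cache["X"]
        B, T, _ = X.shape
        H = self.hidden
        Wx, Wh = params[f"{self.prefix}.Wx"], params[f"{self.prefix}.Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dX = np.zeros_like(X)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            i, f, g, o, c_prev, h_prev, tanh_c = cache["steps"][t]
            dh = dhs[:, t] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += X[:, t].T @ da
            dWh += h_prev.T @ da
            db += da.sum(0)
            dX[:, t] = da @ Wx.T
            dh_next = da @ Wh.T
            dc_next = dc * f
        grads[f"{self.prefix}.Wx"] = grads.get(f"{self.prefix}.Wx", 0) + dWx
        grads[f"{self.prefix}.Wh"] = grads.get(f"{self.prefix}.Wh", 0) + dWh
        grads[f"{self.prefix}.b"] = grads.get(f"{self.prefix}.b", 0) + db
        return dX


class _BiLSTM:
    """Stacked bidirectional LSTM; per-timestep outputs are fwd/bwd concat."""

    def __init__(self, input_dim: int, hidden: int, layers: int):
        self.hidden, self.layers = hidden, layers
        self.dirs: list[tuple[_LSTMDirection, _LSTMDirection]] = []
        d = input_dim
        for layer in range(layers):
            self.dirs.append(
                (
                    _LSTMDirection(f"lstm{layer}.fwd", d, hidden),
                    _LSTMDirection(f"lstm{layer}.bwd", d, hidden),
                )
            )
            d = 2 * hidden

    def init(self, rng: np.random.Generator, params: dict) -> None:
        for fwd, bwd in self.dirs:
            fwd.init(rng, params)
            bwd.init(rng, params)

    def forward(self, params: dict, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
        """Returns (per-timestep outputs (B,T,2H), final states (B,2H), cache)."""
        cache: dict = {"layers": []}
        out = X
        for fwd, bwd in self.dirs:
            hs_f, cache_f = fwd.forward(params, out)
            hs_b_rev, cache_b = bwd.forward(params, out[:, ::-1])
            out = np.concatenate([hs_f, hs_b_rev[:, ::-1]], axis=2)
            cache["layers"].append((cache_f, cache_b))
        final = np.concatenate([hs_f[:, -1], hs_b_rev[:, -1]], axis=1)
        return out, final, cache

    def backward(self, params: dict, cache: dict, dout: np.ndarray,
                 dfinal: np.ndarray | None, grads: dict) -> np.ndarray:
        H = self.hidden
        d = dout
        for layer in reversed(range(self.layers)):
            fwd, bwd = self.dirs[layer]
            cache_f, cache_b = cache["layers"][layer]
            dh_f = d[:, :, :H].copy()
            dh_b_rev = d[:, ::-1, H:].copy()
            if dfinal is not None and layer == self.layers - 1:
                dh_f[:, -1] += dfinal[:, :H]
                dh_b_rev[:, -1] += dfinal[:, H:]
            dX_f = fwd.backward(params, cache_f, dh_f, grads)
            dX_b = bwd.backward(params, cache_b, dh_b_rev, grads)
            d = dX_f + dX_b[:, ::-1]
        return d


class _MultiHeadAttention:
    """Self-attention over timesteps with h heads in a model width Dm."""

    def __init__(self, input_dim: int, model_dim: int, heads: int):
        self.input_dim, self.model_dim, self.heads = input_dim, model_dim, heads
        self.head_dim = model_dim // heads

    def init(self, rng: np.random.Generator, params: dict) -> None:
        for name in ("Wq", "Wk", "Wv"):
            params[f"attn.{name}"] = _glorot(rng, self.input_dim, self.model_dim)
            params[f"attn.{name[1].upper()}b"] = np.zeros(self.model_dim)
        params["attn.Wo"] = _glorot(rng, self.model_dim, self.model_dim)
        params["attn.ob"] = np.zeros(self.model_dim)

    def _split(self, Z: np.ndarray) -> np.ndarray:
        B, T, _ = Z.shape
        return Z.reshape(B, T, self.heads, self.head_dim).transpose(0, 2, 1, 3)

    def _merge(self, Z: np.ndarray) -> np.ndarray:
        B, h, T, dk = Z.shape
        return Z.transpose(0, 2, 1, 3).reshape(B, T, h * dk)

    def forward(self, params: dict, X: np.ndarray) -> tuple[np.ndarray, dict]:
        Q = self._split(X @ params["attn.Wq"] + params["attn.Qb"])
        K = self._split(X @ params["attn.Wk"] + params["attn.Kb"])
        V = self._split(X @ params["attn.Wv"] + params["attn.Vb"])
        S = Q @ K.transpose(0, 1, 3, 2) / np.sqrt(self.head_dim)
        S -= S.max(axis=-1, keepdims=True)
        E = np.exp(S)
        A = E / E.sum(axis=-1, keepdims=True)
        ctx = A @ V  # (B, h, T, dk)
        merged = self._merge(ctx)
        out = merged @ params["attn.Wo"] + params["attn.ob"]
        return out, {"X": X, "Q": Q, "K": K, "V": V, "A": A, "merged": merged}

    def backward(self, params: dict, cache: dict, dout: np.ndarray,
                 grads: dict) -> np.ndarray:
        X, Q, K, V, A, merged = (cache[k] for k in ("X", "Q", "K", "V", "A", "merged"))
        B, T, _ = X.shape
        grads["attn.Wo"] = merged.reshape(-1, self.model_dim).T @ dout.reshape(-1, self.model_dim)
        grads["attn.ob"] = dout.sum((0, 1))
        dmerged = dout @ params["attn.Wo"].T
        dctx = self._split(dmerged)
        dA = dctx @ V.transpose(0, 1, 3, 2)
        dV = A.transpose(0, 1, 3, 2) @ dctx
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dS /= np.sqrt(self.head_dim)
        dQ = dS @ K
        dK = dS.transpose(0, 1, 3, 2) @ Q
        dX = np.zeros_like(X)
        for name, dZ in (("Wq", dQ), ("Wk", dK), ("Wv", dV)):
            dflat = self._merge(dZ)
            grads[f"attn.{name}"] = (
                X.reshape(-1, self.input_dim).T @ dflat.reshape(-1, self.model_dim)
            )
            grads[f"attn.{name[1].upper()}b"] = dflat.sum((0, 1))
            dX += dflat @ params[f"attn.{name}"].T
        return dX


# ---------------------------------------------------------------------------
# model

@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_tsv(self, path: str | Path) -> None:
        lines = ["epoch\ttrain_loss\ttrain_acc\tval_loss\tval_acc"]
        for e in range(len(self.train_loss)):
            lines.append(
                f"{e}\t{self.train_loss[e]:.6f}\t{self.train_acc[e]:.6f}"
                f"\t{self.val_loss[e]:.6f}\t{self.val_acc[e]:.6f}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


class SequenceClassifier:
    """BiLSTM + multi-head-attention binary classifier and its ablations."""

    def __init__(self, variant: ModelVariant | str = ModelVariant.FULL,
                 config: NetConfig | None = None):
        self.variant = ModelVariant(variant)
        self.config = config or NetConfig()
        cfg = self.config
        self.T = cfg.resolved_timesteps
        self.d = cfg.step_dim
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, np.ndarray] = {}
        self.bilstm: _BiLSTM | None = None
        self.attn: _MultiHeadAttention | None = None

        use_lstm = self.variant in (ModelVariant.FULL, ModelVariant.V2_NO_ATTN)
        use_attn = self.variant in (ModelVariant.FULL, ModelVariant.V1_NO_BILSTM)
        if use_lstm:
            self.bilstm = _BiLSTM(self.d, cfg.lstm_hidden, cfg.lstm_layers)
            self.bilstm.init(rng, self.params)
        if use_attn:
            attn_in = 2 * cfg.lstm_hidden if use_lstm else self.d
            self.attn = _MultiHeadAttention(attn_in, cfg.attn_dim, cfg.attn_heads)
            self.attn.init(rng, self.params)
        if self.variant is ModelVariant.V3_HEAD_ONLY:
            head_in = cfg.input_dim
        elif self.variant is ModelVariant.V2_NO_ATTN:
            head_in = 2 * cfg.lstm_hidden
        else:
            head_in = cfg.attn_dim
        self.params["head.W1"] = _glorot(rng, head_in, cfg.head_hidden)
        self.params["head.b1"] = np.zeros(cfg.head_hidden)
        self.params["head.W2"] = _glorot(rng, cfg.head_hidden, 1)
        self.params["head.b2"] = np.zeros(1)
        self._head_in = head_in
        self.trained = False
        self.history = TrainingHistory()

    # -- forward / backward ------------------------------------------------

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def _forward(self, X: np.ndarray, dropout_mask: np.ndarray | None = None
                 ) -> tuple[np.ndarray, dict]:
        cfg = self.config
        B = X.shape[0]
        cache: dict = {}
        if self.variant is ModelVariant.V3_HEAD_ONLY:
            flat = X
        else:
            seq = X.reshape(B, self.T, self.d)
            cache["seq_shape"] = seq.shape
            if self.bilstm is not None:
                seq_out, final, cache["lstm"] = self.bilstm.forward(self.params, seq)
            else:
                seq_out, final = seq, None
            if self.attn is not None:
                attn_out, cache["attn"] = self.attn.forward(self.params, seq_out)
                flat = attn_out.mean(axis=1)  # pool over timesteps
                cache["pool_T"] = attn_out.shape[1]
            else:
                flat = final
        if dropout_mask is not None:
            flat = flat * dropout_mask
        z1 = flat @ self.params["head.W1"] + self.params["head.b1"]
        h1 = _selu(z1)
        logits = (h1 @ self.params["head.W2"] + self.params["head.b2"]).ravel()
        cache.update({"flat": flat, "z1": z1, "h1": h1, "mask": dropout_mask})
        return _sigmoid(logits), cache

    def _backward(self, X: np.ndarray, y: np.ndarray, probs: np.ndarray,
                  cache: dict) -> dict[str, np.ndarray]:
        B = X.shape[0]
        grads: dict[str, np.ndarray] = {}
        dlogits = ((probs - y) / B)[:, None]
        grads["head.W2"] = cache["h1"].T @ dlogits
        grads["head.b2"] = dlogits.sum(0)
        dh1 = dlogits @ self.params["head.W2"].T
        dz1 = dh1 * _selu_grad(cache["z1"])
        grads["head.W1"] = cache["flat"].T @ dz1
        grads["head.b1"] = dz1.sum(0)
        dflat = dz1 @ self.params["head.W1"].T
        if cache["mask"] is not None:
            dflat = dflat * cache["mask"]
        if self.variant is ModelVariant.V3_HEAD_ONLY:
            return grads
        if self.attn is not None:
            T = cache["pool_T"]
            dattn = np.repeat(dflat[:, None, :], T, axis=1) / T
            dseq_out = self.attn.backward(self.params, cache["attn"], dattn, grads)
            dfinal = None
        else:
            dseq_out = np.zeros(cache["seq_shape"][:2] + (2 * self.config.lstm_hidden,))
            dfinal = dflat
        if self.bilstm is not None:
            self.bilstm.backward(self.params, cache["lstm"], dseq_out, dfinal, grads)
        return grads

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray
                       ) -> tuple[float, dict[str, np.ndarray]]:
        """BCE loss and parameter gradients (no dropout); used for training
        steps and finite-difference verification."""
        probs, cache = self._forward(X)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))
        return loss, self._backward(X, y, probs, cache)

    # -- training ----------------------------------------------------------

    def fit(self, X_train: np.ndarray, y_train: np.ndarray,
            X_val: np.ndarray, y_val: np.ndarray) -> "SequenceClassifier":
        """Adam + early stopping on validation loss; restores the best epoch."""
        cfg = self.config
        X_train = np.asarray(X_train, dtype=float)
        X_val = np.asarray(X_val, dtype=float)
        y_train = np.asarray(y_train, dtype=float).ravel()
        y_val = np.asarray(y_val, dtype=float).ravel()
        if X_train.shape[1] != cfg.input_dim:
            raise ValueError(
                f"feature width {X_train.shape[1]} != input_dim {cfg.input_dim}"
            )
        if X_val.size == 0:
            raise ValueError("validation set must be nonempty")
        for arr in (y_train, y_val):
            if not set(np.unique(arr)) <= {0.0, 1.0}:
                raise ValueError("labels must be binary")
        if len(set(y_train)) < 2:
            raise ValueError("single-class training set")

        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x747261696E]))
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_loss = np.inf
        best_params: dict[str, np.ndarray] | None = None
        stale = 0
        n = X_train.shape[0]
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                Xb, yb = X_train[idx], y_train[idx]
                if cfg.dropout > 0:
                    mask = (rng.random((len(idx), self._head_in)) >= cfg.dropout)
                    mask = mask.astype(float) / (1.0 - cfg.dropout)
                else:
                    mask = None
                probs, cache = self._forward(Xb, dropout_mask=mask)
                e = 1e-12
                loss = float(-np.mean(
                    yb * np.log(probs + e) + (1 - yb) * np.log(1 - probs + e)))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        "NaN/inf training loss — try a smaller learning rate"
                    )
                epoch_losses.append(loss)
                grads = self._backward(Xb, yb, probs, cache)
                step += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - b2**step) / (1 - b1**step)
                for k, g in grads.items():
                    g = np.asarray(g).reshape(self.params[k].shape)
                    m[k] = b1 * m[k] + (1 - b1) * g
                    v[k] = b2 * v[k] + (1 - b2) * g * g
                    self.params[k] -= lr_t * m[k] / (np.sqrt(v[k]) + eps)
            tr_probs = self.predict_proba(X_train, _allow_untrained=True)
            va_probs = self.predict_proba(X_val, _allow_untrained=True)
            e = 1e-12
            va_loss = float(-np.mean(
                y_val * np.log(va_probs + e) + (1 - y_val) * np.log(1 - va_probs + e)))
            self.history.train_loss.append(float(np.mean(epoch_losses)))
            self.history.train_acc.append(float(np.mean((tr_probs >= 0.5) == y_train)))
            self.history.val_loss.append(va_loss)
            self.history.val_acc.append(float(np.mean((va_probs >= 0.5) == y_val)))
            if va_loss < best_loss - 1e-6:
                best_loss = va_loss
                best_params = {k: p.copy() for k, p in self.params.items()}
                self.history.best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        if best_params is not None:
            self.params = best_params
        self.trained = True
        return self

    def predict_proba(self, X: np.ndarray, _allow_untrained: bool = False) -> np.ndarray:
        if not self.trained and not _allow_untrained:
            raise RuntimeError("model is not trained; call fit() first")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected (n, {self.config.input_dim}) features, got {X.shape}"
            )
        probs, _ = self._forward(X)
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    # -- persistence --------------------------------------------------------

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        np.savez(prefix.with_suffix(".npz"), **self.params)
        prefix.with_suffix(".json").write_text(json.dumps({
            "variant": self.variant.value,
            "config": self.config.__dict__,
            "trained": self.trained,
            "parameter_count": self.parameter_count,
        }, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "SequenceClassifier":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        model = cls(meta["variant"], NetConfig(**meta["config"]))
        arrays = np.load(prefix.with_suffix(".npz"))
        model.params = {k: arrays[k] for k in arrays.files}
        model.trained = meta["trained"]
        return model


def build_model(variant: ModelVariant | str, config: NetConfig | None = None
                ) -> SequenceClassifier:
    """Construct an untrained classifier for the given ablation variant."""
    return SequenceClassifier(variant, config)


def train_model(model: SequenceClassifier,
                train_features: np.ndarray, train_labels: np.ndarray,
                val_features: np.ndarray, val_labels: np.ndarray
                ) -> SequenceClassifier:
    return model.fit(train_features, train_labels, val_features, val_labels)
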