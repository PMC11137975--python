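"""GRU-based deep feature extraction.

A small gated recurrent classifier is trained end-to-end on embedded
transcripts (6-token vocabulary: pad, A, C, G, T, N -> 50-dim learned
embedding) and its pooled hidden activations are exposed as a fixed-length
deep feature vector.

The recurrent cell follows the standard gated-unit equations: an update gate
``u_m = sigmoid(W_u.[h_{m-1}, x_m])`` decides how much of the previous hidden
state carries over, a reset gate ``c_m = sigmoid(W_c.[h_{m-1}, x_m])`` decides
how much of it enters the candidate state
``h~_m = tanh(W.[c_m * h_{m-1}, x_m])``, and the new state is the convex
combination ``h_m = u_m * h~_m + (1 - u_m) * h_{m-1}``.

Pooling reduces the (seq_length x hidden_units) activation map along the
hidden axis only: two successive max-pool stages (default sizes 5 then 3,
20 -> 4 -> 2) followed by a max-merge of the remaining channels leave exactly
one feature per sequence position, so the default configuration emits a
1200-dimensional vector.  A bidirectional variant pools each direction the
same way and max-merges the two directions, preserving the 1200-dim output.

The whole network — embedding, recurrent cell(s), pooling and a sigmoid
classification head — is implemented in numpy with explicit backpropagation
through time and Adam updates, fully deterministic under a fixed seed on one
device.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .encoding import VOCAB_SIZE


@dataclass(frozen=True)
class ExtractorConfig:
    """Hyperparameters of the deep feature extractor.

    Defaults follow the tuned configuration: learning rate 0.001, 20 hidden
    units, batch size 16, input length 1200, 50-dim embedding, pool kernels
    5 then 3.
    """

    seq_length: int = 1200
    embedding_dim: int = 50
    hidden_units: int = 20
    bidirectional: bool = False
    pool1_size: int = 5
    pool2_size: int = 3
    learning_rate: float = 0.001
    batch_size: int = 16
    epochs: int = 30
    patience: int = 5
    clip_norm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("seq_length", "embedding_dim", "hidden_units",
                     "pool1_size", "pool2_size", "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        c1 = math.ceil(self.hidden_units / self.pool1_size)
        c2 = math.ceil(c1 / self.pool2_size)
        if c2 < 1:
            raise ValueError(
                "pooling stages leave no channel: "
                f"ceil(ceil({self.hidden_units}/{self.pool1_size})/{self.pool2_size}) = {c2}; "
                "one channel per position is required"
            )

    @property
    def feature_dim(self) -> int:
        """Output dimension: one pooled feature per sequence position."""
        return self.seq_length

    @property
    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class DeepFeatureVector:
    values: np.ndarray
    config_fingerprint: str


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    limit = math.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return q * np.sign(np.diag(r))


class _GruCell:
    """One direction's parameters and BPTT machinery.

    Recurrent matrices start orthogonal and the update-gate bias starts at -1
    (gates initially favor carrying the previous state), the usual recipe for
    stable gradient flow over long sequences.
    """

    def __init__(self, rng: np.random.Generator, emb_dim: int, hidden: int):
        self.params = {
            "Wu": _glorot(rng, (emb_dim, hidden)),
            "Wr": _glorot(rng, (emb_dim, hidden)),
            "Wc": _glorot(rng, (emb_dim, hidden)),
            "Uu": _orthogonal(rng, hidden),
            "Ur": _orthogonal(rng, hidden),
            "Uc": _orthogonal(rng, hidden),
            "bu": np.full(hidden, -1.0),
            "br": np.zeros(hidden),
            "bc": np.zeros(hidden),
        }

    def forward(self, X: np.ndarray, cache: bool):
        """X: (B, L, E) -> H: (B, L, hidden). Cache gate activations for BPTT."""
        p = self.params
        B, L, _ = X.shape
        hid = p["bu"].shape[0]
        h = np.zeros((B, hid))
        H = np.empty((B, L, hid))
        caches = [] if cache else None
        for t in range(L):
            x = X[:, t, :]
            u = _sigmoid(x @ p["Wu"] + h @ p["Uu"] + p["bu"])
            r = _sigmoid(x @ p["Wr"] + h @ p["Ur"] + p["br"])
            c = np.tanh(x @ p["Wc"] + (r * h) @ p["Uc"] + p["bc"])
            h_new = u * c + (1.0 - u) * h
            if cache:
                caches.append((h, u, r, c))
            h = h_new
            H[:, t, :] = h
        return H, caches

    def backward(self, X: np.ndarray, dH: np.ndarray, caches) -> tuple[dict, np.ndarray]:
        """Backpropagate dL/dH through time; returns grads and dL/dX."""
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dX = np.zeros_like(X)
        dh_next = np.zeros_like(dH[:, 0, :])
        for t in range(X.shape[1] - 1, -1, -1):
            h_prev, u, r, c = caches[t]
            dh = dH[:, t, :] + dh_next
            du = dh * (c - h_prev)
            dc = dh * u
            dh_prev = dh * (1.0 - u)
            da_c = dc * (1.0 - c * c)
            drh = da_c @ p["Uc"].T
            dr = drh * h_prev
            dh_prev += drh * r
            da_u = du * u * (1.0 - u)
            da_r = dr * r * (1.0 - r)
            x = X[:, t, :]
            grads["Wu"] += x.T @ da_u
            grads["Wr"] += x.T @ da_r
            grads["Wc"] += x.T @ da_c
            grads["Uu"] += h_prev.T @ da_u
            grads["Ur"] += h_prev.T @ da_r
            grads["Uc"] += (r * h_prev).T @ da_c
            grads["bu"] += da_u.sum(axis=0)
            grads["br"] += da_r.sum(axis=0)
            grads["bc"] += da_c.sum(axis=0)
            dX[:, t, :] = da_u @ p["Wu"].T + da_r @ p["Wr"].T + da_c @ p["Wc"].T
            dh_prev += da_u @ p["Uu"].T + da_r @ p["Ur"].T
            dh_next = dh_prev
        return grads, dX


class GruExtractor:
    """Embedding + (bi)directional gated recurrent layer + hidden-axis max
    pooling + sigmoid head, trained with Adam on binary cross-entropy."""

    def __init__(self, config: ExtractorConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.embedding = rng.normal(0.0, 0.1, size=(VOCAB_SIZE, config.embedding_dim))
        self.cells = [_GruCell(rng, config.embedding_dim, config.hidden_units)]
        if config.bidirectional:
            self.cells.append(_GruCell(rng, config.embedding_dim, config.hidden_units))
        D = config.feature_dim
        self.head_w = rng.normal(0.0, 1.0 / math.sqrt(D), size=D)
        self.head_b = 0.0
        self._adam: dict | None = None
        self.history: list[dict] = []

    # ---- forward pieces -------------------------------------------------

    def _pool(self, Hs: list[np.ndarray]):
        """Max over the hidden axis (two staged kernels compose to a full
        max), then max-merge directions; returns pooled (B, L) and the argmax
        bookkeeping (direction index, hidden index) for gradient routing."""
        stacked = np.stack([H.max(axis=2) for H in Hs], axis=0)      # (dir, B, L)
        arg_hidden = [H.argmax(axis=2) for H in Hs]                  # (B, L) each
        arg_dir = stacked.argmax(axis=0)                             # (B, L)
        pooled = stacked.max(axis=0)
        return pooled, arg_dir, arg_hidden

    def _forward(self, idx: np.ndarray, cache: bool = False):
        X = self.embedding[idx]                                      # (B, L, E)
        results = []
        for d, cell in enumerate(self.cells):
            Xd = X[:, ::-1, :] if d == 1 else X
            H, caches = cell.forward(Xd, cache)
            if d == 1:
                H = H[:, ::-1, :]
            results.append((H, caches))
        pooled, arg_dir, arg_hidden = self._pool([H for H, _ in results])
        logits = pooled @ self.head_w + self.head_b
        probs = _sigmoid(logits)
        return X, results, pooled, arg_dir, arg_hidden, probs

    # ---- public API -----------------------------------------------------

    def predict_proba(self, idx: np.ndarray) -> np.ndarray:
        """Head probabilities (of the positive class) for an (n, L) batch."""
        self._check_length(idx)
        return self._forward(np.atleast_2d(idx))[-1]

    def features(self, idx: np.ndarray) -> np.ndarray:
        """Post-pooling, pre-head activations: (n, seq_length)."""
        self._check_length(idx)
        return self._forward(np.atleast_2d(idx))[2]

    def _check_length(self, idx: np.ndarray) -> None:
        L = np.atleast_2d(idx).shape[1]
        if L != self.config.seq_length:
            raise ValueError(
                f"encoded length {L} != configured seq_length {self.config.seq_length}"
            )

    # ---- training -------------------------------------------------------

    def _init_adam(self) -> None:
        shapes = {"emb": self.embedding, "head_w": self.head_w}
        for d, cell in enumerate(self.cells):
            for k, v in cell.params.items():
                shapes[f"cell{d}:{k}"] = v
        self._adam = {
            "m": {k: np.zeros_like(v) for k, v in shapes.items()},
            "v": {k: np.zeros_like(v) for k, v in shapes.items()},
            "mb": 0.0, "vb": 0.0, "t": 0,
        }

    def _adam_step(self, grads: dict[str, np.ndarray], gb: float) -> None:
        a = self._adam
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        a["t"] += 1
        corr1 = 1.0 - b1 ** a["t"]
        corr2 = 1.0 - b2 ** a["t"]
        for k, g in grads.items():
            a["m"][k] = b1 * a["m"][k] + (1 - b1) * g
            a["v"][k] = b2 * a["v"][k] + (1 - b2) * g * g
            update = lr * (a["m"][k] / corr1) / (np.sqrt(a["v"][k] / corr2) + eps)
            if k == "emb":
                self.embedding -= update
            elif k == "head_w":
                self.head_w -= update
            else:
                d, name = k.split(":")
                self.cells[int(d[4:])].params[name] -= update
        a["mb"] = b1 * a["mb"] + (1 - b1) * gb
        a["vb"] = b2 * a["vb"] + (1 - b2) * gb * gb
        self.head_b -= lr * (a["mb"] / corr1) / (math.sqrt(a["vb"] / corr2) + eps)

    def _batch_grads(self, idx: np.ndarray, y: np.ndarray) -> tuple[float, dict, float]:
        X, results, pooled, arg_dir, arg_hidden, probs = self._forward(idx, cache=True)
        B, L = pooled.shape
        eps = 1e-12
        loss = -float(np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))
        dlogits = (probs - y) / B
        grads: dict[str, np.ndarray] = {
            "head_w": pooled.T @ dlogits,
            "emb": np.zeros_like(self.embedding),
        }
        gb = float(dlogits.sum())
        dpooled = np.outer(dlogits, self.head_w)                     # (B, L)
        dX_total = np.zeros_like(X)
        bi, li = np.meshgrid(np.arange(B), np.arange(L), indexing="ij")
        for d, (H, caches) in enumerate(results):
            dH = np.zeros_like(H)
            mask = arg_dir == d
            dH[bi[mask], li[mask], arg_hidden[d][mask]] = dpooled[mask]
            if d == 1:
                dH = dH[:, ::-1, :]
                Xd = X[:, ::-1, :]
            else:
                Xd = X
            cell_grads, dXd = self.cells[d].backward(Xd, dH, caches)
            for k, v in cell_grads.items():
                grads[f"cell{d}:{k}"] = v
            dX_total += dXd[:, ::-1, :] if d == 1 else dXd
        np.add.at(grads["emb"], idx.reshape(-1), dX_total.reshape(-1, X.shape[2]))
        return loss, grads, gb

    def fit(self, idx: np.ndarray, y: np.ndarray) -> list[dict]:
        """Minimize binary cross-entropy; returns per-epoch history.

        A deterministic 20% slice of the input monitors validation loss for
        early stopping (restoring the best parameters); shuffling and the
        slice are driven by the config seed only.
        """
        cfg = self.config
        y = np.asarray(y, dtype=np.float64)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        if len(y) < 2 * cfg.batch_size:
            raise ValueError(
                f"need at least {2 * cfg.batch_size} examples, got {len(y)}"
            )
        rng = np.random.default_rng(cfg.seed)
        n = len(y)
        perm = rng.permutation(n)
        n_val = max(cfg.batch_size, int(round(0.2 * n)))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = idx[tr_idx], y[tr_idx]
        Xval, yval = idx[val_idx], y[val_idx]
        self._init_adam()
        best_val = np.inf
        best_state: dict | None = None
        stall = 0
        self.history = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(ytr))
            losses = []
            correct = 0
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                loss, grads, gb = self._batch_grads(Xtr[batch], ytr[batch])
                if cfg.clip_norm > 0:
                    total = math.sqrt(sum(float(np.sum(g * g))
                                          for g in grads.values()) + gb * gb)
                    if total > cfg.clip_norm:
                        scale = cfg.clip_norm / total
                        grads = {k: g * scale for k, g in grads.items()}
                        gb *= scale
                self._adam_step(grads, gb)
                losses.append(loss * len(batch))
            probs_tr = self.predict_proba(Xtr)
            correct = int(((probs_tr >= 0.5) == (ytr == 1)).sum())
            pv = self.predict_proba(Xval)
            eps = 1e-12
            val_loss = -float(np.mean(
                yval * np.log(pv + eps) + (1 - yval) * np.log(1 - pv + eps)))
            self.history.append({
                "epoch": epoch,
                "train_loss": float(np.sum(losses) / len(ytr)),
                "train_acc": correct / len(ytr),
                "val_loss": val_loss,
            })
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = self._state_copy()
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
        if best_state is not None:
            self._restore(best_state)
        return self.history

    def _state_copy(self) -> dict:
        state = {"emb": self.embedding.copy(), "head_w": self.head_w.copy(),
                 "head_b": self.head_b}
        for d, cell in enumerate(self.cells):
            for k, v in cell.params.items():
                state[f"cell{d}:{k}"] = v.copy()
        return state

    def _restore(self, state: dict) -> None:
        self.embedding = state["emb"].copy()
        self.head_w = state["head_w"].copy()
        self.head_b = state["head_b"]
        for d, cell in enumerate(self.cells):
            for k in cell.params:
                cell.params[k] = state[f"cell{d}:{k}"].copy()

    # ---- persistence ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = self._state_copy()
        arrays["head_b"] = np.asarray(arrays["head_b"])
        np.savez(path, __config__=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path: str | Path, expected_fingerprint: str | None = None) -> "GruExtractor":
        data = np.load(path, allow_pickle=False)
        config = ExtractorConfig(**json.loads(str(data["__config__"])))
        if expected_fingerprint and config.fingerprint != expected_fingerprint:
            raise ValueError(
                f"checkpoint config fingerprint {config.fingerprint} does not "
                f"match expected {expected_fingerprint}"
            )
        model = cls(config)
        state = {k: data[k] for k in data.files if k != "__config__"}
        state["head_b"] = float(state["head_b"])
        model._restore(state)
        return model


def build_extractor(config: ExtractorConfig | None = None) -> GruExtractor:
    """Construct an untrained extractor, parameters seeded from the config."""
    return GruExtractor(config or ExtractorConfig())


def train_extractor(
    model: GruExtractor,
    encoded_train: np.ndarray,
    labels: np.ndarray,
    config: ExtractorConfig | None = None,
) -> tuple[GruExtractor, list[dict]]:
    """Train the extractor's classification objective; returns (model, history).

    ``labels`` may be class-name strings (positive class ``ncRNA``) or 0/1.
    """
    if config is not None and config != model.config:
        raise ValueError("config does not match the model's build config")
    y = _as_binary(labels)
    history = model.fit(np.asarray(encoded_train), y)
    return model, history


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return (arr == "ncRNA").astype(np.float64)
    return arr.astype(np.float64)


def extract_deep_features(model: GruExtractor, encoded: np.ndarray) -> DeepFeatureVector:
    """Pooled pre-head activations for one encoded sequence."""
    values = model.features(np.atleast_2d(np.asarray(encoded)))[0]
    return DeepFeatureVector(values, model.config.fingerprint)


def extract_deep_features_batch(model: GruExtractor, encoded: np.ndarray):
    """Deep feature table (rows x feature_dim) for an (n, L) encoded batch."""
    import pandas as pd

    encoded = np.asarray(encoded)
    if encoded.size == 0:
        return pd.DataFrame(
            np.zeros((0, model.config.feature_dim)),
            columns=_deep_names(model.config.feature_dim),
        )
    values = model.features(encoded)
    return pd.DataFrame(values, columns=_deep_names(values.shape[1]))


def _deep_names(d: int) -> list[str]:
    return [f"deep_{i:04d}" for i in range(d)]
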