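"""Twin-subnetwork (Siamese) metric-learning model for field metadata.

Two copies of one subnetwork — a trainable token-lookup table, an LSTM whose
per-position states are kept, a flatten step and a linear projection — share a
single parameter set and map each encoded field to a low-dimensional embedding
(default 32-d).  Training pulls same-class pairs toward Euclidean distance 0
and pushes different-class pairs toward distance 1: the model output is
``sigmoid(distance_scale * (d - 1))`` regressed to the 0/1 pair target with
binary cross-entropy (a margin-1 contrastive loss is available via
``ModelConfig.loss``).

Everything here is plain NumPy: the forward pass, backpropagation through
time, and the Adam optimizer are implemented directly so the model has no
framework dependency and is bitwise reproducible from a seed on one thread.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .encoding import Vocabulary
from .pairing import PairSet

__all__ = [
    "ModelConfig",
    "TrainedEncoder",
    "TrainingDivergenceError",
    "build_encoder",
    "pair_distance",
    "train_siamese",
    "embed",
    "embed_batch",
    "save_encoder",
    "load_encoder",
]

_SCHEMA_VERSION = 1


class TrainingDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class ModelConfig:
    """Hyperparameters of the twin subnetwork and its training loop.

    Defaults follow the reference setup: 256-d token lookup, 64-unit LSTM,
    32-d embedding, 3 epochs at batch size 64, no tuning.
    """

    vocab_size: int
    max_len: int
    lookup_dim: int = 256
    recurrent_units: int = 64
    embedding_dim: int = 32
    epochs: int = 3
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    distance_scale: float = 4.0
    loss: str = "bce"  # "bce" or "contrastive"

    def validate(self) -> None:
        for name in ("vocab_size", "max_len", "lookup_dim", "recurrent_units",
                     "embedding_dim", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"ModelConfig.{name} must be >= 1")
        if self.learning_rate <= 0 or self.distance_scale <= 0:
            raise ValueError("learning_rate and distance_scale must be positive")
        if self.loss not in ("bce", "contrastive"):
            raise ValueError("loss must be 'bce' or 'contrastive'")


@dataclass
class TrainedEncoder:
    """Shared-weight subnetwork plus its vocabulary, config and history."""

    params: dict[str, np.ndarray]
    vocab: Vocabulary
    config: ModelConfig
    history: list[dict[str, float]] = field(default_factory=list)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def build_encoder(config: ModelConfig) -> TrainedEncoder:
    """Initialize the subnetwork parameters deterministically from the seed.

    Layout: lookup table ``(vocab_size + 1, lookup_dim)`` (row 0 serves the
    unknown/padding code), fused LSTM gate weights in i|f|g|o order, and the
    final linear projection over the flattened per-position states.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    d, h, L = config.lookup_dim, config.recurrent_units, config.max_len
    params = {
        "emb": rng.uniform(-0.05, 0.05, size=(config.vocab_size + 1, d)).astype(np.float32),
        "Wx": _glorot(rng, (d, 4 * h)),
        "Wh": _glorot(rng, (h, 4 * h)),
        "b": np.zeros(4 * h, dtype=np.float32),
        "Wp": _glorot(rng, (L * h, config.embedding_dim)),
        "bp": np.zeros(config.embedding_dim, dtype=np.float32),
    }
    params["b"][h : 2 * h] = 1.0  # forget-gate bias, standard LSTM practice
    return TrainedEncoder(params=params, vocab=None, config=config)  # type: ignore[arg-type]


def pair_distance(a: np.ndarray, b: np.ndarray) -> float | np.ndarray:
    """Euclidean distance between two embeddings (or two stacks of them)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    d = np.sqrt(np.sum((a - b) ** 2, axis=-1))
    return float(d) if d.ndim == 0 else d


def _forward(params: dict[str, np.ndarray], X: np.ndarray, keep_cache: bool):
    """Subnetwork forward pass over a batch of encoded sequences.

    Returns the (B, embedding_dim) output and, when ``keep_cache``, the
    intermediates needed for backpropagation through time.
    """
    B, L = X.shape
    h_units = params["Wh"].shape[0]
    emb = params["emb"][X]  # (B, L, D)
    pre = emb.reshape(B * L, -1) @ params["Wx"]
    pre = pre.reshape(B, L, 4 * h_units) + params["b"]
    h = np.zeros((B, h_units), dtype=np.float32)
    c = np.zeros((B, h_units), dtype=np.float32)
    H_seq = np.empty((B, L, h_units), dtype=np.float32)
    cache = [] if keep_cache else None
    for t in range(L):
        z = pre[:, t] + h @ params["Wh"]
        i = _sigmoid(z[:, :h_units])
        f = _sigmoid(z[:, h_units : 2 * h_units])
        g = np.tanh(z[:, 2 * h_units : 3 * h_units])
        o = _sigmoid(z[:, 3 * h_units :])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h_prev = h
        h = o * tc
        H_seq[:, t] = h
        if keep_cache:
            cache.append((i, f, g, o, c_prev, tc, h_prev))
    flat = H_seq.reshape(B, L * h_units)
    out = flat @ params["Wp"] + params["bp"]
    return out, (emb, flat, cache) if keep_cache else None


def _backward(
    params: dict[str, np.ndarray],
    X: np.ndarray,
    fwd_cache,
    dZ: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. all parameters given dLoss/dOutput."""
    emb, flat, cache = fwd_cache
    B, L = X.shape
    h_units = params["Wh"].shape[0]
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    grads["Wp"] = flat.T @ dZ
    grads["bp"] = dZ.sum(axis=0)
    dH_seq = (dZ @ params["Wp"].T).reshape(B, L, h_units)
    dpre = np.empty((B, L, 4 * h_units), dtype=np.float32)
    dh_next = np.zeros((B, h_units), dtype=np.float32)
    dc_next = np.zeros((B, h_units), dtype=np.float32)
    dWh = np.zeros_like(params["Wh"])
    db = np.zeros_like(params["b"])
    for t in range(L - 1, -1, -1):
        i, f, g, o, c_prev, tc, h_prev = cache[t]
        dh = dH_seq[:, t] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dpre[:, t] = dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh_next = dz @ params["Wh"].T
        dc_next = dc * f
    grads["Wh"] = dWh
    grads["b"] = db
    dpre2 = dpre.reshape(B * L, 4 * h_units)
    grads["Wx"] = emb.reshape(B * L, -1).T @ dpre2
    demb = dpre2 @ params["Wx"].T
    np.add.at(grads["emb"], X.ravel(), demb)
    return grads


def _pair_loss(za, zb, target, config):
    """Loss, dLoss/dza, dLoss/dzb and thresholded pair predictions for a batch."""
    diff = (za - zb).astype(np.float64)
    d = np.sqrt(np.sum(diff * diff, axis=1) + 1e-12)
    t = target.astype(np.float64)
    if config.loss == "bce":
        s = _sigmoid(config.distance_scale * (d - 1.0))
        eps = 1e-12
        loss = -(t * np.log(s + eps) + (1.0 - t) * np.log(1.0 - s + eps))
        dl_dd = config.distance_scale * (s - t)
        pred = (s >= 0.5).astype(np.int64)
    else:  # margin-1 contrastive
        margin = 1.0
        hinge = np.maximum(0.0, margin - d)
        loss = 0.5 * ((1.0 - t) * d * d + t * hinge * hinge)
        dl_dd = (1.0 - t) * d - t * hinge
        pred = (d >= margin / 2.0).astype(np.int64)
    dd_dza = diff / d[:, None]
    dza = (dl_dd[:, None] * dd_dza).astype(np.float32)
    return loss, dza, -dza, pred


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= (
                self.lr * (self.m[k] / corr1) / (np.sqrt(self.v[k] / corr2) + eps)
            ).astype(np.float32)


def train_siamese(
    pairs: PairSet,
    sequences: np.ndarray,
    config: ModelConfig,
    vocab: Vocabulary | None = None,
) -> TrainedEncoder:
    """Train the shared subnetwork on contrastive pairs.

    Parameters
    ----------
    pairs
        Index pairs with 0/1 targets from :func:`crfmap.pairing.generate_pairs`.
    sequences
        Encoded sequence matrix ``(n_records, max_len)`` the pair indices
        refer to.
    config
        Model and optimization settings; ``config.seed`` drives both the
        parameter initialization and the per-epoch shuffle.
    vocab
        Stored on the returned encoder for later prediction-time encoding.

    The two towers are one parameter set: each batch stacks both pair sides
    through a single forward/backward pass, which makes weight sharing exact
    by construction.  History records per-epoch mean loss and thresholded
    pair accuracy.
    """
    config.validate()
    if len(pairs) == 0:
        raise ValueError("no training pairs supplied")
    if len(np.unique(pairs.target)) < 2:
        raise ValueError("training pairs must contain both targets (0 and 1)")
    if sequences.shape[1] != config.max_len:
        raise ValueError(
            f"sequence length {sequences.shape[1]} != config.max_len {config.max_len}"
        )
    encoder = build_encoder(config)
    encoder.vocab = vocab
    params = encoder.params
    opt = _Adam(params, config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = len(pairs)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        total_correct = 0
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            Xa = sequences[pairs.a[sel]]
            Xb = sequences[pairs.b[sel]]
            X = np.concatenate([Xa, Xb], axis=0)
            out, fwd_cache = _forward(params, X, keep_cache=True)
            za, zb = out[: len(sel)], out[len(sel) :]
            loss, dza, dzb, pred = _pair_loss(za, zb, pairs.target[sel], config)
            dZ = np.concatenate([dza, dzb], axis=0) / len(sel)
            grads = _backward(params, X, fwd_cache, dZ)
            opt.step(params, grads)
            total_loss += float(loss.sum())
            total_correct += int((pred == pairs.target[sel]).sum())
        mean_loss = total_loss / n
        if not np.isfinite(mean_loss):
            raise TrainingDivergenceError(f"non-finite loss at epoch {epoch + 1}")
        encoder.history.append(
            {"epoch": epoch + 1, "loss": mean_loss, "pair_accuracy": total_correct / n}
        )
    return encoder


def embed_batch(encoder: TrainedEncoder, sequences: np.ndarray) -> np.ndarray:
    """Embed a matrix of encoded sequences; rows align with input order."""
    sequences = np.atleast_2d(np.asarray(sequences))
    if sequences.shape[1] != encoder.config.max_len:
        raise ValueError(
            f"sequence length {sequences.shape[1]} != config.max_len "
            f"{encoder.config.max_len}"
        )
    out, _ = _forward(encoder.params, sequences.astype(np.int64), keep_cache=False)
    return out.astype(np.float64)


def embed(encoder: TrainedEncoder, seq: np.ndarray) -> np.ndarray:
    """Deterministic forward pass of one encoded sequence (no distance head)."""
    return embed_batch(encoder, seq)[0]


def save_encoder(encoder: TrainedEncoder, path: str | Path) -> None:
    """Archive weights, vocabulary, config and a schema stamp into one zip."""
    path = Path(path)
    meta = {
        "schema_version": _SCHEMA_VERSION,
        "config": asdict(encoder.config),
        "history": encoder.history,
        "vocab": encoder.vocab.index_of if encoder.vocab is not None else None,
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for k, v in encoder.params.items():
            with zf.open(f"weights/{k}.npy", "w") as fh:
                np.save(fh, v)


def load_encoder(path: str | Path) -> TrainedEncoder:
    """Inverse of :func:`save_encoder`; raises ValueError on schema mismatch."""
    path = Path(path)
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("schema_version") != _SCHEMA_VERSION:
                raise ValueError(
                    f"unsupported encoder schema: {meta.get('schema_version')}"
                )
            params = {}
            for name in zf.namelist():
                if name.startswith("weights/") and name.endswith(".npy"):
                    with zf.open(name) as fh:
                        params[name[len("weights/") : -len(".npy")]] = np.load(fh)
    except (zipfile.BadZipFile, KeyError) as exc:
        raise ValueError(f"not a valid encoder archive: {path}: {exc}") from exc
    config = ModelConfig(**meta["config"])
    vocab = Vocabulary(meta["vocab"]) if meta["vocab"] is not None else None
    return TrainedEncoder(
        params=params, vocab=vocab, config=config, history=meta["history"]
    )
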