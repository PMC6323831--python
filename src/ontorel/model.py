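"""Multi-channel LSTM relation classifier over ontology-ancestor sequences.

Architecture (one "channel" per information source):

    indices -> embedding -> LSTM -> max-pool over time      (x channels)
    pooled channel outputs -> concatenation
    -> dense layer, sigmoid activation -> softmax over classes

Up to four channels are available: the masked shortest-dependency-path
words, their WordNet hypernym classes, and the two ontology views of the
entity pair — the concatenation of both entities' ancestor sequences and
the sequence of their common ancestors.  Each ontology concept enters as
a one-hot vector ``v_c`` over the concept vocabulary; the embedding layer
``f(c) = M . v_c`` maps it to a dense trainable column of the embedding
matrix ``M`` (stored transposed here, one row per concept; index 0 is
padding and fixed at the zero vector).

Training uses mini-batch gradient descent with Adam, cross-entropy loss,
dropout on every layer except the penultimate dense and output layers,
an 80/20 shuffled train/validation split and early stopping on the
validation loss with best-weight restoration.  The whole network —
forward pass, backpropagation through time and the optimiser — is
implemented directly in NumPy; gradients are verified against numeric
differentiation in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .corpus import LABELS, NEGATIVE, CandidatePair
from .preprocess import InstanceFeatures

__all__ = [
    "CHANNELS",
    "ModelConfig",
    "Vocabulary",
    "ConfigurationError",
    "MultiChannelLSTM",
    "build_model",
    "build_vocabularies",
    "embed_concept",
    "train",
    "predict",
    "save_model",
    "load_model",
]

CHANNELS = ("words", "wordnet", "concat_ancestors", "common_ancestors")
DETECTION_LABELS = (NEGATIVE, "positive")
_FORMAT_VERSION = 1

PAD = 0
UNK = 1


class ConfigurationError(Exception):
    pass


@dataclass
class ModelConfig:
    """Channel toggles and hyperparameters.

    Defaults follow the reference configuration: 50-dimensional WordNet
    and ontology embeddings (ontology dimension selected from
    {50, 100, 150}), Adam with learning rate 0.001, dropout 0.5 on every
    layer except the penultimate and output layers, early stopping on
    validation loss.  LSTM/dense widths and batch size are tunable.
    """

    channels: tuple[str, ...] = CHANNELS
    word_dim: int = 100
    wordnet_dim: int = 50
    ontology_dim: int = 50
    lstm_units: int = 100
    dense_units: int = 100
    dropout_rate: float = 0.5
    learning_rate: float = 0.001
    n_classes: int = 5
    batch_size: int = 64
    patience: int = 3
    max_epochs: int = 50
    seed: int = 0
    max_len: dict = field(default_factory=dict)  # per channel; set from data
    train_word_embeddings: bool = False

    def __post_init__(self):
        self.channels = tuple(self.channels)
        if not self.channels:
            raise ConfigurationError("at least one channel must be enabled")
        for ch in self.channels:
            if ch not in CHANNELS:
                raise ConfigurationError(f"unknown channel {ch!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.n_classes not in (2, 5):
            raise ConfigurationError("n_classes must be 2 or 5")

    def dim_of(self, channel: str) -> int:
        return {
            "words": self.word_dim,
            "wordnet": self.wordnet_dim,
            "concat_ancestors": self.ontology_dim,
            "common_ancestors": self.ontology_dim,
        }[channel]

    @property
    def labels(self) -> tuple[str, ...]:
        return LABELS if self.n_classes == 5 else DETECTION_LABELS


class Vocabulary:
    """Dense token -> integer index map; 0 is padding, 1 the unknown token."""

    def __init__(self, tokens: Sequence[str] = ()):
        self.index: dict[str, int] = {}
        for t in sorted(set(tokens)):
            self.index[t] = len(self.index) + 2

    @property
    def size(self) -> int:
        return len(self.index) + 2

    def encode(self, seq: Sequence[str]) -> list[int]:
        return [self.index.get(t, UNK) for t in seq]

    def to_dict(self) -> dict[str, int]:
        return dict(self.index)

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "Vocabulary":
        v = cls()
        v.index = {k: int(i) for k, i in d.items()}
        return v


def _channel_sequence(inst: InstanceFeatures, channel: str) -> list[str]:
    return {
        "words": inst.sdp_tokens,
        "wordnet": inst.wordnet_classes,
        "concat_ancestors": inst.concat_ancestor_seq,
        "common_ancestors": inst.common_ancestor_seq,
    }[channel]


def build_vocabularies(
    instances: Sequence[InstanceFeatures], channels: Sequence[str] = CHANNELS
) -> dict[str, Vocabulary]:
    """One vocabulary per channel from the tokens observed in instances.

    The ontology vocabularies cover exactly the concepts appearing in the
    data (each sequence already includes all ancestors of its entities),
    a small subset of the full ontology.
    """
    return {
        ch: Vocabulary([t for inst in instances for t in _channel_sequence(inst, ch)])
        for ch in channels
    }


def embed_concept(matrix: np.ndarray, concept_index: int) -> np.ndarray:
    """The dense vector ``M . v_c`` for a one-hot concept index.

    ``matrix`` holds one row per vocabulary entry (the transpose of the
    D x C formulation); the padding index returns the zero vector.
    """
    if not 0 <= concept_index < matrix.shape[0]:
        raise IndexError(f"concept index {concept_index} outside vocabulary "
                         f"of size {matrix.shape[0]}")
    return matrix[concept_index]


# ---------------------------------------------------------------------
# network


class MultiChannelLSTM:
    """The trainable network plus its vocabularies and label inventory."""

    def __init__(
        self,
        config: ModelConfig,
        vocabs: dict[str, Vocabulary],
        word_vectors: Optional[tuple[list[str], np.ndarray]] = None,
    ):
        for ch in config.channels:
            if ch not in vocabs:
                raise ConfigurationError(f"no vocabulary for channel {ch!r}")
        self.config = config
        self.vocabs = {ch: vocabs[ch] for ch in config.channels}
        self.params: dict[str, np.ndarray] = {}
        self._frozen: set[str] = set()
        rng = np.random.default_rng(config.seed)
        H = config.lstm_units
        for ch in config.channels:
            D, V = config.dim_of(ch), self.vocabs[ch].size
            E = rng.normal(0.0, 0.1, size=(V, D))
            E[PAD] = 0.0
            if ch == "words" and word_vectors is not None:
                tokens, mat = word_vectors
                if mat.shape[1] != D:
                    raise ConfigurationError(
                        f"word_dim={D} but pre-trained vectors have dim {mat.shape[1]}"
                    )
                lookup = {t: i for i, t in enumerate(tokens)}
                for tok, idx in self.vocabs[ch].index.items():
                    if tok in lookup:
                        E[idx] = mat[lookup[tok]]
            self.params[f"{ch}:E"] = E
            if ch == "words" and not config.train_word_embeddings:
                self._frozen.add(f"{ch}:E")
            s = 1.0 / np.sqrt(D + H)
            self.params[f"{ch}:Wx"] = rng.uniform(-s, s, size=(D, 4 * H))
            self.params[f"{ch}:Wh"] = rng.uniform(-s, s, size=(H, 4 * H))
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias
            self.params[f"{ch}:b"] = b
        P = H * len(config.channels)
        U, K = config.dense_units, config.n_classes
        self.params["dense:W"] = rng.uniform(-1 / np.sqrt(P), 1 / np.sqrt(P), size=(P, U))
        self.params["dense:b"] = np.zeros(U)
        self.params["out:W"] = rng.uniform(-1 / np.sqrt(U), 1 / np.sqrt(U), size=(U, K))
        self.params["out:b"] = np.zeros(K)

    # -- encoding ------------------------------------------------------

    def encode(self, instances: Sequence[InstanceFeatures]) -> dict[str, np.ndarray]:
        """Index, truncate (from the general/left end) and post-pad."""
        batch = {}
        for ch in self.config.channels:
            T = max(int(self.config.max_len.get(ch, 1)), 1)
            idx = np.full((len(instances), T), PAD, dtype=np.int64)
            lengths = np.zeros(len(instances), dtype=np.int64)
            for i, inst in enumerate(instances):
                seq = self.vocabs[ch].encode(_channel_sequence(inst, ch))
                seq = seq[-T:]
                idx[i, : len(seq)] = seq
                lengths[i] = len(seq)
            batch[ch] = idx
            batch[ch + ":len"] = lengths
        return batch

    def encode_labels(self, pairs: Sequence[CandidatePair]) -> np.ndarray:
        if self.config.n_classes == 5:
            lut = {lab: k for k, lab in enumerate(LABELS)}
            return np.array([lut[p.label] for p in pairs], dtype=np.int64)
        return np.array([1 if p.is_positive else 0 for p in pairs], dtype=np.int64)

    # -- forward / backward -------------------------------------------

    def _lstm_forward(self, ch: str, emb: np.ndarray):
        Wx, Wh, b = (self.params[f"{ch}:{k}"] for k in ("Wx", "Wh", "b"))
        B, T, _ = emb.shape
        H = self.config.lstm_units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.zeros((B, T, H))
        cache = []
        for t in range(T):
            z = emb[:, t] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            cache.append((emb[:, t], h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
            hs[:, t] = h
        return hs, cache

    def _lstm_backward(self, ch: str, dhs: np.ndarray, cache, grads):
        Wx, Wh = self.params[f"{ch}:Wx"], self.params[f"{ch}:Wh"]
        B, T, H = dhs.shape
        D = Wx.shape[0]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        demb = np.zeros((B, T, D))
        dh = np.zeros((B, H))
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c_new = cache[t]
            dh = dh + dhs[:, t]
            tc = np.tanh(c_new)
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            demb[:, t] = dz @ Wx.T
            dh = dz @ Wh.T
            dc = dc * f
        grads[f"{ch}:Wx"] = grads.get(f"{ch}:Wx", 0) + dWx
        grads[f"{ch}:Wh"] = grads.get(f"{ch}:Wh", 0) + dWh
        grads[f"{ch}:b"] = grads.get(f"{ch}:b", 0) + db
        return demb

    def forward(
        self,
        batch: dict[str, np.ndarray],
        train_mode: bool = False,
        rng: Optional[np.random.Generator] = None,
    ):
        """Return (class probabilities, cache for backward)."""
        p_drop = self.config.dropout_rate if train_mode else 0.0
        pooled_list, cache = [], {"channels": {}}
        for ch in self.config.channels:
            idx = batch[ch]
            lengths = batch[ch + ":len"]
            E = self.params[f"{ch}:E"]
            emb = E[idx]  # (B, T, D)
            if p_drop > 0:
                mask = (rng.random(emb.shape) >= p_drop) / (1.0 - p_drop)
                emb = emb * mask
            else:
                mask = None
            hs, lstm_cache = self._lstm_forward(ch, emb)
            B, T, H = hs.shape
            valid = np.arange(T)[None, :] < lengths[:, None]  # (B, T)
            masked = np.where(valid[:, :, None], hs, -np.inf)
            empty = lengths == 0
            masked[empty] = 0.0
            arg = masked.argmax(axis=1)  # (B, H)
            pooled = np.take_along_axis(masked, arg[:, None, :], axis=1)[:, 0, :]
            pooled[empty] = 0.0
            pooled_list.append(pooled)
            cache["channels"][ch] = (idx, mask, lstm_cache, arg, empty, T, H)
        concat = np.concatenate(pooled_list, axis=1)
        if p_drop > 0:
            cmask = (rng.random(concat.shape) >= p_drop) / (1.0 - p_drop)
            concat_d = concat * cmask
        else:
            cmask = None
            concat_d = concat
        a = concat_d @ self.params["dense:W"] + self.params["dense:b"]
        d = _sigmoid(a)
        logits = d @ self.params["out:W"] + self.params["out:b"]
        probs = _softmax(logits)
        cache.update(concat_d=concat_d, cmask=cmask, d=d, probs=probs)
        return probs, cache

    def backward(self, batch, cache, y: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean cross-entropy w.r.t. every parameter."""
        probs = cache["probs"]
        B = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads: dict[str, np.ndarray] = {}
        d = cache["d"]
        grads["out:W"] = d.T @ dlogits
        grads["out:b"] = dlogits.sum(axis=0)
        dd = dlogits @ self.params["out:W"].T
        da = dd * d * (1.0 - d)
        grads["dense:W"] = cache["concat_d"].T @ da
        grads["dense:b"] = da.sum(axis=0)
        dconcat = da @ self.params["dense:W"].T
        if cache["cmask"] is not None:
            dconcat = dconcat * cache["cmask"]
        H = self.config.lstm_units
        for k, ch in enumerate(self.config.channels):
            idx, mask, lstm_cache, arg, empty, T, _ = cache["channels"][ch]
            dpooled = dconcat[:, k * H : (k + 1) * H].copy()
            dpooled[empty] = 0.0
            dhs = np.zeros((idx.shape[0], T, H))
            rows = np.repeat(np.arange(idx.shape[0]), H)
            cols = np.tile(np.arange(H), idx.shape[0])
            np.add.at(dhs, (rows, arg.ravel(), cols), dpooled.ravel())
            demb = self._lstm_backward(ch, dhs, lstm_cache, grads)
            if mask is not None:
                demb = demb * mask
            dE = np.zeros_like(self.params[f"{ch}:E"])
            np.add.at(dE, idx, demb)
            dE[PAD] = 0.0
            grads[f"{ch}:E"] = dE
        return grads

    def loss(self, probs: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = weights[k].copy()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_model(
    config: ModelConfig,
    vocabs: dict[str, Vocabulary],
    word_vectors: Optional[tuple[list[str], np.ndarray]] = None,
) -> MultiChannelLSTM:
    """Assemble an untrained network from a config and vocabularies."""
    return MultiChannelLSTM(config, vocabs, word_vectors)


# ---------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, lr: float):
        self.lr = lr
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params, grads, frozen: set[str]):
        self.t += 1
        for k, g in grads.items():
            if k in frozen or np.isscalar(g):
                continue
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
        for k in params:
            if k.endswith(":E"):
                params[k][PAD] = 0.0


def train(
    model: MultiChannelLSTM,
    instances: Sequence[InstanceFeatures],
    split_fraction: float = 0.8,
    seed: Optional[int] = None,
) -> list[dict]:
    """Fit the network; returns the per-epoch train/validation loss log.

    Instances are shuffled and split ``split_fraction`` / rest into
    train/validation sets.  Training stops once the validation loss has
    failed to improve for ``patience`` consecutive epochs, and the
    best-validation weights are restored.
    """
    if len(instances) < 5:
        raise ValueError("need at least 5 instances for a train/validation split")
    cfg = model.config
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(instances))
    cut = int(round(split_fraction * len(instances)))
    if cut == 0 or cut == len(instances):
        raise ValueError("split leaves an empty partition")
    train_set = [instances[i] for i in order[:cut]]
    val_set = [instances[i] for i in order[cut:]]

    for ch in cfg.channels:  # longest observed training sequence
        cfg.max_len.setdefault(
            ch, max(max((len(_channel_sequence(i, ch)) for i in train_set), default=1), 1)
        )

    val_batch = model.encode(val_set)
    val_y = model.encode_labels([i.pair for i in val_set])
    adam = _Adam(cfg.learning_rate)
    log = []
    best_val = np.inf
    best_weights = model.copy_weights()
    bad_epochs = 0
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(train_set), cfg.batch_size):
            chunk = [train_set[i] for i in perm[start : start + cfg.batch_size]]
            batch = model.encode(chunk)
            y = model.encode_labels([i.pair for i in chunk])
            probs, cache = model.forward(batch, train_mode=True, rng=rng)
            losses.append(model.loss(probs, y) * len(chunk))
            grads = model.backward(batch, cache, y)
            adam.step(model.params, grads, model._frozen)
        val_probs, _ = model.forward(val_batch)
        val_loss = model.loss(val_probs, val_y)
        log.append(
            {
                "epoch": epoch,
                "train_loss": float(sum(losses) / len(train_set)),
                "val_loss": val_loss,
            }
        )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_weights = model.copy_weights()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    model.set_weights(best_weights)
    return log


def predict(
    model: MultiChannelLSTM, instances: Sequence[InstanceFeatures]
) -> list[tuple[CandidatePair, str, np.ndarray]]:
    """Label each instance; auto-negative pairs bypass the network.

    Returns (pair, label, class-probability vector) triples; dropout is
    disabled so repeated calls are identical.
    """
    labels = model.config.labels
    out: list[Optional[tuple]] = [None] * len(instances)
    live_idx = []
    for i, inst in enumerate(instances):
        if inst.pair.provenance == "auto_negative":
            probs = np.zeros(model.config.n_classes)
            probs[0] = 1.0
            out[i] = (inst.pair, NEGATIVE, probs)
        else:
            live_idx.append(i)
    if live_idx:
        batch = model.encode([instances[i] for i in live_idx])
        probs, _ = model.forward(batch)
        for row, i in enumerate(live_idx):
            k = int(probs[row].argmax())
            out[i] = (instances[i].pair, labels[k], probs[row])
    return out  # type: ignore[return-value]


# ---------------------------------------------------------------------
# persistence


def save_model(model: MultiChannelLSTM, path) -> None:
    """Write config (JSON), weights (NPZ) and vocabularies to a directory."""
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    cfg = asdict(model.config)
    cfg["channels"] = list(model.config.channels)
    meta = {"format_version": _FORMAT_VERSION, "config": cfg,
            "vocabs": {ch: v.to_dict() for ch, v in model.vocabs.items()}}
    (p / "model.json").write_text(json.dumps(meta))
    np.savez(p / "weights.npz", **model.params)


def load_model(path, channels: Optional[Sequence[str]] = None) -> MultiChannelLSTM:
    """Load a saved model; requesting channels it lacks is an error."""
    p = Path(path)
    meta_file = p / "model.json"
    if not meta_file.exists():
        raise ConfigurationError(f"no model metadata at {meta_file}")
    meta = json.loads(meta_file.read_text())
    if meta.get("format_version") != _FORMAT_VERSION:
        raise ConfigurationError(
            f"model format version {meta.get('format_version')} != {_FORMAT_VERSION}"
        )
    cfg = ModelConfig(**{**meta["config"], "channels": tuple(meta["config"]["channels"])})
    if channels is not None:
        missing = set(channels) - set(cfg.channels)
        if missing:
            raise ConfigurationError(f"model lacks requested channels: {sorted(missing)}")
    vocabs = {ch: Vocabulary.from_dict(d) for ch, d in meta["vocabs"].items()}
    model = MultiChannelLSTM(cfg, vocabs)
    with np.load(p / "weights.npz") as npz:
        model.set_weights({k: npz[k] for k in npz.files})
    return model
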