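"""Phase-1 feature extractors for windowed wearable-sensor data.

Six model families map a window ``[window_len, n_channels]`` to a latent
vector used by phase-2 clustering:

``cnn2d``
    Two convolutional blocks (conv → max-pool → batch-norm) on the window
    reshaped to a 2-D array whose rows per time step are the sensor
    triples (accelerometer, gyroscope, orientation); trained as a
    supervised classifier, optionally followed by an MLP autoencoder that
    compresses the features to a 32-dimensional vector.
``mlp_ae``
    Dense autoencoder with ReLU hidden layers, a 32-dimensional
    bottleneck and a sigmoid output layer.
``lstm_ae``
    1-D convolutional preprocessing followed by a two-layer LSTM encoder
    (128 and 64 units); the decoder mirrors the encoder.
``hybrid_conv_lstm``
    1-D convolutional encoder feeding an LSTM classifier, with dense
    bridge layers producing the clustering features.
``timedist_te``
    Time-distributed extraction: the window is sliced and a small conv
    stack is applied to every slice independently before an LSTM
    aggregates across slices.
``tri_head_te``
    Multi-headed extraction: three parallel convolution heads with kernel
    sizes 5, 7 and 11 (each followed by dropout and max-pooling), merged
    and passed through two BiLSTM layers, dense layers and batch
    normalization.

All families can be trained supervised (categorical cross-entropy via a
softmax head); the three autoencoder families can also be trained with a
reconstruction (MSE) objective.  Training runs on the package's numpy
layer engine with the Adam optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import nn
from .preprocess import WindowSet

FAMILIES = ("cnn2d", "mlp_ae", "lstm_ae", "hybrid_conv_lstm",
            "timedist_te", "tri_head_te")
AE_FAMILIES = ("mlp_ae", "lstm_ae", "hybrid_conv_lstm")

_DEFAULTS = {
    "cnn2d": dict(conv_filters=(32, 64), kernel=(3, 3), pool=(2, 1),
                  dropout=0.3, dense=(64,)),
    "mlp_ae": dict(hidden=(128,), bottleneck=32, output_activation="sigmoid"),
    "lstm_ae": dict(conv_filters=64, conv_kernel=5, pool=2,
                    lstm_units=(128, 64), bidirectional=False,
                    output_activation="sigmoid"),
    "hybrid_conv_lstm": dict(conv_filters=(64, 32), conv_kernel=5, pool=2,
                             lstm_units=64, dense_bridge=(128,),
                             bidirectional=False, dropout=0.3,
                             output_activation="sigmoid"),
    "timedist_te": dict(n_slices=8, conv_filters=64, conv_kernel=3, pool=2,
                        dropout=0.3, lstm_units=64, bidirectional=False),
    "tri_head_te": dict(kernels=(5, 7, 11), filters=32, dropout=0.3, pool=2,
                        bilstm_units=(64, 32), recurrent_sequences=True),
}


@dataclass(frozen=True)
class ExtractorSpec:
    """Fully resolved extractor architecture description."""

    family: str
    latent_dim: int
    n_classes: int
    input_shape: tuple          # (window_len, n_channels)
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


@dataclass
class LatentFeatures:
    """Encoder output matrix — the interface between the two phases."""

    matrix: np.ndarray                 # [n_windows, latent_dim]
    source_labels: Optional[np.ndarray] = None   # ground truth, evaluation only

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.isfinite(self.matrix).all():
            raise ValueError("latent features contain non-finite entries")
        if self.source_labels is not None:
            self.source_labels = np.asarray(self.source_labels, dtype=int)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class TrainedExtractor:
    spec: ExtractorSpec
    encoder: nn.Sequential
    head: Optional[nn.Dense]          # softmax classification head
    decoder: Optional[nn.Sequential]  # reconstruction decoder
    training_history: dict
    seed: int


def build_spec(family: str, input_shape, n_classes: int,
               latent_dim: Optional[int] = None, **overrides) -> ExtractorSpec:
    """Resolve an :class:`ExtractorSpec` with documented defaults.

    Raises ``ValueError`` with a padding suggestion when the window length
    is incompatible with the family's pooling/slicing geometry.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    w, c = int(input_shape[0]), int(input_shape[1])
    hp = dict(_DEFAULTS[family])
    unknown = set(overrides) - set(hp)
    if unknown:
        raise ValueError(f"unknown hyperparameter(s) for {family}: {sorted(unknown)}")
    hp.update(overrides)

    if family == "cnn2d":
        if c != 9:
            raise ValueError("cnn2d expects 9 channels (3 sensor triples)")
        if w % 4 != 0:
            pad = 4 - w % 4
            raise ValueError(f"cnn2d needs window_len divisible by 4 for two "
                             f"pooling stages; pad the window by {pad} samples")
        latent = latent_dim or hp["dense"][-1]
    elif family == "mlp_ae":
        latent = latent_dim or hp["bottleneck"]
        hp["bottleneck"] = latent
    elif family == "lstm_ae":
        latent = latent_dim or hp["lstm_units"][-1]
        if latent != hp["lstm_units"][-1]:
            raise ValueError("lstm_ae latent_dim is the last encoder LSTM width; "
                             "override lstm_units instead")
    elif family == "hybrid_conv_lstm":
        n_pools = len(hp["conv_filters"])
        div = hp["pool"] ** n_pools
        if w % div != 0:
            pad = div - w % div
            raise ValueError(f"hybrid_conv_lstm needs window_len divisible by "
                             f"{div}; pad the window by {pad} samples")
        latent = latent_dim or 64
    elif family == "timedist_te":
        s = hp["n_slices"]
        if w % s != 0:
            pad = s - w % s
            raise ValueError(f"timedist_te needs window_len divisible by "
                             f"n_slices={s}; pad the window by {pad} samples")
        latent = latent_dim or 64
    else:  # tri_head_te
        if len(hp["kernels"]) != 3:
            raise ValueError("tri_head_te requires exactly 3 kernel sizes")
        latent = latent_dim or 64

    return ExtractorSpec(family=family, latent_dim=int(latent),
                         n_classes=int(n_classes), input_shape=(w, c),
                         hyperparams=hp)


# ---------------------------------------------------------------------------
# network construction


def _build_encoder(spec: ExtractorSpec, rng) -> nn.Sequential:
    w, c = spec.input_shape
    hp = spec.hyperparams
    f = spec.family
    if f == "cnn2d":
        f1, f2 = hp["conv_filters"]
        enc = nn.Sequential([
            nn.Reshape((w, 3, 3)),
            nn.Conv2D(3, f1, hp["kernel"], rng, padding="same", activation="relu"),
            nn.MaxPool2D(hp["pool"]),
            nn.BatchNorm(f1),
            nn.Conv2D(f1, f2, hp["kernel"], rng, padding="same", activation="relu"),
            nn.MaxPool2D(hp["pool"]),
            nn.BatchNorm(f2),
            nn.Flatten(),
            nn.Dropout(hp["dropout"], rng),
        ])
        flat = (w // 4) * 3 * f2
        for width in hp["dense"][:-1]:
            enc.add(nn.Dense(flat, width, rng, activation="relu"))
            flat = width
        enc.add(nn.Dense(flat, spec.latent_dim, rng, activation="relu"))
        return enc
    if f == "mlp_ae":
        enc = nn.Sequential([nn.Flatten()])
        n_in = w * c
        for width in hp["hidden"]:
            enc.add(nn.Dense(n_in, width, rng, activation="relu"))
            n_in = width
        enc.add(nn.Dense(n_in, spec.latent_dim, rng, activation="relu"))
        return enc
    if f == "lstm_ae":
        u1, u2 = hp["lstm_units"]
        rec = nn.Bidirectional if hp["bidirectional"] else nn.LSTM
        mult = 2 if hp["bidirectional"] else 1
        enc = nn.Sequential([
            nn.Conv1D(c, hp["conv_filters"], hp["conv_kernel"], rng,
                      padding="same", activation="relu"),
            nn.MaxPool1D(hp["pool"]),
            rec(hp["conv_filters"], u1, rng, return_sequences=True),
            rec(u1 * mult, u2, rng, return_sequences=False),
        ])
        if hp["bidirectional"]:
            enc.add(nn.Dense(u2 * 2, spec.latent_dim, rng, activation="relu"))
        return enc
    if f == "hybrid_conv_lstm":
        f1, f2 = hp["conv_filters"]
        k, p = hp["conv_kernel"], hp["pool"]
        rec = nn.Bidirectional if hp["bidirectional"] else nn.LSTM
        mult = 2 if hp["bidirectional"] else 1
        enc = nn.Sequential([
            nn.Conv1D(c, f1, k, rng, padding="same", activation="relu"),
            nn.MaxPool1D(p),
            nn.Conv1D(f1, f2, k, rng, padding="same", activation="relu"),
            nn.MaxPool1D(p),
            nn.Dropout(hp["dropout"], rng),
            rec(f2, hp["lstm_units"], rng, return_sequences=False),
        ])
        n_in = hp["lstm_units"] * mult
        for width in hp["dense_bridge"]:
            enc.add(nn.Dense(n_in, width, rng, activation="relu"))
            n_in = width
        enc.add(nn.Dense(n_in, spec.latent_dim, rng, activation="relu"))
        return enc
    if f == "timedist_te":
        s = hp["n_slices"]
        slice_len = w // s
        fl = hp["conv_filters"]
        per_slice = nn.Sequential([
            nn.Conv1D(c, fl, hp["conv_kernel"], rng, padding="same",
                      activation="relu"),
            nn.MaxPool1D(hp["pool"]),
            nn.Dropout(hp["dropout"], rng),
            nn.Flatten(),
        ])
        rec = nn.Bidirectional if hp["bidirectional"] else nn.LSTM
        mult = 2 if hp["bidirectional"] else 1
        enc = nn.Sequential([
            nn.Reshape((s, slice_len, c)),
            nn.TimeDistributed(per_slice),
            rec((slice_len // hp["pool"]) * fl, hp["lstm_units"], rng,
                return_sequences=False),
            nn.Dense(hp["lstm_units"] * mult, spec.latent_dim, rng,
                     activation="relu"),
        ])
        return enc
    # tri_head_te
    fl, p = hp["filters"], hp["pool"]
    heads = [nn.Sequential([
        nn.Conv1D(c, fl, kk, rng, padding="same", activation="relu"),
        nn.Dropout(hp["dropout"], rng),
        nn.MaxPool1D(p),
    ]) for kk in hp["kernels"]]
    u1, u2 = hp["bilstm_units"]
    enc = nn.Sequential([
        nn.MultiHead(heads),
        nn.Bidirectional(3 * fl, u1, rng, return_sequences=True),
        nn.Bidirectional(2 * u1, u2, rng, return_sequences=False),
        nn.Dense(2 * u2, spec.latent_dim, rng, activation="relu"),
        nn.BatchNorm(spec.latent_dim),
    ])
    return enc


def _build_decoder(spec: ExtractorSpec, rng) -> nn.Sequential:
    w, c = spec.input_shape
    hp = spec.hyperparams
    out_act = hp.get("output_activation", "sigmoid")
    if spec.family == "mlp_ae":
        dec = nn.Sequential()
        n_in = spec.latent_dim
        for width in reversed(hp["hidden"]):
            dec.add(nn.Dense(n_in, width, rng, activation="relu"))
            n_in = width
        dec.add(nn.Dense(n_in, w * c, rng, activation=out_act))
        dec.add(nn.Reshape((w, c)))
        return dec
    if spec.family == "lstm_ae":
        u1, u2 = hp["lstm_units"]
        return nn.Sequential([
            nn.RepeatVector(w),
            nn.LSTM(spec.latent_dim, u2, rng, return_sequences=True),
            nn.LSTM(u2, u1, rng, return_sequences=True),
            nn.Dense(u1, c, rng, activation=out_act),
        ])
    if spec.family == "hybrid_conv_lstm":
        f1, f2 = hp["conv_filters"]
        p = hp["pool"]
        reduced = w // (p ** 2)
        return nn.Sequential([
            nn.Dense(spec.latent_dim, reduced * f2, rng, activation="relu"),
            nn.Reshape((reduced, f2)),
            nn.Upsample1D(p),
            nn.Conv1D(f2, f1, hp["conv_kernel"], rng, padding="same",
                      activation="relu"),
            nn.Upsample1D(p),
            nn.Conv1D(f1, c, hp["conv_kernel"], rng, padding="same",
                      activation=out_act),
        ])
    raise ValueError(f"family {spec.family!r} has no reconstruction decoder; "
                     f"autoencoder training supports {AE_FAMILIES}")


# ---------------------------------------------------------------------------
# training


def _as_tensor(ws) -> tuple[np.ndarray, Optional[np.ndarray]]:
    if isinstance(ws, WindowSet):
        return ws.tensor, ws.window_labels
    arr = np.asarray(ws, dtype=float)
    return arr, None


def _minibatches(n, batch_size, rng):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train_supervised(spec: ExtractorSpec, train, val=None, epochs: int = 30,
                     seed: int = 0, batch_size: int = 32,
                     lr: float = 1e-3) -> TrainedExtractor:
    """Train ``encoder + softmax head`` with categorical cross-entropy."""
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    X, y = _as_tensor(train)
    if y is None:
        raise ValueError("supervised training requires labeled windows")
    if len(np.unique(y)) < 2:
        raise ValueError("supervised training requires at least 2 classes")
    rng = np.random.default_rng(seed)
    encoder = _build_encoder(spec, rng)
    head = nn.Dense(spec.latent_dim, spec.n_classes, rng)
    opt = nn.Adam(encoder.params + head.params, encoder.grads + head.grads, lr=lr)
    hist = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}

    for _ in range(epochs):
        losses, hits, seen = [], 0, 0
        for idx in _minibatches(len(X), batch_size, rng):
            xb, yb = X[idx], y[idx]
            z = encoder.forward(xb, training=True)
            logits = head.forward(z, training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            encoder.zero_grad(), head.zero_grad()
            encoder.backward(head.backward(dlogits))
            opt.step()
            losses.append(loss * len(idx))
            hits += int((logits.argmax(axis=1) == yb).sum())
            seen += len(idx)
        hist["loss"].append(sum(losses) / seen)
        hist["accuracy"].append(hits / seen)
        if val is not None:
            Xv, yv = _as_tensor(val)
            logits = head.forward(encoder.forward(Xv, training=False),
                                  training=False)
            vloss, _ = nn.softmax_cross_entropy(logits, yv)
            hist["val_loss"].append(vloss)
            hist["val_accuracy"].append(float((logits.argmax(axis=1) == yv).mean()))
    return TrainedExtractor(spec=spec, encoder=encoder, head=head, decoder=None,
                            training_history=hist, seed=seed)


def train_autoencoder(spec: ExtractorSpec, data, epochs: int = 30,
                      seed: int = 0, batch_size: int = 32,
                      lr: float = 1e-3) -> TrainedExtractor:
    """Train ``encoder + decoder`` with mean-squared-error reconstruction."""
    if spec.family not in AE_FAMILIES:
        raise ValueError(f"autoencoder training supports {AE_FAMILIES}, "
                         f"not {spec.family!r}")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    X, _ = _as_tensor(data)
    out_act = spec.hyperparams.get("output_activation", "sigmoid")
    if out_act == "sigmoid" and (X.min() < 0.0 or X.max() > 1.0):
        raise ValueError("sigmoid reconstruction requires inputs scaled to "
                         "[0, 1]; apply MinMax scaling with range (0, 1) first")
    rng = np.random.default_rng(seed)
    encoder = _build_encoder(spec, rng)
    decoder = _build_decoder(spec, rng)
    opt = nn.Adam(encoder.params + decoder.params,
                  encoder.grads + decoder.grads, lr=lr)
    hist = {"loss": []}
    for _ in range(epochs):
        losses, seen = [], 0
        for idx in _minibatches(len(X), batch_size, rng):
            xb = X[idx]
            recon = decoder.forward(encoder.forward(xb, training=True),
                                    training=True)
            loss, dr = nn.mse(recon, xb)
            encoder.zero_grad(), decoder.zero_grad()
            encoder.backward(decoder.backward(dr))
            opt.step()
            losses.append(loss * len(idx))
            seen += len(idx)
        hist["loss"].append(sum(losses) / seen)
    return TrainedExtractor(spec=spec, encoder=encoder, head=None,
                            decoder=decoder, training_history=hist, seed=seed)


def encode(model: TrainedExtractor, ws, batch_size: int = 256) -> LatentFeatures:
    """Deterministic inference-mode encoding of a window set."""
    X, y = _as_tensor(ws)
    if X.shape[1:] != tuple(model.spec.input_shape):
        raise ValueError(f"window shape {X.shape[1:]} does not match spec "
                         f"input_shape {model.spec.input_shape}")
    chunks = [model.encoder.forward(X[i:i + batch_size], training=False)
              for i in range(0, len(X), batch_size)]
    return LatentFeatures(matrix=np.concatenate(chunks, axis=0),
                          source_labels=y)


def classify(model: TrainedExtractor, ws, batch_size: int = 256):
    """Predict window classes; returns ``(labels, accuracy_or_None)``.

    Argmax over class scores; ties resolve to the lowest class index.
    """
    if model.head is None:
        raise ValueError("model has no classification head (autoencoder-trained)")
    X, y = _as_tensor(ws)
    if len(X) == 0:
        raise ValueError("empty window set")
    preds = []
    for i in range(0, len(X), batch_size):
        z = model.encoder.forward(X[i:i + batch_size], training=False)
        preds.append(model.head.forward(z, training=False).argmax(axis=1))
    pred = np.concatenate(preds)
    acc = float((pred == y).mean()) if y is not None else None
    return pred, acc


# ---------------------------------------------------------------------------
# model persistence


def save_extractor(model: TrainedExtractor, path) -> None:
    """Save weights + spec manifest to an ``.npz`` container."""
    import json
    arrays = {f"enc_{i}": p for i, p in enumerate(model.encoder.params)}
    if model.head is not None:
        arrays.update({f"head_{i}": p for i, p in enumerate(model.head.params)})
    if model.decoder is not None:
        arrays.update({f"dec_{i}": p for i, p in enumerate(model.decoder.params)})
    manifest = dict(family=model.spec.family, latent_dim=model.spec.latent_dim,
                    n_classes=model.spec.n_classes,
                    input_shape=list(model.spec.input_shape),
                    hyperparams={k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in model.spec.hyperparams.items()},
                    seed=model.seed,
                    has_head=model.head is not None,
                    has_decoder=model.decoder is not None)
    np.savez(path, manifest=json.dumps(manifest), **arrays)


def load_extractor(path) -> TrainedExtractor:
    import json
    data = np.load(path, allow_pickle=False)
    m = json.loads(str(data["manifest"]))
    hp = {k: (tuple(v) if isinstance(v, list) else v)
          for k, v in m["hyperparams"].items()}
    spec = build_spec(m["family"], m["input_shape"], m["n_classes"],
                      latent_dim=m["latent_dim"], **hp)
    rng = np.random.default_rng(m["seed"])
    encoder = _build_encoder(spec, rng)
    head = nn.Dense(spec.latent_dim, spec.n_classes, rng) if m["has_head"] else None
    decoder = _build_decoder(spec, rng) if m["has_decoder"] else None
    for i, p in enumerate(encoder.params):
        p[...] = data[f"enc_{i}"]
    if head is not None:
        for i, p in enumerate(head.params):
            p[...] = data[f"head_{i}"]
    if decoder is not None:
        for i, p in enumerate(decoder.params):
            p[...] = data[f"dec_{i}"]
    return TrainedExtractor(spec=spec, encoder=encoder, head=head,
                            decoder=decoder, training_history={}, seed=m["seed"])


# ---------------------------------------------------------------------------
# sklearn-style estimators


class SupervisedWindowExtractor(BaseEstimator, TransformerMixin):
    """Supervised deep feature extractor with the sklearn protocol.

    ``fit(X, y)`` trains the chosen family as a classifier;
    ``transform(X)`` returns latent features, ``predict(X)`` class labels.
    ``X`` is ``[n_windows, window_len, n_channels]`` (or a WindowSet).
    """

    def __init__(self, family="hybrid_conv_lstm", latent_dim=None, epochs=30,
                 batch_size=32, lr=1e-3, seed=0, hyperparams=None):
        self.family = family
        self.latent_dim = latent_dim
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed
        self.hyperparams = hyperparams

    def fit(self, X, y=None, validation=None):
        Xa, ya = _as_tensor(X)
        if y is not None:
            ya = np.asarray(y, dtype=int)
        if ya is None:
            raise ValueError("y is required")
        ws = WindowSet(tensor=Xa, window_labels=ya, window_len=Xa.shape[1],
                       step=Xa.shape[1])
        spec = build_spec(self.family, Xa.shape[1:], int(ya.max()) + 1,
                          latent_dim=self.latent_dim,
                          **(self.hyperparams or {}))
        self.spec_ = spec
        self.model_ = train_supervised(spec, ws, val=validation,
                                       epochs=self.epochs, seed=self.seed,
                                       batch_size=self.batch_size, lr=self.lr)
        self.history_ = self.model_.training_history
        return self

    def transform(self, X):
        return encode(self.model_, X).matrix

    def predict(self, X):
        return classify(self.model_, X)[0]

    def score(self, X, y):
        return float((self.predict(X) == np.asarray(y)).mean())


class WindowAutoencoder(BaseEstimator, TransformerMixin):
    """Reconstruction-trained extractor (``mlp_ae``, ``lstm_ae`` or
    ``hybrid_conv_lstm``) with the sklearn transformer protocol."""

    def __init__(self, family="mlp_ae", latent_dim=None, epochs=30,
                 batch_size=32, lr=1e-3, seed=0, hyperparams=None):
        self.family = family
        self.latent_dim = latent_dim
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed
        self.hyperparams = hyperparams

    def fit(self, X, y=None):
        Xa, _ = _as_tensor(X)
        spec = build_spec(self.family, Xa.shape[1:], n_classes=1,
                          latent_dim=self.latent_dim,
                          **(self.hyperparams or {}))
        self.spec_ = spec
        self.model_ = train_autoencoder(spec, Xa, epochs=self.epochs,
                                        seed=self.seed,
                                        batch_size=self.batch_size, lr=self.lr)
        self.history_ = self.model_.training_history
        return self

    def transform(self, X):
        return encode(self.model_, X).matrix

    def inverse_transform(self, Z):
        return self.model_.decoder.forward(np.asarray(Z, dtype=float),
                                           training=False)
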