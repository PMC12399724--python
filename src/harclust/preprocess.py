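"""Preprocessing: per-channel MinMax scaling, sliding-window segmentation
with majority labeling, and SMOTE class rebalancing of window sets.

Estimators follow the scikit-learn protocol (``fit`` / ``transform`` /
``get_params``) so they compose with sklearn pipelines; the module-level
functions are thin one-shot wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import MinMaxScaler

from .io import SensorFrame


@dataclass
class WindowSet:
    """Fixed-length windows cut from a stream, one label per window."""

    tensor: np.ndarray          # [n_windows, window_len, n_channels]
    window_labels: np.ndarray   # [n_windows] int
    window_len: int
    step: int
    label_names: list = field(default_factory=list)
    channel_names: list = field(default_factory=list)
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.tensor = np.asarray(self.tensor, dtype=float)
        self.window_labels = np.asarray(self.window_labels, dtype=int)
        if self.tensor.ndim != 3:
            raise ValueError("tensor must be [n_windows, window_len, n_channels]")
        if self.tensor.shape[1] != self.window_len:
            raise ValueError("tensor second axis must equal window_len")
        if len(self.window_labels) != self.tensor.shape[0]:
            raise ValueError("one label per window required")
        if not (1 <= self.step <= self.window_len):
            raise ValueError("step must satisfy 1 <= step <= window_len")

    @property
    def n_windows(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_channels(self) -> int:
        return self.tensor.shape[2]

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.window_labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


class MinMaxChannelScaler(BaseEstimator, TransformerMixin):
    """Per-channel MinMax rescaling to a target range.

    ``x' = lo + (x - min) * (hi - lo) / (max - min)``; a constant channel
    maps to ``lo``.  Statistics come only from the data passed to ``fit``
    (fit on the training split to avoid leakage; fit on everything to
    reproduce whole-dataset normalization).
    """

    def __init__(self, target_range=(0.0, 1.0)):
        self.target_range = target_range

    def fit(self, X, y=None):
        X = self._as_matrix(X)
        lo, hi = self.target_range
        if not hi > lo:
            raise ValueError("target_range must satisfy hi > lo")
        self._sk = MinMaxScaler(feature_range=(lo, hi), clip=False)
        self._sk.fit(X)
        self.per_channel_min_ = self._sk.data_min_
        self.per_channel_max_ = self._sk.data_max_
        return self

    def transform(self, X):
        if not hasattr(self, "_sk"):
            raise RuntimeError("scaler is not fitted")
        if isinstance(X, SensorFrame):
            return SensorFrame(values=self._sk.transform(X.values),
                               labels=X.labels, label_names=X.label_names,
                               channel_names=X.channel_names, rate_hz=X.rate_hz)
        if isinstance(X, WindowSet):
            flat = X.tensor.reshape(-1, X.n_channels)
            return WindowSet(tensor=self._sk.transform(flat).reshape(X.tensor.shape),
                            window_labels=X.window_labels, window_len=X.window_len,
                            step=X.step, label_names=X.label_names,
                            channel_names=X.channel_names, provenance=X.provenance)
        return self._sk.transform(np.asarray(X, dtype=float))

    @staticmethod
    def _as_matrix(X):
        if isinstance(X, SensorFrame):
            return X.values
        if isinstance(X, WindowSet):
            return X.tensor.reshape(-1, X.n_channels)
        return np.asarray(X, dtype=float)


def fit_scaler(frame, target_range=(0.0, 1.0)) -> MinMaxChannelScaler:
    return MinMaxChannelScaler(target_range=target_range).fit(frame)


def apply_scaler(frame, scaler: MinMaxChannelScaler):
    return scaler.transform(frame)


class WindowSegmenter(BaseEstimator, TransformerMixin):
    """Sliding-window segmentation with majority labeling.

    ``step = max(round(window_len * (1 - overlap_frac)), 1)``; the number
    of windows is ``floor((T - window_len) / step) + 1`` and any trailing
    partial window is discarded.  Each window takes the majority label of
    its samples; ties go to the label of the window's last sample.
    """

    def __init__(self, window_len=200, overlap_frac=0.0):
        self.window_len = window_len
        self.overlap_frac = overlap_frac

    def fit(self, X=None, y=None):
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValueError("overlap_frac must be in [0, 1)")
        self.step_ = max(int(round(self.window_len * (1.0 - self.overlap_frac))), 1)
        return self

    def transform(self, frame: SensorFrame) -> WindowSet:
        self.fit()
        w, step = self.window_len, self.step_
        T = frame.n_samples
        if w > T:
            raise ValueError(f"window_len {w} exceeds stream length {T}")
        n_windows = (T - w) // step + 1
        starts = np.arange(n_windows) * step
        idx = starts[:, None] + np.arange(w)[None, :]
        tensor = frame.values[idx]             # [n_windows, w, C]
        win_labels = frame.labels[idx]         # [n_windows, w]
        labels = np.array([_majority_label(row) for row in win_labels], dtype=int)
        return WindowSet(tensor=tensor, window_labels=labels, window_len=w,
                         step=step, label_names=list(frame.label_names),
                         channel_names=list(frame.channel_names))


def _majority_label(row: np.ndarray) -> int:
    vals, counts = np.unique(row, return_counts=True)
    top = counts.max()
    winners = set(vals[counts == top].tolist())
    if len(winners) == 1:
        return winners.pop()
    return int(row[-1]) if int(row[-1]) in winners else int(
        sorted(winners)[0])  # last sample breaks the tie when it is a winner


def segment_windows(frame: SensorFrame, window_len: int,
                    overlap_frac: float = 0.0) -> WindowSet:
    return WindowSegmenter(window_len, overlap_frac).fit().transform(frame)


class SmoteUpsampler(BaseEstimator):
    """SMOTE rebalancing of a window set.

    Each minority class is augmented up to the majority-class count; a
    synthetic window is ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``,
    where ``x_nn`` is one of the ``k_neighbors`` nearest same-class
    windows of ``x`` under Euclidean distance on the flattened window.
    Original windows are kept untouched, synthetic ones are appended.
    """

    def __init__(self, k_neighbors=5, seed=0):
        self.k_neighbors = k_neighbors
        self.seed = seed

    def fit_resample(self, ws: WindowSet) -> WindowSet:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        counts = ws.class_counts()
        singleton = [c for c, n in counts.items() if n < 2]
        if singleton:
            raise ValueError(
                f"class(es) {singleton} have a single window; SMOTE needs >= 2 "
                "per class — merge these classes or exclude them first")
        target = max(counts.values())
        if all(n == target for n in counts.values()):
            return ws
        rng = np.random.default_rng(self.seed)
        flat = ws.tensor.reshape(ws.n_windows, -1)
        new_x, new_y = [ws.tensor], [ws.window_labels]
        for cls in sorted(counts):
            deficit = target - counts[cls]
            if deficit == 0:
                continue
            members = np.flatnonzero(ws.window_labels == cls)
            Xc = flat[members]
            k = min(self.k_neighbors, len(members) - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
            _, nbrs = nn.kneighbors(Xc)   # first column is the point itself
            base = rng.integers(0, len(members), size=deficit)
            pick = rng.integers(1, k + 1, size=deficit)
            u = rng.random(deficit)[:, None]
            synth = Xc[base] + u * (Xc[nbrs[base, pick]] - Xc[base])
            new_x.append(synth.reshape(deficit, ws.window_len, ws.n_channels))
            new_y.append(np.full(deficit, cls, dtype=int))
        return WindowSet(tensor=np.concatenate(new_x, axis=0),
                         window_labels=np.concatenate(new_y),
                         window_len=ws.window_len, step=ws.step,
                         label_names=ws.label_names,
                         channel_names=ws.channel_names,
                         provenance=ws.provenance + ["smote"])


def smote_upsample(ws: WindowSet, k_neighbors: int = 5, seed: int = 0,
                   scope: str = "train_only") -> WindowSet:
    """One-shot SMOTE.  ``scope`` is a bookkeeping tag: ``train_only``
    callers pass their training split only; ``all`` callers pass the full
    window set.  The resampling itself is identical."""
    if scope not in ("train_only", "all"):
        raise ValueError("scope must be 'train_only' or 'all'")
    return SmoteUpsampler(k_neighbors=k_neighbors, seed=seed).fit_resample(ws)


def train_val_test_split(ws: WindowSet, val_frac=0.16, test_frac=0.20, seed=0):
    """Stratified window split (defaults 64/16/20)."""
    rng = np.random.default_rng(seed)
    n = ws.n_windows
    tr_idx, va_idx, te_idx = [], [], []
    for cls in np.unique(ws.window_labels):
        members = np.flatnonzero(ws.window_labels == cls)
        rng.shuffle(members)
        n_te = int(round(len(members) * test_frac))
        n_va = int(round(len(members) * val_frac))
        te_idx.extend(members[:n_te])
        va_idx.extend(members[n_te:n_te + n_va])
        tr_idx.extend(members[n_te + n_va:])

    def subset(idx):
        idx = np.sort(np.array(idx, dtype=int))
        return WindowSet(tensor=ws.tensor[idx], window_labels=ws.window_labels[idx],
                         window_len=ws.window_len, step=ws.step,
                         label_names=ws.label_names, channel_names=ws.channel_names,
                         provenance=ws.provenance)
    return subset(tr_idx), subset(va_idx), subset(te_idx)
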