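"""Readers for the two supported on-disk layouts.

* MobiAct-dialect CSV: 12 columns — ``timestamp`` (ISO-8601), ``rel_time``
  (seconds), 9 sensor channels (triaxial accelerometer + gyroscope +
  azimuth/pitch/roll), and a string ``label``.  The temporal metadata
  columns are dropped on load; only sensor readings are kept for
  clustering, with the label retained for evaluation.
* UCI-HAR raw-signal directory: nine whitespace-delimited text files of
  pre-windowed signals (one row per window, 128 readings each) plus a
  ``y_<split>.txt`` label file — the dataset ships already segmented with
  2.56 s windows at 50% overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import DEFAULT_CHANNELS

logger = logging.getLogger(__name__)

MOBIACT_COLUMNS = ["timestamp", "rel_time", *DEFAULT_CHANNELS, "label"]

UCI_SIGNALS = [
    "body_acc_x", "body_acc_y", "body_acc_z",
    "body_gyro_x", "body_gyro_y", "body_gyro_z",
    "total_acc_x", "total_acc_y", "total_acc_z",
]
UCI_ACTIVITY_NAMES = ["WALKING", "WALKING_UPSTAIRS", "WALKING_DOWNSTAIRS",
                      "SITTING", "STANDING", "LAYING"]


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass
class SensorFrame:
    """Continuous sensor matrix plus integer-encoded per-sample labels."""

    values: np.ndarray          # [T, n_channels]
    labels: np.ndarray          # [T] int
    label_names: list = field(default_factory=list)
    channel_names: list = field(default_factory=list)
    rate_hz: float = 200.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2 or len(self.values) < 1:
            raise ValueError("values must be a non-empty [T, n_channels] matrix")
        if len(self.labels) != len(self.values):
            raise ValueError("labels length must equal number of samples")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain non-finite entries")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def read_mobiact_csv(path, rate_hz: float = 200.0) -> SensorFrame:
    """Load a MobiAct-dialect CSV into a :class:`SensorFrame`.

    Drops ``timestamp``/``rel_time``, keeps the 9 sensor channels, and
    integer-encodes the ``label`` column (name table in ``label_names``,
    ordered by first appearance).  Unknown extra columns are ignored with
    a warning; a missing required column raises :class:`FormatError`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MOBIACT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in MOBIACT_COLUMNS]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path.name, extra)
    if len(df) == 0:
        raise FormatError(f"{path.name}: no data rows")
    sensor = df[DEFAULT_CHANNELS]
    if sensor.isna().any().any():
        n_before = len(df)
        df = df.dropna(subset=DEFAULT_CHANNELS)
        logger.warning("%s: dropped %d rows with missing sensor values",
                       path.name, n_before - len(df))
        if len(df) == 0:
            raise FormatError(f"{path.name}: all rows had missing values")
        sensor = df[DEFAULT_CHANNELS]
    raw_labels = df["label"].astype(str).to_numpy()
    names = list(dict.fromkeys(raw_labels))
    codes = np.array([names.index(l) for l in raw_labels], dtype=int)
    return SensorFrame(values=sensor.to_numpy(dtype=float), labels=codes,
                       label_names=names, channel_names=list(DEFAULT_CHANNELS),
                       rate_hz=rate_hz)


def read_uci_har_dir(path, split: str = "train"):
    """Load one split of a UCI-HAR-layout raw-signal directory.

    Accepts either the dataset root (containing ``<split>/Inertial
    Signals``) or the split directory itself.  Returns a
    :class:`~harclust.preprocess.WindowSet` with ``window_len=128`` and 9
    channels; window labels are re-coded to 0-based.
    """
    from .preprocess import WindowSet  # local import to avoid a cycle

    if split not in ("train", "test"):
        raise ValueError("split must be 'train' or 'test'")
    root = Path(path)
    split_dir = root / split if (root / split).is_dir() else root
    sig_dir = (split_dir / "Inertial Signals"
               if (split_dir / "Inertial Signals").is_dir() else split_dir)

    mats = []
    for name in UCI_SIGNALS:
        f = sig_dir / f"{name}_{split}.txt"
        if not f.exists():
            raise FormatError(f"missing signal file {f}")
        m = np.loadtxt(f, ndmin=2)
        if m.shape[1] != 128:
            raise FormatError(f"{f.name}: expected 128 readings per window, "
                              f"got {m.shape[1]}")
        mats.append(m)
    n_windows = {m.shape[0] for m in mats}
    if len(n_windows) != 1:
        raise FormatError(f"signal files disagree on window count: {sorted(n_windows)}")

    y_file = split_dir / f"y_{split}.txt"
    if not y_file.exists():
        raise FormatError(f"missing label file {y_file}")
    y = np.loadtxt(y_file, dtype=int, ndmin=1)
    if len(y) != mats[0].shape[0]:
        raise FormatError("label count does not match window count")
    if y.min() < 1 or y.max() > 6:
        raise FormatError("labels must be in 1..6")

    tensor = np.stack(mats, axis=-1)  # [n_windows, 128, 9]
    return WindowSet(tensor=tensor, window_labels=y - 1, window_len=128,
                     step=64, label_names=list(UCI_ACTIVITY_NAMES),
                     channel_names=list(UCI_SIGNALS),
                     provenance=[str(split_dir)])


def frame_from_stream(stream) -> SensorFrame:
    """Adapt a simulated :class:`~harclust.simulate.LabeledStream`."""
    return SensorFrame(values=stream.values, labels=stream.labels,
                       label_names=list(stream.label_names),
                       channel_names=list(stream.channel_names),
                       rate_hz=stream.rate_hz)
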