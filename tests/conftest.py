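import numpy as np
import pytest

import harclust as h


@pytest.fixture(scope="session")
def small_stream():
    """3 well-separated activities, 60 s at 50 Hz, no cross-fade."""
    spec = h.default_stream_spec(k=3, seed=0, total_duration_s=60.0,
                                 rate_hz=50.0, noise_sd=0.1,
                                 transition_len_s=0.0)
    return h.simulate_stream(spec)


@pytest.fixture(scope="session")
def small_windows(small_stream):
    """Separable windowed fixture: 64-sample windows, 50% overlap, scaled
    to (0, 1).  Windows straddling a bout boundary mix two activities, so
    only label-pure windows are kept."""
    from harclust.preprocess import WindowSet

    frame = h.io.frame_from_stream(small_stream)
    ws = h.segment_windows(frame, 64, 0.5)
    starts = np.arange(ws.n_windows) * ws.step
    pure = np.array([len(np.unique(small_stream.labels[s:s + 64])) == 1
                     for s in starts])
    ws = WindowSet(tensor=ws.tensor[pure], window_labels=ws.window_labels[pure],
                   window_len=64, step=ws.step, label_names=ws.label_names)
    return h.MinMaxChannelScaler((0.0, 1.0)).fit(ws).transform(ws)


@pytest.fixture(scope="session")
def small_split(small_windows):
    from harclust.preprocess import train_val_test_split
    return train_val_test_split(small_windows, seed=0)


@pytest.fixture(scope="session")
def latent_blobs():
    """Three moderately overlapping 10-D Gaussian blobs (latent-space
    stand-in), MinMax-scaled to [0, 1]."""
    from sklearn.datasets import make_blobs
    X, y = make_blobs(n_samples=600, n_features=10, centers=3,
                      cluster_std=5.0, random_state=1)
    X = (X - X.min(0)) / (X.max(0) - X.min(0))
    return X, y


def write_uci_fixture(root, n_windows=4, seed=0, labels=None):
    """Create a tiny synthetic UCI-HAR-layout raw-signal directory."""
    from harclust.io import UCI_SIGNALS

    rng = np.random.default_rng(seed)
    split_dir = root / "train" / "Inertial Signals"
    split_dir.mkdir(parents=True)
    for name in UCI_SIGNALS:
        m = rng.standard_normal((n_windows, 128))
        np.savetxt(split_dir / f"{name}_train.txt", m, fmt="%.6e")
    y = np.asarray(labels if labels is not None
                   else rng.integers(1, 7, size=n_windows))
    np.savetxt(root / "train" / "y_train.txt", y, fmt="%d")
    return root
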