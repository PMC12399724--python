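"""Synthetic labeled wearable-sensor streams.

Emulates the statistical structure of smartphone activity-recognition
recordings: each activity has a quasi-periodic per-channel signature
(sinusoid + DC offset + Gaussian noise on 9 channels: triaxial
accelerometer, triaxial gyroscope, and azimuth/pitch/roll orientation),
activity bouts follow a semi-Markov chain (truncated-normal durations,
Markov next-activity draws), and consecutive bouts are joined by a linear
cross-fade so that activities flow into one another the way real
transitional movements (sit-to-stand, etc.) do.

The generative model is an artifact of this package — real benchmark
recordings are not sinusoidal — but it reproduces the properties the
downstream pipeline is sensitive to: class-distinct signatures, brief
ambiguous transitions, class imbalance, and sensor noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEFAULT_CHANNELS = [
    "acc_x", "acc_y", "acc_z",
    "gyro_x", "gyro_y", "gyro_z",
    "azimuth", "pitch", "roll",
]

#: Activity-name pool used by :func:`make_default_profiles` (MobiAct-style codes).
DEFAULT_ACTIVITY_NAMES = [
    "STD", "WAL", "JOG", "STU", "STN", "SIT",
    "CHU", "CSI", "CSO", "LYI", "FOL", "JUM",
]

TRANSITION_LABEL_NAME = "TRA"


@dataclass(frozen=True)
class ActivityProfile:
    """Per-channel sinusoidal signature of one activity class."""

    name: str
    amplitude: np.ndarray   # [n_channels] signal envelope, sensor units
    frequency: np.ndarray   # [n_channels] Hz; 0 for static postures
    phase: np.ndarray       # [n_channels] radians
    baseline: np.ndarray    # [n_channels] DC offset
    duration_mean: float    # seconds
    duration_sd: float      # seconds

    def __post_init__(self):
        for f in ("amplitude", "frequency", "phase", "baseline"):
            object.__setattr__(self, f, np.asarray(getattr(self, f), dtype=float))
        n = len(self.amplitude)
        if not (len(self.frequency) == len(self.phase) == len(self.baseline) == n):
            raise ValueError("amplitude/frequency/phase/baseline lengths differ")
        if self.duration_mean <= 0:
            raise ValueError("duration_mean must be > 0")
        if np.any(self.frequency < 0):
            raise ValueError("frequency must be >= 0")

    @property
    def n_channels(self) -> int:
        return len(self.amplitude)


@dataclass(frozen=True)
class StreamSpec:
    """Full description of one simulated recording."""

    profiles: tuple
    transition_matrix: np.ndarray  # [k, k] row-stochastic
    class_prior: np.ndarray        # [k] initial-state distribution
    rate_hz: float = 200.0
    transition_len_s: float = 0.0
    noise_sd: float = 0.0
    total_duration_s: float = 60.0
    transition_label: str = "incoming"   # "incoming" or "reserved"
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "profiles", tuple(self.profiles))
        object.__setattr__(self, "transition_matrix",
                           np.asarray(self.transition_matrix, dtype=float))
        object.__setattr__(self, "class_prior",
                           np.asarray(self.class_prior, dtype=float))
        k = len(self.profiles)
        if k < 2:
            raise ValueError("need at least 2 activity profiles")
        if self.transition_matrix.shape != (k, k):
            raise ValueError("transition_matrix must be k x k")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition_matrix rows must sum to 1")
        if not np.isclose(self.class_prior.sum(), 1.0, atol=1e-9):
            raise ValueError("class_prior must sum to 1")
        if self.transition_label not in ("incoming", "reserved"):
            raise ValueError("transition_label must be 'incoming' or 'reserved'")
        if self.total_duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("rate_hz and total_duration_s must be > 0")
        if self.transition_len_s < 0 or self.noise_sd < 0:
            raise ValueError("transition_len_s and noise_sd must be >= 0")

    @property
    def k(self) -> int:
        return len(self.profiles)


@dataclass
class LabeledStream:
    """Continuous multichannel recording with a per-sample activity label."""

    values: np.ndarray          # [T, n_channels]
    labels: np.ndarray          # [T] int; k == reserved transition label
    rate_hz: float
    channel_names: list = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    label_names: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values lengths differ")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def make_default_profiles(k: int, n_channels: int = 9, seed: int = 0,
                          duration_mean_s: float = 5.0,
                          duration_sd_s: float = 1.5) -> list[ActivityProfile]:
    """Draw ``k`` pairwise-distinct activity signatures.

    Frequencies are spread over 0.5-4.5 Hz (gait-band), amplitudes over
    0.5-2 sensor units, with per-channel jitter so no two activities share
    an (amplitude, frequency) tuple.  Deterministic for a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    profiles = []
    base_freq = np.linspace(0.5, 4.5, k)
    for j in range(k):
        name = (DEFAULT_ACTIVITY_NAMES[j] if j < len(DEFAULT_ACTIVITY_NAMES)
                else f"ACT{j}")
        freq = base_freq[j] * (1.0 + 0.1 * rng.standard_normal(n_channels))
        freq = np.abs(freq)
        amp = rng.uniform(0.5, 2.0, n_channels)
        phase = rng.uniform(0.0, 2 * np.pi, n_channels)
        baseline = rng.uniform(-1.0, 1.0, n_channels)
        profiles.append(ActivityProfile(
            name=name, amplitude=amp, frequency=freq, phase=phase,
            baseline=baseline, duration_mean=duration_mean_s,
            duration_sd=duration_sd_s))
    return profiles


def default_stream_spec(k: int = 6, seed: int = 0, rate_hz: float = 200.0,
                        total_duration_s: float = 120.0,
                        transition_len_s: float = 0.25,
                        noise_sd: float = 0.15,
                        imbalance: float = 2.0,
                        transition_label: str = "incoming") -> StreamSpec:
    """Study-condition default: ``k`` activities at 200 Hz with brief
    cross-fade transitions, moderate noise and a mildly imbalanced chain.

    ``imbalance`` is the ratio between the largest and smallest stationary
    weight of the activity chain (2 by default: common activities such as
    walking occur about twice as often as the rarest).
    """
    profiles = make_default_profiles(k, seed=seed)
    rng = np.random.default_rng(seed + 1)
    weights = np.linspace(imbalance, 1.0, k)
    weights = weights / weights.sum()
    # Row j: jump to any other class proportionally to its weight.
    P = np.tile(weights, (k, 1))
    np.fill_diagonal(P, 0.0)
    P = P / P.sum(axis=1, keepdims=True)
    return StreamSpec(
        profiles=profiles, transition_matrix=P, class_prior=weights,
        rate_hz=rate_hz, transition_len_s=transition_len_s,
        noise_sd=noise_sd, total_duration_s=total_duration_s,
        transition_label=transition_label, seed=seed)


def _signature(profile: ActivityProfile, t: np.ndarray) -> np.ndarray:
    """Noise-free signal of one activity at absolute times ``t`` (seconds)."""
    return (profile.baseline[None, :]
            + profile.amplitude[None, :]
            * np.sin(2 * np.pi * profile.frequency[None, :] * t[:, None]
                     + profile.phase[None, :]))


def simulate_stream(spec: StreamSpec) -> LabeledStream:
    """Simulate one labeled recording from a :class:`StreamSpec`.

    Bout durations are truncated normal (floor one sample); the next
    activity is drawn from the transition-matrix row of the current one;
    consecutive bouts are mixed by a linear cross-fade of
    ``transition_len_s`` seconds.  Cross-fade samples are labeled with the
    incoming activity by default, or with a reserved label ``k`` when
    ``transition_label == 'reserved'``.
    """
    rng = np.random.default_rng(spec.seed)
    T = int(round(spec.total_duration_s * spec.rate_hz))
    k = spec.k

    # draw the bout sequence until it covers T samples
    states, lengths = [], []
    total = 0
    state = int(rng.choice(k, p=spec.class_prior))
    while total < T:
        prof = spec.profiles[state]
        dur_s = rng.normal(prof.duration_mean, prof.duration_sd)
        n = max(int(round(dur_s * spec.rate_hz)), 1)
        states.append(state)
        lengths.append(n)
        total += n
        state = int(rng.choice(k, p=spec.transition_matrix[state]))
    lengths[-1] -= total - T  # crop final bout to the stream end
    if lengths[-1] < 1:       # fully cropped: drop it
        states.pop(), lengths.pop()
        lengths[-1] = T - sum(lengths[:-1])

    t = np.arange(T) / spec.rate_hz
    values = np.empty((T, spec.profiles[0].n_channels))
    labels = np.empty(T, dtype=int)
    pos = 0
    for state, n in zip(states, lengths):
        sl = slice(pos, pos + n)
        values[sl] = _signature(spec.profiles[state], t[sl])
        labels[sl] = state
        pos += n

    # linear cross-fade around each bout boundary
    fade = int(round(spec.transition_len_s * spec.rate_hz))
    if fade > 0:
        boundaries = np.cumsum(lengths)[:-1]
        for b_idx, b in enumerate(boundaries):
            lo = max(b - fade // 2, 0)
            hi = min(lo + fade, T)
            if hi <= lo:
                continue
            prev_s, next_s = states[b_idx], states[b_idx + 1]
            w = np.linspace(0.0, 1.0, hi - lo)[:, None]
            prev_sig = _signature(spec.profiles[prev_s], t[lo:hi])
            next_sig = _signature(spec.profiles[next_s], t[lo:hi])
            values[lo:hi] = (1 - w) * prev_sig + w * next_sig
            if spec.transition_label == "reserved":
                labels[lo:hi] = k
            else:
                labels[lo:hi] = next_s

    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=values.shape)

    label_names = [p.name for p in spec.profiles]
    if spec.transition_label == "reserved":
        label_names = label_names + [TRANSITION_LABEL_NAME]
    return LabeledStream(values=values, labels=labels, rate_hz=spec.rate_hz,
                         channel_names=list(DEFAULT_CHANNELS[:values.shape[1]])
                         if values.shape[1] <= 9 else
                         [f"ch{i}" for i in range(values.shape[1])],
                         label_names=label_names)


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary vector of an ergodic Markov chain (left eigenvector)."""
    P = np.asarray(transition_matrix, dtype=float)
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def write_stream_csv(stream: LabeledStream, path, start_time=None) -> None:
    """Write a stream as a MobiAct-dialect CSV.

    Twelve columns: ISO-8601 ``timestamp``, ``rel_time`` in seconds, the 9
    sensor channels, and a string ``label``.  Values are printed with 9+
    significant digits so a read-back round-trips to float precision.
    """
    if stream.n_channels != 9:
        warnings.warn(f"MobiAct dialect expects 9 channels, got {stream.n_channels}")
    start = pd.Timestamp("2020-01-01T00:00:00") if start_time is None else pd.Timestamp(start_time)
    rel = np.arange(stream.n_samples) / stream.rate_hz
    names = stream.label_names or []

    def label_str(i):
        j = int(stream.labels[i])
        return names[j] if j < len(names) else str(j)

    df = pd.DataFrame(stream.values, columns=stream.channel_names)
    df.insert(0, "rel_time", rel)
    df.insert(0, "timestamp",
              [(start + pd.Timedelta(seconds=float(s))).isoformat() for s in rel])
    df["label"] = [label_str(i) for i in range(stream.n_samples)]
    df.to_csv(path, index=False, float_format="%.10g")


def with_seed(spec: StreamSpec, seed: int) -> StreamSpec:
    """Copy of a spec with a different seed (convenience for replicates)."""
    return replace(spec, seed=seed)
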