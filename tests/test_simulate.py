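"""Simulator: determinism, degenerate signals, semi-Markov label
structure, CSV round-trips."""

import numpy as np
import pytest

import harclust as h
from harclust.simulate import (ActivityProfile, StreamSpec,
                               stationary_distribution, write_stream_csv)


def _static_profile(name="STD", n=9, baseline=1.0, dur=2.0):
    return ActivityProfile(name=name, amplitude=np.zeros(n),
                           frequency=np.zeros(n), phase=np.zeros(n),
                           baseline=np.full(n, baseline),
                           duration_mean=dur, duration_sd=0.1)


class TestProfiles:
    def test_profiles_are_pairwise_distinct(self):
        profs = h.make_default_profiles(k=2, n_channels=9, seed=0)
        assert len(profs) == 2
        assert not (np.allclose(profs[0].amplitude, profs[1].amplitude)
                    and np.allclose(profs[0].frequency, profs[1].frequency))

    def test_deterministic_for_fixed_seed(self):
        a = h.make_default_profiles(k=6, n_channels=9, seed=1)
        b = h.make_default_profiles(k=6, n_channels=9, seed=1)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.amplitude, pb.amplitude)
            assert np.array_equal(pa.frequency, pb.frequency)
            assert np.array_equal(pa.phase, pb.phase)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            h.make_default_profiles(k=1, n_channels=9, seed=0)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            ActivityProfile(name="X", amplitude=np.ones(3),
                            frequency=np.ones(3), phase=np.zeros(3),
                            baseline=np.zeros(3), duration_mean=-1.0,
                            duration_sd=0.5)


class TestStreamSpec:
    def test_rejects_non_stochastic_matrix(self):
        profs = h.make_default_profiles(2, seed=0)
        with pytest.raises(ValueError):
            StreamSpec(profiles=profs, transition_matrix=[[0.5, 0.4], [0, 1]],
                       class_prior=[0.5, 0.5])

    def test_rejects_bad_prior(self):
        profs = h.make_default_profiles(2, seed=0)
        with pytest.raises(ValueError):
            StreamSpec(profiles=profs, transition_matrix=[[0, 1], [1, 0]],
                       class_prior=[0.7, 0.7])


class TestSimulateStream:
    def test_sample_count(self):
        spec = h.default_stream_spec(k=3, seed=0, total_duration_s=10.0,
                                     rate_hz=50.0)
        s = h.simulate_stream(spec)
        assert s.n_samples == 500
        assert s.n_channels == 9

    def test_determinism_bitwise(self):
        spec = h.default_stream_spec(k=4, seed=7, total_duration_s=20.0,
                                     rate_hz=50.0)
        a, b = h.simulate_stream(spec), h.simulate_stream(spec)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.labels, b.labels)

    def test_static_profile_gives_constant_baseline(self):
        profs = [_static_profile("A", baseline=2.5),
                 _static_profile("B", baseline=2.5)]
        spec = StreamSpec(profiles=profs,
                          transition_matrix=[[0.0, 1.0], [1.0, 0.0]],
                          class_prior=[1.0, 0.0], rate_hz=50.0,
                          transition_len_s=0.0, noise_sd=0.0,
                          total_duration_s=5.0, seed=0)
        s = h.simulate_stream(spec)
        assert np.allclose(s.values, 2.5)

    def test_label_runs_match_bouts_without_crossfade(self):
        spec = h.default_stream_spec(k=3, seed=5, total_duration_s=30.0,
                                     rate_hz=50.0, transition_len_s=0.0)
        s = h.simulate_stream(spec)
        # consecutive runs only change at bout boundaries, each run >= 1
        changes = np.flatnonzero(np.diff(s.labels)) + 1
        runs = np.diff(np.concatenate([[0], changes, [s.n_samples]]))
        assert runs.min() >= 1 and runs.sum() == s.n_samples

    def test_label_proportions_match_stationary_distribution(self):
        # oracle: left eigenvector of the transition matrix
        profs = h.make_default_profiles(3, seed=0, duration_mean_s=0.5,
                                        duration_sd_s=0.05)
        P = np.array([[0.0, 0.7, 0.3], [0.2, 0.0, 0.8], [0.5, 0.5, 0.0]])
        spec = StreamSpec(profiles=profs, transition_matrix=P,
                          class_prior=[1 / 3] * 3, rate_hz=50.0,
                          transition_len_s=0.0, noise_sd=0.0,
                          total_duration_s=600.0, seed=3)
        s = h.simulate_stream(spec)
        pi = stationary_distribution(P)
        emp = np.bincount(s.labels, minlength=3) / s.n_samples
        # equal mean durations: time shares follow the visit distribution
        assert np.all(np.abs(emp - pi) <= 0.1 * pi + 0.02)

    def test_reserved_transition_labeling(self):
        spec = h.default_stream_spec(k=3, seed=1, total_duration_s=30.0,
                                     rate_hz=50.0, transition_len_s=0.5,
                                     transition_label="reserved")
        s = h.simulate_stream(spec)
        assert set(np.unique(s.labels)) <= set(range(4))
        assert (s.labels == 3).any()
        assert s.label_names[-1] == "TRA"

    def test_incoming_transition_labels_stay_in_range(self):
        spec = h.default_stream_spec(k=3, seed=1, total_duration_s=30.0,
                                     rate_hz=50.0, transition_len_s=0.5)
        s = h.simulate_stream(spec)
        assert set(np.unique(s.labels)) <= set(range(3))

    def test_class_centroids_distinct_at_low_noise(self):
        spec = h.default_stream_spec(k=3, seed=0, total_duration_s=60.0,
                                     rate_hz=50.0, noise_sd=0.01,
                                     transition_len_s=0.0)
        s = h.simulate_stream(spec)
        ws = h.segment_windows(h.io.frame_from_stream(s), 50, 0.0)
        cents = [ws.tensor[ws.window_labels == c].mean(axis=0).ravel()
                 for c in range(3)]
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(cents[i] - cents[j]) > 0.5


class TestCsvRoundTrip:
    def test_row_count_and_round_trip(self, tmp_path):
        spec = h.default_stream_spec(k=2, seed=0, total_duration_s=0.05,
                                     rate_hz=200.0)
        s = h.simulate_stream(spec)
        assert s.n_samples == 10
        path = tmp_path / "stream.csv"
        write_stream_csv(s, path)
        assert len(path.read_text().splitlines()) == 11  # header + 10 rows
        frame = h.read_mobiact_csv(path)
        assert frame.n_samples == 10 and frame.n_channels == 9
        assert np.allclose(frame.values, s.values, atol=1e-6)
        assert np.array_equal(frame.labels, s.labels)

    def test_empty_stream_writes_header_only(self, tmp_path):
        s = h.LabeledStream(values=np.empty((0, 9)), labels=np.empty(0, int),
                            rate_hz=200.0)
        path = tmp_path / "empty.csv"
        write_stream_csv(s, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("timestamp,rel_time")
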