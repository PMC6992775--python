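"""Band normalization, peak template, subsequence DTW, pulse features."""

import dataclasses

import numpy as np
import pytest

from p53pulse import (
    BandConstants,
    CellTrajectory,
    PulseFeature,
    TemperatureProtocol,
    band_constants_for_population,
    band_envelope,
    band_normalize,
    detect_pulses,
    dtw_match,
    filter_overlaps,
    generate_experiment,
    make_peak_pattern,
    pulse_features,
    pulse_state_probabilities,
)


def dp_reference(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Independent top-down memoized reference for the subsequence-DTW matrix."""
    import functools

    @functools.lru_cache(maxsize=None)
    def s(i: int, j: int) -> float:
        if i < 0:
            return np.inf  # virtual row above the first signal sample
        c = abs(x[i] - p[j])
        if j == 0:
            return c  # free start anywhere in the signal
        return c + min(s(i - 1, j), s(i, j - 1), s(i - 1, j - 1))

    out = np.empty((x.size, p.size))
    for i in range(x.size):
        for j in range(p.size):
            out[i, j] = s(i, j)
    return out


class TestBandEnvelope:
    def test_constant_signal_band_from_clamp_rules(self):
        c, w = 5.0, 0.8
        consts = BandConstants(min_band_width=w, lower_cap=10.0, upper_floor=0.0)
        env = band_envelope(np.full(50, c), consts)
        np.testing.assert_allclose(env.lower, c)
        np.testing.assert_allclose(env.upper, c + w)

    def test_single_pulse_envelopes_track_extrema(self):
        x = np.zeros(97)
        x[40:57] = make_peak_pattern(4.0, 0.25) * 10
        consts = BandConstants(min_band_width=0.5, lower_cap=0.0, upper_floor=0.0)
        env = band_envelope(x, consts)
        np.testing.assert_allclose(env.lower, 0.0, atol=1e-12)
        assert env.upper.max() == pytest.approx(10.0)
        # oracle: running extrema over the window
        n_win = 25  # 6 h at 0.25 h, forced odd
        for i in (48, 20):
            lo = max(0, i - n_win // 2)
            hi = min(x.size, i + n_win // 2 + 1)
            assert env.upper[i] == pytest.approx(max(x[lo:hi].max(), 0.0 + 0.5))

    def test_anchors_prevent_edge_underestimation(self):
        x = np.zeros(60)
        x[:9] = make_peak_pattern(4.0, 0.25)[8:] * 5  # pulse falling from the edge
        anchored = band_envelope(x, BandConstants(min_band_width=0.1, lower_cap=0.0,
                                                  upper_floor=0.0, anchor_length_h=3.0), 0.25)
        bare = band_envelope(x, BandConstants(min_band_width=0.1, lower_cap=0.0,
                                              upper_floor=0.0, anchor_length_h=0.0), 0.25)
        assert anchored.upper[0] >= bare.upper[0]
        assert anchored.upper[0] == pytest.approx(5.0)

    def test_band_at_least_min_width(self, pulsatile_experiment):
        exp, _ = pulsatile_experiment
        consts = band_constants_for_population([t.p53 for t in exp.trajectories])
        for traj in exp.trajectories:
            env = band_envelope(traj.p53, consts, traj.dt)
            assert np.all(env.upper - env.lower >= consts.min_band_width - 1e-9)


class TestBandNormalize:
    def test_extremes_and_midpoint(self):
        env = band_envelope(np.linspace(1, 9, 40),
                            BandConstants(min_band_width=0.1, lower_cap=100.0, upper_floor=0.0))
        for x, expected in [(env.lower, 0.0), (env.upper, 1.0),
                            (0.5 * (env.lower + env.upper), 0.5)]:
            np.testing.assert_allclose(band_normalize(x, env), expected, atol=1e-12)

    def test_mismatched_lengths_rejected(self):
        env = band_envelope(np.ones(20), BandConstants(min_band_width=1.0))
        with pytest.raises(ValueError):
            band_normalize(np.ones(19), env)


class TestPeakPattern:
    def test_default_four_hours_17_samples(self):
        p = make_peak_pattern(4.0, 0.25)
        assert p.size == 17
        assert p[0] == 0.0 and p[16] == pytest.approx(0.0, abs=1e-12)
        assert p[8] == pytest.approx(1.0)

    def test_mirror_symmetry(self):
        p = make_peak_pattern(5.0, 0.25)
        np.testing.assert_allclose(p, p[::-1], atol=1e-12)

    def test_three_sample_pattern(self):
        np.testing.assert_allclose(make_peak_pattern(1.0, 0.5), [0.0, 1.0, 0.0],
                                   atol=1e-12)


class TestDtwMatch:
    def test_exact_embedded_copy_has_zero_cost(self):
        p = make_peak_pattern(4.0, 0.25)
        x = np.zeros(80)
        x[30:47] = p
        cands, _ = dtw_match(x, p)
        zero = [c for c in cands if c[2] < 1e-12]
        assert len(zero) == 1
        start, end, _ = zero[0]
        assert (start, end) == (30, 46)

    def test_stretched_pulse_found_within_two_samples(self):
        """A ×1.5 time-stretched pulse still matches, boundaries within 2 samples."""
        p = make_peak_pattern(4.0, 0.25)
        stretched = make_peak_pattern(6.0, 0.25)  # 25 samples
        x = np.zeros(90)
        x[30:55] = stretched
        cands, _ = dtw_match(x, p)
        best = min(cands, key=lambda c: c[2])
        assert best[2] < 0.15 * p.size
        assert abs(best[0] - 30) <= 2 and abs(best[1] - 54) <= 2

    def test_all_zero_signal_cost_is_pattern_sum_no_candidates(self):
        p = make_peak_pattern(4.0, 0.25)
        x = np.zeros(60)
        cands, S = dtw_match(x, p)
        assert S[:, -1].min() == pytest.approx(p.sum())
        assert cands == []

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            dtw_match(np.array([]), make_peak_pattern(4.0, 0.25))

    def test_matrix_matches_memoized_reference(self, rng):
        for _ in range(10):
            x = rng.uniform(0, 1, int(rng.integers(8, 31)))
            p = rng.uniform(0, 1, int(rng.integers(3, 8)))
            _, S = dtw_match(x, p, threshold=np.inf)
            np.testing.assert_allclose(S, dp_reference(x, p), atol=1e-12)


class TestFilterOverlaps:
    def test_disjoint_candidates_kept(self):
        cands = [(0, 10, 1.0), (20, 30, 2.0)]
        assert filter_overlaps(cands) == cands

    def test_identical_spans_keep_cheapest(self):
        assert filter_overlaps([(5, 9, 2.0), (5, 9, 1.0)]) == [(5, 9, 1.0)]

    def test_greedy_chain_keeps_only_cheapest_of_overlapping(self):
        """A(0–16) B(12–28) C(24–40): all pairwise-adjacent overlaps; the
        cheapest (B) wins and both neighbours are discarded."""
        a, b, c = (0, 16, 3.0), (12, 28, 1.0), (24, 40, 2.0)
        assert filter_overlaps([a, b, c]) == [b]

    def test_shared_boundary_sample_is_not_overlap(self):
        assert filter_overlaps([(0, 10, 1.0), (10, 20, 2.0)]) == [(0, 10, 1.0), (10, 20, 2.0)]


class TestPulseFeatures:
    def test_flat_raw_signal_zero_amplitude(self):
        feats = pulse_features(np.full(50, 3.0), [(10, 20, 0.5)], 0.25)
        assert feats[0].amplitude == 0.0

    def test_duration_arithmetic(self):
        feats = pulse_features(np.zeros(100), [(8, 32, 0.5)], 0.25)
        assert feats[0].start_h == 2.0
        assert feats[0].end_h == 8.0
        assert feats[0].duration_h == 6.0

    def test_generator_amplitude_recovered_within_1pct(self, clean_config):
        cfg = dataclasses.replace(
            clean_config, amplitude_cv=0.0, amplitude_damping=1.0, baseline_cv=0.0,
            first_peak_delay_sd=0.0, period_jitter_cv=0.0,  # grid-aligned pulses
        )
        exp, truth = generate_experiment(
            cfg, TemperatureProtocol.constant(37.0), 10.0, 5, seed=61,
        )
        consts = band_constants_for_population([t.p53 for t in exp.trajectories])
        for traj in exp.trajectories:
            feats = detect_pulses(traj, consts)
            first = truth["pulses"][truth["pulses"].cell_id == traj.cell_id].iloc[0]
            match = min(feats, key=lambda f: abs((f.start_h + f.end_h) / 2 - first.peak_h))
            assert match.amplitude == pytest.approx(100.0, rel=0.01)


class TestPulseStateProbabilities:
    def _feat(self, cell, start, end, index=0):
        return PulseFeature(cell, start, end, 1.0, 0.1, index)

    def test_shared_pulse_probability_one_inside(self):
        times = np.arange(0, 10.25, 0.25)
        feats = {f"c{i}": [self._feat(f"c{i}", 2.0, 6.0)] for i in range(4)}
        probs = pulse_state_probabilities(feats, times, 2)
        inside = (times >= 2.0) & (times <= 6.0)
        np.testing.assert_array_equal(probs[0, inside], 1.0)
        np.testing.assert_array_equal(probs[0, ~inside], 0.0)
        assert probs.sum(axis=0).max() <= 1.0 + 1e-12

    def test_no_pulses_all_zero(self):
        probs = pulse_state_probabilities({"a": [], "b": []}, np.arange(5.0), 3)
        np.testing.assert_array_equal(probs, 0.0)

    def test_half_and_half_counting(self):
        times = np.arange(0, 10.25, 0.25)
        feats = {"a": [self._feat("a", 2.0, 6.0)], "b": [self._feat("b", 4.0, 8.0)]}
        probs = pulse_state_probabilities(feats, times, 1)
        assert probs[0, np.searchsorted(times, 5.0)] == 1.0
        assert probs[0, np.searchsorted(times, 3.0)] == 0.5


def test_band_normalized_output_within_unit_interval(pulsatile_experiment):
    exp, _ = pulsatile_experiment
    consts = band_constants_for_population([t.p53 for t in exp.trajectories])
    for traj in exp.trajectories:
        env = band_envelope(traj.p53, consts, traj.dt)
        norm = band_normalize(traj.p53, env)
        assert norm.min() >= 0.0 and norm.max() <= 1.0
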