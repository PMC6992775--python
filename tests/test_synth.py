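"""Synthetic trajectory generator: regimes, artifacts, determinism."""

import dataclasses

import numpy as np
import pytest

from p53pulse import (
    CellTrajectory,
    GeneratorConfig,
    TemperatureProtocol,
    generate_experiment,
    inject_artifacts,
    period_at,
    pulse_train,
    sustained_trajectory,
)


class TestTemperatureProtocol:
    def test_constant_and_step(self):
        prot = TemperatureProtocol.step(37.0, 41.0, 12.0)
        assert prot.temperature_at(0.0) == 37.0
        assert prot.temperature_at(11.9) == 37.0
        assert prot.temperature_at(12.0) == 41.0
        assert prot.spans(24.0) == [(0.0, 12.0, 37.0), (12.0, 24.0, 41.0)]

    @pytest.mark.parametrize(
        "segments", [(), ((1.0, 37.0),), ((0.0, 37.0), (0.0, 39.0))]
    )
    def test_invalid_protocols_rejected(self, segments):
        with pytest.raises(ValueError):
            TemperatureProtocol(segments)


class TestPulseTrain:
    def test_q10_scaling_of_mean_interval(self, clean_config):
        """Mean inter-peak interval at 33 °C is period_37·q10^0.4 (±3 SE)."""
        cfg = dataclasses.replace(clean_config, q10=2.0, period_37=5.5, duration=48.0)
        expected = 5.5 * 2.0**0.4
        intervals = []
        for k in range(500):
            r = np.random.default_rng([17, k])
            _, truth = pulse_train(cfg, 33.0, True, r)
            peaks = [p["peak_h"] for p in truth]
            intervals.extend(np.diff(peaks))
        intervals = np.asarray(intervals)
        se = intervals.std(ddof=1) / np.sqrt(intervals.size)
        assert abs(intervals.mean() - expected) < 3 * se + 1e-9

    def test_zero_amplitude_cv_gives_identical_amplitudes(self, clean_config):
        cfg = dataclasses.replace(clean_config, amplitude_cv=0.0, amplitude_damping=1.0)
        _, truth = pulse_train(cfg, 37.0, True, np.random.default_rng(0))
        amps = [p["amplitude"] for p in truth]
        assert len(amps) > 1
        assert np.allclose(amps, cfg.amplitude_mean)

    def test_same_seed_is_bit_identical(self, default_config):
        a, _ = pulse_train(default_config, 37.0, True, np.random.default_rng(5))
        b, _ = pulse_train(default_config, 37.0, True, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_unirradiated_below_39_is_flat_baseline(self, clean_config):
        sig, truth = pulse_train(clean_config, 37.0, False, np.random.default_rng(3))
        assert truth == []
        assert np.ptp(sig) == 0.0

    def test_short_duration_gives_baseline_only(self, clean_config):
        cfg = dataclasses.replace(clean_config, duration=1.0)
        sig, truth = pulse_train(cfg, 37.0, True, np.random.default_rng(1))
        assert truth == []
        assert np.ptp(sig) == 0.0

    def test_regime_guard(self, default_config):
        with pytest.raises(ValueError):
            pulse_train(default_config, 41.0, True, np.random.default_rng(0))

    def test_pulses_fully_observed_and_nonoverlapping(self, default_config):
        for k in range(20):
            _, truth = pulse_train(default_config, 35.0, True, np.random.default_rng([9, k]))
            for p in truth:
                assert p["start_h"] >= -1e-9
                assert p["end_h"] <= default_config.duration + 1e-9
            for a, b in zip(truth, truth[1:]):
                assert b["start_h"] >= a["end_h"] - 1e-9


class TestSustainedTrajectory:
    def test_unirradiated_plateau_is_60pct_of_irradiated_peak(self, clean_config):
        """Non-irradiated 41 °C cells plateau at plateau_frac of the damage peak."""
        cfg = dataclasses.replace(clean_config, amplitude_cv=0.0, baseline_cv=0.0)
        irr = sustained_trajectory(cfg, True, True, np.random.default_rng(0))
        unirr = sustained_trajectory(cfg, False, True, np.random.default_rng(0))
        base = cfg.baseline_mean
        ratio = (unirr[-1] - base) / (irr.max() - base)
        assert abs(ratio - 0.60) < 0.01

    def test_irradiated_peak_time_is_8h(self, clean_config):
        cfg = dataclasses.replace(clean_config, amplitude_cv=0.0, baseline_cv=0.0)
        trace = sustained_trajectory(cfg, True, True, np.random.default_rng(0))
        assert abs(cfg.times[np.argmax(trace)] - 8.0) <= cfg.dt

    def test_acute_peak_is_earlier_with_faster_decay(self, clean_config):
        cfg = dataclasses.replace(clean_config, amplitude_cv=0.0, baseline_cv=0.0)
        acute = sustained_trajectory(cfg, True, False, np.random.default_rng(0))
        pre = sustained_trajectory(cfg, True, True, np.random.default_rng(0))
        assert cfg.times[np.argmax(acute)] < cfg.times[np.argmax(pre)]
        assert acute[-1] < pre[-1]

    def test_zero_plateau_fraction_gives_flat_unirradiated_trace(self, clean_config):
        cfg = dataclasses.replace(clean_config, plateau_frac_unirr=0.0)
        trace = sustained_trajectory(cfg, False, True, np.random.default_rng(0))
        assert np.ptp(trace) == 0.0


class TestInjectArtifacts:
    def _flat_traj(self, cfg):
        times = cfg.times
        return CellTrajectory(
            "c", times, np.full_like(times, 100.0),
            np.full_like(times, cfg.area_mean), np.full_like(times, cfg.marker_mean),
        )

    def test_identity_when_all_rates_zero(self, clean_config):
        traj = self._flat_traj(clean_config)
        out, truth = inject_artifacts(
            traj, dataclasses.replace(clean_config, area_noise_cv=0.0),
            np.random.default_rng(0),
        )
        assert np.array_equal(out.p53, traj.p53)
        assert truth["spikes"] == [] and truth["shifts"] == [] and truth["divisions"] == []

    def test_division_halves_area(self, clean_config):
        cfg = dataclasses.replace(
            clean_config, division_rate_irradiated=8.0, area_noise_cv=0.0
        )
        traj = self._flat_traj(cfg)
        out, truth = inject_artifacts(traj, cfg, np.random.default_rng(4))
        assert len(truth["divisions"]) >= 1
        t_d = truth["divisions"][0]
        idx = int(round(t_d / cfg.dt))
        assert out.area[idx] == pytest.approx(0.5 * out.area[idx - 1], rel=1e-9)

    def test_mean_spike_count_matches_poisson_rate(self, clean_config):
        cfg = dataclasses.replace(clean_config, spike_rate=3.0)
        counts = [
            len(inject_artifacts(self._flat_traj(cfg), cfg, np.random.default_rng([8, k]))[1]["spikes"])
            for k in range(1000)
        ]
        # Poisson(3): SE of the mean at n=1000 is sqrt(3/1000) ~ 0.055
        assert abs(np.mean(counts) - 3.0) < 3 * np.sqrt(3.0 / 1000)


class TestGenerateExperiment:
    def test_reproducible_population(self, default_config):
        prot = TemperatureProtocol.constant(37.0)
        e1, _ = generate_experiment(default_config, prot, 10.0, 20, seed=7)
        e2, _ = generate_experiment(default_config, prot, 10.0, 20, seed=7)
        assert e1.n_cells == 20
        assert np.array_equal(e1.p53_matrix(), e2.p53_matrix())

    def test_batch_effect_is_exactly_affine(self, default_config):
        prot = TemperatureProtocol.constant(37.0)
        base, _ = generate_experiment(default_config, prot, 10.0, 10, seed=3)
        cfg2 = dataclasses.replace(default_config, batch_gain=2.0, batch_offset=7.0)
        scaled, _ = generate_experiment(cfg2, prot, 10.0, 10, seed=3)
        np.testing.assert_allclose(
            scaled.p53_matrix(), 2.0 * base.p53_matrix() + 7.0, rtol=0, atol=1e-9
        )

    def test_temperature_shift_switches_regime(self, clean_config):
        """37→41 °C at 12 h: pulses confined before the shift, sustained after."""
        prot = TemperatureProtocol.step(37.0, 41.0, 12.0)
        exp, truth = generate_experiment(clean_config, prot, 10.0, 20, seed=9)
        assert (truth["pulses"]["peak_h"] < 12.0).all()
        times = exp.times
        post = times >= 12.0
        for traj in exp.trajectories[:5]:
            # sustained segment rises from the shift toward a later maximum
            seg = traj.p53[post]
            assert np.argmax(seg) > 4  # not at the shift itself

    def test_invalid_inputs_rejected(self, default_config):
        prot = TemperatureProtocol.constant(37.0)
        with pytest.raises(ValueError):
            generate_experiment(default_config, prot, 10.0, 0)
        with pytest.raises(TypeError):
            generate_experiment(default_config, [(0.0, 37.0)], 10.0, 5)

    def test_truth_tables_cover_all_injected_events(self, pulsatile_experiment):
        exp, truth = pulsatile_experiment
        cells = {t.cell_id for t in exp.trajectories}
        for name in ("pulses", "artifacts", "divisions"):
            table = truth[name]
            if len(table):
                assert set(table["cell_id"]).issubset(cells)
        # divisions recorded on the trajectories match the truth table
        per_traj = sorted(
            (t.cell_id, d) for t in exp.trajectories for d in t.divisions
        )
        per_table = sorted(
            (r.cell_id, r.time_h) for r in truth["divisions"].itertuples()
        )
        assert per_traj == per_table


def test_period_at_closed_form():
    cfg = GeneratorConfig(period_37=5.5, q10=2.0)
    assert period_at(cfg, 33.0) == pytest.approx(5.5 * 2.0**0.4)
    assert period_at(cfg, 37.0) == pytest.approx(5.5)
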