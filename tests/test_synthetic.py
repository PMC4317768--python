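"""Synthetic generator: determinism, closed forms and ground-truth recovery."""
import dataclasses

import numpy as np
import pytest
from scipy.special import i0, i1

from pfcsync import (FrequencyBand, LFPSignal, DEFAULT_BANDS, SyntheticConfig,
                     band_energy, gen_experiment, gen_lfp, gen_locked_spikes,
                     gen_synchronous_pair, resultant_vector, welch_psd)
from pfcsync.synthetic import slow_phase_series

THETA = [b for b in DEFAULT_BANDS if b.name == "theta"][0]


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"duration": -1.0}, {"fs": 0.0}, {"base_rate": 0.0},
        {"theta_amp_pcp_factor": 0.0}, {"theta_amp_pcp_factor": 1.5},
        {"kappa_pcp": -0.1}, {"updown_gate_ratio": 1.2},
        {"coincidence_jitter": -0.001}, {"n_pcp_sessions": 0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestGenLfp:
    def test_structure_off_gives_white_noise_of_configured_variance(self):
        cfg = SyntheticConfig(background_exponent=0.0, background_sigma=3.0,
                              slow_osc_amp=0.0, theta_amp_vehicle=1e-12,
                              duration=200.0)
        lfp = gen_lfp(cfg, "vehicle", seed=0)
        assert np.std(lfp.samples) == pytest.approx(3.0, rel=0.02)
        psd = welch_psd(lfp)
        # flat spectrum: delta and gamma levels agree
        d = band_energy(psd, FrequencyBand("lo", 10, 30))
        g = band_energy(psd, FrequencyBand("hi", 100, 200))
        assert d == pytest.approx(g, rel=0.15)

    def test_factor_one_equalizes_expected_theta_energy(self):
        cfg = SyntheticConfig(theta_amp_pcp_factor=1.0, duration=60.0)
        ev = np.mean([band_energy(welch_psd(gen_lfp(cfg, "vehicle", s)), THETA)
                      for s in range(10)])
        ep = np.mean([band_energy(welch_psd(gen_lfp(cfg, "pcp", s + 100)),
                                  THETA) for s in range(10)])
        assert ep == pytest.approx(ev, rel=0.05)

    def test_theta_power_scales_as_amplitude_squared(self):
        # amplitude factor 0.5 -> band energy factor 0.25 after removing the
        # background floor (50-seed averages)
        cfg = SyntheticConfig(theta_amp_pcp_factor=0.5, slow_osc_amp=0.0,
                              theta_amp_jitter=0.0, duration=60.0)
        floor_cfg = dataclasses.replace(cfg, theta_amp_vehicle=1e-12)
        ev, ep, floor = [], [], []
        for s in range(50):
            ev.append(band_energy(welch_psd(gen_lfp(cfg, "vehicle", s)),
                                  THETA))
            ep.append(band_energy(welch_psd(gen_lfp(cfg, "pcp", s)), THETA))
            floor.append(band_energy(
                welch_psd(gen_lfp(floor_cfg, "vehicle", s)), THETA))
        ratio = ((np.mean(ep) - np.mean(floor))
                 / (np.mean(ev) - np.mean(floor)))
        assert ratio == pytest.approx(0.25, abs=0.05 * 0.25 + 0.01)

    def test_deterministic_under_seed(self):
        cfg = SyntheticConfig(duration=10.0)
        a = gen_lfp(cfg, "pcp", seed=5)
        b = gen_lfp(cfg, "pcp", seed=5)
        assert np.array_equal(a.samples, b.samples)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            gen_lfp(SyntheticConfig(duration=5.0), "sham", seed=0)


class TestGenLockedSpikes:
    def _phase(self, duration=300.0, fs=500.0, freq=6.0):
        cfg = SyntheticConfig(duration=duration, fs=fs, theta_freq=freq)
        return slow_phase_series(dataclasses.replace(cfg,
                                                     slow_osc_freq=freq), 0.0)

    def test_kappa_zero_is_homogeneous_poisson(self):
        phase = self._phase(duration=600.0)
        train = gen_locked_spikes(phase, 2.0, 0.0, seed=0)
        rate = train.n_spikes / 600.0
        assert abs(rate - 2.0) < 3 * np.sqrt(2.0 / 600.0)

    def test_large_kappa_concentrates_at_preferred_phase(self):
        phase = self._phase()
        train = gen_locked_spikes(phase, 5.0, 50.0, preferred_phase=1.0,
                                  seed=1)
        idx = np.minimum(np.round(train.times * phase.fs).astype(int),
                         phase.n_samples - 1)
        R, ang = resultant_vector(phase.phase[idx])
        assert R > 0.97
        assert abs(np.angle(np.exp(1j * (ang - 1.0)))) < 0.1

    @pytest.mark.parametrize("kappa", [0.0, 1.0, 2.0, 4.0])
    def test_resultant_length_converges_to_bessel_ratio(self, kappa):
        phase = self._phase(duration=600.0)
        train = gen_locked_spikes(phase, 10.0, kappa, seed=int(kappa * 7) + 1)
        idx = np.minimum(np.round(train.times * phase.fs).astype(int),
                         phase.n_samples - 1)
        R, _ = resultant_vector(phase.phase[idx])
        assert train.n_spikes >= 5000
        assert R == pytest.approx(i1(kappa) / i0(kappa), abs=0.02)

    def test_rate_conserved_across_seeds(self):
        # I0 normalization: time-averaged intensity equals base_rate
        phase = self._phase(duration=120.0)
        rates = [gen_locked_spikes(phase, 0.9, 2.0, seed=s).n_spikes / 120.0
                 for s in range(100)]
        se = np.sqrt(0.9 / (120.0 * 100))
        assert abs(np.mean(rates) - 0.9) < 3 * se

    def test_phase_shorter_than_duration_rejected(self):
        phase = self._phase(duration=10.0)
        with pytest.raises(ValueError, match="shorter"):
            gen_locked_spikes(phase, 1.0, 0.0, duration=20.0)


class TestGenSynchronousPair:
    def test_zero_coincidence_rate_near_zero_lag_excess(self):
        a, b, injected = gen_synchronous_pair(2.0, 2.0, 0.0, 0.002, 600.0,
                                              seed=3)
        assert injected == 0
        from pfcsync import cross_correlogram, integrated_area
        cc = cross_correlogram(a, b, 0.001, 0.012, "raw")
        area = integrated_area(cc, [0.006]).area[0]
        chance = a.n_spikes * b.n_spikes * 0.012 / 600.0
        assert abs(area - chance) < 4 * np.sqrt(max(chance, 1.0))

    def test_common_input_only_trains_identical_up_to_jitter(self):
        a, b, injected = gen_synchronous_pair(0.0, 0.0, 0.5, 0.002, 600.0,
                                              seed=9)
        assert a.n_spikes == injected
        assert b.n_spikes == injected
        assert np.all(np.abs(a.times - b.times) < 6 * 0.002 * np.sqrt(2))

    def test_injected_count_near_rate_times_duration(self):
        _, _, injected = gen_synchronous_pair(1.0, 1.0, 0.5, 0.002, 600.0,
                                              seed=17)
        assert abs(injected - 300) < 3 * np.sqrt(300)

    def test_negative_jitter_rejected(self):
        with pytest.raises(ValueError):
            gen_synchronous_pair(1.0, 1.0, 0.5, -0.001, 10.0)


class TestGenExperiment:
    def test_default_group_sizes_and_labels(self, fast_config):
        ds = gen_experiment(fast_config)
        labels = [s.group for s in ds.sessions]
        assert labels == ["vehicle"] * 2 + ["pcp"] * 2
        cfg = SyntheticConfig()
        assert cfg.n_vehicle_sessions == 8 and cfg.n_pcp_sessions == 7

    def test_byte_identical_datasets_for_same_config(self, fast_config):
        d1 = gen_experiment(fast_config)
        d2 = gen_experiment(fast_config)
        for a, b in zip(d1.sessions, d2.sessions):
            assert np.array_equal(a.lfp.samples, b.lfp.samples)
            for x, y in zip(a.trains, b.trains):
                assert np.array_equal(x.times, y.times)
            assert a.pair_injected == b.pair_injected

    def test_single_unit_session_has_no_pairs(self, fast_config):
        cfg = dataclasses.replace(fast_config, n_units_per_session=1)
        ds = gen_experiment(cfg)
        assert all(s.pairs == [] for s in ds.sessions)
        from pfcsync import bootstrap_group_curves
        with pytest.raises(ValueError):
            bootstrap_group_curves([])

    def test_spikes_within_duration_and_sorted(self, fast_config):
        ds = gen_experiment(fast_config)
        for s in ds.sessions:
            for t in s.trains:
                assert t.times.size == 0 or (
                    t.times[0] >= 0 and t.times[-1] < t.duration)
                assert np.all(np.diff(t.times) > 0)

    def test_ground_truth_records_realized_parameters(self, fast_config):
        ds = gen_experiment(fast_config)
        gt = ds.ground_truth()
        assert gt["config"]["seed"] == fast_config.seed
        assert len(gt["sessions"]) == 4
        for s, rec in zip(ds.sessions, gt["sessions"]):
            assert rec["theta_amp"] == s.theta_amp
            assert len(rec["pair_injected"]) == len(s.pairs)
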