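"""Cross-correlograms, integrated synchrony curves, bootstrap CIs, UP/DOWN."""
import numpy as np
import pytest

from pfcsync import (LFPSignal, SpikeTrain, SynchronyCurve,
                     bootstrap_group_curves, cross_correlogram,
                     expected_chance_area, in_state, integrated_area,
                     segment_up_down, state_restricted_curves)


def poisson_train(rng, rate, duration, unit_id="u", session_id="s0"):
    times = np.sort(rng.uniform(0, duration, size=rng.poisson(rate * duration)))
    times = times[np.concatenate([[True], np.diff(times) > 0])]
    return SpikeTrain(times, unit_id, duration=duration, session_id=session_id)


TOY_REF = SpikeTrain([0.010, 0.050, 0.120], "a", duration=1.0)
TOY_TGT = SpikeTrain([0.012, 0.055, 0.300], "b", duration=1.0)


class TestCrossCorrelogram:
    def test_toy_lists_match_hand_enumeration(self):
        # pair lags within +/-50 ms: +2, +45, -38, +5 ms
        cc = cross_correlogram(TOY_REF, TOY_TGT, bin_width=0.010,
                               max_lag=0.050, normalization="raw")
        by_edge = dict(zip(np.round(cc.lag_bin_edges[:-1] * 1000).astype(int),
                           cc.counts.astype(int)))
        assert by_edge[0] == 2
        assert by_edge[40] == 1
        assert by_edge[-40] == 1
        assert cc.counts.sum() == 4

    def test_shifted_train_concentrates_in_one_bin(self):
        ref = SpikeTrain(np.arange(1.0, 50.0), "a", duration=60.0)
        tgt = SpikeTrain(np.arange(1.0, 50.0) + 0.010 + 0.002, "b",
                         duration=60.0)
        cc = cross_correlogram(ref, tgt, 0.010, 0.050, normalization="raw")
        k = int(np.argmax(cc.counts))
        assert cc.lag_bin_edges[k] == pytest.approx(0.010)
        assert cc.counts[k] == 49

    def test_empty_train_gives_zero_correlogram(self):
        empty = SpikeTrain([], "e", duration=1.0)
        cc = cross_correlogram(TOY_REF, empty, normalization="raw")
        assert np.all(cc.counts == 0)

    def test_mirror_symmetry_between_orders(self, rng):
        a = poisson_train(rng, 4.0, 30.0, "a")
        b = poisson_train(rng, 3.0, 30.0, "b")
        ab = cross_correlogram(a, b, 0.005, 0.2, normalization="raw")
        ba = cross_correlogram(b, a, 0.005, 0.2, normalization="raw")
        assert np.array_equal(ab.counts, ba.counts[::-1])

    def test_cross_session_rejected(self):
        other = SpikeTrain([0.5], "x", duration=1.0, session_id="s1")
        with pytest.raises(ValueError, match="session"):
            cross_correlogram(TOY_REF, other)

    def test_per_reference_normalization_divides_by_ref_count(self):
        raw = cross_correlogram(TOY_REF, TOY_TGT, 0.010, 0.050, "raw")
        norm = cross_correlogram(TOY_REF, TOY_TGT, 0.010, 0.050,
                                 "per_reference_spike")
        assert np.allclose(norm.counts, raw.counts / 3.0)


class TestIntegratedArea:
    def test_toy_windows(self):
        cc = cross_correlogram(TOY_REF, TOY_TGT, 0.010, 0.050, "raw")
        curve = integrated_area(cc, [0.010, 0.050])
        assert curve.area[0] == 2.0
        assert curve.area[1] == 4.0

    def test_zero_correlogram_zero_curve(self):
        empty = SpikeTrain([], "e", duration=1.0)
        cc = cross_correlogram(TOY_REF, empty, normalization="raw")
        curve = integrated_area(cc, [0.005, 0.050])
        assert np.all(curve.area == 0.0)

    def test_monotone_nondecreasing_in_window(self, rng):
        a = poisson_train(rng, 5.0, 20.0, "a")
        b = poisson_train(rng, 5.0, 20.0, "b")
        cc = cross_correlogram(a, b, 0.001, 0.5, "raw")
        curve = integrated_area(cc, [0.005, 0.01, 0.05, 0.1, 0.5])
        assert np.all(np.diff(curve.area) >= 0)

    def test_window_beyond_lag_range_rejected(self):
        cc = cross_correlogram(TOY_REF, TOY_TGT, 0.010, 0.050, "raw")
        with pytest.raises(ValueError):
            integrated_area(cc, [0.2])

    def test_independent_poisson_area_matches_chance_expectation(self):
        rA, rB, T, w = 2.0, 3.0, 400.0, 0.05
        areas = []
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            a = poisson_train(rng, rA, T, "a")
            b = poisson_train(rng, rB, T, "b")
            cc = cross_correlogram(a, b, 0.005, 0.06, "raw")
            areas.append(integrated_area(cc, [w]).area[0])
        expected = expected_chance_area(rA, rB, T, w)
        se = np.std(areas, ddof=1) / np.sqrt(len(areas))
        assert abs(np.mean(areas) - expected) < 3 * se


class TestBootstrap:
    def _curves(self, mat):
        w = np.array([0.01, 0.05, 0.1])
        return [SynchronyCurve(w, row) for row in mat]

    def test_identical_curves_zero_width_ci(self):
        curves = self._curves(np.tile([1.0, 2.0, 3.0], (5, 1)))
        mean, ci = bootstrap_group_curves(curves, n_boot=200, seed=0)
        assert np.allclose(mean.area, [1, 2, 3])
        assert np.allclose(ci.lower, ci.upper)

    def test_single_resample_degenerate(self, rng):
        curves = self._curves(rng.normal(5, 1, size=(4, 3)))
        _, ci = bootstrap_group_curves(curves, n_boot=1, seed=3)
        assert np.allclose(ci.lower, ci.upper)

    def test_single_pair_warns_and_collapses(self):
        curves = self._curves(np.array([[1.0, 2.0, 3.0]]))
        with pytest.warns(UserWarning, match="single pair"):
            mean, ci = bootstrap_group_curves(curves, n_boot=100, seed=0)
        assert np.allclose(ci.lower, mean.area)

    def test_deterministic_under_seed(self, rng):
        curves = self._curves(rng.normal(0, 1, size=(8, 3)))
        _, ci1 = bootstrap_group_curves(curves, n_boot=500, seed=42)
        _, ci2 = bootstrap_group_curves(curves, n_boot=500, seed=42)
        assert np.array_equal(ci1.lower, ci2.lower)
        assert np.array_equal(ci1.upper, ci2.upper)


def cosine_lfp(freq=1.0, fs=500.0, duration=10.0, amp=100.0, sign=1.0):
    t = np.arange(int(duration * fs)) / fs
    return LFPSignal(sign * amp * np.cos(2 * np.pi * freq * t), fs)


class TestUpDownSegmentation:
    def test_peak_locked_spikes_define_up(self):
        lfp = cosine_lfp()
        spikes = [SpikeTrain(np.arange(1.0, 9.0), "u", duration=10.0)]
        seg = segment_up_down(lfp, spikes)
        assert np.all(in_state(spikes[0].times, seg, "UP"))
        # interior segments alternate with ~0.5 s length
        lengths = [e - s for s, e, _ in seg.intervals[1:-1]]
        assert np.allclose(lengths, 0.5, atol=0.05)

    def test_polarity_inversion_does_not_flip_labels(self):
        spikes = [SpikeTrain(np.arange(1.0, 9.0), "u", duration=10.0)]
        seg_a = segment_up_down(cosine_lfp(sign=1.0), spikes)
        seg_b = segment_up_down(cosine_lfp(sign=-1.0), spikes)
        assert np.all(in_state(spikes[0].times, seg_a, "UP"))
        assert np.all(in_state(spikes[0].times, seg_b, "UP"))

    def test_no_spikes_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="phase convention"):
            seg = segment_up_down(cosine_lfp(), [])
        assert in_state([1.0], seg, "UP")[0]

    def test_state_partition_of_pair_counts(self, rng):
        lfp = cosine_lfp(duration=60.0)
        a = poisson_train(rng, 4.0, 60.0, "a")
        b = poisson_train(rng, 4.0, 60.0, "b")
        seg = segment_up_down(lfp, [a, b])
        w = 0.05
        def count_pairs(mask_a, mask_b):
            ta, tb = a.times[mask_a], b.times[mask_b]
            return sum(np.sum(np.abs(tb - t) <= w) for t in ta)
        ua = in_state(a.times, seg, "UP")
        ub = in_state(b.times, seg, "UP")
        total = count_pairs(np.ones_like(ua, bool), np.ones_like(ub, bool))
        upup = count_pairs(ua, ub)
        downdown = count_pairs(~ua, ~ub)
        cross = count_pairs(ua, ~ub) + count_pairs(~ua, ub)
        assert upup + downdown + cross == total


class TestStateRestrictedCurves:
    def test_full_coverage_state_equals_unrestricted(self, rng):
        a = poisson_train(rng, 4.0, 20.0, "a")
        b = poisson_train(rng, 4.0, 20.0, "b")
        from pfcsync import StateSegments
        seg = StateSegments([(0.0, 20.0, "UP")])
        full = integrated_area(
            cross_correlogram(a, b, 0.001, 0.1, "raw"), [0.01, 0.1])
        restricted = state_restricted_curves(a, b, seg, "UP", 0.001, 0.1,
                                             [0.01, 0.1], "raw")
        assert np.array_equal(full.area, restricted.area)

    def test_state_with_no_spikes_gives_zero_curve(self, rng):
        a = poisson_train(rng, 4.0, 20.0, "a")
        b = poisson_train(rng, 4.0, 20.0, "b")
        from pfcsync import StateSegments
        seg = StateSegments([(0.0, 20.0, "UP")])
        curve = state_restricted_curves(a, b, seg, "DOWN", 0.001, 0.1,
                                        [0.01], "raw")
        assert np.all(curve.area == 0.0)
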