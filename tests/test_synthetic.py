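import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats

from eegtcn.synthetic import (SimulationConfig, inject_spike_wave,
                              simulate_background, simulate_bonn_style,
                              simulate_cohort)
from eegtcn.types import EP, HEALTHY


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(duration=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(rate=-1.0)
    with pytest.raises(ValueError):
        SimulationConfig(event_rate=-2.0)


def test_background_shape_and_group():
    cfg = SimulationConfig(n_channels=3, rate=250.0, duration=4.5, seed=0)
    rec = simulate_background(cfg)
    assert rec.signal.shape == (3, int(np.floor(4.5 * 250.0)))
    assert rec.group == HEALTHY
    assert rec.rate == 250.0


def test_background_deterministic():
    cfg = SimulationConfig(n_channels=2, duration=2.0, seed=99)
    a = simulate_background(cfg)
    b = simulate_background(cfg)
    np.testing.assert_array_equal(a.signal, b.signal)
    c = simulate_background(SimulationConfig(n_channels=2, duration=2.0, seed=100))
    assert not np.array_equal(a.signal, c.signal)


def test_background_zero_config_is_silent():
    cfg = SimulationConfig(n_channels=2, duration=2.0, noise_scale=0.0,
                           background_bands=((10.0, 0.0),), seed=3)
    rec = simulate_background(cfg)
    assert np.all(rec.signal == 0.0)


def test_background_dominant_band_peak():
    # FFT periodogram oracle: a dominant 10 Hz band puts the peak at 10 +/- 0.5 Hz
    cfg = SimulationConfig(n_channels=1, duration=30.0, noise_scale=3.0,
                           background_bands=((10.0, 40.0),), seed=1)
    rec = simulate_background(cfg)
    freqs, power = sps.welch(rec.signal[0], fs=cfg.rate, nperseg=4096)
    assert abs(freqs[np.argmax(power)] - 10.0) <= 0.5


class TestInjectSpikeWave:
    def test_empty_event_list_is_noop(self, small_sim_config):
        rec = simulate_background(small_sim_config, subject_id="s1")
        out = inject_spike_wave(rec, [], small_sim_config)
        np.testing.assert_array_equal(out.signal, rec.signal)
        assert out.group == HEALTHY

    def test_out_of_range_event_rejected(self, small_sim_config):
        rec = simulate_background(small_sim_config, subject_id="s1")
        with pytest.raises(ValueError):
            inject_spike_wave(rec, [(9.5, 1.0)], small_sim_config)
        with pytest.raises(ValueError):
            inject_spike_wave(rec, [(-0.5, 1.0)], small_sim_config)

    def test_non_event_samples_unchanged(self, small_sim_config):
        rec = simulate_background(small_sim_config, subject_id="s1")
        out = inject_spike_wave(rec, [(2.0, 1.0)], small_sim_config)
        assert out.group == EP
        rate = rec.rate
        np.testing.assert_array_equal(
            out.signal[:, : int(2.0 * rate)], rec.signal[:, : int(2.0 * rate)]
        )
        np.testing.assert_array_equal(
            out.signal[:, int(3.1 * rate):], rec.signal[:, int(3.1 * rate):]
        )

    def test_spike_count_matches_peak_oracle(self):
        # one ~2 s event at 3 Hz -> exactly 6 spike peaks above 3x background
        # std (2.1 s holds floor(2.1 * 3) = 6 complete spike-wave cycles)
        cfg = SimulationConfig(n_channels=1, rate=500.0, duration=10.0,
                               event_freq=3.0, event_amplitude=300.0,
                               noise_scale=3.0, background_bands=((10.0, 6.0),),
                               seed=5)
        rec = simulate_background(cfg, subject_id="s1")
        out = inject_spike_wave(rec, [(4.0, 2.1)], cfg)
        period = int(round(cfg.rate / cfg.event_freq))
        window = out.signal[0, int(4.0 * cfg.rate): int(4.0 * cfg.rate) + 6 * period]
        threshold = 3.0 * rec.signal[0].std()
        # a one-period minimum distance keeps exactly one (the tallest: the
        # spike) peak per spike-wave cycle
        peaks, _ = sps.find_peaks(window, height=threshold, distance=period - 1)
        assert len(peaks) == 6

    def test_band_power_raised_in_event_windows(self):
        # Welch oracle: 2-4 Hz power inside events >= 2x matched background power
        cfg = SimulationConfig(n_channels=1, rate=500.0, duration=12.0, seed=8)
        rec = simulate_background(cfg, subject_id="s1")
        out = inject_spike_wave(rec, [(2.0, 2.0)], cfg)

        def band_power(x):
            f, p = sps.welch(x, fs=cfg.rate, nperseg=512)
            return p[(f >= 2.0) & (f <= 4.0)].sum()

        ev = out.signal[0, int(2.0 * cfg.rate): int(4.0 * cfg.rate)]
        bg = out.signal[0, int(6.0 * cfg.rate): int(8.0 * cfg.rate)]
        assert band_power(ev) >= 2.0 * band_power(bg)

    def test_amplitude_zero_is_indistinguishable(self):
        # separability knob: at amplitude 0, EP and healthy band powers match
        cfg = SimulationConfig(n_channels=1, rate=500.0, duration=20.0,
                               event_amplitude=0.0, event_rate=18.0, seed=10)
        cohort = simulate_cohort(1, 1, cfg)

        def powers(rec):
            f, p = sps.welch(rec.signal[0].reshape(10, -1), fs=cfg.rate,
                             nperseg=512, axis=1)
            band = (f >= 2.0) & (f <= 4.0)
            return p[:, band].sum(axis=1)

        res = stats.mannwhitneyu(powers(cohort[0]), powers(cohort[1]),
                                 alternative="two-sided")
        assert res.pvalue > 0.05


class TestSimulateCohort:
    def test_paper_cohort_sizes(self):
        cfg = SimulationConfig(n_channels=2, duration=4.0, seed=0)
        cohort = simulate_cohort(21, 14, cfg)
        assert len(cohort) == 35
        assert sum(r.group == HEALTHY for r in cohort) == 21
        assert sum(r.group == EP for r in cohort) == 14

    def test_single_healthy_subject(self):
        cfg = SimulationConfig(n_channels=2, duration=4.0, seed=0)
        cohort = simulate_cohort(1, 0, cfg)
        assert len(cohort) == 1 and cohort[0].group == HEALTHY

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(0, 0, SimulationConfig())

    def test_distinct_subject_ids(self, small_cohort):
        ids = [r.subject_id for r in small_cohort]
        assert len(set(ids)) == len(ids)

    def test_determinism_across_runs(self, small_sim_config, small_cohort):
        again = simulate_cohort(3, 3, small_sim_config)
        for a, b in zip(small_cohort, again):
            np.testing.assert_array_equal(a.signal, b.signal)
        other_seed = simulate_cohort(
            3, 3, SimulationConfig(
                n_channels=4, rate=500.0, duration=10.0, event_rate=18.0,
                event_duration=(0.8, 1.5), seed=43,
            )
        )
        assert not np.array_equal(small_cohort[0].signal, other_seed[0].signal)


class TestBonnStyle:
    def test_record_count_and_length(self):
        records = simulate_bonn_style("healthy", 5, seed=1)
        assert len(records) == 5
        for rec in records:
            assert rec.signal.shape == (1, 4097)  # floor(23.6 * 173.61)
            assert rec.rate == pytest.approx(173.61)
            assert rec.group == HEALTHY

    def test_hundred_records(self):
        assert len(simulate_bonn_style("healthy", 100, seed=0)) == 100

    def test_ictal_records_carry_discharge(self):
        healthy = simulate_bonn_style("healthy", 2, seed=2)
        ictal = simulate_bonn_style("ictal", 2, seed=2)
        assert all(r.group == EP for r in ictal)
        assert ictal[0].signal.std() > 3.0 * healthy[0].signal.std()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            simulate_bonn_style("interictal", 1, seed=0)
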