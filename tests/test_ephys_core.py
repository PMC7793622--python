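"""Spike detection, PSTH estimation, windowed responses, baseline state."""

import numpy as np
import pytest

from windcompass import ephys_core as ec
from windcompass import synthetic_ephys as se


def _trace_from_samples(samples, trial=None, fs=10_000.0):
    trial = trial or se.TrialSpec(direction=0.0, condition="airflow")
    return se.VoltageTrace(samples=np.asarray(samples, float), trial=trial, fs=fs)


class TestDetectSpikes:
    def test_flat_trace_with_subthreshold_noise(self):
        rng = np.random.default_rng(0)
        samples = -30.0 + 0.1 * rng.normal(size=120_000)
        tr = _trace_from_samples(samples)
        cfg = ec.ThresholdConfig(threshold=5.0)
        assert len(ec.detect_spikes(tr, cfg)) == 0

    def test_injected_templates_recovered_within_1ms(self):
        """Every injected spike template is found at its time, ±1 ms."""
        fs = 10_000.0
        samples = np.full(120_000, -30.0)
        injected = np.array([1.0, 2.5, 4.2, 7.7, 10.0])
        width = int(0.002 * fs)
        bump = 40.0 * np.hanning(width)
        for t0 in injected:
            i = int(t0 * fs)
            samples[i:i + width] += bump
        st = ec.detect_spikes(_trace_from_samples(samples),
                              ec.ThresholdConfig(threshold=5.0))
        assert len(st) == len(injected)
        assert np.all(np.abs(st - injected) <= 1e-3)

    def test_one_wide_excursion_is_one_spike(self):
        """A broad (10 ms) suprathreshold excursion yields one spike: only
        its rising edge counts."""
        fs = 10_000.0
        samples = np.full(60_000, -30.0)
        samples[10_000:10_100] += 40.0 * np.hanning(100)  # 10 ms hump
        st = ec.detect_spikes(_trace_from_samples(samples, fs=fs),
                              ec.ThresholdConfig(threshold=5.0))
        assert len(st) == 1

    def test_nonfinite_threshold_rejected(self):
        tr = _trace_from_samples(np.zeros(40_000))
        with pytest.raises(ValueError):
            ec.detect_spikes(tr, ec.ThresholdConfig(threshold=np.inf))

    def test_cutoff_above_nyquist_rejected(self):
        tr = _trace_from_samples(np.zeros(40_000), fs=60.0)
        with pytest.raises(ValueError):
            ec.detect_spikes(tr, ec.ThresholdConfig(cutoff_hz=40.0))


class TestPsth:
    def test_no_spikes_is_zero(self):
        rate = ec.psth([np.array([])], duration=12.0)
        assert np.all(rate == 0.0)

    def test_regular_train_plateaus_at_rate(self):
        spikes = np.arange(0.05, 12.0, 0.1)  # 10 Hz regular
        rate = ec.psth([spikes], duration=12.0, fs_out=1000.0)
        middle = rate[2000:10_000]
        assert np.allclose(middle, 10.0, atol=0.1)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        spikes = np.sort(rng.uniform(0, 12.0, 40))
        single = ec.psth([spikes], duration=12.0)
        doubled = ec.psth([np.sort(np.concatenate([spikes, spikes]))],
                          duration=12.0)
        assert np.allclose(doubled, 2 * single, rtol=1e-9, atol=1e-9)

    def test_mass_conservation_random_trains(self):
        """Integral of the PSTH equals the mean spike count, even with
        spikes near the trial edges."""
        rng = np.random.default_rng(2)
        fs_out = 1000.0
        for _ in range(10):
            trains = [np.sort(rng.uniform(0, 12.0, rng.integers(0, 80)))
                      for _ in range(rng.integers(1, 5))]
            rate = ec.psth(trains, duration=12.0, fs_out=fs_out)
            mass = rate.sum() / fs_out
            mean_count = np.mean([len(t) for t in trains])
            assert mass == pytest.approx(mean_count, rel=1e-6)

    def test_empty_trial_list_rejected(self):
        with pytest.raises(ValueError):
            ec.psth([], duration=12.0)


class TestTrialResponse:
    @pytest.mark.parametrize("base,resp,expected", [
        (5.0, 12.0, 7.0),
        (5.0, 5.0, 0.0),
        (8.0, 3.0, -5.0),
    ])
    def test_window_difference(self, base, resp, expected):
        fs = 1000.0
        series = np.zeros(12_000)
        w = ec.WindowSpec()
        series[int(w.baseline[0] * fs):int(w.baseline[1] * fs)] = base
        series[int(w.response[0] * fs):int(w.response[1] * fs)] = resp
        assert ec.trial_response(series, fs, w) == pytest.approx(expected)

    def test_invariant_to_everything_outside_windows(self):
        rng = np.random.default_rng(3)
        fs = 1000.0
        w = ec.WindowSpec()
        series = rng.normal(size=12_000)
        r0 = ec.trial_response(series, fs, w)
        noisy = series.copy()
        mask = np.ones(12_000, bool)
        for lo, hi in (w.baseline, w.response):
            mask[int(lo * fs):int(hi * fs)] = False
        noisy[mask] += rng.normal(scale=100.0, size=mask.sum())
        assert ec.trial_response(noisy, fs, w) == pytest.approx(r0)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            ec.trial_response(np.zeros(100), 1000.0, ec.WindowSpec())


class TestInputResistance:
    def test_ohms_law(self, airflow_trial):
        n = se.NeuronModel(r_in=10.0, osc_amp=0.0, noise_sd=0.0,
                           baseline_rate=0.0, a_air=0.0)
        tr = se.simulate_trial_vm(n, airflow_trial, 0)
        assert ec.input_resistance(tr) == pytest.approx(10.0, rel=0.02)

    def test_units_match_reported_range(self, airflow_trial):
        """A -12.42 mV deflection at -2 pA is 6.21 GOhm (the P-F1N3 mean)."""
        n = se.NeuronModel(r_in=6.21, osc_amp=0.0, noise_sd=0.0,
                           baseline_rate=0.0, a_air=0.0)
        tr = se.simulate_trial_vm(n, airflow_trial, 0)
        assert ec.input_resistance(tr) == pytest.approx(6.21, rel=0.02)

    def test_zero_deflection_gives_zero(self, quiet_neuron, airflow_trial):
        tr = se.simulate_trial_vm(quiet_neuron, airflow_trial, 0)
        tr.samples = np.full_like(tr.samples, quiet_neuron.v_rest)
        assert ec.input_resistance(tr) == pytest.approx(0.0)

    def test_zero_current_rejected(self, quiet_neuron):
        trial = se.TrialSpec(direction=0.0, condition="airflow",
                             pulse=(0.0, 0.5, 0.0))
        tr = se.simulate_trial_vm(quiet_neuron, trial, 0)
        with pytest.raises(ValueError):
            ec.input_resistance(tr)


class TestBaselineProfile:
    def test_pure_sinusoid_frequency(self):
        fs = 10_000.0
        t = np.arange(int(3 * fs)) / fs
        seg = -30.0 + 3.0 * np.sin(2 * np.pi * 2.0 * t)
        assert ec.oscillation_frequency(seg, fs) == pytest.approx(2.0, abs=0.3)

    def test_white_noise_has_no_peak(self):
        rng = np.random.default_rng(4)
        for s in range(5):
            seg = rng.normal(size=30_000)
            assert ec.oscillation_frequency(seg, 10_000.0) is None

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            ec.oscillation_frequency(np.zeros(1000), 10_000.0)

    def test_width_monotone_in_oscillation_amplitude(self, airflow_trial):
        widths = []
        for amp in (0.0, 2.0, 4.0):
            n = se.NeuronModel(osc_freq=2.0, osc_amp=amp, baseline_rate=0.0,
                               a_air=0.0)
            traces = [se.simulate_trial_vm(n, airflow_trial, s) for s in range(3)]
            widths.append(ec.baseline_profile(traces).vm_width)
        assert widths[0] < widths[1] < widths[2]

    def test_profile_recovers_generator_parameters(self, airflow_trial):
        rhythmic = se.NeuronModel(osc_freq=2.0, osc_amp=3.0,
                                  baseline_rate=0.0, a_air=0.0)
        traces = [se.simulate_trial_vm(rhythmic, airflow_trial, s)
                  for s in range(4)]
        assert ec.baseline_profile(traces).osc_freq == pytest.approx(2.0, abs=0.5)
        # input resistance read from a tonic cell (an ongoing oscillation
        # biases the two pulse windows differently, as it would in vivo)
        tonic = se.NeuronModel(osc_amp=0.0, r_in=6.0, baseline_rate=0.0,
                               a_air=0.0)
        traces = [se.simulate_trial_vm(tonic, airflow_trial, s) for s in range(4)]
        assert ec.baseline_profile(traces).r_in == pytest.approx(6.0, rel=0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ec.baseline_profile([])


class TestStrongestDirection:
    @pytest.mark.parametrize("responses,expected", [
        ({0.0: [2.0], 90.0: [8.0], 180.0: [-1.0], -90.0: [0.0]}, 8.0),
        ({0.0: [0.0], 90.0: [0.0]}, 0.0),
        ({90.0: [-9.0], 0.0: [8.0]}, 9.0),  # inhibition can win
    ])
    def test_examples(self, responses, expected):
        assert ec.strongest_direction_response(responses) == pytest.approx(expected)

    def test_signed_mean_then_absolute(self):
        """Per-direction trials are averaged signed before the absolute
        value, so cancelling trials do not win."""
        responses = {0.0: [10.0, -10.0], 90.0: [3.0, 3.0]}
        assert ec.strongest_direction_response(responses) == pytest.approx(3.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ec.strongest_direction_response({})
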