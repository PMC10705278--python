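"""Vm conditioning, spike detection, rates and band-power estimation."""

import numpy as np
import pytest
from scipy import signal as sps

from pfnavec import synth
from pfnavec.ephys import (
    EphysTrace,
    SpikeTrain,
    band_power_2_6,
    baseline_vm,
    condition_vm,
    detect_sodium_spikes,
    pulse_conditioned_power,
    spike_rate,
)
from pfnavec.tuning import TuningCurve1D

FS = 10_000.0


def _trace(vm, fs=FS):
    return EphysTrace(np.arange(vm.size) / fs, vm, fs)


class TestConditionVm:
    def test_constant_passthrough(self):
        out = condition_vm(_trace(np.full(50_000, -60.0)))
        assert out.fs == 1000.0
        assert np.allclose(out.vm, -60.0)

    def test_single_spike_removed(self):
        vm = synth.insert_spike_templates(np.full(50_000, -60.0), [25_000], FS)
        out = condition_vm(_trace(vm))
        assert np.max(np.abs(out.vm + 60.0)) < 0.1

    def test_slow_sinusoid_preserved(self):
        t = np.arange(100_000) / FS
        out = condition_vm(_trace(-60.0 + 5.0 * np.sin(2 * np.pi * 1.0 * t)))
        attenuation = 1.0 - (out.vm.max() + 60.0) / 5.0
        assert attenuation < 0.05

    def test_rejects_short_trace(self):
        with pytest.raises(ValueError):
            condition_vm(_trace(np.full(100, -60.0)))


class TestSpikeDetection:
    def test_known_spike_times_recovered(self, rng):
        vm = np.full(100_000, -60.0)
        onsets = 1.0 + np.arange(10) * 0.5  # >= 20 ms apart
        true_times = onsets + synth.SPIKE_PEAK_OFFSET_S  # waveform peaks
        vm = synth.insert_spike_templates(vm, (onsets * FS).astype(int), FS)
        vm = vm + rng.normal(0.0, 0.1, vm.size)
        spikes = detect_sodium_spikes(_trace(vm))
        assert len(spikes) == 10
        offsets = np.abs(spikes.spike_times[:, None] - true_times[None, :]).min(axis=1)
        assert offsets.max() < 0.5e-3

    def test_subthreshold_noise_no_detections(self, rng):
        vm = -60.0 + rng.normal(0.0, 0.2, 100_000)
        spikes = detect_sodium_spikes(_trace(vm), threshold_mv=2.0)
        assert len(spikes) == 0

    def test_refractory_rule_keeps_earlier(self):
        vm = np.full(50_000, -60.0)
        vm = synth.insert_spike_templates(vm, [20_000, 20_050], FS)  # 5 ms apart
        spikes = detect_sodium_spikes(_trace(vm), threshold_mv=1.0)
        assert len(spikes) == 1
        assert spikes.spike_times[0] == pytest.approx(2.0, abs=1e-3)

    def test_false_rate_during_hyperpolarization(self):
        """Quiet cells at default noise yield < 0.1 Hz spurious events."""
        p = synth.GroundTruthParams(side="right", bH=0.0, bW=0.0, seed=61)
        n = int(120 * 80)
        beh = synth.BehaviorTrace(
            np.arange(n) / 80.0,
            np.full(n, 180.0),  # anti-preferred: hyperpolarized
            np.full(n, 2.0),
        )
        trials = synth.make_protocol(1, seed=62)
        trace, _ = synth.simulate_vm_trace(p, beh, trials)
        spikes = detect_sodium_spikes(trace)
        assert len(spikes) / trace.duration_s < 0.1

    def test_spiketrain_validates_isi(self):
        with pytest.raises(ValueError):
            SpikeTrain(np.array([0.0, 0.003]))


class TestSpikeRate:
    def test_single_spike_integrates_to_one(self):
        grid = np.arange(0, 10, 1e-3)
        rate = spike_rate(SpikeTrain(np.array([5.0])), grid)
        assert np.trapezoid(rate, grid) == pytest.approx(1.0, rel=1e-3)

    def test_empty_train_zero(self):
        grid = np.arange(0, 5, 1e-3)
        assert np.all(spike_rate(SpikeTrain(np.empty(0)), grid) == 0.0)

    def test_poisson_train_mean_rate(self, rng):
        duration, lam = 100.0, 20.0
        n = rng.poisson(lam * duration)
        times = np.sort(rng.uniform(0, duration, n))
        times = times[np.concatenate([[True], np.diff(times) >= 6.66e-3])]
        grid = np.arange(0, duration, 1e-3)
        mean_rate = spike_rate(SpikeTrain(times), grid).mean()
        # dead-time thinning removes ~12% of events; compare to kept count
        expected = times.size / duration
        assert mean_rate == pytest.approx(expected, rel=0.02)


class TestBandPower:
    def test_constant_trace_zero(self):
        pt = band_power_2_6(_trace(np.full(100_000, -55.0)))
        assert np.allclose(pt.band_power, 0.0, atol=1e-12)

    def test_tone_matches_periodogram_oracle(self):
        """4 Hz tone: sliding band power matches an independent periodogram."""
        t = np.arange(0, 40, 1 / FS)
        A = 2.0
        x = -60.0 + A * np.sin(2 * np.pi * 4.0 * t)
        pt = band_power_2_6(_trace(x))
        measured = pt.band_power.mean()
        # oracle: full-length periodogram of the *raw* trace, integrated
        # over the band -- independent of the downsampling path
        freqs, psd = sps.periodogram(x, fs=FS, detrend="constant")
        band = (freqs >= 2.0) & (freqs <= 6.0)
        oracle = np.sum(psd[band]) * (freqs[1] - freqs[0])
        assert measured == pytest.approx(oracle, rel=0.01)
        assert oracle == pytest.approx(A**2 / 2.0, rel=0.01)

    def test_out_of_band_tone_rejected(self):
        t = np.arange(0, 40, 1 / FS)
        in_band = band_power_2_6(_trace(-60 + 2 * np.sin(2 * np.pi * 4 * t)))
        out_band = band_power_2_6(_trace(-60 + 2 * np.sin(2 * np.pi * 20 * t)))
        assert out_band.band_power.mean() < 0.01 * in_band.band_power.mean()

    def test_rejects_short_trace(self):
        with pytest.raises(ValueError):
            band_power_2_6(_trace(np.full(10_000, -60.0)))


class TestPulseConditionedPower:
    def _pulse_trace(self, oscillate, end=5.0):
        t = np.arange(0, end + 5.0, 1 / FS)
        vm = np.full(t.size, -60.0)
        pulse = (t >= 3.0) & (t < end)
        vm[pulse] -= 15.0
        if oscillate:
            vm[pulse] += 2.0 * np.sin(2 * np.pi * 4.0 * t[pulse])
        return _trace(vm)

    def _raw_pulse_power(self, trace, start, end):
        from pfnavec.ephys import _downsample, _stft_band_power

        x = _downsample(trace.vm, FS, 100.0)
        times, pw = _stft_band_power(x, 100.0, 2.0, 0.010)
        return pw[(times >= start) & (times <= end)].mean()

    def test_step_artifact_removed(self):
        """Ramp replacement suppresses the step's band power by > 98%."""
        trace = self._pulse_trace(False)
        conditioned = pulse_conditioned_power(trace, 3.0, 5.0)
        raw = self._raw_pulse_power(trace, 3.0, 5.0)
        assert conditioned < 0.05
        assert conditioned < 0.02 * raw

    def test_in_pulse_oscillation_measured(self):
        power = pulse_conditioned_power(self._pulse_trace(True, end=7.0), 3.0, 7.0)
        # compare against the sliding estimator on a long oscillatory core
        t = np.arange(0, 20, 1 / FS)
        core = band_power_2_6(_trace(-75.0 + 2.0 * np.sin(2 * np.pi * 4.0 * t)))
        assert power == pytest.approx(core.band_power.mean(), rel=0.10)

    def test_interpolation_suppresses_step_power(self):
        """Without edge interpolation the Vm steps leak into the band."""
        trace = self._pulse_trace(False)
        conditioned = pulse_conditioned_power(trace, 3.0, 5.0)
        raw = self._raw_pulse_power(trace, 3.0, 5.0)
        assert raw > 10.0 * conditioned

    def test_rejects_short_pulse(self):
        with pytest.raises(ValueError):
            pulse_conditioned_power(self._pulse_trace(False), 3.0, 3.3)


class TestBaselineVm:
    def test_minimum_of_populated_bins(self):
        curve = TuningCurve1D(
            np.array([-90.0, 0.0, 90.0]),
            np.array([-64.0, -55.0, -50.0]),
            np.array([5.0, 5.0, 5.0]),
            np.array([True, True, True]),
        )
        assert baseline_vm(curve) == -64.0

    def test_constant_curve(self):
        curve = TuningCurve1D(
            np.array([0.0, 90.0]),
            np.array([-60.0, -60.0]),
            np.array([3.0, 3.0]),
            np.array([True, True]),
        )
        assert baseline_vm(curve) == -60.0

    def test_rejects_empty(self):
        curve = TuningCurve1D(
            np.array([0.0]), np.array([np.nan]), np.array([0.0]), np.array([False])
        )
        with pytest.raises(ValueError):
            baseline_vm(curve)


class TestRoundTrips:
    """Estimator round trips on a controlled-sweep synthetic recording."""

    def _truth_surface(self, fixture, model):
        m = fixture["analysis"]["map_vm"]
        H, W = np.meshgrid(
            m.heading_centers_deg, m.airflow_directions_deg, indexing="ij"
        )
        return model(fixture["truth"], H, W)

    def test_rate_map_matches_model(self, ephys_roundtrip):
        m = ephys_roundtrip["analysis"]["map_rate"]
        truth = self._truth_surface(ephys_roundtrip, synth.model_rate)
        mask = m.populated
        data, pred = m.means[mask], truth[mask]
        r2 = 1 - np.sum((data - pred) ** 2) / np.sum((data - data.mean()) ** 2)
        assert r2 > 0.95

    def test_power_map_matches_model_up_to_scale(self, ephys_roundtrip):
        m = ephys_roundtrip["analysis"]["map_power"]
        truth = self._truth_surface(ephys_roundtrip, synth.model_power)
        mask = m.populated
        data, pred = m.means[mask], truth[mask]
        scale = np.sum(data * pred) / np.sum(pred**2)  # single global factor
        assert 0.8 < scale < 1.2
        pred = scale * pred
        r2 = 1 - np.sum((data - pred) ** 2) / np.sum((data - data.mean()) ** 2)
        assert r2 > 0.95

    def test_detection_matches_generated_spikes(self, ephys_roundtrip):
        spikes = ephys_roundtrip["analysis"]["spikes"]
        true = ephys_roundtrip["true_spikes"]
        assert abs(len(spikes) - true.size) / true.size < 0.05

    def test_baseline_vm_matches_model_minimum(self, ephys_roundtrip):
        """Heading-curve minimum recovers a0 - aH on puff-free samples.

        The controlled sweep couples heading dwells to trials, so the
        airflow term would bias per-bin means; restricting to
        inter-puff samples isolates the heading tuning.
        """
        from pfnavec.ephys import baseline_vm as bvm
        from pfnavec.tuning import heading_tuning

        cond = ephys_roundtrip["analysis"]["conditioned"]
        outside = np.ones(cond.t.size, dtype=bool)
        for tr in ephys_roundtrip["trials"]:
            outside &= ~((cond.t >= tr.onset_s) & (cond.t < tr.offset_s))
        curve = heading_tuning(
            cond.t[outside], cond.vm[outside], ephys_roundtrip["behavior"]
        )
        truth = ephys_roundtrip["truth"]
        assert bvm(curve) == pytest.approx(truth.a0 - truth.aH, abs=1.0)
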