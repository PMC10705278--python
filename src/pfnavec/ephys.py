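"""Membrane-potential processing: conditioning, spike detection, rates,
2-6 Hz band power and pulse-conditioned power.

The processing chain follows standard whole-cell current-clamp practice
for small central-brain neurons: the raw 10 kHz record is downsampled
and median-filtered for a subthreshold Vm estimate; sodium spikes are
detected on a 150-1000 Hz bandpassed copy with a robust threshold and a
6.66 ms refractory rule; calcium-spike strength is quantified as mean
spectral power in the 2-6 Hz band of a short-time Fourier transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .tuning import TuningCurve1D

__all__ = [
    "EphysTrace",
    "SpikeTrain",
    "PowerTrace",
    "condition_vm",
    "detect_sodium_spikes",
    "spike_rate",
    "band_power_2_6",
    "pulse_conditioned_power",
    "baseline_vm",
]

NATIVE_FS = 10_000.0
CONDITIONED_FS = 1_000.0
MEDIAN_KERNEL_S = 0.040
BANDPASS_HZ = (150.0, 1000.0)
REFRACTORY_S = 6.66e-3
BAND_HZ = (2.0, 6.0)
SPEC_WINDOW_S = 4.0
SPEC_STEP_S = 0.020


@dataclass
class EphysTrace:
    """Uniformly sampled membrane-potential record (mV)."""

    t: np.ndarray
    vm: np.ndarray
    fs: float
    injected_current: np.ndarray | None = None
    trials: list = field(default_factory=list)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        if self.t.shape != self.vm.shape:
            raise ValueError("t and vm must have the same shape")
        if not np.all(np.isfinite(self.vm)):
            raise ValueError("vm must be finite")

    @property
    def duration_s(self) -> float:
        return self.t.size / self.fs


@dataclass
class SpikeTrain:
    """Sorted spike times (s) respecting the 6.66 ms refractory rule."""

    spike_times: np.ndarray

    def __post_init__(self):
        st = np.asarray(self.spike_times, dtype=float)
        if st.size and np.any(np.diff(st) < REFRACTORY_S):
            raise ValueError("inter-spike intervals must be >= 6.66 ms")
        self.spike_times = st

    def __len__(self):
        return self.spike_times.size


@dataclass
class PowerTrace:
    """Band power (mV^2) over time; timestamps are window centres."""

    t: np.ndarray
    band_power: np.ndarray


def condition_vm(trace: EphysTrace) -> EphysTrace:
    """Downsample to 1 kHz and median-filter (40 ms kernel).

    The downsampling takes the median of each 1 ms block, which already
    suppresses brief spikes; the 40 ms running median removes what
    remains, yielding a subthreshold Vm estimate.
    """
    factor = int(round(trace.fs / CONDITIONED_FS))
    kernel = int(round(MEDIAN_KERNEL_S * CONDITIONED_FS)) | 1  # odd
    n = (trace.vm.size // factor) * factor
    if n < factor * kernel:
        raise ValueError("trace shorter than one median-filter kernel")
    blocks = trace.vm[:n].reshape(-1, factor)
    vm_ds = np.median(blocks, axis=1)
    t_ds = trace.t[:n:factor] + 0.5 * (factor - 1) / trace.fs
    vm_f = sps.medfilt(vm_ds, kernel_size=kernel)
    return EphysTrace(t_ds, vm_f, CONDITIONED_FS, trials=trace.trials)


def _bandpassed(trace: EphysTrace) -> np.ndarray:
    # 8-pole Bessel bandpass, applied forward-backward for zero phase lag
    sos = sps.bessel(
        4, BANDPASS_HZ, btype="bandpass", fs=trace.fs, output="sos", norm="phase"
    )
    return sps.sosfiltfilt(sos, trace.vm)


def detect_sodium_spikes(
    trace: EphysTrace,
    threshold_mult: float = 6.0,
    threshold_mv: float | None = None,
) -> SpikeTrain:
    """Threshold crossings of the 150-1000 Hz bandpassed trace.

    The threshold defaults to ``threshold_mult`` times a robust
    (median-absolute-deviation based) SD of the bandpassed trace; pass
    ``threshold_mv`` to override with an absolute value. Events closer
    than 6.66 ms to an accepted event are rejected, keeping the earlier.
    """
    bp = _bandpassed(trace)
    if threshold_mv is None:
        robust_sd = 1.4826 * np.median(np.abs(bp - np.median(bp)))
        threshold_mv = threshold_mult * robust_sd
    peaks, _ = sps.find_peaks(bp, height=threshold_mv)
    if peaks.size == 0:
        return SpikeTrain(np.empty(0))
    times = trace.t[peaks]
    kept = [times[0]]
    for tt in times[1:]:
        if tt - kept[-1] >= REFRACTORY_S:
            kept.append(tt)
    return SpikeTrain(np.array(kept))


def spike_rate(spikes: SpikeTrain, t_grid) -> np.ndarray:
    """Spike rate (spikes/s) by convolution with a unit-area 1 s Hann window."""
    t_grid = np.asarray(t_grid, dtype=float)
    dt = float(np.median(np.diff(t_grid)))
    counts = np.zeros_like(t_grid)
    if len(spikes):
        idx = np.clip(
            np.round((spikes.spike_times - t_grid[0]) / dt).astype(int),
            0,
            t_grid.size - 1,
        )
        np.add.at(counts, idx, 1.0)
    width = max(int(round(1.0 / dt)), 3)
    kernel = sps.windows.hann(width)
    kernel /= kernel.sum() * dt  # unit area in time
    return np.convolve(counts, kernel, mode="same")


def _downsample(x, fs, fs_out):
    """Zero-phase FIR anti-aliased downsampling with a flat passband.

    The low-frequency band of interest (2-6 Hz) must be preserved to
    well under 1%; a generously long zero-phase FIR (cutoff at 45% of
    the output rate) keeps the passband gain error below 0.1%.
    """
    if np.isclose(fs, fs_out):
        return x
    q = int(round(fs / fs_out))
    taps = sps.firwin(50 * q + 1, 0.45 * fs_out, fs=fs)
    return sps.filtfilt(taps, [1.0], x)[::q]


def _stft_band_power(x, fs, window_s, step_s, band=BAND_HZ):
    """Mean-free Hann-tapered sliding FFT; integrated band power per window."""
    nper = int(round(window_s * fs))
    step = max(int(round(step_s * fs)), 1)
    if x.size < nper:
        raise ValueError("trace shorter than one spectral window")
    noverlap = nper - step
    freqs, times, sxx = sps.spectrogram(
        x,
        fs=fs,
        window="hann",
        nperseg=nper,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        mode="psd",
    )
    sel = (freqs >= band[0]) & (freqs <= band[1])
    df = freqs[1] - freqs[0]
    power = sxx[sel].sum(axis=0) * df
    return times, power


def band_power_2_6(trace: EphysTrace, fs_spec: float = 100.0) -> PowerTrace:
    """Sliding-window 2-6 Hz power (4 s Hann windows stepped 20 ms).

    The trace is downsampled to 100 Hz first. Powers are integrated
    spectral densities over [2, 6] Hz, so a pure tone of amplitude A
    inside the band yields ~A^2/2 (its variance).
    """
    x = _downsample(trace.vm, trace.fs, fs_spec)
    times, power = _stft_band_power(x, fs_spec, SPEC_WINDOW_S, SPEC_STEP_S)
    return PowerTrace(times + trace.t[0], power)


def pulse_conditioned_power(
    trace: EphysTrace,
    pulse_start_s: float,
    pulse_end_s: float,
    fs_spec: float = 100.0,
) -> float:
    """2-6 Hz power during a current pulse, with edge artifacts removed.

    Two 600 ms segments -- one starting 550 ms before pulse onset, one
    starting 50 ms before pulse offset -- are replaced by linear ramps
    between their endpoints, which removes the step transients that
    would otherwise leak broadband power into the band. Power is then
    computed with 2 s windows stepped 10 ms, and the mean over windows
    whose centre lies inside the pulse is returned (with 2 s windows on
    2 s pulses, requiring full containment would leave a single window,
    and it is precisely the edge-spanning windows that motivate the
    interpolation step).
    """
    seg_len = 0.600
    if pulse_end_s - pulse_start_s < seg_len:
        raise ValueError("pulse too short for the interpolation segments")
    vm = trace.vm.copy()
    for seg_start in (pulse_start_s - 0.550, pulse_end_s - 0.050):
        i0 = int(round((seg_start - trace.t[0]) * trace.fs))
        i1 = i0 + int(round(seg_len * trace.fs))
        if i0 < 0 or i1 > vm.size:
            raise ValueError("insufficient flanking data around the pulse")
        vm[i0:i1] = np.linspace(vm[i0], vm[i1 - 1], i1 - i0)
    x = _downsample(vm, trace.fs, fs_spec)
    times, power = _stft_band_power(x, fs_spec, window_s=2.0, step_s=0.010)
    times = times + trace.t[0]
    inside = (times >= pulse_start_s) & (times <= pulse_end_s)
    if not inside.any():
        raise ValueError("no spectral window centred inside the pulse")
    return float(power[inside].mean())


def baseline_vm(heading_curve: TuningCurve1D) -> float:
    """Baseline Vm: the minimum of the populated heading-tuning bin means."""
    if not heading_curve.populated.any():
        raise ValueError("heading curve has no populated bins")
    return float(np.nanmin(heading_curve.means[heading_curve.populated]))
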