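"""Synthetic in-silico experiment generator.

Produces a complete closed-loop heading + open-loop air-puff experiment
from a generative model of PFNa physiology, so that every downstream
processing stage can be exercised and validated without recorded data:

* a pseudorandomized 12-direction air-puff protocol (4 s puffs, 5 s
  inter-pulse intervals, each block a permutation of the 12 directions);
* a wrapped-random-walk heading trajectory with a forward-speed trace;
* 10 kHz intracellular Vm traces containing sodium spikes (Poisson, rate
  ``[bH cos H + bW cos(W +/- 45)]_+^2``) and hyperpolarization-gated
  2-6 Hz oscillations (band power ``c0 + [cH cos H + cW cos(W +/- 45)]_-^2``)
  on top of a sum-of-sinusoids mean path
  ``a0 + aH cos H + aW cos(W +/- 45)``;
* sector-resolved calcium-imaging matrices for the protocerebral bridge,
  ellipsoid body and noduli, generated from a dual-threshold calcium
  model: instantaneous drive
  ``k_na [Vm - theta_na]_+^2 + k_ca [theta_ca - Vm]_+^2``
  convolved with an exponential indicator kernel.

Here H is the heading relative to a cell's preferred direction, W is the
egocentric airflow direction, and the +/- 45 deg airflow offset applies
to left-/right-bridge cells respectively (left: +45). All generators are
pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .circular import BRIDGE18, EB16, NODULI2, PFN_LEFT_COLS, PFN_RIGHT_COLS, wrap_deg
from .ephys import EphysTrace
from .imaging import SectorMatrix
from .tuning import AIRFLOW_DIRECTIONS_DEG, ConjunctiveMap, heading_bin_centers

__all__ = [
    "ProtocolTrial",
    "BehaviorTrace",
    "GroundTruthParams",
    "SyntheticDataset",
    "make_protocol",
    "make_heading_trajectory",
    "make_stepped_heading",
    "simulate_vm_trace",
    "simulate_imaging",
    "default_population",
    "model_vm",
    "model_rate",
    "model_power",
    "make_conjunctive_maps",
    "insert_spike_templates",
]

PUFF_DURATION_S = 4.0
INTER_PULSE_S = 5.0
EPHYS_FS = 10_000.0
BEHAVIOR_FS = 80.0


@dataclass(frozen=True)
class ProtocolTrial:
    """One open-loop air puff."""

    direction_deg: float
    onset_s: float
    duration_s: float = PUFF_DURATION_S
    block_index: int = 0

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class BehaviorTrace:
    """Closed-loop heading (bar position) and forward speed on one clock."""

    t: np.ndarray
    heading_deg: np.ndarray
    forward_speed: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.heading_deg = np.asarray(self.heading_deg, dtype=float)
        self.forward_speed = np.asarray(self.forward_speed, dtype=float)
        if np.any(self.forward_speed < 0):
            raise ValueError("forward speed must be nonnegative")

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) + float(np.median(np.diff(self.t)))


@dataclass(frozen=True)
class GroundTruthParams:
    """Generative parameters for one PFNa cell (and its population).

    The sinusoid amplitudes follow the recorded physiology: baseline Vm
    around -64 mV with ~14 mV peak-to-trough heading modulation. The
    two spike thresholds of the dual-threshold calcium model are package
    defaults (the qualitative model constrains only their ordering):
    symmetric about the baseline so depolarizing and hyperpolarizing
    deviations are equally detectable. ``k_ca/k_na = 5`` reflects the
    larger fluorescence transients of calcium spikes; its reciprocal is
    the decoder's calcium-to-sodium conversion factor (0.2).
    """

    side: str = "right"  # "left" | "right"
    preferred_heading_deg: float = 0.0
    a0: float = -64.0  # mV
    aH: float = 7.0  # mV
    aW: float = 5.0  # mV
    bH: float = 4.0  # sqrt(spikes/s); peak rate (bH+bW)^2 ~ 50 spikes/s
    bW: float = 3.0  # sqrt(spikes/s)
    c0: float = 0.5  # mV^2
    cH: float = 3.0  # sqrt(mV^2); peak oscillation amplitude ~ 7 mV
    cW: float = 2.25  # sqrt(mV^2)
    theta_na: float = -60.0  # mV, sodium-spike threshold
    theta_ca: float = -68.0  # mV, calcium-spike threshold
    k_na: float = 1.0  # calcium drive per (mV)^2 above theta_na
    k_ca: float = 5.0  # calcium drive per (mV)^2 below theta_ca
    vm_noise_sd: float = 1.0  # mV
    osc_freq_hz: float = 4.0  # within the 2-6 Hz band
    ca_tau_s: float = 1.0  # indicator decay
    frame_rate_hz: float = 8.0
    imaging_noise_sd: float = 0.05
    rear_spike_deficit: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        for name in ("aH", "aW", "bH", "bW", "cH", "cW", "k_na", "k_ca"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.theta_ca > self.theta_na:
            raise ValueError("theta_ca must be <= theta_na")
        if not 2.0 <= self.osc_freq_hz <= 6.0:
            raise ValueError("osc_freq_hz must lie in [2, 6]")

    @property
    def airflow_sign(self) -> float:
        """Sign s of the cos(W + s*45) airflow term: +1 left, -1 right."""
        return 1.0 if self.side == "left" else -1.0


@dataclass
class SyntheticDataset:
    """One complete in-silico experiment."""

    behavior: BehaviorTrace
    trials: list
    vm: dict  # cell label -> EphysTrace
    true_spikes: dict  # cell label -> spike times (s)
    imaging: dict  # structure -> SectorMatrix
    truths: list  # GroundTruthParams per imaging cell
    ephys_truths: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# protocol and behaviour


def make_protocol(
    n_blocks: int,
    seed: int,
    start_s: float = 5.0,
    duration_s: float = PUFF_DURATION_S,
    gap_s: float = INTER_PULSE_S,
):
    """Pseudorandomized blocks of the 12 air-puff directions."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    trials = []
    onset = start_s
    for b in range(n_blocks):
        for d in rng.permutation(AIRFLOW_DIRECTIONS_DEG):
            trials.append(
                ProtocolTrial(float(d), onset, duration_s, block_index=b)
            )
            onset += duration_s + gap_s
    return trials


def make_heading_trajectory(
    duration_s: float,
    turn_rate_sd: float = 60.0,
    seed: int = 0,
    rate_hz: float = BEHAVIOR_FS,
    moving_fraction: float = 0.9,
    mean_speed_mm_s: float = 2.0,
) -> BehaviorTrace:
    """Saccadic heading trajectory with a two-state forward-speed trace.

    Emulates a tethered fly fixating a closed-loop bar: the heading is
    near-constant between discrete saccadic turns (Poisson events,
    ~1 every 2 s) whose size has SD ``turn_rate_sd`` deg, plus a small
    within-bout drift (``turn_rate_sd / 8`` deg per sqrt-second). With
    the 60 deg default a 10 min walk visits every 10 deg heading bin.
    ``turn_rate_sd = 0`` yields a constant heading. The speed trace
    alternates between walking bouts (mean dwell 5 s) and standing
    pauses so that ``moving_fraction`` of the samples exceed the
    0.5 mm/s behavioural gate.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) * dt
    saccade_rate_hz = 0.5
    jumps = np.where(
        rng.random(n) < saccade_rate_hz * dt,
        rng.normal(0.0, turn_rate_sd, n),
        0.0,
    )
    drift = rng.normal(0.0, (turn_rate_sd / 8.0) * np.sqrt(dt), size=n)
    steps = jumps + drift
    steps[0] = rng.uniform(-180.0, 180.0)
    heading = wrap_deg(np.cumsum(steps))
    # two-state walk/stand process
    speed = np.empty(n)
    moving = True
    dwell_move = 5.0
    dwell_stand = dwell_move * (1.0 - moving_fraction) / max(moving_fraction, 1e-9)
    i = 0
    while i < n:
        dwell = dwell_move if moving else max(dwell_stand, dt)
        length = max(1, int(round(rng.exponential(dwell) * rate_hz)))
        j = min(n, i + length)
        if moving:
            speed[i:j] = mean_speed_mm_s + np.abs(rng.normal(0.0, 0.5, j - i))
        else:
            speed[i:j] = rng.uniform(0.0, 0.3, j - i)
        moving = not moving
        i = j
    if moving_fraction >= 1.0:
        speed = np.full(n, mean_speed_mm_s)
    return BehaviorTrace(t, heading, speed)


def make_stepped_heading(
    duration_s: float,
    dwell_s: float = 9.0,
    step_deg: float = 140.0,
    start_deg: float = 0.0,
    rate_hz: float = BEHAVIOR_FS,
    speed_mm_s: float = 2.0,
) -> BehaviorTrace:
    """Piecewise-constant heading sweep (controlled-protocol analogue).

    The heading advances by ``step_deg`` every ``dwell_s`` seconds (a
    stride of 140 deg cycles through all 18 conjunctive heading bins
    with consecutive dwells well separated). Used to validate the
    conditional estimators without the smearing that natural saccadic
    behaviour introduces across binning windows.
    """
    if duration_s <= 0 or dwell_s <= 0:
        raise ValueError("duration and dwell must be positive")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    k = np.floor(t / dwell_s)
    heading = wrap_deg(start_deg + k * step_deg)
    return BehaviorTrace(t, heading, np.full(n, speed_mm_s))


# ---------------------------------------------------------------------------
# response model


def _airflow_term(W_deg, sign):
    return np.cos(np.deg2rad(np.asarray(W_deg, dtype=float) + sign * 45.0))


def model_vm(p: GroundTruthParams, H_deg, W_deg, airflow_on=True):
    """Mean subthreshold Vm: a0 + aH cos H + aW cos(W +/- 45)."""
    H = np.deg2rad(np.asarray(H_deg, dtype=float))
    out = p.a0 + p.aH * np.cos(H)
    if np.any(airflow_on):
        out = out + p.aW * _airflow_term(W_deg, p.airflow_sign) * airflow_on
    return out


def model_rate(p: GroundTruthParams, H_deg, W_deg, airflow_on=True):
    """Sodium-spike rate: positive-rectified quadratic of the drive."""
    H = np.deg2rad(np.asarray(H_deg, dtype=float))
    drive = p.bH * np.cos(H) + p.bW * _airflow_term(W_deg, p.airflow_sign) * np.asarray(
        airflow_on, dtype=float
    )
    r = np.clip(drive, 0.0, None) ** 2
    if p.rear_spike_deficit:
        rear = np.isclose(np.abs(wrap_deg(W_deg)), 180.0) & (
            np.asarray(airflow_on, dtype=bool)
        )
        r = np.where(rear, 0.0, r)
    return r


def model_power(p: GroundTruthParams, H_deg, W_deg, airflow_on=True):
    """2-6 Hz band power: c0 plus negative-rectified quadratic drive."""
    H = np.deg2rad(np.asarray(H_deg, dtype=float))
    drive = p.cH * np.cos(H) + p.cW * _airflow_term(W_deg, p.airflow_sign) * np.asarray(
        airflow_on, dtype=float
    )
    return p.c0 + np.clip(drive, None, 0.0) ** 2


# ---------------------------------------------------------------------------
# electrophysiology generator


SPIKE_TEMPLATE_MS = 2.0
SPIKE_AMPLITUDE_MV = 3.0
#: the biphasic template peaks a quarter-cycle after its onset; reported
#: spike times refer to the waveform peak, as detection does
SPIKE_PEAK_OFFSET_S = SPIKE_TEMPLATE_MS * 1e-3 / 4.0


def _spike_template(fs: float) -> np.ndarray:
    """Brief biphasic somatic spike waveform (~3 mV, 2 ms)."""
    n = int(round(SPIKE_TEMPLATE_MS * 1e-3 * fs))
    tt = np.arange(n) / fs
    return SPIKE_AMPLITUDE_MV * np.sin(2.0 * np.pi * tt / (SPIKE_TEMPLATE_MS * 1e-3))


def insert_spike_templates(vm: np.ndarray, spike_idx, fs: float) -> np.ndarray:
    out = vm.copy()
    tpl = _spike_template(fs)
    for i in np.asarray(spike_idx, dtype=int):
        j = min(i + tpl.size, out.size)
        out[i:j] += tpl[: j - i]
    return out


def _ou_noise(rng, n, dt, sd, tau=0.010):
    if sd == 0:
        return np.zeros(n)
    a = np.exp(-dt / tau)
    white = rng.normal(0.0, 1.0, n)
    return sps.lfilter([sd * np.sqrt(1.0 - a * a)], [1.0, -a], white)


SPIKE_DEAD_TIME_S = 7.5e-3


def _dead_time_poisson(rng, rate, dt):
    """Spike sample indices of a refractory Poisson process.

    Candidates are drawn at intensity ``r / (1 - r d)`` and thinned by
    an absolute dead time d, which makes the observed rate equal the
    requested ``rate`` (for r d < 1) while enforcing ISIs >= d.
    """
    d = SPIKE_DEAD_TIME_S
    excess = np.clip(rate * d, None, 0.9)
    lam = rate / (1.0 - excess)
    candidates = np.flatnonzero(rng.random(rate.size) < lam * dt)
    kept = []
    dead = int(round(d / dt))
    last = -dead
    for i in candidates:
        if i - last >= dead:
            kept.append(i)
            last = i
    return np.asarray(kept, dtype=int)


def _trial_signals(t, trials):
    """(in_puff flag, W_deg during puffs) sampled on grid t."""
    in_puff = np.zeros(t.size, dtype=bool)
    W = np.zeros(t.size)
    for tr in trials:
        sel = (t >= tr.onset_s) & (t < tr.offset_s)
        in_puff |= sel
        W[sel] = tr.direction_deg
    return in_puff, W


def simulate_vm_trace(
    truth: GroundTruthParams,
    behavior: BehaviorTrace,
    trials,
    fs: float = EPHYS_FS,
    seed: int | None = None,
):
    """10 kHz Vm trace from the generative model.

    Returns ``(EphysTrace, true_spike_times)``. The airflow terms are
    active only inside puff windows. Sodium spikes are drawn as an
    inhomogeneous Poisson process from the rectified-quadratic rate and
    inserted as biphasic 2 ms templates. Spike generation uses a
    dead-time (refractory) Poisson process -- candidate intensity
    ``r / (1 - r * d)`` thinned by an absolute dead time d = 7.5 ms --
    so that the observed rate equals the model rate ``r`` while
    inter-spike intervals respect the physiological refractory period
    (and therefore survive the 6.66 ms analysis rule downstream). The
    2-6 Hz oscillation is an
    amplitude-modulated sinusoid whose instantaneous band power follows
    the reverse-rectified quadratic model (the rectification itself acts
    as the hyperpolarization gate). Additive Vm noise is an
    Ornstein-Uhlenbeck process with SD ``vm_noise_sd``.
    """
    for tr in trials:
        if tr.offset_s > behavior.duration_s + 1e-9:
            raise ValueError("trial window outside the behavioural recording")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    dt = 1.0 / fs
    n = int(round(behavior.duration_s * fs))
    t = np.arange(n) * dt
    unwrapped = np.rad2deg(np.unwrap(np.deg2rad(behavior.heading_deg)))
    heading = wrap_deg(np.interp(t, behavior.t, unwrapped))
    H = wrap_deg(heading - truth.preferred_heading_deg)
    in_puff, W = _trial_signals(t, trials)
    vm = model_vm(truth, H, W, airflow_on=in_puff.astype(float))
    rate = model_rate(truth, H, W, airflow_on=in_puff.astype(float))
    power = model_power(truth, H, W, airflow_on=in_puff.astype(float))
    # oscillation: slowly amplitude-modulated sinusoid with band power = model p
    amp = np.sqrt(2.0 * power)
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    osc = amp * np.sin(2.0 * np.pi * truth.osc_freq_hz * t + phase0)
    noise = _ou_noise(rng, n, dt, truth.vm_noise_sd)
    spike_idx = _dead_time_poisson(rng, rate, dt)
    vm_full = insert_spike_templates(vm + osc + noise, spike_idx, fs)
    trace = EphysTrace(t, vm_full, fs, trials=list(trials))
    return trace, t[spike_idx] + SPIKE_PEAK_OFFSET_S


# ---------------------------------------------------------------------------
# imaging generator


def default_population(
    n_per_side: int = 8, seed: int = 0, **overrides
):
    """Population of PFNa cells with preferred headings tiling 360 deg.

    Each bridge half holds ``n_per_side`` cells at ``360/n_per_side``
    deg spacing, matching the 8 innervated glomeruli per half.
    """
    truths = []
    step = 360.0 / n_per_side
    for side in ("left", "right"):
        for k in range(n_per_side):
            truths.append(
                GroundTruthParams(
                    side=side,
                    preferred_heading_deg=wrap_deg(k * step),
                    seed=seed,
                    **overrides,
                )
            )
    return truths


def _calcium_drive(p: GroundTruthParams, vm: np.ndarray) -> np.ndarray:
    up = np.clip(vm - p.theta_na, 0.0, None)
    down = np.clip(p.theta_ca - vm, 0.0, None)
    return p.k_na * up**2 + p.k_ca * down**2


def _exp_filter(x, dt, tau):
    a = np.exp(-dt / tau)
    return sps.lfilter([1.0 - a], [1.0, -a], x, axis=0)


FLUOR_BASELINE = 1.0
FLUOR_GAIN = 0.05


def simulate_imaging(
    truths,
    behavior: BehaviorTrace,
    trials,
    seed: int = 0,
):
    """Sector-resolved calcium matrices for bridge, ellipsoid body, noduli.

    Per-cell calcium drive follows the dual-threshold model; the drive is
    convolved with a single-exponential indicator kernel (``ca_tau_s``),
    sampled at the frame rate and embedded into raw fluorescence as
    ``F = baseline + gain * drive + noise`` (clipped at 0). The compass
    (EPG) signal is a unit-contrast cosine bump at the current heading,
    passed through the same kernel. Left-bridge cells fill glomeruli 1-8
    and right-bridge cells glomeruli 11-18 (1-based, left to right viewed
    from posterior); the left nodulus pools the right-bridge population
    and vice versa.
    """
    truths = list(truths)
    left = [p for p in truths if p.side == "left"]
    right = [p for p in truths if p.side == "right"]
    if len(left) != 8 or len(right) != 8:
        raise ValueError(
            "imaging generator needs exactly 8 cells per side tiling the "
            "8 innervated glomeruli of each bridge half"
        )
    for group in (left, right):
        group.sort(key=lambda p: wrap_deg(p.preferred_heading_deg) % 360.0)
        prefs = np.sort(np.array([p.preferred_heading_deg for p in group]) % 360.0)
        if not np.allclose(np.diff(prefs), 45.0):
            raise ValueError("preferred headings must tile 360 deg in 45 deg steps")
    rng = np.random.default_rng(seed)
    p0 = truths[0]
    for tr in trials:
        if tr.offset_s > behavior.duration_s + 1e-9:
            raise ValueError("trial window outside the behavioural recording")
    t_b = behavior.t
    dt_b = float(np.median(np.diff(t_b)))
    in_puff, W = _trial_signals(t_b, trials)
    heading = behavior.heading_deg

    def cell_drive(p: GroundTruthParams) -> np.ndarray:
        H = wrap_deg(heading - p.preferred_heading_deg)
        vm = model_vm(p, H, W, airflow_on=in_puff.astype(float))
        return _calcium_drive(p, vm)

    drive_left = np.column_stack([cell_drive(p) for p in left])
    drive_right = np.column_stack([cell_drive(p) for p in right])

    # EPG: cosine bump across the 16 innervated glomeruli, 45 deg each
    j = np.arange(16)
    epg16 = 1.0 + np.cos(np.deg2rad(j[None, :] * 45.0 - heading[:, None]))
    # ellipsoid body: same bump over the 16 wedges
    eb = 1.0 + np.cos(np.deg2rad(EB16.centers[None, :] - heading[:, None]))

    n_frames = int(np.floor(behavior.duration_s * p0.frame_rate_hz))
    t_frames = (np.arange(n_frames) + 0.5) / p0.frame_rate_hz

    def to_frames(x, gain=FLUOR_GAIN):
        y = _exp_filter(x, dt_b, p0.ca_tau_s)
        sampled = np.empty((n_frames, x.shape[1]))
        for c in range(x.shape[1]):
            sampled[:, c] = np.interp(t_frames, t_b, y[:, c])
        noise = rng.normal(0.0, p0.imaging_noise_sd, sampled.shape)
        return np.clip(FLUOR_BASELINE + gain * sampled + noise, 0.0, None)

    pfn = np.zeros((n_frames, 18))
    pfn_frames_left = to_frames(drive_left)
    pfn_frames_right = to_frames(drive_right)
    base = np.clip(
        FLUOR_BASELINE + rng.normal(0.0, p0.imaging_noise_sd, (n_frames, 2)), 0.0, None
    )
    pfn[:, list(PFN_LEFT_COLS)] = pfn_frames_left
    pfn[:, list(PFN_RIGHT_COLS)] = pfn_frames_right
    pfn[:, 8:10] = base  # medial pair not innervated by PFN cells

    epg = np.zeros((n_frames, 18))
    epg[:, 1:17] = to_frames(epg16, gain=1.0)
    epg[:, [0, 17]] = np.clip(
        FLUOR_BASELINE + rng.normal(0.0, p0.imaging_noise_sd, (n_frames, 2)), 0.0, None
    )

    noduli = to_frames(
        np.column_stack([drive_right.mean(axis=1), drive_left.mean(axis=1)])
    )

    return {
        "pfn_bridge": SectorMatrix(BRIDGE18, t_frames, pfn),
        "epg_bridge": SectorMatrix(BRIDGE18, t_frames, epg),
        "eb_epg": SectorMatrix(EB16, t_frames, to_frames(eb, gain=1.0)),
        "noduli": SectorMatrix(NODULI2, t_frames, noduli),
    }


# ---------------------------------------------------------------------------
# map-level generator (for parameter-recovery studies)


def make_conjunctive_maps(
    truth: GroundTruthParams,
    seed: int = 0,
    occupancy_s: float = 2.0,
    vm_map_noise_sd: float = 0.5,
    power_rel_sd: float = 0.2,
    noiseless: bool = False,
):
    """Noisy (or exact) conjunctive maps drawn directly from the model.

    Emulates the measurement noise of the full pipeline at the level of
    the 18 x 12 grid: Gaussian noise on binned Vm means, Poisson spike
    counts over ``occupancy_s`` of data per grid cell, and multiplicative
    gamma noise (relative SD ``power_rel_sd``) on spectral power
    estimates. Heading is already expressed relative to the preferred
    direction, so fits on these maps recover the generating parameters
    directly.
    """
    rng = np.random.default_rng(seed)
    H = heading_bin_centers(20.0)
    W = np.sort(AIRFLOW_DIRECTIONS_DEG)
    Hg, Wg = np.meshgrid(H, W, indexing="ij")
    vm = model_vm(truth, Hg, Wg)
    rate = model_rate(truth, Hg, Wg)
    power = model_power(truth, Hg, Wg)
    if not noiseless:
        vm = vm + rng.normal(0.0, vm_map_noise_sd, vm.shape)
        rate = rng.poisson(rate * occupancy_s) / occupancy_s
        shape = 1.0 / power_rel_sd**2
        power = power * rng.gamma(shape, 1.0 / shape, power.shape)
    occ = np.full(vm.shape, occupancy_s)
    populated = np.ones(vm.shape, dtype=bool)

    def as_map(values):
        return ConjunctiveMap(H, W, np.asarray(values, dtype=float), occ, populated)

    return {"vm": as_map(vm), "rate": as_map(rate), "power": as_map(power)}
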