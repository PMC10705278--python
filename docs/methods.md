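# Methods

## Scope

`pfnavec` implements, as one testable pipeline, the analysis of a
closed-loop heading / open-loop air-puff experiment on PFNa neurons:
a synthetic-data generator (behaviour, stimuli, 10 kHz membrane
potential, sector-resolved calcium imaging), the electrophysiology and
imaging signal processing, tuning-curve and conjunctive-map
construction, response-model fitting, and the invertible-phasor decoder
for allocentric airflow direction. No recorded data ship with the
package; every quantitative claim in the test suite is validated
against the generative model or an independent numerical oracle.

## Conventions

Angles are degrees in `(-180, 180]` (180 preferred over −180 so each
class has one representative); 0° is directly in front of the fly,
180° behind, negative left, positive right. Times are seconds, voltages
mV. The protocerebral bridge has 18 glomeruli indexed left→right viewed
from the posterior; PFN cells skip the medial pair (8 innervated
glomeruli per half, 45°/glomerulus, one full cycle per half), EPG cells
skip the lateral pair (16 glomeruli, two bump copies 8 glomeruli
apart). Ellipsoid-body wedges 1 and 16 flank the ventral bisector,
which maps to the rear. Airflow terms use `cos(W + 45°)` for
left-bridge and `cos(W − 45°)` for right-bridge cells; the
bridge→fan-shaped-body heading shifts are −45° (left) and +45° (right).
This pairing is the one under which the explicit two-term pair output
equals the closed form `bH² + bW² + 2bHbW cos(W+H)` (verified to 1e−9
over 10⁴ random draws).

## Generative model

Ground-truth parameters (per cell; defaults in parentheses):

| parameter | meaning | default |
|---|---|---|
| `a0, aH, aW` | Vm baseline and modulation depths (mV) | −64, 7, 5 |
| `bH, bW` | spike-rate drive (√(spikes/s)) | 4, 3 |
| `c0, cH, cW` | 2–6 Hz power drive (mV units) | 0.5, 3, 2.25 |
| `theta_na, theta_ca` | sodium-/calcium-spike thresholds (mV) | −60, −68 |
| `k_na, k_ca` | calcium-drive gains per (mV)² beyond threshold | 1, 5 |
| `vm_noise_sd` | OU noise SD (mV, τ = 10 ms) | 1 |
| `osc_freq_hz` | calcium-spike oscillation frequency | 4 |
| `ca_tau_s` | calcium-indicator decay | 1.0 |
| `frame_rate_hz`, `imaging_noise_sd` | imaging clock and noise | 8, 0.05 |

Defaults follow the recorded physiology where magnitudes are published
(baseline near −64 mV; ~14 mV peak-to-trough heading modulation of Vm)
and realistic magnitudes elsewhere: peak sodium-spike rate
(bH+bW)² ≈ 50 spikes/s and peak oscillation amplitude
√(2·(cH+cW)²) ≈ 7 mV, both typical for central-complex recordings. The
two spike thresholds of the dual-threshold calcium model are package
choices (only their ordering is constrained by the physiology): they
sit symmetrically ±4 mV about the baseline so that, at rest, the
heading sinusoid straddles both. The gain ratio k_ca/k_na = 5 expresses
the larger fluorescence transients of calcium spikes; its reciprocal,
0.2, is exactly the decoder's default calcium→sodium conversion
factor κ, so the default experiment is "κ-matched".

**Vm traces (10 kHz).** Mean path `a0 + aH cos H + aW cos(W±45°)`,
airflow term active only inside 4 s puff windows. Sodium spikes are a
*dead-time* Poisson process: candidate intensity `r/(1 − r·d)` thinned
with an absolute dead time d = 7.5 ms, which makes the observed rate
equal the model rate `r = [bH cos H + bW cos(W±45°)]₊²` while keeping
inter-spike intervals above the 6.66 ms analysis refractory rule (a
plain Poisson train at ~50 spikes/s would lose ~25% of events to that
rule and bias every rate estimate downward). Spikes are 2 ms biphasic
3 mV templates; reported spike times refer to the waveform peak. The
calcium-spike oscillation is an amplitude-modulated sinusoid at
`osc_freq_hz` whose instantaneous band power equals
`p = c0 + [cH cos H + cW cos(W±45°)]₋²`; the negative rectification
itself acts as the hyperpolarization gate, so no separate threshold
comparison is applied on the Vm path (the thresholds govern the
calcium/imaging model). Additive noise is an Ornstein–Uhlenbeck
process. An optional `rear_spike_deficit` switch zeroes the sodium-spike
rate for puffs from directly behind, for robustness testing of the
fitters against the empirically observed rear anomaly; it is off by
default and the fitters never special-case it.

**Behaviour.** The heading trace emulates a tethered fly fixating a
closed-loop bar: Poisson saccades (~1 per 2 s, jump SD = `turn_rate_sd`
= 60°) plus a small within-bout drift, wrapped. A Brownian walk fast
enough to cover all heading bins would wander >100° within one 4 s
spectral window, which real flies do not. A two-state walk/stand
process makes ~90% of samples pass the 0.5 mm/s speed gate. A
deterministic `make_stepped_heading` sweep (heading constant within
each 9 s trial, striding 140° so consecutive dwells are uncorrelated)
is provided for estimator-validation protocols; round-trip tests use it
so binning windows see stationary conditions.

**Imaging.** Per-cell calcium drive
`k_na[Vm−θna]₊² + k_ca[θca−Vm]₊²` (subthreshold Vm, noiseless per
cell), convolved with a unit-gain single-exponential kernel
(`ca_tau_s`), sampled at the frame rate and embedded as
`F = 1 + 0.05·drive + noise`, clipped at zero. The compass signal is a
unit-contrast cosine bump at the current heading through the same
kernel (bridge and ellipsoid body). The left nodulus pools the
right-bridge population mean drive and vice versa. The generator
reproduces the qualitative signatures it is meant to: uniform
depolarization yields a bump at the compass phase, uniform
hyperpolarization a bump 180° away, and nodulus airflow tuning is
double-peaked (~180° apart) unless `theta_ca` is set unreachably low,
in which case it is single-peaked.

What the generator does **not** emulate: motion artifacts and ROI
segmentation errors, indicator nonlinearity and bleaching, synaptic
conductance dynamics, EPG bump deformation during puffs, fly-to-fly
parameter variability, and the rear-puff sodium-spike deficit (unless
switched on). Passing tests therefore demonstrate correctness of the
*analysis chain* under the stated model, not robustness to every
artifact of real recordings.

## Signal processing

**Vm conditioning.** Median of each 1 ms block (10 kHz → 1 kHz), then a
41-sample (40 ms) running median; removes 2 ms spikes to <0.1 mV while
attenuating a 1 Hz sinusoid by <5%.

**Spike detection.** 150–1000 Hz 8-pole Bessel bandpass (two-pass,
zero-phase — alignment tests need zero lag), peaks above a threshold of
6 robust (MAD-based) SDs of the bandpassed trace, then a 6.66 ms
refractory rule keeping the earlier event. The multiplier is a package
choice: spikes stand ~15σ above the passband noise while 6σ keeps the
false-positive rate during hyperpolarized epochs well below 0.1 Hz at
default noise (at 4–5σ it is not). Rates come from convolving spike
times with a unit-area 1 s Hann window.

**Band power (2–6 Hz).** The trace is downsampled to 100 Hz with a
long zero-phase FIR (cutoff 45 Hz; passband flat to <0.1% — an
off-the-shelf short decimation filter alone inflates a 4 Hz tone by
~0.5%, which would break the 1% periodogram-oracle agreement). Sliding
Hann-tapered, mean-detrended 4 s windows stepped 20 ms; band power is
the integrated one-sided spectral density over [2, 6] Hz, so a pure
in-band tone of amplitude A reads ≈ A²/2. For current-injection pulses,
two 600 ms segments (starting 550 ms before pulse onset and 50 ms
before offset) are replaced by linear ramps before a 2 s / 10 ms
spectrogram; the summary is the mean over windows whose *centre* lies
in the pulse — with 2 s windows on 2 s pulses almost no window is fully
contained, and the edge-spanning windows are precisely why the ramp
replacement exists (it suppresses the step's band power by >98%).

**Imaging.** Normalizations are per sector over the full recording:
ΔF/F against the 5th percentile (ellipsoid body / fan-shaped body),
5th–95th percentile range scaling (bridge glomeruli, whose brightness
varies), z-scoring (noduli); degenerate sectors are rejected or
flagged. The compass phase in the bridge is the phase of the discrete
Fourier component with an 8-glomerulus wavelength across the 16
innervated glomeruli; ellipsoid-body/fan-shaped-body phases are
population vector averages with a 0.15 strength floor (negative
post-normalization values are clipped before the vector sum). Phase
nulling interpolates each bridge half to 1/10-glomerulus resolution
with a *periodic* cubic spline (each half is one 360° cycle), rotates
every frame by the EPG-determined shift rounded to the 4.5° fine grid
(the same rotation for both halves), and averages the selected frames.
The "peak" of a nulled profile is its PVA phase by default, with argmax
as the documented alternative — on noiseless data argmax recovers a
180° offset exactly, while the PVA phase of the baseline-subtracted
profile can deviate by a fraction of a fine step due to shift rounding.

**Tuning.** Heading curves: 36 × 10° half-open bins, samples gated on
forward speed > 0.5 mm/s, bins populated at ≥ 2 s occupancy; preferred
direction is the shift maximizing Pearson correlation with a cosine
(0.5° search grid, ties to the smallest |shift|). Airflow curves
average within-trial window means ([0.5, 2.5] s post-onset for
electrophysiology, [2, 4] s for noduli calcium). Conjunctive maps:
18 × 20° heading bins by the 12 exact protocol directions (216 cells),
per-sample concurrent heading, cells populated at ≥ 0.5 s; the
electrophysiology maps use the [0.5, 2.5] s puff core so the 1 s rate
kernel and 4 s spectral windows are not contaminated by puff edges.
Pooling across cells rotates each map by the nearest whole bin to
centre its preferred heading at 0°; the airflow-nulled variant mirrors
left-side maps about 0° and relabels the pooled axis by −45° (45° is
not a multiple of the 30° direction spacing, so the shift is a
relabelling, not a resampling).

## Model fitting

The Vm model is linear in (a0, aH, aW) and solved by least squares
(equal to the normal-equation oracle to machine precision). The two
rectified-square models use bounded multi-start nonlinear least squares
(9 starts over amplitude scales; tolerances 1e−14), with amplitudes
constrained nonnegative — a sign flip of the drive equals a 180° phase
shift, so the constraint only fixes the parameterization. Unpopulated
grid cells are excluded, never imputed. Reported r² is 1 − SSE/SST over
populated cells (a perfectly fitted flat map reports 1.0). Parameter
recovery at default map noise (Gaussian σ = 0.5 mV on Vm bins, Poisson
spike counts over 2 s occupancy per cell, gamma-multiplicative spectral
noise with 20% relative SD — realistic magnitudes for the full
pipeline's per-cell estimates) is within 10% (Vm, rate) / 15%
(oscillation) in ≥ 90 of 100 Monte-Carlo runs; error medians shrink
monotonically along a noise ladder. The quadratic input–output relation
fits a degree-2 polynomial to the summed min-max-scaled rate and power
curves against Vm minus the heading-curve minimum.

## Decoder

Each side's signed cosine amplitude at relative angle 0° (least-squares
cosine projection of the nulled profile) classifies the vector as
aligned (phase 0°) or inverted (phase 180°, magnitude multiplied by κ,
default 0.2, applied per component); side shifts of ∓45° are added and
the two phasors summed. The decoded relative angle is the phase of the
sum (argmax over the summed profile as alternative); adding the heading
gives the allocentric estimate of W + H. Decodes are flagged undefined
when both amplitudes vanish. On the default κ-matched experiment the
median circular error across the 12 directions is a few degrees
(≤ 15°); with κ = 0 the decoded angle never leaves the ±45° sector
spanned by the two aligned vectors and rear directions become
undecodable.

## Reproducibility

All generators are pure functions of (parameters, seed). The pipeline
derives per-stage substreams from one seed (SHA-256 of `seed:stage`,
reduced below 2³¹), records a configuration hash (excluding the output
directory) in every report, and writes byte-identical CSV/JSON outputs
for identical configurations. Problem sizes in the test suite — 3
imaging blocks for decode tests, 10 stepped-heading blocks for the
electrophysiology round trips, 100-run Monte-Carlo recovery at the map
level — were chosen to give stable statistics on a single CPU.

## Known limitations

- The imaging forward model is phenomenological (quadratic threshold
  deviations, single-exponential indicator); it is not a biophysical
  conductance model, and absolute fluorescence units are arbitrary.
- Bridge range-normalization assumes every glomerulus samples similar
  activity extremes over a recording; very short recordings violate
  this and distort profile amplitudes.
- The spectral estimator's 4 s windows limit conjunctive resolution
  when heading changes quickly; oscillation-model offsets (c0) absorb
  leakage from neighbouring epochs and are recovered less accurately
  than the modulation amplitudes on full time-series pipelines.
- The decoder assumes the nulled profiles are well approximated by
  single-cycle sinusoids; strongly multimodal profiles are reduced to
  their cosine component.
- Circular hypothesis tests (e.g. Watson–Williams) are out of scope and
  left to standard statistics packages.
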