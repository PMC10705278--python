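"""End-to-end orchestration: simulate -> process -> tune -> fit -> decode.

Every stage is a thin wrapper over the library modules; all randomness
derives from a single seed via per-stage substreams so stages can be
re-run in isolation. Outputs are CSV/JSON (plus one HDF5 container for
the raw synthetic recording); every run records its configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ephys as ep
from . import imaging as im
from . import io as pio
from . import modelfit as mf
from . import synth
from . import tuning as tu
from .circular import circ_mean, wrap_deg
from .decoder import DecoderConfig, decode_protocol
from .synth import GroundTruthParams, SyntheticDataset

__all__ = [
    "RunConfig",
    "run",
    "simulate_experiment",
    "process_imaging",
    "nulled_profiles_by_direction",
    "analyze_ephys_cell",
    "tube_transit_time",
]

log = logging.getLogger("pfnavec")

ALL_STAGES = ("simulate", "process-ephys", "process-imaging", "tune", "fit", "decode", "report")


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run.

    Defaults follow the experimental conventions baked into the library
    modules (40 ms median kernel, 150-1000 Hz spike band, 6.66 ms
    refractory, 1 s Hann rate window, 4 s / 20 ms spectrogram, 2-6 Hz
    band, 10 deg and 20x30 deg bins, 2 s / 0.5 s occupancy rules,
    0.5 mm/s speed gate, 5th/95th percentile normalization, 0.15 PVA
    floor, [0.5, 2.5] s and [2, 4] s airflow windows, kappa = 0.2).
    """

    seed: int = 0
    out_dir: str = "pfnavec_run"
    n_blocks: int = 3
    ephys_sides: tuple = ("left", "right")
    generator_overrides: dict = field(default_factory=dict)
    kappa: float = 0.2
    strength_floor: float = 0.15
    stages: tuple = ALL_STAGES

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31 - 1)


def tube_transit_time(length_m: float, speed_of_sound_m_s: float = 343.0) -> float:
    """Transit time (ms, to 0.1 ms) of a pressure pulse along a tube."""
    if length_m <= 0 or speed_of_sound_m_s <= 0:
        raise ValueError("length and speed of sound must be positive")
    return round(1000.0 * length_m / speed_of_sound_m_s, 1)


# ---------------------------------------------------------------------------
# stages


def simulate_experiment(config: RunConfig) -> SyntheticDataset:
    """Generate the full in-silico experiment for this configuration."""
    seed = config.stage_seed("simulate")
    trials = synth.make_protocol(config.n_blocks, seed)
    duration = trials[-1].offset_s + synth.INTER_PULSE_S
    behavior = synth.make_heading_trajectory(duration, seed=seed + 1)
    truths = synth.default_population(seed=seed, **config.generator_overrides)
    imaging = synth.simulate_imaging(truths, behavior, trials, seed=seed + 2)
    vm, spikes, ephys_truths = {}, {}, {}
    for i, side in enumerate(config.ephys_sides):
        p = GroundTruthParams(
            side=side, preferred_heading_deg=0.0, seed=seed + 10 + i,
            **config.generator_overrides,
        )
        name = f"{side}_cell"
        trace, st = synth.simulate_vm_trace(p, behavior, trials)
        vm[name], spikes[name], ephys_truths[name] = trace, st, p
    return SyntheticDataset(behavior, trials, vm, spikes, imaging, truths, ephys_truths)


def analyze_ephys_cell(trace, behavior, trials) -> dict:
    """Full single-cell electrophysiology analysis.

    Conditions the Vm, detects sodium spikes, computes the Hann-window
    spike rate and sliding 2-6 Hz power, then builds heading/airflow
    tuning curves and the three conjunctive maps (Vm, rate, power) in
    preferred-heading-relative coordinates.
    """
    cond = ep.condition_vm(trace)
    spikes = ep.detect_sodium_spikes(trace)
    rate = ep.spike_rate(spikes, cond.t)
    power = ep.band_power_2_6(trace)
    heading_curve = tu.heading_tuning(cond.t, cond.vm, behavior)
    pref = tu.preferred_heading(heading_curve)
    base = ep.baseline_vm(heading_curve)
    out = {
        "conditioned": cond,
        "spikes": spikes,
        "rate_trace": rate,
        "power_trace": power,
        "heading_curve": heading_curve,
        "preferred_heading_deg": pref,
        "baseline_vm": base,
        "airflow_curve": tu.airflow_tuning(cond.t, cond.vm, trials, window_s=(0.5, 2.5)),
    }
    # conjunctive maps centred on the preferred heading; the airflow
    # coordinate uses the core of each puff (the ephys analysis window)
    # so that the 1 s rate kernel and 4 s spectral windows are not
    # contaminated by puff onset/offset transients
    for key, (t_sig, sig) in {
        "vm": (cond.t, cond.vm),
        "rate": (cond.t, rate),
        "power": (power.t, power.band_power),
    }.items():
        raw = tu.conjunctive_map(t_sig, sig, behavior, trials, window_s=(0.5, 2.5))
        out[f"map_{key}"] = tu.pool_cells([raw], [pref], ["n/a"])
    return out


def process_imaging(imaging: dict, strength_floor: float = 0.15) -> dict:
    """Normalize matrices and extract bump-phase series.

    Bridge matrices are range-normalized per glomerulus, the ellipsoid
    body is dF/F-normalized, the noduli are z-scored. Returns the
    normalized matrices plus the EPG bridge phase and ellipsoid-body
    PVA phase series.
    """
    pfn = im.normalize(imaging["pfn_bridge"], "range")
    epg = im.normalize(imaging["epg_bridge"], "range")
    out = {
        "pfn_bridge": pfn,
        "epg_bridge": epg,
        "epg_phase": im.epg_phase_bridge(epg),
    }
    if "eb_epg" in imaging:
        eb = im.normalize(imaging["eb_epg"], "dff")
        out["eb_epg"] = eb
        out["eb_phase"] = im.pva_phase(eb, strength_floor=strength_floor)
    if "noduli" in imaging:
        out["noduli"] = im.normalize(imaging["noduli"], "zscore")
    return out


def nulled_profiles_by_direction(
    pfn_norm, epg_phase, trials, window_s=(0.5, None)
) -> dict:
    """Phase-nulled bridge profile pair for each airflow direction.

    Frames within each puff (optionally restricted by ``window_s``
    relative to onset) are pooled over that direction's trials before
    nulling, so dim single-frame bumps average into a clean profile.
    """
    t = pfn_norm.t
    out = {}
    for w in np.sort(tu.AIRFLOW_DIRECTIONS_DEG):
        sel = np.zeros(t.size, dtype=bool)
        for tr in trials:
            if not np.isclose(wrap_deg(tr.direction_deg), w):
                continue
            w0, w1 = window_s
            hi = tr.offset_s if w1 is None else tr.onset_s + w1
            sel |= (t >= tr.onset_s + w0) & (t < hi)
        if sel.any():
            out[float(w)] = im.phase_null(pfn_norm, epg_phase, frames=sel)
    return out


def _direction_headings(behavior, trials, epg_t) -> dict:
    """Circular-mean heading during each direction's puff frames."""
    heading = tu._interp_circular(epg_t, behavior.t, behavior.heading_deg)
    out = {}
    for w in np.sort(tu.AIRFLOW_DIRECTIONS_DEG):
        sel = np.zeros(epg_t.size, dtype=bool)
        for tr in trials:
            if np.isclose(wrap_deg(tr.direction_deg), w):
                sel |= (epg_t >= tr.onset_s) & (epg_t < tr.offset_s)
        if sel.any():
            mean, _, defined = circ_mean(heading[sel])
            out[float(w)] = mean if defined else 0.0
    return out


def run(config: RunConfig) -> dict:
    """Execute the selected stages; returns the report dictionary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": list(config.stages),
    }
    ds = None
    stage = None
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            ds = simulate_experiment(config)
            pio.save_dataset(out_dir / "dataset.h5", ds)
            pio.trials_to_frame(ds.trials).to_csv(out_dir / "trials.csv", index=False)
            log.info("simulate: %d trials, %d imaging cells", len(ds.trials), len(ds.truths))
        else:
            ds = pio.load_dataset(out_dir / "dataset.h5")

        cell_results = {}
        if "process-ephys" in config.stages or "tune" in config.stages or "fit" in config.stages:
            stage = "process-ephys"
            for name, trace in ds.vm.items():
                res = analyze_ephys_cell(trace, ds.behavior, ds.trials)
                cell_results[name] = res
                pd.DataFrame({"spike_time_s": res["spikes"].spike_times}).to_csv(
                    out_dir / f"{name}_spikes.csv", index=False
                )
                pio.curve_to_frame(res["heading_curve"]).to_csv(
                    out_dir / f"{name}_heading_curve.csv", index=False
                )

        if "tune" in config.stages:
            stage = "tune"
            for name, res in cell_results.items():
                for key in ("vm", "rate", "power"):
                    pio.map_to_frame(res[f"map_{key}"]).to_csv(
                        out_dir / f"{name}_map_{key}.csv", index=False
                    )

        if "fit" in config.stages:
            stage = "fit"
            fits = {}
            for name, res in cell_results.items():
                side = ds.ephys_truths[name].side if name in ds.ephys_truths else "right"
                entry = {}
                try:
                    entry["vm"] = dataclasses.asdict(mf.fit_vm(res["map_vm"], side))
                    entry["rate"] = dataclasses.asdict(mf.fit_rate(res["map_rate"], side))
                    entry["power"] = dataclasses.asdict(mf.fit_osc(res["map_power"], side))
                except (ValueError, RuntimeError) as exc:
                    entry["error"] = str(exc)
                truth = ds.ephys_truths.get(name)
                if truth is not None:
                    entry["truth"] = {
                        k: getattr(truth, k)
                        for k in ("a0", "aH", "aW", "bH", "bW", "c0", "cH", "cW")
                    }
                fits[name] = entry
            report["fits"] = fits
            pio.dump_json(out_dir / "fits.json", fits)

        if "process-imaging" in config.stages or "decode" in config.stages:
            stage = "process-imaging"
            proc = process_imaging(ds.imaging, strength_floor=config.strength_floor)

        if "decode" in config.stages:
            stage = "decode"
            profiles = nulled_profiles_by_direction(
                proc["pfn_bridge"], proc["epg_phase"], ds.trials
            )
            headings = _direction_headings(ds.behavior, ds.trials, proc["epg_phase"].t)
            table = decode_protocol(
                profiles, headings, DecoderConfig(kappa=config.kappa)
            )
            table.to_csv(out_dir / "decode.csv", index=False)
            errs = table["circular_error_deg"].abs()
            report["decode_median_abs_error_deg"] = float(np.nanmedian(errs))

        if "report" in config.stages:
            stage = "report"
            pio.dump_json(out_dir / "report.json", report)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report
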