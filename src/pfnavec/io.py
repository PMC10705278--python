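"""File I/O: HDF5 dataset container, CSV tables, YAML configuration.

Layout of the HDF5 container written by :func:`save_dataset`::

    /behavior/{t, heading_deg, forward_speed}
    /trials/{direction_deg, onset_s, duration_s, block_index}
    /ephys/<cell>/{t, vm}            (+ attrs fs)
    /ephys/<cell>/true_spike_times
    /imaging/<structure>/{t, F}      (+ attrs structure)
    /truth/<cell i>                  (attrs = generative parameters)

Angles are degrees, times seconds, Vm millivolts throughout.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
import pandas as pd
import yaml

from .circular import BRIDGE18, EB16, FB16, NODULI2
from .ephys import EphysTrace
from .imaging import SectorMatrix
from .synth import BehaviorTrace, GroundTruthParams, ProtocolTrial, SyntheticDataset
from .tuning import ConjunctiveMap, TuningCurve1D

__all__ = [
    "save_dataset",
    "load_dataset",
    "trials_to_frame",
    "curve_to_frame",
    "map_to_frame",
    "load_yaml_config",
    "dump_json",
]

_GEOMETRIES = {g.structure: g for g in (BRIDGE18, EB16, FB16, NODULI2)}


def trials_to_frame(trials) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "direction_deg": [tr.direction_deg for tr in trials],
            "onset_s": [tr.onset_s for tr in trials],
            "duration_s": [tr.duration_s for tr in trials],
            "block_index": [tr.block_index for tr in trials],
        }
    )


def _frame_to_trials(df: pd.DataFrame):
    return [
        ProtocolTrial(
            float(r.direction_deg),
            float(r.onset_s),
            float(r.duration_s),
            int(r.block_index),
        )
        for r in df.itertuples()
    ]


def save_dataset(path, ds: SyntheticDataset) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("behavior")
        g.create_dataset("t", data=ds.behavior.t)
        g.create_dataset("heading_deg", data=ds.behavior.heading_deg)
        g.create_dataset("forward_speed", data=ds.behavior.forward_speed)
        tf = trials_to_frame(ds.trials)
        g = f.create_group("trials")
        for col in tf.columns:
            g.create_dataset(col, data=tf[col].to_numpy())
        g = f.create_group("ephys")
        for name, trace in ds.vm.items():
            cg = g.create_group(name)
            cg.create_dataset("t", data=trace.t)
            cg.create_dataset("vm", data=trace.vm)
            cg.attrs["fs"] = trace.fs
            if name in ds.true_spikes:
                cg.create_dataset("true_spike_times", data=ds.true_spikes[name])
        g = f.create_group("imaging")
        for name, mat in ds.imaging.items():
            mg = g.create_group(name)
            mg.create_dataset("t", data=mat.t)
            mg.create_dataset("F", data=mat.F)
            mg.attrs["structure"] = mat.geometry.structure
        g = f.create_group("truth")
        for i, p in enumerate(ds.truths):
            tg = g.create_group(f"cell{i:02d}")
            for k, v in dataclasses.asdict(p).items():
                tg.attrs[k] = v
        for name, p in ds.ephys_truths.items():
            tg = g.create_group(f"ephys_{name}")
            for k, v in dataclasses.asdict(p).items():
                tg.attrs[k] = v


def load_dataset(path) -> SyntheticDataset:
    with h5py.File(path, "r") as f:
        behavior = BehaviorTrace(
            f["behavior/t"][:],
            f["behavior/heading_deg"][:],
            f["behavior/forward_speed"][:],
        )
        trials = _frame_to_trials(
            pd.DataFrame({k: f["trials"][k][:] for k in f["trials"]})
        )
        vm, spikes = {}, {}
        for name, cg in f["ephys"].items():
            vm[name] = EphysTrace(
                cg["t"][:], cg["vm"][:], float(cg.attrs["fs"]), trials=trials
            )
            if "true_spike_times" in cg:
                spikes[name] = cg["true_spike_times"][:]
        imaging = {}
        for name, mg in f["imaging"].items():
            geom = _GEOMETRIES[mg.attrs["structure"]]
            imaging[name] = SectorMatrix(geom, mg["t"][:], mg["F"][:])
        truths, ephys_truths = [], {}
        for name in sorted(f["truth"]):
            attrs = dict(f["truth"][name].attrs)
            attrs["side"] = str(attrs["side"])
            attrs["rear_spike_deficit"] = bool(attrs["rear_spike_deficit"])
            attrs["seed"] = int(attrs["seed"])
            p = GroundTruthParams(**attrs)
            if name.startswith("ephys_"):
                ephys_truths[name[len("ephys_"):]] = p
            else:
                truths.append(p)
    return SyntheticDataset(behavior, trials, vm, spikes, imaging, truths, ephys_truths)


def curve_to_frame(curve: TuningCurve1D) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_center_deg": curve.bin_centers_deg,
            "mean": curve.means,
            "occupancy_s": curve.occupancy_s,
            "populated": curve.populated,
        }
    )


def map_to_frame(m: ConjunctiveMap) -> pd.DataFrame:
    """Tidy (heading, airflow, mean, occupancy, populated) table."""
    Hg, Wg = np.meshgrid(
        m.heading_centers_deg, m.airflow_directions_deg, indexing="ij"
    )
    return pd.DataFrame(
        {
            "heading_deg": Hg.ravel(),
            "airflow_deg": Wg.ravel(),
            "mean": m.means.ravel(),
            "occupancy_s": m.occupancy_s.ravel(),
            "populated": m.populated.ravel(),
        }
    )


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
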