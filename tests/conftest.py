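"""Shared synthetic-experiment fixtures.

The fixtures are session-scoped because they generate full in-silico
recordings (minutes of 10 kHz Vm or multi-structure imaging) that
several test modules analyse from different angles.
"""

import numpy as np
import pytest

from pfnavec import pipeline as pl
from pfnavec import synth


@pytest.fixture(scope="session")
def imaging_experiment():
    """Default imaging experiment: 3 blocks, 8+8 cells, default noise."""
    trials = synth.make_protocol(3, seed=101)
    duration = trials[-1].offset_s + synth.INTER_PULSE_S
    behavior = synth.make_heading_trajectory(duration, seed=102)
    truths = synth.default_population(seed=103)
    imaging = synth.simulate_imaging(truths, behavior, trials, seed=104)
    return {
        "trials": trials,
        "behavior": behavior,
        "truths": truths,
        "imaging": imaging,
    }


@pytest.fixture(scope="session")
def imaging_processed(imaging_experiment):
    """Normalized matrices, EPG phase, and per-direction nulled profiles."""
    proc = pl.process_imaging(imaging_experiment["imaging"])
    profiles = pl.nulled_profiles_by_direction(
        proc["pfn_bridge"], proc["epg_phase"], imaging_experiment["trials"]
    )
    return {**proc, "profiles": profiles}


@pytest.fixture(scope="session")
def ephys_roundtrip():
    """Controlled-sweep electrophysiology recording plus full analysis.

    10 protocol blocks with a stepped heading (constant within each
    9 s trial) give clean conditional estimates for validating the
    estimator round trips against the generative model.
    """
    truth = synth.GroundTruthParams(side="right", seed=111)
    trials = synth.make_protocol(10, seed=112)
    duration = trials[-1].offset_s + synth.INTER_PULSE_S
    # start at 10 deg so dwell headings sit on 20 deg conjunctive-bin centres
    behavior = synth.make_stepped_heading(duration, dwell_s=9.0, step_deg=140.0, start_deg=10.0)
    trace, true_spikes = synth.simulate_vm_trace(truth, behavior, trials)
    analysis = pl.analyze_ephys_cell(trace, behavior, trials)
    return {
        "truth": truth,
        "trials": trials,
        "behavior": behavior,
        "trace": trace,
        "true_spikes": true_spikes,
        "analysis": analysis,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
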