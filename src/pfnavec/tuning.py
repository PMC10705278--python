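"""Tuning-curve construction with occupancy and behavioural gating.

One-dimensional heading tuning uses 36 bins of 10 deg with a 2 s
occupancy rule and a forward-speed gate (> 0.5 mm/s). Airflow tuning is
trial-based over the 12 puff directions. Conjunctive (heading x airflow)
maps use an 18 x 12 grid (20 deg heading bins by the 12 protocol
directions) with a 0.5 s occupancy rule per cell of the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .circular import wrap_deg

__all__ = [
    "TuningCurve1D",
    "ConjunctiveMap",
    "HEADING_BIN_DEG",
    "CONJ_HEADING_BIN_DEG",
    "AIRFLOW_DIRECTIONS_DEG",
    "heading_bin_centers",
    "heading_tuning",
    "preferred_heading",
    "airflow_tuning",
    "conjunctive_map",
    "pool_cells",
]

HEADING_BIN_DEG = 10.0
CONJ_HEADING_BIN_DEG = 20.0
SPEED_GATE_MM_S = 0.5
MIN_OCCUPANCY_1D_S = 2.0
MIN_OCCUPANCY_CONJ_S = 0.5

#: The 12 protocol airflow directions (30 deg spacing) in wrap order.
AIRFLOW_DIRECTIONS_DEG = wrap_deg(np.arange(12) * 30.0)
_AIRFLOW_SORTED = np.sort(AIRFLOW_DIRECTIONS_DEG)


@dataclass
class TuningCurve1D:
    """Binned circular tuning curve with per-bin occupancy bookkeeping."""

    bin_centers_deg: np.ndarray
    means: np.ndarray
    occupancy_s: np.ndarray
    populated: np.ndarray  # bool per bin

    def populated_values(self):
        return self.bin_centers_deg[self.populated], self.means[self.populated]


@dataclass
class ConjunctiveMap:
    """18 heading-bins x 12 airflow-direction grid of a response variable."""

    heading_centers_deg: np.ndarray  # (18,)
    airflow_directions_deg: np.ndarray  # (12,)
    means: np.ndarray  # (18, 12), NaN where unpopulated
    occupancy_s: np.ndarray  # (18, 12)
    populated: np.ndarray  # (18, 12) bool

    @property
    def n_cells(self) -> int:
        return self.means.size


def heading_bin_centers(bin_deg: float = HEADING_BIN_DEG) -> np.ndarray:
    n = int(round(360.0 / bin_deg))
    return wrap_deg(-180.0 + (np.arange(n) + 0.5) * bin_deg)


def _heading_bin_index(heading_deg, bin_deg):
    """Index of the half-open bin [center - w/2, center + w/2) holding each angle."""
    h = np.asarray(wrap_deg(heading_deg), dtype=float)
    idx = np.floor((h + 180.0) / bin_deg).astype(int)
    n = int(round(360.0 / bin_deg))
    return np.clip(idx, 0, n - 1)


def _interp_circular(t_out, t_in, angle_deg):
    """Linear interpolation of a wrapped angle series via unwrapping."""
    unwrapped = np.rad2deg(np.unwrap(np.deg2rad(angle_deg)))
    return wrap_deg(np.interp(t_out, t_in, unwrapped))


def heading_tuning(
    t,
    signal,
    behavior,
    bin_deg: float = HEADING_BIN_DEG,
    min_occupancy_s: float = MIN_OCCUPANCY_1D_S,
    speed_gate_mm_s: float = SPEED_GATE_MM_S,
) -> TuningCurve1D:
    """Mean of ``signal`` in heading bins, gated on forward speed.

    ``t``/``signal`` may be on any uniform clock; heading and speed are
    interpolated from the behaviour trace onto it. Samples where the fly
    is standing (forward speed <= gate) are excluded, and bins with less
    than ``min_occupancy_s`` of gated data are flagged unpopulated.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.shape != y.shape:
        raise ValueError("t and signal must have the same shape")
    dt = float(np.median(np.diff(t))) if t.size > 1 else 0.0
    heading = _interp_circular(t, behavior.t, behavior.heading_deg)
    speed = np.interp(t, behavior.t, behavior.forward_speed)
    moving = speed > speed_gate_mm_s
    centers = heading_bin_centers(bin_deg)
    n = centers.size
    means = np.full(n, np.nan)
    occ = np.zeros(n)
    idx = _heading_bin_index(heading[moving], bin_deg)
    ymov = y[moving]
    for b in range(n):
        sel = idx == b
        occ[b] = sel.sum() * dt
        if sel.any():
            means[b] = ymov[sel].mean()
    populated = occ >= min_occupancy_s
    means[~populated] = np.nan
    return TuningCurve1D(centers, means, occ, populated)


def preferred_heading(curve: TuningCurve1D, step_deg: float = 0.5) -> float:
    """Angular shift maximizing Pearson correlation with a cosine.

    The preferred direction is the shift ``phi`` for which
    ``cos(theta - phi)`` best correlates with the populated bin means.
    Ties are broken in favour of the smallest ``|phi|``.
    """
    th, vals = curve.populated_values()
    if th.size < 3:
        raise ValueError("preferred_heading needs at least 3 populated bins")
    if np.ptp(vals) == 0:
        raise ValueError("degenerate (constant) tuning curve")
    shifts = wrap_deg(np.arange(0.0, 360.0, step_deg))
    v = vals - vals.mean()
    v_norm = np.linalg.norm(v)
    th_rad = np.deg2rad(th)
    best_r, best_shift = -np.inf, 0.0
    # sort candidate shifts by |shift| so the first maximum wins ties
    for phi in shifts[np.argsort(np.abs(shifts), kind="stable")]:
        c = np.cos(th_rad - np.deg2rad(phi))
        c = c - c.mean()
        denom = v_norm * np.linalg.norm(c)
        if denom == 0:
            continue
        r = float(np.dot(v, c) / denom)
        if r > best_r + 1e-12:
            best_r, best_shift = r, float(phi)
    return wrap_deg(best_shift)


def airflow_tuning(
    t,
    signal,
    trials,
    window_s=(0.5, 2.5),
) -> TuningCurve1D:
    """Per-direction mean over trials of the within-window signal mean.

    ``window_s`` is (start, end) relative to puff onset: (0.5, 2.5) for
    electrophysiology-derived signals, (2.0, 4.0) for noduli calcium.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(signal, dtype=float)
    w0, w1 = window_s
    dirs = _AIRFLOW_SORTED.copy()
    per_dir = {d: [] for d in dirs}
    occ = {d: 0.0 for d in dirs}
    for tr in trials:
        sel = (t >= tr.onset_s + w0) & (t < tr.onset_s + w1)
        if sel.any():
            d = wrap_deg(tr.direction_deg)
            per_dir[d].append(float(y[sel].mean()))
            occ[d] += float(sel.sum()) * float(np.median(np.diff(t)))
    means = np.array([np.mean(per_dir[d]) if per_dir[d] else np.nan for d in dirs])
    occupancy = np.array([occ[d] for d in dirs])
    populated = np.array([len(per_dir[d]) > 0 for d in dirs])
    return TuningCurve1D(dirs, means, occupancy, populated)


def conjunctive_map(
    t,
    signal,
    behavior,
    trials,
    min_occupancy_s: float = MIN_OCCUPANCY_CONJ_S,
    window_s=(0.0, None),
) -> ConjunctiveMap:
    """Grid of within-puff signal means over 18 heading x 12 airflow bins.

    Heading is the concurrent (per-sample) behavioural heading; the
    airflow coordinate is the direction of the ongoing puff. Grid cells
    with less than ``min_occupancy_s`` of data are unpopulated.
    ``window_s`` restricts the within-trial analysis window
    ((0, None) = the whole puff).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(signal, dtype=float)
    dt = float(np.median(np.diff(t)))
    heading = _interp_circular(t, behavior.t, behavior.heading_deg)
    h_centers = heading_bin_centers(CONJ_HEADING_BIN_DEG)
    dirs = _AIRFLOW_SORTED.copy()
    sums = np.zeros((h_centers.size, dirs.size))
    counts = np.zeros_like(sums)
    w0, w1 = window_s
    for tr in trials:
        hi = tr.onset_s + (tr.duration_s if w1 is None else w1)
        sel = (t >= tr.onset_s + w0) & (t < hi)
        if not sel.any():
            continue
        j = int(np.searchsorted(dirs, wrap_deg(tr.direction_deg)))
        hb = _heading_bin_index(heading[sel], CONJ_HEADING_BIN_DEG)
        np.add.at(sums[:, j], hb, y[sel])
        np.add.at(counts[:, j], hb, 1.0)
    occupancy = counts * dt
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    populated = occupancy >= min_occupancy_s
    means[~populated] = np.nan
    return ConjunctiveMap(h_centers, dirs, means, occupancy, populated)


def _roll_heading_axis(m: ConjunctiveMap, shift_bins: int) -> ConjunctiveMap:
    return ConjunctiveMap(
        m.heading_centers_deg,
        m.airflow_directions_deg,
        np.roll(m.means, shift_bins, axis=0),
        np.roll(m.occupancy_s, shift_bins, axis=0),
        np.roll(m.populated, shift_bins, axis=0),
    )


def pool_cells(
    maps,
    preferred_deg,
    sides,
    null_airflow: bool = False,
):
    """Average conjunctive maps across cells in heading-nulled coordinates.

    Each cell's map is rotated along the heading axis so its preferred
    heading sits at the 0 deg bin (shift rounded to whole 20 deg bins).
    With ``null_airflow`` the maps of left-bridge cells are mirrored
    about 0 deg airflow first, and the pooled map's airflow axis is
    relabelled by a -45 deg shift so the common airflow peak reads 0.
    Unpopulated cells are ignored in the average.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("pool_cells requires at least one map")
    h_centers = maps[0].heading_centers_deg
    dirs = maps[0].airflow_directions_deg
    stack, occ_stack = [], []
    for m, pref, side in zip(maps, preferred_deg, sides):
        shift = -int(np.round(wrap_deg(pref) / CONJ_HEADING_BIN_DEG))
        r = _roll_heading_axis(m, shift)
        means, occ = r.means.copy(), r.occupancy_s.copy()
        if null_airflow and side == "left":
            # mirror about 0 deg airflow: direction d -> -d
            order = np.array(
                [int(np.searchsorted(dirs, wrap_deg(-d))) for d in dirs]
            )
            means, occ = means[:, order], occ[:, order]
        stack.append(means)
        occ_stack.append(occ)
    stack = np.array(stack)
    occ = np.array(occ_stack).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        pooled = np.nanmean(stack, axis=0)  # all-NaN cells stay NaN
    populated = ~np.isnan(pooled)
    out_dirs = wrap_deg(dirs - 45.0) if null_airflow else dirs
    return ConjunctiveMap(h_centers, out_dirs, pooled, occ, populated)
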