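"""Calcium-imaging processing for sector-resolved fluorescence matrices.

Covers the standard normalizations (dF/F, range, z-score), heading-bump
phase extraction (Fourier phase across the bridge for compass neurons,
population vector average for ellipsoid body / fan-shaped body), phase
nulling of bridge profiles into heading-relative coordinates, and
circular phase-offset statistics between two bump-phase series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .circular import (
    EPG_COLS,
    PFN_LEFT_COLS,
    PFN_RIGHT_COLS,
    SectorGeometry,
    circ_diff,
    circ_mean,
    pva,
    wrap_deg,
)

__all__ = [
    "SectorMatrix",
    "PhaseSeries",
    "NulledProfiles",
    "OffsetStats",
    "normalize",
    "epg_phase_bridge",
    "pva_phase",
    "phase_null",
    "profile_peak",
    "phase_offset_stats",
]

PVA_STRENGTH_FLOOR = 0.15
FINE_STEPS_PER_SECTOR = 10  # interpolate to 1/10 glomerulus resolution
DEG_PER_GLOMERULUS = 45.0


@dataclass
class SectorMatrix:
    """Frames x sectors fluorescence matrix for one structure."""

    geometry: SectorGeometry
    t: np.ndarray
    F: np.ndarray
    normalization_state: str = "raw"
    bad_sectors: tuple = ()

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (self.t.size, self.geometry.n_sectors):
            raise ValueError("F must be (n_frames, n_sectors)")
        if self.normalization_state == "raw" and np.nanmin(self.F) < 0:
            raise ValueError("raw fluorescence must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.t.size


@dataclass
class PhaseSeries:
    """Per-frame bump phase with PVA strength and validity flags."""

    t: np.ndarray
    phase_deg: np.ndarray
    strength: np.ndarray
    valid: np.ndarray


@dataclass
class NulledProfiles:
    """Frame-averaged bridge profiles in EPG-relative coordinates.

    ``rel_angle_deg[j]`` is the angle relative to the EPG (heading) bump
    peak, which sits at index 0; profiles are per bridge side.
    """

    rel_angle_deg: np.ndarray
    left: np.ndarray
    right: np.ndarray
    n_frames: int


@dataclass
class OffsetStats:
    """Circular summary of a phase-offset distribution."""

    offsets_deg: np.ndarray
    mean_offset_deg: float
    resultant: float
    mean_defined: bool
    hist_centers_deg: np.ndarray
    density_per_deg: np.ndarray
    frontal_mean_density: float


def normalize(matrix: SectorMatrix, method: str, strict: bool = True) -> SectorMatrix:
    """Per-sector normalization over the full recording.

    dff
        (F - F5) / F5 with F5 the 5th percentile of the sector.
    range
        (F - F5) / (F95 - F5), the convention for bridge glomeruli whose
        brightness varies with expression level.
    zscore
        (F - mean) / SD per sector (used for the noduli).

    Sectors with a degenerate denominator are rejected (strict) or
    flagged in ``bad_sectors`` with NaN output.
    """
    if matrix.normalization_state != "raw":
        raise ValueError("normalize expects a raw matrix")
    F = matrix.F
    if method == "dff":
        f5 = np.percentile(F, 5, axis=0)
        denom, offset = f5, f5
    elif method == "range":
        f5 = np.percentile(F, 5, axis=0)
        f95 = np.percentile(F, 95, axis=0)
        denom, offset = f95 - f5, f5
    elif method == "zscore":
        denom, offset = F.std(axis=0), F.mean(axis=0)
    else:
        raise ValueError(f"unknown normalization {method!r}")
    bad = np.abs(denom) < 1e-12
    if bad.any() and strict:
        raise ValueError(
            f"degenerate sectors for {method}: {np.flatnonzero(bad).tolist()}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (F - offset) / denom
    out[:, bad] = np.nan
    return SectorMatrix(
        matrix.geometry,
        matrix.t,
        out,
        normalization_state=method,
        bad_sectors=tuple(np.flatnonzero(bad).tolist()),
    )


def _epg16(matrix: SectorMatrix) -> np.ndarray:
    if matrix.geometry.n_sectors == 18:
        return matrix.F[:, list(EPG_COLS)]
    if matrix.geometry.n_sectors == 16:
        return matrix.F
    raise ValueError("EPG bridge matrix must have 16 or 18 sectors")


def epg_phase_bridge(matrix: SectorMatrix) -> PhaseSeries:
    """Heading phase from the period-8 Fourier component across the bridge.

    The two copies of the compass bump sit 8 glomeruli apart, so the
    discrete Fourier component with a wavelength of 8 glomeruli across
    the 16 innervated glomeruli carries the shared heading estimate.
    An 18-sector matrix is restricted to the 16 EPG glomeruli first.
    """
    F = _epg16(matrix)
    j = np.arange(16)
    basis = np.exp(-1j * 2.0 * np.pi * j / 8.0)
    C = F @ basis
    total = np.abs(F).sum(axis=1)
    valid = total > 0
    strength = np.zeros(F.shape[0])
    strength[valid] = np.abs(C[valid]) / total[valid]
    phase = np.full(F.shape[0], np.nan)
    # each glomerulus spans 45 deg; basis angle theta_j = j * 45 deg
    phase[valid] = wrap_deg(-np.rad2deg(np.angle(C[valid])))
    valid = valid & (np.abs(C) > 1e-12)
    phase[~valid] = np.nan
    return PhaseSeries(matrix.t, phase, strength, valid)


def pva_phase(
    matrix: SectorMatrix, strength_floor: float = PVA_STRENGTH_FLOOR
) -> PhaseSeries:
    """Per-frame population vector average for eb16/fb16 matrices.

    Negative (post-normalization) values are clipped at zero before the
    vector average; frames whose PVA strength falls below the floor are
    flagged invalid.
    """
    if matrix.geometry.structure not in ("eb16", "fb16"):
        raise ValueError("pva_phase expects an eb16 or fb16 matrix")
    n = matrix.n_frames
    phase = np.full(n, np.nan)
    strength = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        profile = np.clip(matrix.F[i], 0.0, None)
        ph = pva(profile, matrix.geometry)
        strength[i] = ph.strength
        if ph.defined and ph.strength >= strength_floor:
            phase[i] = ph.phase_deg
            valid[i] = True
    return PhaseSeries(matrix.t, phase, strength, valid)


def _fine_profile(half: np.ndarray) -> np.ndarray:
    """Periodic cubic-spline upsampling of an 8-glomerulus half profile.

    Each bridge half covers one full 360 deg cycle (45 deg/glomerulus);
    output has 80 samples (1/10 glomerulus = 4.5 deg resolution).
    """
    n = half.shape[-1]
    x = np.arange(n + 1, dtype=float)
    y = np.concatenate([half, half[..., :1]], axis=-1)
    cs = CubicSpline(x, y, axis=-1, bc_type="periodic")
    xf = np.arange(0, n, 1.0 / FINE_STEPS_PER_SECTOR)
    return cs(xf)


def phase_null(
    pfn_matrix: SectorMatrix,
    epg_phase: PhaseSeries,
    frames=None,
) -> NulledProfiles:
    """Rotate bridge-half profiles into EPG-relative coordinates and average.

    Each half (8 innervated glomeruli) is spline-interpolated to 1/10
    glomerulus resolution and circularly rotated, per frame, by the
    EPG-determined shift so the heading bump peak sits at relative
    angle 0. Frames with an undefined EPG phase are excluded; ``frames``
    optionally restricts the average further (boolean mask).
    """
    if pfn_matrix.geometry.n_sectors != 18:
        raise ValueError("phase_null expects an 18-glomerulus bridge matrix")
    if pfn_matrix.t.shape != epg_phase.t.shape or not np.allclose(
        pfn_matrix.t, epg_phase.t
    ):
        raise ValueError("PFN matrix and EPG phase must share one clock")
    sel = epg_phase.valid.copy()
    if frames is not None:
        sel &= np.asarray(frames, dtype=bool)
    if not sel.any():
        raise ValueError("no frames with a defined EPG phase selected")
    deg_per_step = DEG_PER_GLOMERULUS / FINE_STEPS_PER_SECTOR
    n_fine = 8 * FINE_STEPS_PER_SECTOR
    halves = {
        "left": pfn_matrix.F[:, list(PFN_LEFT_COLS)],
        "right": pfn_matrix.F[:, list(PFN_RIGHT_COLS)],
    }
    out = {}
    idx = np.flatnonzero(sel)
    shifts = np.round(epg_phase.phase_deg[idx] / deg_per_step).astype(int) % n_fine
    for name, half in halves.items():
        fine = _fine_profile(half[idx])
        rows = np.arange(idx.size)[:, None]
        cols = (np.arange(n_fine)[None, :] + shifts[:, None]) % n_fine
        out[name] = fine[rows, cols].mean(axis=0)
    rel = wrap_deg(np.arange(n_fine) * deg_per_step)
    return NulledProfiles(rel, out["left"], out["right"], int(idx.size))


def profile_peak(profile, rel_angle_deg, method: str = "pva") -> float:
    """Peak location of a nulled profile, as PVA phase (default) or argmax."""
    p = np.asarray(profile, dtype=float)
    ang = np.asarray(rel_angle_deg, dtype=float)
    if method == "argmax":
        return float(ang[int(np.argmax(p))])
    if method == "pva":
        w = np.clip(p - p.min(), 0.0, None)
        mean, _, defined = circ_mean(ang, w)
        if not defined:
            raise ValueError("profile has no defined peak")
        return mean
    raise ValueError(f"unknown peak method {method!r}")


def phase_offset_stats(
    phase_a: PhaseSeries,
    phase_b: PhaseSeries,
    window=None,
    bin_deg: float = 10.0,
) -> OffsetStats:
    """Circular statistics of the per-frame offset ``phase_a - phase_b``.

    Returns the circular-mean offset over the selected frames, plus a
    histogram density (per degree, integrating to 1 over 360 deg) and
    its mean within +/-10 deg of 0 ("frontal" density).
    """
    if phase_a.t.shape != phase_b.t.shape or not np.allclose(phase_a.t, phase_b.t):
        raise ValueError("phase series must share one clock")
    sel = phase_a.valid & phase_b.valid
    if window is not None:
        sel &= np.asarray(window, dtype=bool)
    if not sel.any():
        raise ValueError("empty frame selection")
    offsets = circ_diff(phase_a.phase_deg[sel], phase_b.phase_deg[sel])
    offsets = np.atleast_1d(offsets)
    mean, resultant, defined = circ_mean(offsets)
    nbins = int(round(360.0 / bin_deg))
    # bins [c - w/2, c + w/2) with centres at multiples of bin_deg
    edges = -180.0 - bin_deg / 2.0 + np.arange(nbins + 1) * bin_deg
    shifted = np.where(offsets > 180.0 - bin_deg / 2.0, offsets - 360.0, offsets)
    counts, _ = np.histogram(shifted, bins=edges)
    centers = wrap_deg(edges[:-1] + bin_deg / 2.0)
    density = counts / (offsets.size * bin_deg)
    frontal = np.abs(wrap_deg(centers)) <= 10.0 + 1e-9
    return OffsetStats(
        offsets_deg=offsets,
        mean_offset_deg=mean,
        resultant=resultant,
        mean_defined=defined,
        hist_centers_deg=centers,
        density_per_deg=density,
        frontal_mean_density=float(density[frontal].mean()),
    )
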