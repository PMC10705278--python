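"""Angle conventions, circular statistics and phasor extraction.

All public interfaces work in degrees. Angles live in the half-open
interval ``(-180, 180]`` with 0 = directly in front of the fly,
180 = directly behind, negative angles to the fly's left and positive
to its right. Sinusoidal population profiles across the sectors of a
central-complex structure are summarised as phasors: an amplitude
(vector length) and a phase (vector angle), plus a normalized resultant
length ("PVA strength") used to flag frames where no bump is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Phasor",
    "SectorGeometry",
    "BRIDGE18",
    "EB16",
    "FB16",
    "NODULI2",
    "wrap_deg",
    "circ_mean",
    "circ_diff",
    "pva",
    "cosine_projection",
]

#: Resultant lengths below this are treated as an undefined circular mean.
RESULTANT_TOL = 1e-9


def wrap_deg(x):
    """Wrap angle(s) in degrees into the interval ``(-180, 180]``.

    180 is preferred over -180 so that every equivalence class has a
    single representative. Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("wrap_deg requires finite input")
    w = np.mod(x, 360.0)
    w = np.where(w > 180.0, w - 360.0, w)
    # mod can return -0.0/360.0-eps edge values; map exact -180 to 180
    w = np.where(w == -180.0, 180.0, w)
    if w.ndim == 0:
        return float(w)
    return w


@dataclass(frozen=True)
class Phasor:
    """Amplitude + angle summary of a sinusoidal population profile.

    amplitude
        Half peak-to-trough of the best-fit single-cycle sinusoid, in
        the units of the underlying signal.
    phase_deg
        Angle of the population vector average, degrees in (-180, 180].
        Meaningless when ``defined`` is False.
    strength
        Normalized resultant length in [0, 1].
    defined
        False when the profile carries no directional information
        (all-zero profile or vanishing resultant).
    """

    amplitude: float
    phase_deg: float
    strength: float
    defined: bool = True


@dataclass(frozen=True)
class SectorGeometry:
    """Mapping from sector index to angular position for one structure."""

    structure: str
    n_sectors: int
    sector_center_deg: tuple = field(repr=False)

    def __post_init__(self):
        if len(self.sector_center_deg) != self.n_sectors:
            raise ValueError("sector_center_deg length must equal n_sectors")

    @property
    def centers(self) -> np.ndarray:
        return np.asarray(self.sector_center_deg, dtype=float)


def _half_cycle_centers(n: int) -> tuple:
    # one full 360 deg cycle over n sectors, sector 0 centred at 0 deg
    return tuple(wrap_deg(np.arange(n) * (360.0 / n)).tolist())


#: Protocerebral bridge: 18 glomeruli, 9 per hemisphere, indexed left to
#: right when viewed from posterior. Each hemisphere's 8 PFN-innervated
#: glomeruli cover one full 360 deg cycle at 45 deg per glomerulus.
BRIDGE18 = SectorGeometry(
    "bridge18",
    18,
    tuple(wrap_deg(np.concatenate([np.arange(9), np.arange(9)]) * 45.0).tolist()),
)

#: Ellipsoid body: 16 wedges of 22.5 deg. Wedges 1 and 16 (indices 0 and
#: 15) flank the ventral bisector, which maps to the rear (180 deg).
EB16 = SectorGeometry(
    "eb16",
    16,
    tuple(wrap_deg(-180.0 + (np.arange(16) + 0.5) * 22.5).tolist()),
)

#: Fan-shaped body: 16 columns, column 1 leftmost viewed from posterior;
#: column k corresponds functionally to ellipsoid-body wedge k.
FB16 = SectorGeometry("fb16", 16, EB16.sector_center_deg)

#: Noduli: two sides (left, right); no angular interpretation.
NODULI2 = SectorGeometry("noduli2", 2, (0.0, 0.0))

# Bridge innervation conventions (0-based column indices into the
# 18-glomerulus matrix): PFN cells skip the medial-most pair, EPG cells
# skip the lateral-most pair.
PFN_LEFT_COLS = tuple(range(0, 8))
PFN_RIGHT_COLS = tuple(range(10, 18))
EPG_COLS = tuple(range(1, 17))


def circ_mean(angles_deg, weights=None):
    """Weighted circular mean (phase of the weighted resultant vector).

    Returns ``(mean_deg, resultant_length, defined)``. ``resultant_length``
    is normalized by the total weight. When the resultant vanishes (e.g.
    a balanced triple of angles) the mean is undefined and flagged rather
    than reported as an arbitrary angle.
    """
    a = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("circ_mean requires at least one angle")
    if weights is None:
        w = np.ones_like(a)
    else:
        w = np.atleast_1d(np.asarray(weights, dtype=float))
        if w.shape != a.shape:
            raise ValueError("weights must match angles in length")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    z = np.sum(w * np.exp(1j * np.deg2rad(a))) / total
    r = float(np.abs(z))
    if r < RESULTANT_TOL:
        return float("nan"), r, False
    return wrap_deg(np.rad2deg(np.angle(z))), r, True


def circ_diff(a_deg, b_deg):
    """Signed angular difference ``wrap_deg(a - b)`` in degrees."""
    return wrap_deg(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float))


def pva(profile, geometry: SectorGeometry) -> Phasor:
    """Population vector average of a per-sector activity profile.

    The phase is the angle of ``sum_i p_i * (cos t_i, sin t_i)`` over
    sector centre angles ``t_i``; strength is the resultant length
    normalized by total activity; amplitude is the half peak-to-trough
    of the least-squares single-cycle sinusoid through the profile.
    """
    p = np.asarray(profile, dtype=float)
    if p.shape != (geometry.n_sectors,):
        raise ValueError(
            f"profile length {p.shape} does not match geometry "
            f"({geometry.n_sectors} sectors)"
        )
    if not np.all(np.isfinite(p)):
        raise ValueError("profile must be finite")
    th = np.deg2rad(geometry.centers)
    total = p.sum()
    z = np.sum(p * np.exp(1j * th))
    amp = _sinusoid_amplitude(p, th)
    if total <= 0 or np.abs(z) < RESULTANT_TOL * max(1.0, np.abs(p).sum()):
        return Phasor(amplitude=amp, phase_deg=float("nan"), strength=0.0, defined=False)
    strength = float(np.clip(np.abs(z) / total, 0.0, 1.0))
    return Phasor(
        amplitude=amp,
        phase_deg=wrap_deg(np.rad2deg(np.angle(z))),
        strength=strength,
        defined=True,
    )


def _sinusoid_amplitude(p: np.ndarray, th_rad: np.ndarray) -> float:
    # least-squares fit of c + A cos(th - phi): A = |a + ib| from the
    # regression on cos(th), sin(th) with an intercept
    X = np.column_stack([np.ones_like(th_rad), np.cos(th_rad), np.sin(th_rad)])
    coef, *_ = np.linalg.lstsq(X, p, rcond=None)
    return float(np.hypot(coef[1], coef[2]))


def cosine_projection(profile, ref_phase_deg: float, geometry: SectorGeometry) -> float:
    """Signed amplitude of the ``cos(theta - ref_phase)`` component.

    Least-squares coefficient (with intercept) of a unit cosine centred
    on ``ref_phase_deg``. A negative value means the profile is
    phase-inverted (peak ~180 deg away from the reference).
    """
    p = np.asarray(profile, dtype=float)
    if p.shape != (geometry.n_sectors,):
        raise ValueError("profile length does not match geometry")
    th = np.deg2rad(geometry.centers - ref_phase_deg)
    X = np.column_stack([np.ones_like(th), np.cos(th)])
    coef, *_ = np.linalg.lstsq(X, p, rcond=None)
    return float(coef[1])


def cosine_projection_dense(profile, angles_deg, ref_phase_deg: float) -> float:
    """`cosine_projection` for profiles on an arbitrary dense angle grid."""
    p = np.asarray(profile, dtype=float)
    th = np.deg2rad(np.asarray(angles_deg, dtype=float) - ref_phase_deg)
    X = np.column_stack([np.ones_like(th), np.cos(th)])
    coef, *_ = np.linalg.lstsq(X, p, rcond=None)
    return float(coef[1])
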