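"""Invertible-phasor readout of the allocentric airflow direction.

A matched pair of left-/right-bridge populations encodes two vectors
that are shifted by -45 deg (left) and +45 deg (right) on projection to
the fan-shaped body. Each vector is read from the phase-nulled bridge
profile of its side: an aligned profile (positive cosine component at
0 deg) contributes a sodium-spike phasor at the side's shift; an
inverted profile (negative component) contributes a calcium-spike
phasor at 180 deg plus the shift, scaled by the calcium-to-sodium
conversion factor kappa (default 0.2). Summing the two phasors and
taking the phase of the sum yields the airflow direction relative to
the heading bump; adding the heading gives the allocentric direction
W + H.

The closed-form identity for the summed pair output,
``bH^2 + bW^2 + 2 bH bW cos(W + H)``, is implemented alongside the
explicit two-term sum for cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circular import cosine_projection_dense, wrap_deg
from .imaging import NulledProfiles

__all__ = [
    "DecoderConfig",
    "DecodeResult",
    "pair_output",
    "closed_form",
    "decode_allocentric",
    "decode_protocol",
]

AMPLITUDE_TOL = 1e-9


@dataclass(frozen=True)
class DecoderConfig:
    """Parameters of the phasor-sum readout.

    kappa
        Dimensionless factor converting the calcium-spike (inverted)
        population signal into sodium-spike-equivalent units.
    left_shift_deg / right_shift_deg
        Anatomical bridge-to-fan-shaped-body offsets applied to the
        heading-carrying axis of each side; they must be opposite
        45 deg shifts.
    profile_peak_method
        'pva' (default) or 'argmax' peak definition for summed profiles.
    """

    kappa: float = 0.2
    left_shift_deg: float = -45.0
    right_shift_deg: float = 45.0
    profile_peak_method: str = "pva"

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")
        if not np.isclose(self.left_shift_deg, -self.right_shift_deg) or not np.isclose(
            abs(self.left_shift_deg), 45.0
        ):
            raise ValueError("side shifts must be opposite 45 deg offsets")


@dataclass
class DecodeResult:
    """Decoded airflow direction from one pair of nulled profiles."""

    relative_deg: float  # airflow direction relative to the heading bump
    allocentric_deg: float  # relative + heading
    amp_left: float  # signed cosine amplitude of the left profile
    amp_right: float
    inverted_left: bool
    inverted_right: bool
    defined: bool
    summed_profile: np.ndarray = field(repr=False, default=None)
    rel_angle_deg: np.ndarray = field(repr=False, default=None)


def pair_output(bH: float, bW: float, H_deg: float, W_deg: float) -> float:
    """Summed output of a matched left/right pair, explicit two-term form.

    ``(bH cos(H-45) + bW cos(W+45))^2 + (bH cos(H+45) + bW cos(W-45))^2``.
    """
    H = np.deg2rad(np.asarray(H_deg, dtype=float))
    W = np.deg2rad(np.asarray(W_deg, dtype=float))
    q = np.pi / 4.0
    left = bH * np.cos(H - q) + bW * np.cos(W + q)
    right = bH * np.cos(H + q) + bW * np.cos(W - q)
    out = left**2 + right**2
    return float(out) if np.isscalar(H_deg) or np.ndim(H_deg) == 0 else out


def closed_form(bH: float, bW: float, H_deg: float, W_deg: float) -> float:
    """Closed-form pair output ``bH^2 + bW^2 + 2 bH bW cos(W + H)``."""
    s = np.deg2rad(np.asarray(W_deg, dtype=float) + np.asarray(H_deg, dtype=float))
    out = bH**2 + bW**2 + 2.0 * bH * bW * np.cos(s)
    return float(out) if np.ndim(s) == 0 else out


def _side_phasor(amp_signed: float, shift_deg: float, kappa: float):
    """(amplitude, phase) of one side's fan-shaped-body phasor."""
    if amp_signed >= 0:
        return amp_signed, shift_deg
    return kappa * (-amp_signed), wrap_deg(180.0 + shift_deg)


def decode_allocentric(
    profiles: NulledProfiles,
    heading_deg: float = 0.0,
    config: DecoderConfig = DecoderConfig(),
) -> DecodeResult:
    """Vector-sum decode from a pair of phase-nulled bridge profiles.

    Each side's signed cosine amplitude at relative angle 0 determines
    whether the encoded vector is aligned (sodium-spike mode) or
    inverted (calcium-spike mode, weighted by kappa). The two phasors,
    shifted by their anatomical +/-45 deg offsets, are summed as
    sinusoids; the phase of the sum is the decoded airflow direction
    relative to the heading bump, reported allocentrically by adding
    ``heading_deg``.
    """
    ang = profiles.rel_angle_deg
    a_left = cosine_projection_dense(profiles.left, ang, 0.0)
    a_right = cosine_projection_dense(profiles.right, ang, 0.0)
    amp_l, ph_l = _side_phasor(a_left, config.left_shift_deg, config.kappa)
    amp_r, ph_r = _side_phasor(a_right, config.right_shift_deg, config.kappa)
    z = amp_l * np.exp(1j * np.deg2rad(ph_l)) + amp_r * np.exp(1j * np.deg2rad(ph_r))
    summed = amp_l * np.cos(np.deg2rad(ang - ph_l)) + amp_r * np.cos(
        np.deg2rad(ang - ph_r)
    )
    if max(amp_l, amp_r) < AMPLITUDE_TOL or np.abs(z) < AMPLITUDE_TOL:
        return DecodeResult(
            float("nan"),
            float("nan"),
            a_left,
            a_right,
            a_left < 0,
            a_right < 0,
            defined=False,
            summed_profile=summed,
            rel_angle_deg=ang,
        )
    if config.profile_peak_method == "argmax":
        rel = float(ang[int(np.argmax(summed))])
    else:
        rel = wrap_deg(np.rad2deg(np.angle(z)))
    return DecodeResult(
        rel,
        wrap_deg(rel + heading_deg),
        a_left,
        a_right,
        a_left < 0,
        a_right < 0,
        defined=True,
        summed_profile=summed,
        rel_angle_deg=ang,
    )


def decode_protocol(
    per_direction_profiles: dict,
    per_direction_heading: dict | None = None,
    config: DecoderConfig = DecoderConfig(),
):
    """Decode each airflow direction's phase-nulled profile pair.

    ``per_direction_profiles`` maps egocentric airflow direction (deg)
    to a :class:`NulledProfiles`; ``per_direction_heading`` optionally
    maps direction to the (circular mean) heading during those trials,
    so the decoded and true directions can be reported allocentrically.
    Returns a pandas DataFrame with true vs decoded angles and circular
    errors; undefined decodes carry NaN angles.
    """
    import pandas as pd

    rows = []
    for w, prof in sorted(per_direction_profiles.items()):
        h = 0.0 if per_direction_heading is None else per_direction_heading[w]
        res = decode_allocentric(prof, heading_deg=h, config=config)
        true_allo = wrap_deg(w + h)
        err = (
            wrap_deg(res.relative_deg - w) if res.defined else float("nan")
        )
        rows.append(
            {
                "airflow_deg": float(w),
                "heading_deg": float(h),
                "true_allocentric_deg": float(true_allo),
                "decoded_relative_deg": res.relative_deg,
                "decoded_allocentric_deg": res.allocentric_deg,
                "circular_error_deg": err,
                "amp_left": res.amp_left,
                "amp_right": res.amp_right,
                "inverted_left": res.inverted_left,
                "inverted_right": res.inverted_right,
                "defined": res.defined,
            }
        )
    return pd.DataFrame(rows)
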