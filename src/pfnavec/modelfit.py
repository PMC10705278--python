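"""Fitting the sum-of-sinusoids and rectified-quadratic response models.

Three models are fit to conjunctive (heading x airflow) maps, with H the
heading relative to the preferred direction, W the egocentric airflow
direction and s = +1/-1 for left-/right-bridge cells:

* Vm:    ``a0 + aH cos H + aW cos(W + s*45)``   (linear least squares)
* rate:  ``([bH cos H + bW cos(W + s*45)]_+)^2`` (nonlinear, multi-start)
* power: ``c0 + ([cH cos H + cW cos(W + s*45)]_-)^2``

plus the quadratic input-output relation between normalized Vm and the
normalized combined (spike-rate + oscillation) output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .tuning import ConjunctiveMap

__all__ = [
    "VmFitParams",
    "RateFitParams",
    "OscFitParams",
    "QuadraticIOFit",
    "fit_vm",
    "fit_rate",
    "fit_osc",
    "variance_explained",
    "fit_quadratic_io",
]


@dataclass(frozen=True)
class VmFitParams:
    a0: float
    aH: float
    aW: float
    side: str
    r2: float


@dataclass(frozen=True)
class RateFitParams:
    bH: float
    bW: float
    side: str
    r2: float
    converged: bool = True


@dataclass(frozen=True)
class OscFitParams:
    c0: float
    cH: float
    cW: float
    side: str
    r2: float
    converged: bool = True


@dataclass(frozen=True)
class QuadraticIOFit:
    """Coefficients (highest power first) of y ~ c2 x^2 + c1 x + c0."""

    coefficients: tuple
    r2: float


def _design_angles(m: ConjunctiveMap, side: str):
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    s = 1.0 if side == "left" else -1.0
    Hg, Wg = np.meshgrid(
        m.heading_centers_deg, m.airflow_directions_deg, indexing="ij"
    )
    mask = m.populated & np.isfinite(m.means)
    cosH = np.cos(np.deg2rad(Hg[mask]))
    cosW = np.cos(np.deg2rad(Wg[mask] + s * 45.0))
    return cosH, cosW, m.means[mask]


def _r2(y, pred):
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise ValueError("zero-variance data")
    return float(1.0 - np.sum((y - pred) ** 2) / sst)


def _r2_fit(y, pred):
    """R^2 for fit reporting; a perfectly fit flat map yields 1.0."""
    sst = np.sum((y - y.mean()) ** 2)
    sse = np.sum((y - pred) ** 2)
    if sst == 0:
        return 1.0 if sse < 1e-24 else float("-inf")
    return float(1.0 - sse / sst)


def fit_vm(m: ConjunctiveMap, side: str) -> VmFitParams:
    """Linear least squares for the sum-of-sinusoids Vm model."""
    cosH, cosW, y = _design_angles(m, side)
    if y.size < 4:
        raise ValueError("need at least 4 populated cells")
    X = np.column_stack([np.ones_like(cosH), cosH, cosW])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design (populated cells too clustered)")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ coef
    return VmFitParams(float(coef[0]), float(coef[1]), float(coef[2]), side, _r2_fit(y, pred))


def _fit_rectified(cosH, cosW, y, rectify: str, with_offset: bool):
    """Multi-start nonlinear least squares for the rectified-square models."""

    def predict(params):
        if with_offset:
            c0, g1, g2 = params
        else:
            c0, (g1, g2) = 0.0, params
        drive = g1 * cosH + g2 * cosW
        if rectify == "positive":
            return c0 + np.clip(drive, 0.0, None) ** 2
        return c0 + np.clip(drive, None, 0.0) ** 2

    def resid(params):
        return predict(params) - y

    scale = np.sqrt(max(np.ptp(y), 1e-12))
    starts = []
    for g1 in (0.25, 1.0, 2.0):
        for g2 in (0.25, 1.0, 2.0):
            base = [g1 * scale, g2 * scale]
            starts.append(([max(y.min(), 0.0)] if with_offset else []) + base)
    best = None
    lo = ([0.0] if with_offset else []) + [0.0, 0.0]
    for x0 in starts:
        try:
            sol = least_squares(
                resid, x0, bounds=(lo, np.inf), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("rectified-model fit failed from every start")
    pred = predict(best.x)
    return best.x, _r2_fit(y, pred), bool(best.success)


def fit_rate(m: ConjunctiveMap, side: str) -> RateFitParams:
    """Fit the positive-rectified quadratic sodium-spike-rate model.

    bH and bW are constrained nonnegative; a sign flip of the drive is
    equivalent to a 180 deg phase shift, so the constraint only fixes
    the parameterization.
    """
    cosH, cosW, y = _design_angles(m, side)
    if y.size < 4:
        raise ValueError("need at least 4 populated cells")
    (bH, bW), r2, ok = _fit_rectified(cosH, cosW, y, "positive", with_offset=False)
    return RateFitParams(float(bH), float(bW), side, r2, ok)


def fit_osc(m: ConjunctiveMap, side: str) -> OscFitParams:
    """Fit the negative-rectified quadratic oscillation-power model."""
    cosH, cosW, y = _design_angles(m, side)
    if y.size < 4:
        raise ValueError("need at least 4 populated cells")
    (c0, cH, cW), r2, ok = _fit_rectified(cosH, cosW, y, "negative", with_offset=True)
    return OscFitParams(float(c0), float(cH), float(cW), side, r2, ok)


def variance_explained(prediction, data) -> float:
    """Fraction of variance explained, 1 - SSE/SST over finite cells."""
    p = np.asarray(prediction, dtype=float).ravel()
    d = np.asarray(data, dtype=float).ravel()
    mask = np.isfinite(p) & np.isfinite(d)
    if not mask.any():
        raise ValueError("no overlapping populated cells")
    return _r2(d[mask], p[mask])


def fit_quadratic_io(vm_norm, combined_norm) -> QuadraticIOFit:
    """Degree-2 polynomial fit of normalized combined output vs Vm.

    ``vm_norm`` is membrane potential minus the minimum of the heading
    tuning curve; ``combined_norm`` is the sum of the min-max-scaled
    spike-rate and oscillation-power curves.
    """
    x = np.asarray(vm_norm, dtype=float)
    y = np.asarray(combined_norm, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct Vm values")
    coef = np.polyfit(x, y, 2)
    pred = np.polyval(coef, x)
    return QuadraticIOFit(tuple(float(c) for c in coef), _r2_fit(y, pred))


def minmax_scale(values) -> np.ndarray:
    """Scale to [0, 1] (used for the quadratic input-output relation)."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        raise ValueError("constant curve cannot be min-max scaled")
    return (v - lo) / (hi - lo)
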