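"""Normalization, bump-phase extraction, phase nulling, offset statistics."""

import numpy as np
import pytest

from pfnavec.circular import BRIDGE18, EB16, SectorGeometry, circ_diff, pva, wrap_deg
from pfnavec.imaging import (
    PhaseSeries,
    SectorMatrix,
    epg_phase_bridge,
    normalize,
    phase_null,
    phase_offset_stats,
    profile_peak,
    pva_phase,
)


def _eb_matrix(F):
    return SectorMatrix(EB16, np.arange(F.shape[0]) * 0.2, F)


def _bridge_matrix(F):
    return SectorMatrix(BRIDGE18, np.arange(F.shape[0]) * 0.2, F)


class TestNormalize:
    def test_dff_constant_sector_zero(self):
        F = np.column_stack([np.full(100, 3.0), np.linspace(1, 2, 100)])
        geom = SectorGeometry("noduli2", 2, (0.0, 0.0))
        out = normalize(SectorMatrix(geom, np.arange(100.0), F), "dff")
        assert np.allclose(out.F[:, 0], 0.0)
        assert out.normalization_state == "dff"

    def test_range_linear_ramp_percentiles(self):
        """A ramp over [10, 20] maps to ~[-0.056, 1.056] with 5/95 anchors."""
        F = np.linspace(10.0, 20.0, 1001)[:, None]
        geom = SectorGeometry("noduli2", 1, (0.0,))
        out = normalize(SectorMatrix(geom, np.arange(1001.0), F), "range")
        assert out.F.min() == pytest.approx((10 - 10.5) / 9.0, abs=1e-9)
        assert out.F.max() == pytest.approx((20 - 10.5) / 9.0, abs=1e-9)

    def test_zscore_constant_sector_rejected(self):
        F = np.column_stack([np.full(50, 2.0), np.linspace(0, 1, 50)])
        geom = SectorGeometry("noduli2", 2, (0.0, 0.0))
        mat = SectorMatrix(geom, np.arange(50.0), F)
        with pytest.raises(ValueError, match="degenerate"):
            normalize(mat, "zscore")
        flagged = normalize(mat, "zscore", strict=False)
        assert flagged.bad_sectors == (0,)
        assert np.isnan(flagged.F[:, 0]).all()

    def test_zscore_standardizes(self, rng):
        F = rng.gamma(2.0, 1.0, size=(500, 2))
        geom = SectorGeometry("noduli2", 2, (0.0, 0.0))
        out = normalize(SectorMatrix(geom, np.arange(500.0), F), "zscore")
        assert np.allclose(out.F.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(out.F.std(axis=0), 1.0, atol=1e-12)

    def test_double_normalization_rejected(self):
        F = np.linspace(1, 2, 50)[:, None]
        geom = SectorGeometry("noduli2", 1, (0.0,))
        out = normalize(SectorMatrix(geom, np.arange(50.0), F), "dff")
        with pytest.raises(ValueError):
            normalize(out, "dff")


class TestEpgPhaseBridge:
    def _tone(self, g0):
        g = np.arange(16)
        return 1.0 + np.cos(2 * np.pi * (g - g0) / 8.0)

    @pytest.mark.parametrize("g0", [0.0, 1.5, 3.7, 7.99])
    def test_pure_tone_phase_exact(self, g0):
        F18 = np.concatenate([[0.0], self._tone(g0), [0.0]])[None, :]
        ph = epg_phase_bridge(_bridge_matrix(F18))
        assert ph.valid[0]
        assert abs(circ_diff(ph.phase_deg[0], wrap_deg(g0 * 45.0))) < 1e-9

    def test_half_period_shift_is_180(self):
        a = epg_phase_bridge(_bridge_matrix(np.concatenate([[0], self._tone(1.0), [0]])[None, :]))
        b = epg_phase_bridge(_bridge_matrix(np.concatenate([[0], self._tone(5.0), [0]])[None, :]))
        assert abs(abs(circ_diff(a.phase_deg[0], b.phase_deg[0])) - 180.0) < 1e-9

    def test_uniform_frame_undefined(self):
        F18 = np.ones((1, 18))
        ph = epg_phase_bridge(_bridge_matrix(F18))
        assert not ph.valid[0]
        assert np.isnan(ph.phase_deg[0])

    def test_agrees_with_pva_on_single_bumps(self):
        """Fourier phase and PVA agree to < 2 deg for bumps >= 2 sectors wide."""
        # glomerulus j carries angle j*45 deg; both bridge bump copies
        # reinforce in the vector average
        geom16 = SectorGeometry("eb16", 16, tuple(wrap_deg(np.arange(16) * 45.0).tolist()))
        for phi in (-120.0, 0.0, 37.0, 155.0):
            bump = np.exp(1.5 * np.cos(np.deg2rad(np.arange(16) * 45.0 - phi)))
            F18 = np.concatenate([[0.0], bump, [0.0]])[None, :]
            fourier = epg_phase_bridge(_bridge_matrix(F18)).phase_deg[0]
            vector = pva(bump, geom16).phase_deg
            assert abs(circ_diff(fourier, vector)) < 2.0


class TestPvaPhase:
    def test_single_wedge(self):
        F = np.zeros((1, 16))
        F[0, 4] = 1.0
        ph = pva_phase(_eb_matrix(F))
        assert ph.valid[0]
        assert ph.phase_deg[0] == pytest.approx(EB16.centers[4])

    def test_cosine_bump_at_100(self):
        F = (1.0 + np.cos(np.deg2rad(EB16.centers - 100.0)))[None, :]
        ph = pva_phase(_eb_matrix(F))
        assert abs(ph.phase_deg[0] - 100.0) < 1e-6

    def test_uniform_frame_flagged(self):
        ph = pva_phase(_eb_matrix(np.ones((1, 16))))
        assert not ph.valid[0]

    def test_strength_floor(self):
        weak = (1.0 + 0.1 * np.cos(np.deg2rad(EB16.centers)))[None, :]
        assert not pva_phase(_eb_matrix(weak), strength_floor=0.15).valid[0]
        assert pva_phase(_eb_matrix(weak), strength_floor=0.01).valid[0]


def _pfn_frames(epg_phases_deg, offset_left, offset_right, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = len(epg_phases_deg)
    F = np.zeros((n, 18))
    ang = np.arange(8) * 45.0
    for i, h in enumerate(epg_phases_deg):
        F[i, :8] = 1 + np.cos(np.deg2rad(ang - (h + offset_left)))
        F[i, 10:] = 1 + np.cos(np.deg2rad(ang - (h + offset_right)))
    F += rng.normal(0.0, noise_sd, F.shape)
    F = np.clip(F, 0.0, None)
    mat = SectorMatrix(BRIDGE18, np.arange(n) * 0.2, F)
    phases = PhaseSeries(
        mat.t, np.asarray(epg_phases_deg, float), np.ones(n), np.ones(n, bool)
    )
    return mat, phases


class TestPhaseNull:
    def test_aligned_bumps_peak_at_zero(self, rng):
        phases = rng.uniform(-180, 180, 40)
        mat, eph = _pfn_frames(phases, 0.0, 0.0)
        nulled = phase_null(mat, eph)
        assert profile_peak(nulled.left, nulled.rel_angle_deg, "argmax") == 0.0
        assert profile_peak(nulled.right, nulled.rel_angle_deg, "argmax") == 0.0

    def test_inverted_bumps_peak_at_180(self, rng):
        phases = rng.uniform(-180, 180, 40)
        mat, eph = _pfn_frames(phases, 180.0, 180.0)
        nulled = phase_null(mat, eph)
        assert profile_peak(nulled.left, nulled.rel_angle_deg, "argmax") == 180.0

    def test_fixed_offset_recovered_under_noise(self, rng):
        """A fixed bump offset survives noisy frames to one fine step."""
        delta = 67.5
        phases = rng.uniform(-180, 180, 300)
        mat, eph = _pfn_frames(phases, delta, delta, noise_sd=0.3, seed=4)
        nulled = phase_null(mat, eph)
        for prof in (nulled.left, nulled.right):
            peak = profile_peak(prof, nulled.rel_angle_deg, "argmax")
            assert abs(circ_diff(peak, delta)) <= 4.5 + 1e-9

    def test_rotation_equivariance(self, rng):
        """Rotating PFN halves and EPG phase together leaves the result fixed."""
        phases = rng.uniform(-180, 180, 25)
        mat, eph = _pfn_frames(phases, 45.0, 225.0)
        base = phase_null(mat, eph)
        shift = 2  # sectors = 90 deg
        F2 = mat.F.copy()
        F2[:, :8] = np.roll(mat.F[:, :8], shift, axis=1)
        F2[:, 10:] = np.roll(mat.F[:, 10:], shift, axis=1)
        mat2 = SectorMatrix(BRIDGE18, mat.t, F2)
        eph2 = PhaseSeries(
            eph.t, wrap_deg(eph.phase_deg + shift * 45.0), eph.strength, eph.valid
        )
        rotated = phase_null(mat2, eph2)
        assert np.allclose(rotated.left, base.left, atol=1e-9)
        assert np.allclose(rotated.right, base.right, atol=1e-9)

    def test_undefined_epg_frames_excluded(self, rng):
        phases = rng.uniform(-180, 180, 10)
        mat, eph = _pfn_frames(phases, 0.0, 0.0)
        eph.valid[5:] = False
        nulled = phase_null(mat, eph)
        assert nulled.n_frames == 5
        with pytest.raises(ValueError):
            phase_null(mat, PhaseSeries(eph.t, eph.phase_deg, eph.strength, np.zeros(10, bool)))


class TestPhaseOffsetStats:
    def _series(self, phases):
        n = len(phases)
        return PhaseSeries(np.arange(n) * 1.0, np.asarray(phases, float), np.ones(n), np.ones(n, bool))

    def test_identical_series(self):
        a = self._series([10.0, -50.0, 170.0, 30.0])
        stats = phase_offset_stats(a, a)
        assert stats.mean_offset_deg == pytest.approx(0.0, abs=1e-9)
        # all mass concentrated in the central bin of the +/-10 deg band
        assert stats.density_per_deg.sum() * 10.0 == pytest.approx(1.0)
        assert stats.frontal_mean_density == pytest.approx(0.1 / 3.0)

    def test_constant_180_offset(self):
        a = self._series([0.0, 90.0, -90.0])
        b = self._series([180.0, -90.0, 90.0])
        stats = phase_offset_stats(a, b)
        assert abs(abs(stats.mean_offset_deg) - 180.0) < 1e-9
        assert stats.frontal_mean_density == 0.0

    def test_uniform_offsets_approach_uniform_density(self, rng):
        n = 20000
        a = self._series(rng.uniform(-180, 180, n))
        b = self._series(np.zeros(n))
        stats = phase_offset_stats(a, b)
        assert stats.frontal_mean_density == pytest.approx(1.0 / 360.0, rel=0.15)
        assert not stats.mean_defined or stats.resultant < 0.05

    def test_window_selection(self):
        a = self._series([0.0, 0.0, 90.0])
        b = self._series([0.0, 0.0, 0.0])
        stats = phase_offset_stats(a, b, window=[True, True, False])
        assert stats.mean_offset_deg == pytest.approx(0.0, abs=1e-9)
        with pytest.raises(ValueError):
            phase_offset_stats(a, b, window=[False, False, False])


class TestInversionPhenomenology:
    """Qualitative bump-inversion pattern on the full synthetic experiment."""

    def test_front_rear_and_side_puffs(self, imaging_processed):
        profiles = imaging_processed["profiles"]
        tol = 22.5  # half a bridge sector

        front = profiles[0.0]
        for prof in (front.left, front.right):
            peak = profile_peak(prof, front.rel_angle_deg)
            assert abs(circ_diff(peak, 0.0)) <= tol

        rear = profiles[180.0]
        for prof in (rear.left, rear.right):
            peak = profile_peak(prof, rear.rel_angle_deg)
            assert abs(circ_diff(peak, 180.0)) <= tol

        for w, inverted_side in ((90.0, "left"), (-90.0, "right")):
            prof = profiles[w]
            peaks = {
                "left": profile_peak(prof.left, prof.rel_angle_deg),
                "right": profile_peak(prof.right, prof.rel_angle_deg),
            }
            other = "right" if inverted_side == "left" else "left"
            assert abs(circ_diff(peaks[inverted_side], 180.0)) <= tol
            assert abs(circ_diff(peaks[other], 0.0)) <= tol
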