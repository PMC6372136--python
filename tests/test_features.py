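"""Attractor density and the scalar feature catalogue."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from pulseattractor import (
    PulseModelParams,
    UVWSeries,
    arm_widths,
    attractor_size,
    density2d,
    generate_pulse_train,
    periodicity_score,
    rotation_angle,
    symmetrize,
    u_statistics,
)
from pulseattractor.features import (
    ARM_REFERENCE_DEG,
    DensityGrid,
    ROTATION_REFERENCE_DEG,
    SIZE_CALIBRATION,
    calibration_uvw,
)
from .conftest import pipeline_uvw


def make_uvw(v, w, u=None, fs=250.0):
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    u = np.zeros_like(v) if u is None else np.asarray(u, dtype=float)
    return UVWSeries(u=u, v=v, w=w, tau=1 / 3, fs=fs)


def rotate_uvw(uvw, deg):
    th = np.deg2rad(deg)
    v = np.cos(th) * uvw.v - np.sin(th) * uvw.w
    w = np.sin(th) * uvw.v + np.cos(th) * uvw.w
    return make_uvw(v, w, uvw.u, uvw.fs)


class TestDensity2d:
    def test_identical_points_occupy_one_cell(self):
        uvw = make_uvw(np.full(150, 0.4), np.full(150, -0.2))
        den = density2d(uvw, n=64)
        assert den.rho.max() == pytest.approx(1.0)
        assert np.count_nonzero(den.rho) == 1

    def test_normalization(self, calibration_vw):
        den = density2d(calibration_vw)
        assert den.rho.sum() == pytest.approx(1.0, abs=1e-12)
        assert (den.rho >= 0).all()

    def test_matches_brute_force_binning(self, rng):
        """Histogram agrees cell-for-cell with per-point loop binning."""
        n_pts, n, B = 10_000, 48, 1.0
        r = np.sqrt(rng.uniform(0, 1, n_pts)) * 0.9
        ang = rng.uniform(0, 2 * np.pi, n_pts)
        v, w = r * np.cos(ang), r * np.sin(ang)
        den = density2d(make_uvw(v, w), n=n, B=B)

        # Per-point loop with half-open bins [e_i, e_{i+1}) and the
        # upper edge folded into the last bin.
        brute = np.zeros((n, n))
        edges = np.linspace(-B, B, n + 1)
        for vi, wi in zip(v, w):
            i = min(np.searchsorted(edges, vi, side="right") - 1, n - 1)
            j = min(np.searchsorted(edges, wi, side="right") - 1, n - 1)
            brute[i, j] += 1
        assert np.array_equal(den.rho, brute / n_pts)

    def test_auto_extent_covers_all_points(self, calibration_vw):
        den = density2d(calibration_vw)
        r_max = np.hypot(calibration_vw.v, calibration_vw.w).max()
        assert den.extent == pytest.approx(1.05 * r_max)

    def test_too_few_points_is_an_error(self):
        uvw = make_uvw(np.zeros(50), np.zeros(50))
        with pytest.raises(ValueError, match="points"):
            density2d(uvw)


class TestSymmetrize:
    @staticmethod
    def gaussian_grid(n=128, B=1.0, sd=0.3, center=(0.0, 0.0)):
        c = -B + (np.arange(n) + 0.5) * (2 * B / n)
        V, W = np.meshgrid(c, c, indexing="ij")
        rho = np.exp(
            -((V - center[0]) ** 2 + (W - center[1]) ** 2) / (2 * sd**2)
        )
        return DensityGrid(rho=rho / rho.sum(), extent=B)

    def test_rotationally_symmetric_input_is_fixed_point(self):
        den = self.gaussian_grid()
        out = symmetrize(den)
        assert np.allclose(out.rho, den.rho, atol=1e-6)

    def test_point_mass_splits_into_three_blobs(self):
        n, B = 96, 1.0
        rho = np.zeros((n, n))
        # Unit mass near (v, w) = (0.5, 0): cell centre coordinates.
        i = int((0.5 + B) / (2 * B / n))
        rho[i, n // 2] = 1.0
        out = symmetrize(DensityGrid(rho=rho, extent=B))
        c = -B + (np.arange(n) + 0.5) * (2 * B / n)
        V, W = np.meshgrid(c, c, indexing="ij")
        for ang in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
            target_v, target_w = 0.5 * np.cos(ang), 0.5 * np.sin(ang)
            near = (V - target_v) ** 2 + (W - target_w) ** 2 < 0.05**2
            assert out.rho[near].sum() == pytest.approx(1 / 3, abs=0.02)

    def test_idempotent_within_resampling_tolerance(self):
        den = self.gaussian_grid(sd=0.15, center=(0.4, 0.1))
        once = symmetrize(den)
        twice = symmetrize(once)
        assert np.abs(twice.rho - once.rho).max() < 1e-4
        assert np.abs(twice.rho - once.rho).sum() < 0.01


class TestAttractorSize:
    def test_homogeneous_under_scaling(self, calibration_vw):
        k = 3.7
        scaled = make_uvw(
            k * calibration_vw.v, k * calibration_vw.w, k * calibration_vw.u
        )
        assert attractor_size(scaled) == pytest.approx(
            k * attractor_size(calibration_vw), rel=1e-12
        )

    @pytest.mark.parametrize("A", [25.0, 40.0])
    def test_recovers_pulse_amplitude(self, A):
        """Calibration pulse of amplitude A reports size A within 2%."""
        assert attractor_size(calibration_uvw(A=A)) == pytest.approx(A, rel=0.02)

    def test_size_invariant_to_offset(self):
        base = generate_pulse_train(
            PulseModelParams(T=1.0, A=40.0), 10.0, 250.0
        )
        shifted = generate_pulse_train(
            PulseModelParams(T=1.0, A=40.0, offset=90.0), 10.0, 250.0
        )
        a = attractor_size(pipeline_uvw(base, T=1.0))
        b = attractor_size(pipeline_uvw(shifted, T=1.0))
        assert b == pytest.approx(a, rel=1e-9)

    def test_degenerate_cloud_has_zero_size(self):
        uvw = make_uvw(np.zeros(200), np.zeros(200))
        assert attractor_size(uvw) == 0.0

    def test_frozen_calibration_constant_matches_recomputation(self):
        r = np.sort(np.hypot(calibration_uvw().v, calibration_uvw().w))
        band = r[int(np.floor(0.1 * r.size)) : int(np.ceil(0.9 * r.size))]
        assert 1.0 / band.mean() == pytest.approx(SIZE_CALIBRATION, rel=1e-8)


class TestRotationAngle:
    def test_calibration_waveform_defines_zero(self, calibration_vw):
        theta = rotation_angle(density2d(calibration_vw))
        assert abs(theta) < 0.5

    def test_equivariant_under_rotation(self, calibration_vw):
        base = rotation_angle(density2d(calibration_vw))
        rotated = rotate_uvw(calibration_vw, 10.0)
        assert rotation_angle(density2d(rotated)) == pytest.approx(
            base + 10.0, abs=0.5
        )

    def test_concave_downstroke_rotates_clockwise(self):
        """Raising the downstroke concavity turns the attractor clockwise."""
        thetas = []
        for kappa in (1.0, 1.5, 2.0, 2.5, 3.0):
            sig = generate_pulse_train(
                PulseModelParams(T=1.0, A=40.0, kappa=kappa), 30.0, 250.0
            )
            thetas.append(rotation_angle(density2d(pipeline_uvw(sig, T=1.0))))
        assert all(b < a for a, b in zip(thetas, thetas[1:]))

    def test_symmetric_density_has_no_orientation(self):
        den = TestSymmetrize.gaussian_grid()
        with pytest.raises(ValueError, match="orientation"):
            rotation_angle(den)

    def test_frozen_rotation_reference_matches_recomputation(self):
        den = density2d(calibration_uvw())
        V, W = den.cell_centers()
        m3 = np.sum(den.rho * np.exp(3j * np.arctan2(W, V)))
        raw = np.degrees(np.angle(m3)) / 3.0
        assert raw == pytest.approx(ROTATION_REFERENCE_DEG, abs=1e-4)


class TestArmWidths:
    @staticmethod
    def triangle_cloud(rng, sd, h=10.0, n_per_side=2000):
        """Three straight sides at distance h plus transverse noise sd."""
        half = h * np.tan(np.pi / 3)  # equilateral side half-length
        pts_v, pts_w = [], []
        for arm in range(3):
            psi = np.deg2rad(ARM_REFERENCE_DEG + 120.0 * arm)
            e_mid = np.array([np.cos(psi), np.sin(psi)])
            e_tan = np.array([-np.sin(psi), np.cos(psi)])
            along = rng.uniform(-half, half, n_per_side)
            perp = h + rng.normal(0.0, sd, n_per_side)
            p = np.outer(perp, e_mid) + np.outer(along, e_tan)
            pts_v.append(p[:, 0])
            pts_w.append(p[:, 1])
        return make_uvw(np.concatenate(pts_v), np.concatenate(pts_w))

    def test_periodic_waveform_has_razor_thin_arms(self, calibration_vw):
        theta = rotation_angle(density2d(calibration_vw))
        widths, _ = arm_widths(calibration_vw, theta)
        size = attractor_size(calibration_vw)
        assert (widths < 0.01 * size).all()

    def test_width_recovers_transverse_noise_sd(self, rng):
        sd = 0.5
        uvw = self.triangle_cloud(rng, sd)
        widths, _ = arm_widths(uvw, 0.0)
        assert widths == pytest.approx(sd, rel=0.10)

    def test_sparse_sector_reports_missing(self, rng):
        # Points only along arm 1's side: the other two sectors are empty.
        psi = np.deg2rad(ARM_REFERENCE_DEG)
        along = rng.uniform(-5, 5, 400)
        v = 10 * np.cos(psi) - along * np.sin(psi)
        w = 10 * np.sin(psi) + along * np.cos(psi)
        widths, cvs = arm_widths(make_uvw(v, w), 0.0)
        assert np.isfinite(widths[0])
        assert np.isnan(widths[1]) and np.isnan(widths[2])

    def test_upstroke_jitter_widens_a_unique_dominant_arm(self):
        """Sweeping upstroke-fraction jitter must single out one arm whose
        width grows monotonically and much faster than the others'."""
        levels = [0.0, 0.02, 0.04, 0.06, 0.08]
        W = []
        for i, sa in enumerate(levels):
            sig = generate_pulse_train(
                PulseModelParams(T=1.0, A=40.0, sigma_alpha=sa, seed=100 + i),
                60.0,
                250.0,
            )
            uvw = pipeline_uvw(sig, T=1.0)
            theta = rotation_angle(density2d(uvw))
            widths, _ = arm_widths(uvw, theta)
            W.append(widths)
        W = np.array(W)
        growth = W[-1] - W[0]
        dominant = int(np.argmax(growth))
        rho = spearmanr(levels, W[:, dominant]).statistic
        assert rho == pytest.approx(1.0)
        others = np.delete(growth, dominant)
        assert (growth[dominant] > 1.5 * others).all()

    def test_non_uniform_edge_density_raises_cv(self, rng):
        uniform = self.triangle_cloud(rng, 0.2)
        _, cv_uniform = arm_widths(uniform, 0.0)
        # Concentrate arm 1's points in one half of the side.
        clustered = self.triangle_cloud(rng, 0.2)
        psi = np.deg2rad(ARM_REFERENCE_DEG)
        e_tan = np.array([-np.sin(psi), np.cos(psi)])
        along = clustered.v * e_tan[0] + clustered.w * e_tan[1]
        phi = np.degrees(np.arctan2(clustered.w, clustered.v))
        d = (phi - ARM_REFERENCE_DEG + 180) % 360 - 180
        keep = ~((np.abs(d) < 60) & (along > 0) & (rng.uniform(size=along.size) < 0.8))
        squeezed = make_uvw(clustered.v[keep], clustered.w[keep])
        _, cv_clustered = arm_widths(squeezed, 0.0)
        assert cv_clustered[0] > 2 * cv_uniform[0]


class TestPeriodicityScore:
    def test_zero_widths_score_zero(self):
        assert periodicity_score((0.0, 0.0, 0.0), 10.0) == 0.0

    def test_simple_ratio(self):
        assert periodicity_score((1.0, 1.0, 1.0), 10.0) == pytest.approx(0.1)

    def test_ignores_missing_arms(self):
        assert periodicity_score((2.0, np.nan, 4.0), 10.0) == pytest.approx(0.3)

    def test_zero_size_is_an_error(self):
        with pytest.raises(ValueError):
            periodicity_score((1.0, 1.0, 1.0), 0.0)

    def test_amplitude_jitter_raises_score(self):
        """A jittered train is strictly less periodic than its clean twin."""
        def score(sigma_A):
            sig = generate_pulse_train(
                PulseModelParams(T=1.0, A=40.0, sigma_A=sigma_A, seed=7),
                30.0,
                250.0,
            )
            uvw = pipeline_uvw(sig, T=1.0)
            theta = rotation_angle(density2d(uvw))
            widths, _ = arm_widths(uvw, theta)
            return periodicity_score(widths, attractor_size(uvw))

        assert score(0.1) > score(0.0)


class TestUStatistics:
    def test_constant_signal(self):
        uvw = make_uvw(np.zeros(10), np.zeros(10), u=np.full(10, 7 * np.sqrt(3)))
        mean, trend = u_statistics(uvw, fs=10.0)
        assert mean == pytest.approx(7.0)
        assert trend == pytest.approx(0.0, abs=1e-12)

    def test_linear_drift_recovered(self):
        sig = generate_pulse_train(
            PulseModelParams(T=1.0, A=40.0, drift_rate=1.0), 10.0, 250.0
        )
        uvw = pipeline_uvw(sig, T=1.0)
        _, trend = u_statistics(uvw, fs=sig.fs)
        assert trend == pytest.approx(1.0, abs=0.01)

    def test_u_mean_equals_window_mean(self):
        """The rescaled u average reproduces the raw-signal window mean."""
        sig = generate_pulse_train(
            PulseModelParams(T=1.0, A=40.0, offset=100.0), 10.0, 250.0
        )
        traj_start = int(np.ceil(2 * (1 / 3) * sig.fs - 1e-9))
        uvw = pipeline_uvw(sig, T=1.0)
        mean, _ = u_statistics(uvw, fs=sig.fs)
        direct = np.mean(
            [
                sig.samples[traj_start:],
                np.interp(
                    np.arange(traj_start, len(sig)) - sig.fs / 3,
                    np.arange(len(sig)),
                    sig.samples,
                ),
                np.interp(
                    np.arange(traj_start, len(sig)) - 2 * sig.fs / 3,
                    np.arange(len(sig)),
                    sig.samples,
                ),
            ]
        )
        assert mean == pytest.approx(direct, abs=1e-9)
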