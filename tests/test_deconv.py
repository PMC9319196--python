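"""Fourier-domain projectors, RL updates, TV step and full reconstruction."""

import numpy as np
import pandas as pd
import pytest

from lfdeconv import (
    DeconvConfig,
    FourierProjector,
    PhaseSpaceDeconvolution,
    Volume,
    bp_fourier,
    direct_conv_op_count,
    forward_project,
    fp_fourier,
    make_subset_schedule,
    reconstruct,
    rl_update_full,
    rl_update_subset,
    tv_gradient,
    tv_step,
)
from helpers import direct_backward, direct_conv_same, direct_corr_same, direct_forward


class TestFourierForwardProjection:
    def test_impulse_volume_returns_psf_slice(self, small_psf, small_cfg):
        n = 16
        g = np.zeros((n, n, small_cfg.n_z))
        g[8, 8, 2] = 1.0
        vol = Volume(g, small_cfg.z_planes)
        for u in [(0, 0), (2, 2), (4, 1)]:
            out = fp_fourier(vol, small_psf, u)
            oracle = direct_conv_same(g[:, :, 2], small_psf.h[u[0], u[1], :, :, 2])
            assert np.abs(out - oracle).max() <= 1e-12 * max(oracle.max(), 1e-30)

    def test_matches_spatial_oracle_random_volumes(self, small_psf, small_cfg):
        rng = np.random.default_rng(11)
        g = rng.random((32, 32, small_cfg.n_z))
        vol = Volume(g, small_cfg.z_planes)
        proj = FourierProjector(small_psf, (32, 32))
        for u in [(0, 0), (1, 3), (4, 4)]:
            out = fp_fourier(vol, small_psf, u, proj)
            oracle = sum(
                direct_conv_same(g[:, :, iz], small_psf.h[u[0], u[1], :, :, iz])
                for iz in range(small_cfg.n_z)
            )
            assert np.abs(out - oracle).max() <= 1e-5 * oracle.max()

    def test_zero_volume_projects_to_zero(self, small_psf, small_cfg):
        vol = Volume(np.zeros((12, 12, small_cfg.n_z)), small_cfg.z_planes)
        assert np.abs(fp_fourier(vol, small_psf, (2, 2))).max() == 0.0


class TestFourierBackProjection:
    def test_impulse_image_returns_flipped_psf_stack(self, small_psf, small_cfg):
        n = 15
        a = np.zeros((n, n))
        a[n // 2, n // 2] = 1.0
        vol = bp_fourier(a, small_psf, (1, 2))
        half = (small_cfg.n_x_psf - 1) // 2
        c = n // 2
        sl = slice(c - half, c + half + 1)
        for iz in range(small_cfg.n_z):
            flipped = small_psf.h[1, 2, ::-1, ::-1, iz]
            assert np.allclose(vol.g[sl, sl, iz], flipped, atol=1e-12)

    def test_matches_spatial_oracle(self, small_psf, small_cfg):
        rng = np.random.default_rng(13)
        a = rng.random((16, 16))
        vol = bp_fourier(a, small_psf, (3, 1))
        oracle = direct_backward(a, small_psf.h, 3, 1)
        assert np.abs(vol.g - oracle).max() <= 1e-5 * oracle.max()

    def test_adjoint_identity(self, small_psf, small_cfg):
        """<FP(g), a> == <g, BP(a)> over random nonnegative instances."""
        rng = np.random.default_rng(17)
        proj = FourierProjector(small_psf, (16, 16))
        for trial in range(20):
            g = rng.random((16, 16, small_cfg.n_z))
            a = rng.random((16, 16))
            u = (int(rng.integers(5)), int(rng.integers(5)))
            fp = proj.fp(g, proj.hhat(u))
            bp = proj.bp(a, proj.hhat(u))
            lhs = float(np.sum(fp * a))
            rhs = float(np.sum(g * bp))
            assert abs(lhs - rhs) <= 1e-8 * np.linalg.norm(g) * np.linalg.norm(a)


@pytest.fixture(scope="module")
def fixed_point_setup(small_psf, small_cfg):
    rng = np.random.default_rng(19)
    x = Volume(rng.random((16, 16, small_cfg.n_z)) + 0.5, small_cfg.z_planes)
    y = forward_project(x, small_psf)
    return x, y


@pytest.fixture(scope="module")
def impulse_problem(small_psf, small_cfg):
    g = np.zeros((16, 16, small_cfg.n_z))
    g[8, 7, 2] = 1000.0  # photon-scale amplitude
    vol = Volume(g, small_cfg.z_planes)
    y = forward_project(vol, small_psf)
    return vol, y


class TestRLUpdates:
    def test_full_update_fixed_point(self, fixed_point_setup, small_psf):
        x, y = fixed_point_setup
        x2 = rl_update_full(x, y, small_psf)
        assert np.abs(x2.g - x.g).max() <= 1e-10 * x.g.max()

    def test_subset_update_fixed_point(self, fixed_point_setup, small_psf):
        x, y = fixed_point_setup
        for group in [(0, 13), (7,), (3, 21)]:
            x2 = rl_update_subset(x, y, small_psf, group)
            assert np.abs(x2.g - x.g).max() <= 1e-10 * x.g.max()

    def test_updates_preserve_nonnegativity_and_zeros(self, small_psf, small_cfg):
        rng = np.random.default_rng(23)
        g = rng.random((16, 16, small_cfg.n_z))
        g[g < 0.3] = 0.0  # plant exact zeros
        x = Volume(g, small_cfg.z_planes)
        y = forward_project(
            Volume(rng.random((16, 16, small_cfg.n_z)), small_cfg.z_planes), small_psf
        )
        for out in (
            rl_update_full(x, y, small_psf),
            rl_update_subset(x, y, small_psf, (2, 11)),
        ):
            assert np.all(out.g >= 0)
            assert np.all(out.g[g == 0] == 0)  # multiplicative updates keep zeros

    def test_full_update_matches_spatial_oracle(self, tiny_psf, tiny_cfg):
        """The Fourier-domain weighted update equals the same update computed
        with brute-force spatial convolutions."""
        from lfdeconv import angle_weights

        rng = np.random.default_rng(29)
        nz = tiny_cfg.n_z
        x = rng.random((12, 12, nz)) + 0.1
        truth = rng.random((12, 12, nz))
        y = direct_forward(truth, tiny_psf.h)
        w = angle_weights(tiny_psf).w
        nu = tiny_cfg.n_u
        num = np.zeros_like(x)
        den = np.zeros_like(x)
        for iu1 in range(nu):
            for iu2 in range(nu):
                num += w[iu1, iu2] * direct_backward(y[iu1, iu2], tiny_psf.h, iu1, iu2)
                fp = sum(
                    direct_conv_same(x[:, :, iz], tiny_psf.h[iu1, iu2, :, :, iz])
                    for iz in range(nz)
                )
                den += w[iu1, iu2] * direct_backward(fp, tiny_psf.h, iu1, iu2)
        oracle = x * num / np.maximum(den, 1e-10 * den.max())
        from lfdeconv import PhaseSpaceMeasurement

        got = rl_update_full(
            Volume(x, tiny_cfg.z_planes),
            PhaseSpaceMeasurement(y, tiny_cfg.n_u),
            tiny_psf,
        )
        assert np.abs(got.g - oracle).max() <= 1e-5 * oracle.max()

    def test_subset_update_matches_spatial_oracle(self, tiny_psf, tiny_cfg):
        """Merged pair update: Y' = Y_u1 + Y_u2, H' = H_u1 + H_u2, single
        ratio of backprojections — verified against direct convolutions."""
        from lfdeconv import PhaseSpaceMeasurement

        rng = np.random.default_rng(31)
        nz = tiny_cfg.n_z
        x = rng.random((12, 12, nz)) + 0.1
        truth = rng.random((12, 12, nz))
        y = direct_forward(truth, tiny_psf.h)
        pair = (1, 7)  # flat indices into the 3x3 angle grid
        nu = tiny_cfg.n_u
        (a1, b1), (a2, b2) = divmod(pair[0], nu), divmod(pair[1], nu)
        y_merged = y[a1, b1] + y[a2, b2]
        h_merged = tiny_psf.h[a1, b1] + tiny_psf.h[a2, b2]  # (nx, nx, nz)
        fp = sum(
            direct_conv_same(x[:, :, iz], h_merged[:, :, iz]) for iz in range(nz)
        )
        num = np.stack(
            [direct_corr_same(y_merged, h_merged[:, :, iz]) for iz in range(nz)], axis=2
        )
        den = np.stack(
            [direct_corr_same(fp, h_merged[:, :, iz]) for iz in range(nz)], axis=2
        )
        oracle = x * num / np.maximum(den, 1e-10 * den.max())
        got = rl_update_subset(
            Volume(x, tiny_cfg.z_planes),
            PhaseSpaceMeasurement(y, tiny_cfg.n_u),
            tiny_psf,
            pair,
        )
        assert np.abs(got.g - oracle).max() <= 1e-5 * oracle.max()

    def test_empty_group_rejected(self, small_psf, small_cfg):
        x = Volume(np.ones((8, 8, small_cfg.n_z)), small_cfg.z_planes)
        y = forward_project(x, small_psf)
        with pytest.raises(ValueError):
            rl_update_subset(x, y, small_psf, ())


class TestSubsetSchedule:
    def test_partition_property_small(self):
        s = make_subset_schedule(4, n_iter=3, seed=0)
        for groups in s.epochs:
            assert len(groups) == 2
            assert sorted(a for g in groups for a in g) == [0, 1, 2, 3]

    def test_odd_angle_count_gives_singleton(self):
        s = make_subset_schedule(169, n_iter=2, seed=1)
        for groups in s.epochs:
            assert len(groups) == 85  # 84 pairs + 1 singleton
            sizes = sorted(len(g) for g in groups)
            assert sizes == [1] + [2] * 84

    def test_seed_reproducibility_and_epoch_variety(self):
        a = make_subset_schedule(25, 4, seed=5)
        b = make_subset_schedule(25, 4, seed=5)
        assert a.epochs == b.epochs
        assert len({tuple(map(tuple, ep)) for ep in a.epochs}) > 1

    def test_group_size_generalisation(self):
        s = make_subset_schedule(169, 1, seed=2, group_size=20)
        sizes = [len(g) for g in s.epochs[0]]
        assert sum(sizes) == 169 and max(sizes) == 20 and sizes[-1] == 9


class TestTVStep:
    def test_zero_alpha_is_identity(self):
        rng = np.random.default_rng(37)
        x = rng.random((6, 6, 4))
        assert np.array_equal(tv_step(x, alpha=0.0, k_tv=1), x)

    def test_constant_volume_is_fixed_point(self):
        x = np.full((5, 5, 5), 2.0)
        out = tv_step(x, alpha=3.0, k_tv=2)
        assert np.array_equal(out, x)

    def test_gradient_matches_finite_differences(self):
        """TV gradient on a 3x3x3 impulse vs central finite differences of
        the smoothed functional."""
        delta = 1e-2
        x = np.zeros((3, 3, 3))
        x[1, 1, 1] = 1.0

        def tv_value(v):
            d1 = np.zeros_like(v)
            d2 = np.zeros_like(v)
            d3 = np.zeros_like(v)
            d1[:-1] = v[1:] - v[:-1]
            d2[:, :-1] = v[:, 1:] - v[:, :-1]
            d3[:, :, :-1] = v[:, :, 1:] - v[:, :, :-1]
            return np.sum(np.sqrt(d1**2 + d2**2 + d3**2 + delta**2))

        grad = tv_gradient(x, delta)
        h = 1e-6
        fd = np.zeros_like(x)
        for idx in np.ndindex(x.shape):
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            fd[idx] = (tv_value(xp) - tv_value(xm)) / (2 * h)
        assert np.abs(grad - fd).max() <= 1e-6

    def test_step_is_normalised_descent_with_clipping(self):
        delta = 1e-2
        x = np.zeros((3, 3, 3))
        x[1, 1, 1] = 10.0  # large value: no clipping at the impulse
        v = tv_gradient(x, 1e-8)
        expected = np.clip(x - 3.0 * v / np.linalg.norm(v), 0.0, None)
        out = tv_step(x, alpha=3.0, k_tv=1)
        assert np.allclose(out, expected, atol=1e-12)
        assert np.all(out >= 0)

    def test_volume_type_preserved(self):
        vol = Volume(np.ones((4, 4, 3)), np.array([-1.0, 0.0, 1.0]))
        out = tv_step(vol, alpha=1.0, k_tv=1)
        assert isinstance(out, Volume)
        assert np.array_equal(out.z_planes, vol.z_planes)


class TestReconstruct:
    def test_impulse_recovery_subset_mode(self, impulse_problem, small_psf):
        vol, y = impulse_problem
        res = reconstruct(
            y, small_psf, DeconvConfig(n_iter=5, mode="subset_pairs", seed=1)
        )
        am = np.unravel_index(np.argmax(res.volume.g), res.volume.g.shape)
        assert abs(am[0] - 8) <= 1 and abs(am[1] - 7) <= 1 and abs(am[2] - 2) <= 1

    def test_metrics_one_row_per_epoch(self, impulse_problem, small_psf):
        vol, y = impulse_problem
        res = reconstruct(y, small_psf, DeconvConfig(n_iter=3, seed=0), reference=vol)
        m = res.per_iteration_metrics
        assert isinstance(m, pd.DataFrame) and len(m) == 3
        assert list(m["iteration"]) == [1, 2, 3]
        assert np.all(np.isfinite(m["ssim"]))

    def test_deterministic_for_fixed_seed(self, impulse_problem, small_psf):
        _, y = impulse_problem
        cfg = DeconvConfig(n_iter=3, mode="subset_pairs", seed=7)
        r1 = reconstruct(y, small_psf, cfg)
        r2 = reconstruct(y, small_psf, cfg)
        assert np.array_equal(r1.volume.g, r2.volume.g)
        assert r1.schedule.epochs == r2.schedule.epochs
        pd.testing.assert_frame_equal(r1.per_iteration_metrics, r2.per_iteration_metrics)

    def test_mle_nll_nonincreasing_noise_free(self, impulse_problem, small_psf):
        """Empirical data-fit monotonicity of the all-angle update on the
        noise-free fixture (TV disabled: the regulariser trades fit for
        smoothness by design)."""
        _, y = impulse_problem
        res = reconstruct(
            y, small_psf, DeconvConfig(n_iter=6, mode="mle_all_angles", alpha=0.0, k_tv=0)
        )
        nll = res.per_iteration_metrics["nll"].to_numpy()
        assert np.all(np.diff(nll) <= 1e-8 * np.abs(nll[:-1]))

    def test_single_angle_mode_runs(self, impulse_problem, small_psf):
        _, y = impulse_problem
        res = reconstruct(
            y, small_psf, DeconvConfig(n_iter=2, mode="single_angle", alpha=0.0, k_tv=0)
        )
        assert np.all(res.volume.g >= 0)

    def test_upsample_scaffold_not_implemented(self, impulse_problem, small_psf):
        _, y = impulse_problem
        with pytest.raises(NotImplementedError):
            reconstruct(y, small_psf, DeconvConfig(upsample=2))

    def test_model_fit_summary(self, impulse_problem, small_psf):
        vol, y = impulse_problem
        model = PhaseSpaceDeconvolution(y, small_psf)
        res = model.fit(n_iter=2, seed=3, reference=None)
        text = res.summary()
        assert "subset_pairs" in text and "epochs" in text

    def test_mismatched_views_rejected(self, small_psf):
        from lfdeconv import PhaseSpaceMeasurement

        bad = PhaseSpaceMeasurement(np.ones((3, 3, 8, 8)), pitch_px=3)
        with pytest.raises(ValueError, match="views"):
            PhaseSpaceDeconvolution(bad, small_psf)


class TestComplexityScaling:
    def test_fourier_path_op_growth(self, small_psf, small_cfg):
        """Measured operation counts of one full-angle FP+BP pass grow like
        N^2 log N in the lateral size, while the direct spatial-convolution
        model keeps its PSF-footprint factor."""
        counts = {}
        for n in (32, 64, 128):
            proj = FourierProjector(small_psf, (n, n))
            g = np.ones((n, n, small_cfg.n_z))
            ghat = proj.ghat(g)
            for a in range(small_psf.n_angles):
                fp = proj.fp_from_ghat(ghat, proj.hhat(a))
                proj.bp(fp, proj.hhat(a))
            counts[n] = proj.op_count
        for n in (32, 64):
            measured_ratio = counts[2 * n] / counts[n]
            nlogn_ratio = (2 * n) ** 2 * np.log(2 * n) / (n**2 * np.log(n))
            assert measured_ratio <= 1.25 * nlogn_ratio
        # spatial model: quadratic in N with the full PSF-footprint burden
        npsf_px = small_cfg.n_x_psf
        for n in (32, 64, 128):
            spatial = direct_conv_op_count((n, n), npsf_px, small_cfg.n_z, 25)
            assert spatial >= n * n * npsf_px**2 * small_cfg.n_z * 25
            assert spatial > counts[n] / np.log2(n)  # footprint factor dominates
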