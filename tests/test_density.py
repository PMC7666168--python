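import numpy as np
import pytest

from tubeflex import (DensityMap, FSCCurve, FscFitResults, bootstrap_replicates,
                      compute_fsc, fit_fsc_sigmoid, isosurface_variance,
                      lowpass_filter, make_half_maps, make_monomer, render_map,
                      resolution_at, sharpen_map)
from tubeflex.density import _bisect_resolution, _sigmoid, read_mrc, write_mrc


class TestRenderMap:
    def test_empty_model_is_zero(self):
        m = render_map(np.zeros((0, 3)), 1.0, (8, 8, 8))
        assert np.all(m.grid == 0)

    def test_single_atom_peak_at_center_and_symmetric(self):
        m = render_map([[8.0, 8.0, 8.0]], 1.0, (17, 17, 17), atom_sigma=1.5)
        assert np.unravel_index(m.grid.argmax(), m.grid.shape) == (8, 8, 8)
        assert np.allclose(m.grid, m.grid[::-1, :, :], atol=1e-12)
        assert np.allclose(m.grid, np.transpose(m.grid, (2, 0, 1)), atol=1e-12)

    def test_integral_matches_gaussian_normalisation(self):
        sigma, voxel = 1.2, 0.8
        m = render_map([[12.0, 12.0, 12.0], [10.0, 12.0, 14.0]], voxel,
                       (30, 30, 30), atom_sigma=sigma)
        expected = 2 * (2 * np.pi) ** 1.5 * sigma**3 / voxel**3
        assert m.grid.sum() == pytest.approx(expected, rel=1e-3)

    def test_linear_in_atoms(self):
        a = render_map([[5.0, 5.0, 5.0]], 1.0, (12, 12, 12))
        b = render_map([[7.0, 5.0, 5.0]], 1.0, (12, 12, 12))
        both = render_map([[5.0, 5.0, 5.0], [7.0, 5.0, 5.0]], 1.0, (12, 12, 12))
        assert np.allclose(both.grid, a.grid + b.grid, atol=1e-12)

    def test_atom_outside_box_lists_offenders(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            render_map([[5.0, 5.0, 5.0], [99.0, 5.0, 5.0]], 1.0, (12, 12, 12))


class TestFilters:
    @pytest.fixture
    def noise_map(self):
        # voxel 1.25 A: B = +/-150 A^2 then amplifies Nyquist shells by ~1e8,
        # the round trip is identity to well under 1e-8
        rng = np.random.default_rng(0)
        return DensityMap(rng.normal(size=(24, 24, 24)), 1.25)

    def test_zero_bfactor_is_identity(self, noise_map):
        out = sharpen_map(noise_map, 0.0)
        assert np.allclose(out.grid, noise_map.grid, atol=1e-10)

    def test_sharpen_blur_round_trip(self, noise_map):
        out = sharpen_map(sharpen_map(noise_map, -150.0), 150.0)
        assert np.abs(out.grid - noise_map.grid).max() < 1e-8

    def test_constant_map_unchanged_by_lowpass(self):
        m = DensityMap(np.full((16, 16, 16), 3.7), 1.0)
        out = lowpass_filter(m, 5.0)
        assert np.allclose(out.grid, 3.7, atol=1e-10)

    def test_sinusoid_above_cutoff_suppressed(self):
        n = 32
        x = np.arange(n)
        sin = (np.sin(2 * np.pi * x * 10 / n)[:, None, None]
               * np.ones((1, n, n)))
        m = DensityMap(sin, 1.0)
        out = lowpass_filter(m, 4.0)  # sinusoid at 0.3125 1/A > 0.25 1/A
        assert np.abs(out.grid).max() < 0.01 * np.abs(m.grid).max()

    def test_cutoff_below_nyquist_rejected(self, noise_map):
        with pytest.raises(ValueError):
            lowpass_filter(noise_map, 2.0)


class TestFSC:
    def test_identical_maps_give_unit_fsc(self):
        rng = np.random.default_rng(1)
        m = DensityMap(rng.normal(size=(20, 20, 20)), 1.0)
        curve = compute_fsc(m, m)
        assert np.allclose(curve.correlations, 1.0, atol=1e-10)

    def test_independent_noise_decorrelates(self):
        rng = np.random.default_rng(2)
        a = DensityMap(rng.normal(size=(32, 32, 32)), 1.0)
        b = DensityMap(rng.normal(size=(32, 32, 32)), 1.0)
        curve = compute_fsc(a, b)
        assert np.all(np.abs(curve.correlations[2:]) < 0.1)

    def test_symmetric_in_arguments(self):
        mono = make_monomer(12, 14.0, seed=3)
        h1, h2 = make_half_maps(mono, 1.5, noise_sigma=0.05, n_replicates=2,
                                seed=4)
        c12 = compute_fsc(h1, h2)
        c21 = compute_fsc(h2, h1)
        assert np.allclose(c12.correlations, c21.correlations, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        a = DensityMap(np.zeros((8, 8, 8)) + 1, 1.0)
        b = DensityMap(np.zeros((10, 10, 10)) + 1, 1.0)
        with pytest.raises(ValueError):
            compute_fsc(a, b)


class TestFscSigmoid:
    PAPER_FIT = dict(A=0.122, B=0.015, C=0.228)

    def _curve(self, **kw):
        x = np.linspace(0.005, 0.5, 80)
        return FSCCurve(x, _sigmoid(x, kw["A"], kw["B"], kw["C"]))

    def test_self_consistency_recovery(self):
        fit = fit_fsc_sigmoid(self._curve(**self.PAPER_FIT))
        assert fit.A == pytest.approx(0.122, rel=1e-6)
        assert fit.B == pytest.approx(0.015, rel=1e-6)
        assert fit.C == pytest.approx(0.228, rel=1e-6)

    def test_step_like_curve_flagged_narrow(self):
        x = np.linspace(0.01, 0.5, 40)
        y = np.where(x < 0.25, 1.0, 0.0)
        fit = fit_fsc_sigmoid(FSCCurve(x, y))
        assert fit.B < np.min(np.diff(x)) or "width below shell spacing" in fit.flags

    def test_invariant_to_duplicating_points(self):
        c = self._curve(**self.PAPER_FIT)
        fit1 = fit_fsc_sigmoid(c)
        x2 = np.sort(np.concatenate([c.frequencies, c.frequencies + 1e-9]))
        fit2 = fit_fsc_sigmoid(FSCCurve(x2, _sigmoid(x2, 0.122, 0.015, 0.228)))
        assert fit2.A == pytest.approx(fit1.A, rel=1e-6)
        assert fit2.C == pytest.approx(fit1.C, rel=1e-6)

    def test_resolution_at_criterion(self):
        fit = FscFitResults(residual=0.0, **self.PAPER_FIT)
        assert round(resolution_at(fit, 0.143), 1) == 4.0

    def test_closed_form_matches_bisection(self):
        fit = FscFitResults(residual=0.0, **self.PAPER_FIT)
        for t in (0.143, 0.5, 0.8):
            assert resolution_at(fit, t) == pytest.approx(
                _bisect_resolution(fit, t), rel=1e-10)

    def test_resolution_monotone_in_threshold(self):
        fit = FscFitResults(residual=0.0, **self.PAPER_FIT)
        # lower criterion -> finer (smaller) resolution
        assert resolution_at(fit, 0.143) < resolution_at(fit, 0.5)

    def test_raw_curve_crossing_interpolated(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        y = np.array([1.0, 0.8, 0.5, 0.2, 0.0])
        # exact crossing at a shell center
        assert resolution_at(FSCCurve(x, y), 0.5) == pytest.approx(1 / 0.3)
        # interpolated crossing halfway between shells
        assert resolution_at(FSCCurve(x, y), 0.35) == pytest.approx(1 / 0.35)

    def test_no_crossing_rejected(self):
        x = np.linspace(0.01, 0.3, 10)
        with pytest.raises(ValueError):
            resolution_at(FSCCurve(x, np.full(10, 0.9)), 0.143)
        fit = FscFitResults(residual=0.0, **self.PAPER_FIT)
        with pytest.raises(ValueError):
            resolution_at(fit, 1.5)


class TestBootstrapAndVariance:
    def test_identical_members_give_identical_replicates(self):
        m = DensityMap(np.ones((8, 8, 8)), 1.0)
        reps = bootstrap_replicates([m.copy(), m.copy(), m.copy()], n_boot=5,
                                    seed=0)
        for r in reps:
            assert np.array_equal(r.grid, m.grid)

    def test_replicate_mean_approaches_member_mean(self):
        rng = np.random.default_rng(3)
        members = [DensityMap(rng.normal(size=(6, 6, 6)), 1.0)
                   for _ in range(12)]
        reps = bootstrap_replicates(members, n_boot=400, seed=1)
        boot_mean = np.mean(np.stack([r.grid for r in reps]), axis=0)
        member_mean = np.mean(np.stack([m.grid for m in members]), axis=0)
        assert np.abs(boot_mean - member_mean).max() < 0.15

    def test_default_boot_count_is_300(self):
        import inspect

        assert inspect.signature(bootstrap_replicates).parameters[
            "n_boot"].default == 300

    def test_identical_replicates_give_zero_variance(self):
        mono = make_monomer(10, 12.0, seed=5)
        maps = make_half_maps(mono, 2.0, n_replicates=4, seed=6)
        var = isosurface_variance(maps, threshold=0.162)
        assert np.all(var.grid == 0.0)

    def test_variance_localises_at_jittered_isosurface(self, two_blob_positions):
        from types import SimpleNamespace

        model = SimpleNamespace(positions=two_blob_positions)
        members = make_half_maps(model, 2.0, jitter=2.0, n_replicates=10,
                                 seed=4, jitter_selection=np.arange(10),
                                 atom_sigma=2.5)
        reps = bootstrap_replicates(members, n_boot=50, seed=5)
        var = isosurface_variance(reps, threshold=0.162, lowpass=8.0,
                                  smooth_sigma=2.0)
        # reference isosurface of the unjittered first blob alone
        blob_map = make_half_maps(
            SimpleNamespace(positions=two_blob_positions[:10]), 2.0,
            n_replicates=2, seed=0, atom_sigma=2.5)[0]
        blob_lp = lowpass_filter(blob_map, 8.0)
        # embed the blob-only isosurface into the full grid frame
        ijk_max = np.array(np.unravel_index(var.grid.argmax(), var.grid.shape))
        pos_max = ijk_max * 2.0 + var.origin
        iso = np.argwhere(np.abs(blob_lp.grid - 0.162)
                          < 0.3 * blob_lp.grid.max())
        iso_pos = iso * 2.0 + blob_lp.origin
        dmin = np.min(np.linalg.norm(iso_pos - pos_max, axis=1))
        assert dmin <= 2 * 2.0  # within 2 voxels of the isosurface
        # static blob stays quiet: variance near its centre ~ 0
        centre_b = two_blob_positions[10:].mean(axis=0)
        idx_b = np.round((centre_b - var.origin) / 2.0).astype(int)
        assert var.grid[tuple(idx_b)] < 0.05 * var.grid.max()

    def test_threshold_outside_range_rejected(self):
        maps = [DensityMap(np.zeros((8, 8, 8)), 1.0) for _ in range(2)]
        with pytest.raises(ValueError):
            isosurface_variance(maps, threshold=5.0, lowpass=None)

    def test_permutation_invariance(self):
        mono = make_monomer(12, 14.0, seed=8)
        maps = make_half_maps(mono, 2.0, jitter=1.0, n_replicates=6, seed=9,
                              jitter_selection=np.arange(3))
        a = isosurface_variance(maps, threshold=0.162)
        b = isosurface_variance(maps[::-1], threshold=0.162)
        assert np.allclose(a.grid, b.grid, atol=1e-14)


def test_mrc_round_trip(tmp_path):
    rng = np.random.default_rng(4)
    m = DensityMap(rng.normal(size=(8, 10, 12)), 1.25, np.array([3.0, -2.0, 1.5]))
    write_mrc(m, tmp_path / "t.mrc")
    back = read_mrc(tmp_path / "t.mrc")
    assert back.voxel_size == pytest.approx(1.25, rel=1e-6)
    assert np.allclose(back.origin, m.origin)
    assert np.abs(back.grid - m.grid).max() < 1e-5  # float32 storage
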