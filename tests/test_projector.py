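"""Projector physics: resolution model, attenuation, counting statistics."""

import numpy as np
import pytest
from scipy import stats

from lu177planar import phantoms as ph
from lu177planar import projector as pr


def point_phantom(activity=1.0, depth_index=10, n=48, ny=24, mu=0.0,
                  voxel=2.2):
    act = np.zeros((n, ny, n))
    act[n // 2, depth_index, n // 2] = activity
    att = np.full_like(act, mu)
    return ph.VoxelPhantom(act, att, (voxel, voxel, voxel), "point")


class TestSystemFwhm:
    def test_reference_depth_calibration(self):
        sc = pr.ScannerModel()
        assert pr.system_fwhm(100.0, sc) == pytest.approx(9.4, abs=1e-12)

    def test_monotone_in_depth(self):
        sc = pr.ScannerModel()
        depths = np.linspace(0, 400, 50)
        r = pr.system_fwhm(depths, sc)
        assert np.all(np.diff(r) > 0)

    def test_depth_zero_closed_form(self):
        sc = pr.ScannerModel()
        expect = np.sqrt(sc.intrinsic_fwhm**2 + sc.collimator.d_eff**2)
        assert pr.system_fwhm(0.0, sc) == pytest.approx(expect, rel=1e-12)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            pr.system_fwhm(-1.0, pr.ScannerModel())


class TestProjectExpected:
    def test_zero_activity_gives_zero_image(self):
        p = point_phantom(activity=0.0)
        img = pr.project_expected(p, pr.ScannerModel(matrix=(48, 48)))
        assert img.total == 0.0

    def test_point_source_sum_is_sensitivity_times_time(self):
        # A MBq * 65 cps/MBq * 300 s, any depth, in air
        sc = pr.ScannerModel(matrix=(48, 48))
        for a in (0.5, 2.0):
            img = pr.project_expected(point_phantom(activity=a), sc)
            assert img.total == pytest.approx(a * 65.0 * 300.0, rel=1e-6)

    def test_attenuation_reduces_by_beer_lambert(self):
        sc = pr.ScannerModel(matrix=(48, 48))
        mu = ph.MU_WATER_208KEV
        depth_index = 10
        p = point_phantom(activity=1.0, depth_index=depth_index, mu=mu)
        img = pr.project_expected(p, sc)
        # water path from slab centre to the camera face
        d = (depth_index + 0.5) * 2.2
        expect = 65.0 * 300.0 * np.exp(-mu * d)
        assert img.total == pytest.approx(expect, rel=1e-6)

    def test_linearity_in_activity(self, rng):
        sc = pr.ScannerModel(matrix=(32, 32))
        act1 = rng.random((32, 8, 32))
        act2 = rng.random((32, 8, 32))
        att = np.full((32, 8, 32), 0.01)
        mk = lambda a: ph.VoxelPhantom(a, att, (2.2, 2.2, 2.2))
        img1 = pr.project_expected(mk(act1), sc).values
        img2 = pr.project_expected(mk(act2), sc).values
        img12 = pr.project_expected(mk(2 * act1 + 3 * act2), sc).values
        np.testing.assert_allclose(img12, 2 * img1 + 3 * img2, atol=1e-9)

    def test_point_source_fwhm_recovered_at_reference_depth(self):
        sc = pr.ScannerModel(matrix=(64, 64))
        p = point_phantom(depth_index=10, n=64)
        standoff = 100.0 - 10.5 * 2.2
        img = pr.project_expected(p, sc, standoff=standoff)
        fwhm = pr.fit_point_fwhm(img.values, sc.pixel_size)
        assert fwhm == pytest.approx(9.4, abs=0.2)

    def test_posterior_is_mirrored_and_attenuated_from_far_side(self):
        sc = pr.ScannerModel(matrix=(32, 32))
        act = np.zeros((32, 10, 32))
        act[8, 1, 16] = 1.0  # near anterior face, off-centre in x
        att = np.full_like(act, 0.01)
        p = ph.VoxelPhantom(act, att, (2.2, 2.2, 2.2))
        ant = pr.project_expected(p, sc, "anterior")
        post = pr.project_expected(p, sc, "posterior")
        assert ant.total > post.total  # deeper for the posterior head
        ai = np.unravel_index(np.argmax(ant.values), ant.values.shape)
        pi = np.unravel_index(np.argmax(post.values), post.values.shape)
        assert ai[1] == pi[1]
        assert pi[0] == ant.values.shape[0] - 1 - ai[0]  # mirrored in x

    def test_oversized_phantom_requires_crop_flag(self):
        p = point_phantom(n=48)
        sc = pr.ScannerModel(matrix=(32, 32))
        with pytest.raises(ValueError, match="crop"):
            pr.project_expected(p, sc)
        img = pr.project_expected(p, sc, crop=True)
        assert img.values.shape == (32, 32)


class TestSampling:
    def test_zero_expected_gives_zero_counts(self):
        img = pr.ExpectedImage(np.zeros((8, 8)), "anterior", 2.2, 300.0)
        c = pr.sample_counts(img, seed=0)
        assert c.total == 0

    def test_poisson_mean_within_tail_bound(self):
        img = pr.ExpectedImage(np.full((1, 1), 1e4), "anterior", 2.2, 300.0)
        c = pr.sample_counts(img, seed=1)
        assert abs(c.total - 1e4) < 4 * 100  # 4 sigma

    def test_poisson_variance_to_mean(self):
        # 10^4 repeated draws at one pixel: var/mean in [0.9, 1.1]
        img = pr.ExpectedImage(np.full((100, 100), 25.0), "anterior", 2.2,
                               300.0)
        c = pr.sample_counts(img, seed=2).counts.ravel()
        assert 0.9 < c.var() / c.mean() < 1.1

    def test_sampling_deterministic(self):
        img = pr.ExpectedImage(np.full((16, 16), 50.0), "anterior", 2.2,
                               300.0)
        a = pr.sample_counts(img, seed=3).counts
        b = pr.sample_counts(img, seed=3).counts
        np.testing.assert_array_equal(a, b)


class TestThinning:
    def make_counts(self, mean=50.0, shape=(32, 32), seed=0):
        img = pr.ExpectedImage(np.full(shape, mean), "anterior", 2.2, 300.0)
        return pr.sample_counts(img, seed=seed)

    def test_identity_at_current_fraction(self):
        c = self.make_counts()
        t = pr.thin_counts(c, 1.0, seed=0)
        np.testing.assert_array_equal(t.counts, c.counts)

    def test_fraction_above_current_rejected(self):
        c = self.make_counts()
        half = pr.thin_counts(c, 0.5, seed=0)
        with pytest.raises(ValueError):
            pr.thin_counts(half, 0.8, seed=0)

    def test_expected_total_binomial(self):
        c = self.make_counts(mean=100.0, shape=(16, 16))
        n = c.total
        totals = [pr.thin_counts(c, 0.3, seed=s).total for s in range(200)]
        se = np.sqrt(n * 0.3 * 0.7 / 200)
        assert abs(np.mean(totals) - 0.3 * n) < 4 * se

    def test_thinned_poisson_is_poisson_with_scaled_mean(self):
        # chi-square goodness of fit on 1e4 thinned draws at mean 5
        full = pr.sample_counts(
            pr.ExpectedImage(np.full((100, 100), 10.0), "anterior", 2.2,
                             300.0), seed=4)
        thin = pr.thin_counts(full, 0.5, seed=5).counts.ravel()
        kmax = 14
        obs = np.bincount(np.minimum(thin, kmax), minlength=kmax + 1)
        pmf = stats.poisson.pmf(np.arange(kmax), 5.0)
        probs = np.append(pmf, 1.0 - pmf.sum())
        res = stats.chisquare(obs, probs * thin.size)
        assert res.pvalue > 0.001


class TestSimulateScan:
    def test_output_structure_and_nesting(self):
        p = point_phantom(activity=5.0, n=32, ny=8, depth_index=4)
        sc = pr.ScannerModel(matrix=(32, 32))
        out = pr.simulate_scan(p, sc, (0.3, 0.5, 0.9), seed=0)
        assert set(out) == {"anterior", "posterior"}
        series = out["anterior"]
        assert set(series) == {1.0, 0.9, 0.5, 0.3}
        assert np.all(series[0.3].counts <= series[0.5].counts)
        assert np.all(series[0.5].counts <= series[0.9].counts)
        assert np.all(series[0.9].counts <= series[1.0].counts)

    def test_thinned_total_tracks_fraction(self):
        p = point_phantom(activity=5.0, n=32, ny=8, depth_index=4)
        sc = pr.ScannerModel(matrix=(32, 32))
        series = pr.simulate_scan(p, sc, (0.3,), seed=1)["anterior"]
        n = series[1.0].total
        sd = np.sqrt(n * 0.3 * 0.7)
        assert abs(series[0.3].total - 0.3 * n) < 4 * sd

    def test_deterministic_under_seed(self):
        p = point_phantom(activity=2.0, n=32, ny=8, depth_index=4)
        sc = pr.ScannerModel(matrix=(32, 32))
        a = pr.simulate_scan(p, sc, (0.5,), seed=9)
        b = pr.simulate_scan(p, sc, (0.5,), seed=9)
        for view in a:
            for f in a[view]:
                np.testing.assert_array_equal(a[view][f].counts,
                                              b[view][f].counts)
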