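"""ROI segmentation and significance statistics."""

import numpy as np
import pytest
from scipy import integrate, special

from lu177planar import phantoms as ph
from lu177planar import roistats as rs


def otsu_bruteforce(image, nbins=256):
    """Exhaustive search over histogram split points, maximizing
    between-class variance computed directly per candidate."""
    image = np.asarray(image, dtype=float).ravel()
    hist, edges = np.histogram(image, bins=nbins,
                               range=(image.min(), image.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best, best_var = None, -1.0
    for i in range(nbins - 1):
        w0 = hist[:i + 1].sum()
        w1 = hist[i + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:i + 1] * centers[:i + 1]).sum() / w0
        mu1 = (hist[i + 1:] * centers[i + 1:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_var:
            best_var, best = v, centers[i]
    return best


class TestOtsu:
    def test_two_level_image_threshold_between(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 100.0
        t = rs.otsu_threshold(img)
        assert 0.0 < t < 100.0

    def test_matches_exhaustive_search_on_random_images(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            img = rng.integers(0, 256, (24, 24)).astype(float)
            assert rs.otsu_threshold(img) == pytest.approx(
                otsu_bruteforce(img), abs=1e-9)

    def test_matches_skimage(self):
        from skimage.filters import threshold_otsu
        rng = np.random.default_rng(8)
        img = np.concatenate([rng.normal(20, 5, 500),
                              rng.normal(80, 10, 500)])
        ours = rs.otsu_threshold(img)
        theirs = threshold_otsu(img, nbins=256)
        assert ours == pytest.approx(theirs, abs=(img.max() - img.min())
                                     / 256)

    def test_shift_invariance_up_to_binning(self):
        rng = np.random.default_rng(9)
        img = rng.integers(0, 100, (16, 16)).astype(float)
        t0 = rs.otsu_threshold(img)
        t1 = rs.otsu_threshold(img + 37.5)
        assert t1 - t0 == pytest.approx(37.5, abs=1e-9)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            rs.otsu_threshold(np.full((5, 5), 3.0))


@pytest.fixture(scope="module")
def derenzo_scene():
    from lu177planar import projector as pr
    phantom, labels = ph.make_derenzo()
    scanner = pr.ScannerModel(matrix=(160, 160))
    expected = pr.project_expected(phantom, scanner)
    full = pr.sample_counts(expected, seed=0)
    proj = rs.project_labels(labels, voxel_dy=phantom.voxel_size[1])
    proj = {n: rs.embed_mask(m > 0, scanner.matrix).astype(float)
            for n, m in proj.items()}
    return full, proj


class TestRodRois:
    def test_six_disjoint_masks(self, derenzo_scene):
        full, proj = derenzo_scene
        rois = rs.rod_rois(full.counts, proj)
        assert len(rois) == 6
        overlap = np.zeros(full.counts.shape, dtype=int)
        for r in rois:
            overlap += r.mask
        assert overlap.max() == 1

    def test_mask_area_grows_with_diameter(self, derenzo_scene):
        full, proj = derenzo_scene
        rois = {r.name: r.n for r in rs.rod_rois(full.counts, proj)}
        areas = [rois[f"rod_{d:g}mm"] for d in (10, 13, 17, 22, 28, 33)]
        assert areas == sorted(areas)


class TestOrganRois:
    def test_four_masks_inside_body(self):
        phantom, labels = ph.make_anthropomorphic(tac=ph.default_tac())
        rois = rs.organ_rois(labels, voxel_dy=phantom.voxel_size[1])
        assert len(rois) == 4
        body = (phantom.attenuation > 0).any(axis=1)
        for r in rois:
            assert not (r.mask & ~body).any()

    def test_liver_larger_than_kidneys(self):
        phantom, labels = ph.make_anthropomorphic(tac=ph.default_tac())
        rois = {r.name: r.n
                for r in rs.organ_rois(labels,
                                       voxel_dy=phantom.voxel_size[1])}
        assert rois["liver"] > rois["right_kidney"]
        assert rois["liver"] > rois["left_kidney"]


class TestRoiSummary:
    def test_constant_region(self):
        img = np.full((4, 4), 7.0)
        roi = rs.RoiMask(np.ones((4, 4), bool), "all")
        assert rs.roi_summary(img, roi) == (7.0, 0.0, 16)

    def test_hand_computed_four_pixvalues(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        roi = rs.RoiMask(np.ones((2, 2), bool), "all")
        mean, sd, n = rs.roi_summary(img, roi)
        assert (mean, n) == (2.5, 4)
        assert sd == pytest.approx(1.2910, abs=5e-5)


def t_pvalue_by_integration(t_stat, df):
    """Two-sided p by numeric integration of the t density."""
    norm = special.gamma((df + 1) / 2) / (np.sqrt(df * np.pi)
                                          * special.gamma(df / 2))
    pdf = lambda u: norm * (1 + u * u / df) ** (-(df + 1) / 2)
    tail, _ = integrate.quad(pdf, abs(t_stat), np.inf)
    return 2.0 * tail


class TestTTest:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        t, df, p = rs.two_sample_ttest(x, x.copy())
        assert t == 0.0 and p == 1.0

    def test_swap_flips_sign_keeps_p(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 25)
        t1, _, p1 = rs.two_sample_ttest(x, y)
        t2, _, p2 = rs.two_sample_ttest(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_p_matches_numeric_integration(self, rng):
        for _ in range(5):
            x = rng.normal(0, 1, 20)
            y = rng.normal(0.7, 1.3, 24)
            t, df, p = rs.two_sample_ttest(x, y)
            assert p == pytest.approx(t_pvalue_by_integration(t, df),
                                      abs=1e-6)

    def test_textbook_pooled_statistic(self):
        # pooled-variance two-sample t computed by hand
        x = np.array([5.0, 6.0, 7.0, 8.0])
        y = np.array([1.0, 2.0, 3.0])
        sp2 = (3 * np.var(x, ddof=1) + 2 * np.var(y, ddof=1)) / 5
        expect = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 3))
        t, df, _ = rs.two_sample_ttest(x, y)
        assert df == 5
        assert t == pytest.approx(expect, rel=1e-12)

    def test_zero_variance_equal_means_convention(self):
        x = np.full(5, 2.0)
        t, df, p = rs.two_sample_ttest(x, x.copy())
        assert (t, p) == (0.0, 1.0)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            rs.two_sample_ttest([1.0], [1.0, 2.0])


class TestPercentDifference:
    @pytest.mark.parametrize("ref,test,expect", [
        (57.96, 55.32, 4.55),   # 10 mm rods, 5:1, 30%-count output
        (74.95, 70.82, 5.51),   # 10 mm rods, 20:1, 30%-count output
        (57.96, 56.47, 2.57),   # 10 mm rods, 5:1, 50%-count output
        (74.95, 72.25, 3.60),   # 10 mm rods, 20:1, 50%-count output
    ])
    def test_reported_rod_differences(self, ref, test, expect):
        assert rs.percent_difference(ref, test) == expect

    def test_equal_means_zero(self):
        assert rs.percent_difference(10.0, 10.0) == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            rs.percent_difference(0.0, 1.0)


class TestSignificanceTable:
    def test_self_comparison_never_significant(self, rng):
        img = rng.integers(10, 40, (32, 32)).astype(float)
        roi = rs.RoiMask(img > 20, "hot")
        df = rs.significance_table(img, {"same": img.copy()}, [roi])
        row = df[df.image_id == "same"].iloc[0]
        assert row.p == 1.0 and not row.significant

    def test_row_count(self, rng):
        img = rng.integers(10, 40, (32, 32)).astype(float)
        rois = [rs.RoiMask(img > 20, "hot"), rs.RoiMask(img <= 20, "cold")]
        tests = {"a": img + 1, "b": img + 2, "c": img + 3}
        df = rs.significance_table(img, tests, rois)
        assert len(df) == len(rois) * (len(tests) + 1)

    def test_scaled_image_detected(self, rng):
        lam = np.full((40, 40), 100.0)
        img = rng.poisson(lam).astype(float)
        thin = rng.binomial(img.astype(int), 0.1).astype(float)
        roi = rs.RoiMask(np.ones_like(img, bool), "all")
        df = rs.significance_table(img, {"thin10": thin}, [roi])
        assert bool(df[df.image_id == "thin10"].significant.iloc[0])
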