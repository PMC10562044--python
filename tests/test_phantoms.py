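"""Phantom generators: geometry, bookkeeping and determinism."""

import numpy as np
import pytest

from lu177planar import phantoms as ph


class TestSheppLogan:
    def test_zero_outside_outer_ellipsoid(self):
        shape = (48, 48, 40)
        p = ph.make_shepp_logan(shape)
        # analytic membership evaluated independently over all voxels
        x, y, z = np.meshgrid(*[np.linspace(-1, 1, n) for n in shape],
                              indexing="ij")
        outside = (x / 0.69) ** 2 + (y / 0.92) ** 2 + (z / 0.81) ** 2 > 1.0
        assert np.all(p.activity[outside] == 0.0)
        assert np.all(p.attenuation[outside] == 0.0)
        assert np.all(p.activity >= 0)

    def test_activity_scaling_is_linear(self):
        p = ph.make_shepp_logan((32, 32, 24))
        assert ph.total_activity(p.scaled(3.0)) == pytest.approx(
            3.0 * ph.total_activity(p))

    def test_total_activity_normalization(self):
        p = ph.make_shepp_logan((32, 32, 24), total_activity=12.5)
        assert ph.total_activity(p) == pytest.approx(12.5)

    def test_rejects_bad_shape(self):
        with pytest.raises(ValueError):
            ph.make_shepp_logan((0, 32, 32))


class TestBrainLike:
    def test_deterministic_under_seed(self):
        a = ph.make_brain_like((40, 40, 32), seed=7)
        b = ph.make_brain_like((40, 40, 32), seed=7)
        assert np.array_equal(a.activity, b.activity)
        c = ph.make_brain_like((40, 40, 32), seed=8)
        assert not np.array_equal(a.activity, c.activity)

    def test_grey_white_ratio(self):
        p = ph.make_brain_like((48, 48, 40), seed=0, gm_wm_ratio=4.0)
        inside = p.activity > 0
        hi = p.activity == p.activity.max()
        lo = inside & ~hi
        ratio = p.activity[hi].mean() / p.activity[lo].mean()
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_support_fraction_reasonable(self):
        p = ph.make_brain_like((40, 40, 32), seed=1)
        frac = np.mean(p.attenuation > 0)
        assert 0.2 < frac < 0.8


class TestDerenzo:
    def test_booked_totals_match_rounded_volume_arithmetic(self):
        # 10 MBq/kg, 180 cm^3 rods in 7000 cm^3 at unit density
        assert ph.derenzo_booked_activity(ph.RodSpec(tbr=5)) == \
            pytest.approx(15.44, abs=1e-9)
        assert ph.derenzo_booked_activity(ph.RodSpec(tbr=20)) == \
            pytest.approx(5.21, abs=1e-9)

    def test_total_activity_of_generated_phantom(self):
        p5, _ = ph.make_derenzo(ph.RodSpec(tbr=5))
        assert ph.total_activity(p5) == pytest.approx(15.44, abs=1e-9)

    def test_exact_cylinder_volumes(self):
        # sum pi (d/2)^2 h for the six rods; the booked value rounds this
        # to ~180 cm^3
        assert ph.RodSpec().rod_volume_cm3() == pytest.approx(178.576,
                                                              abs=1e-2)

    def test_voxelized_rod_volume_near_analytic(self):
        spec = ph.RodSpec()
        _, labels = ph.make_derenzo(spec)
        vox_cm3 = np.prod([2.2, 2.6, 2.2]) / 1000.0
        vol = (labels.labels > 0).sum() * vox_cm3
        assert vol == pytest.approx(spec.rod_volume_cm3(), rel=0.05)

    def test_rod_background_concentration_ratio(self):
        spec = ph.RodSpec(tbr=5)
        p, labels = ph.make_derenzo(spec)
        rod_mean = p.activity[labels.labels > 0].mean()
        bg = (labels.labels == 0) & (p.attenuation > 0)
        assert rod_mean / p.activity[bg].mean() == pytest.approx(5.0,
                                                                 rel=1e-6)

    def test_overlapping_rods_rejected(self):
        spec = ph.RodSpec()
        centers = [(0.0, 0.0)] * 6
        with pytest.raises(ValueError, match="overlap"):
            ph.make_derenzo(spec, centers_mm=centers)

    def test_six_labelled_rods(self):
        _, labels = ph.make_derenzo()
        assert sorted(labels.organ_names.values()) == sorted(
            f"rod_{d:g}mm" for d in (10, 13, 17, 22, 28, 33))


class TestAnthropomorphic:
    def test_organ_activity_bookkeeping(self):
        tac = ph.default_tac(injected_activity=500.0)
        p, labels = ph.make_anthropomorphic(tac=tac, time_h=24.0)
        expected = sum(tac.activity_mbq(o, 24.0) for o in tac.organs)
        assert ph.total_activity(p) == pytest.approx(expected, rel=1e-9)

    def test_zero_injected_activity(self):
        tac = ph.default_tac(injected_activity=0.0)
        p, _ = ph.make_anthropomorphic(tac=tac, time_h=24.0)
        assert ph.total_activity(p) == 0.0

    def test_time_outside_curve_raises_without_flag(self):
        tac = ph.default_tac()
        with pytest.raises(ValueError, match="outside"):
            ph.make_anthropomorphic(tac=tac, time_h=500.0)

    def test_retention_ratios_across_time_points(self):
        tac = ph.default_tac()
        a24 = [tac.activity_mbq(o, 24.0) for o in tac.organs]
        a96 = [tac.activity_mbq(o, 96.0) for o in tac.organs]
        a168 = [tac.activity_mbq(o, 168.0) for o in tac.organs]
        np.testing.assert_allclose(np.array(a96) / a24, 0.6, rtol=1e-12)
        np.testing.assert_allclose(np.array(a168) / a24, 0.4, rtol=1e-12)

    def test_four_named_organs(self):
        _, labels = ph.make_anthropomorphic(tac=ph.default_tac())
        assert sorted(labels.organ_names.values()) == [
            "left_kidney", "liver", "right_kidney", "spleen"]


class TestTrainingCorpus:
    def test_corpus_size_is_twice_n_slices(self):
        spec = ph.TrainingCorpusSpec(n_slices=5, n_duplicates=4, matrix=32)
        sets = list(ph.make_training_corpus(spec, seed=0))
        assert len(sets) == 2 * spec.n_slices

    def test_default_spec_yields_300_sets(self):
        spec = ph.TrainingCorpusSpec(matrix=32, n_duplicates=2)
        count = sum(1 for _ in ph.make_training_corpus(spec, seed=0))
        assert count == 300

    def test_duplicated_slices_identical(self):
        spec = ph.TrainingCorpusSpec(n_slices=3, n_duplicates=6, matrix=32)
        for p in ph.make_training_corpus(spec, seed=0):
            assert p.shape == (32, 6, 32)
            for j in range(1, 6):
                np.testing.assert_array_equal(p.activity[:, j, :],
                                              p.activity[:, 0, :])

    def test_activity_endpoints_match_configured_range(self):
        spec = ph.TrainingCorpusSpec(n_slices=4, n_duplicates=2, matrix=32,
                                     activity_range_a=(2.88, 20.6),
                                     activity_range_b=(1.36, 31.0))
        sets = list(ph.make_training_corpus(spec, seed=0))
        fam_a = [ph.total_activity(p) for p in sets[:4]]
        fam_b = [ph.total_activity(p) for p in sets[4:]]
        assert min(fam_a) == pytest.approx(2.88, rel=1e-6)
        assert max(fam_a) == pytest.approx(20.6, rel=1e-6)
        assert min(fam_b) == pytest.approx(1.36, rel=1e-6)
        assert max(fam_b) == pytest.approx(31.0, rel=1e-6)

    def test_generators_deterministic(self):
        spec = ph.TrainingCorpusSpec(n_slices=2, n_duplicates=2, matrix=32)
        a = [p.activity for p in ph.make_training_corpus(spec, seed=5)]
        b = [p.activity for p in ph.make_training_corpus(spec, seed=5)]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestTotalActivity:
    def test_zero_phantom(self):
        p = ph.VoxelPhantom(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)),
                            (1, 1, 1))
        assert ph.total_activity(p) == 0.0

    def test_additive_over_disjoint_masks(self, rng):
        act = rng.random((6, 6, 6))
        p = ph.VoxelPhantom(act, np.zeros_like(act), (1, 1, 1))
        half = act.copy()
        half[3:] = 0
        other = act - half
        assert ph.total_activity(p) == pytest.approx(
            half.sum() + other.sum())
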