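"""Unit tests for the image-based viability score."""

import numpy as np
import pytest

from spherodrop.viability import (SpheroidMask, build_mask, compute_viability,
                                  estimate_K, measure_radius, otsu_threshold,
                                  pi_threshold, score_well)

from conftest import make_disk


def brute_force_otsu(image: np.ndarray) -> int:
    """Exhaustive 256-level scan minimising within-class variance."""
    img = image.ravel().astype(np.float64)
    best_t, best_v = 0, np.inf
    for t in range(256):
        lo, hi = img[img <= t], img[img > t]
        v = 0.0
        if lo.size:
            v += lo.size * lo.var()
        if hi.size:
            v += hi.size * hi.var()
        v /= img.size
        if v < best_v - 1e-12:
            best_t, best_v = t, v
    return best_t


class TestOtsu:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan_on_8bit(self, seed):
        rng = np.random.default_rng(seed)
        # bimodal-ish random image
        img = np.concatenate([
            rng.integers(0, 90, 600), rng.integers(120, 256, 400)
        ]).astype(np.uint8)
        rng.shuffle(img)
        img = img.reshape(40, 25)
        assert otsu_threshold(img) == brute_force_otsu(img)

    def test_perfect_bimodality(self):
        img = np.array([[0] * 8, [200] * 8])
        t = otsu_threshold(img)
        assert 0 <= t < 200
        assert ((img > t) == (img == 200)).all()

    def test_shift_equivariance(self, rng):
        img = rng.integers(0, 200, (16, 16))
        assert otsu_threshold(img + 17) == otsu_threshold(img) + 17

    def test_constant_image_degenerate(self):
        img = np.full((8, 8), 42)
        t = otsu_threshold(img)
        assert t == 42
        assert not (img > t).any()  # strict > convention: empty foreground


class TestPiThreshold:
    def test_constant_image(self):
        assert pi_threshold(np.full((5, 5), 7.0)) == 7.0

    def test_direct_evaluation_population_sigma(self):
        # median 3, population sigma sqrt(2)
        assert pi_threshold(np.array([1.0, 2, 3, 4, 5])) == pytest.approx(
            3 + 2 * np.sqrt(2)
        )

    def test_homogeneity(self, rng):
        img = rng.random((12, 12)) * 100
        assert pi_threshold(2 * img) == pytest.approx(2 * pi_threshold(img))


class TestEstimateK:
    def test_uniform_above_threshold(self):
        img = np.array([1.0, 2.0, 9.0, 9.0])
        assert estimate_K(img, 5.0) == 9.0

    def test_direct_evaluation(self):
        assert estimate_K(np.array([0.0, 10.0, 20.0]), 5.0) == 25.0

    def test_empty_above_set_is_none(self):
        assert estimate_K(np.array([1.0, 2.0]), 5.0) is None


class TestBuildMask:
    def test_gfp_disk_background_pi(self, rng):
        disk = make_disk()
        gfp = np.where(disk, 800.0, 100.0) + rng.normal(0, 1, disk.shape)
        pi = np.full(disk.shape, 100.0) + rng.normal(0, 1, disk.shape)
        mask = build_mask(gfp, pi)
        # mask recovers the disk within a 1-pixel ring
        assert abs(mask.area_px - disk.sum()) < 2 * np.pi * 16
        # only the ~2.3% Gaussian tail above median+2 sigma survives
        assert mask.pi.sum() < 0.05 * mask.area_px
        assert mask.pi[~mask.overall].sum() == 0  # subset invariant

    def test_union_keeps_largest_component(self):
        shape = (64, 64)
        gfp_disk = make_disk(shape, center=(20, 20), radius=12)
        pi_disk = make_disk(shape, center=(48, 48), radius=6)
        gfp = np.where(gfp_disk, 800.0, 100.0)
        pi = np.where(pi_disk, 900.0, 100.0)
        mask = build_mask(gfp, pi)
        # the two disks are disjoint; the larger (GFP) one wins
        assert (mask.overall == gfp_disk).all()

    def test_all_background_flat_is_empty_and_flagged(self):
        img = np.full((32, 32), 100.0)
        mask = build_mask(img, img)
        assert mask.area_px == 0
        assert "empty_mask" in mask.flags

    def test_all_background_noisy_is_empty_and_flagged(self, rng):
        gfp = rng.normal(100, 3, (64, 64))
        pi = rng.normal(100, 3, (64, 64))
        mask = build_mask(gfp, pi)
        assert mask.area_px == 0
        assert "empty_mask" in mask.flags

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shapes differ"):
            build_mask(np.zeros((4, 4)), np.zeros((5, 5)))


def naive_viability(pi, overall, pi_mask, K):
    """Per-pixel loop reference for the viability formula."""
    integral, area = 0.0, 0
    for i in range(pi.shape[0]):
        for j in range(pi.shape[1]):
            if overall[i, j]:
                area += 1
            if pi_mask[i, j] and overall[i, j]:
                integral += pi[i, j]
    return 1.0 - integral / (K * area)


class TestComputeViability:
    def test_matches_naive_loop_exactly(self, rng):
        for _ in range(20):
            pi = rng.integers(0, 4096, (16, 16)).astype(np.float64)
            overall = rng.random((16, 16)) < 0.5
            overall.ravel()[0] = True
            pim = overall & (rng.random((16, 16)) < 0.4)
            mask = SpheroidMask(overall=overall, pi=pim)
            _, raw, _ = compute_viability(pi, mask, K=50.0)
            assert raw == naive_viability(pi, overall, pim, 50.0)

    def test_every_mask_pixel_at_K_means_fully_dead(self):
        disk = make_disk()
        pi = np.where(disk, 80.0, 1.0)
        mask = SpheroidMask(overall=disk, pi=disk)
        v, raw, _ = compute_viability(pi, mask, K=80.0)
        assert v == 0.0
        assert raw == pytest.approx(0.0)

    def test_half_mask_at_K_gives_half_viability(self):
        overall = np.zeros((10, 10), bool)
        overall[:, :] = True
        pim = np.zeros((10, 10), bool)
        pim[:5] = True
        pi = np.where(pim, 40.0, 1.0)
        mask = SpheroidMask(overall=overall, pi=pim)
        v, _, _ = compute_viability(pi, mask, K=40.0)
        assert v == pytest.approx(0.5)

    def test_empty_pi_mask_gives_one(self):
        overall = make_disk()
        mask = SpheroidMask(overall=overall, pi=np.zeros_like(overall))
        v, _, _ = compute_viability(np.full(overall.shape, 5.0), mask, K=40.0)
        assert v == 1.0

    def test_empty_mask_raises(self):
        mask = SpheroidMask(overall=np.zeros((4, 4), bool), pi=np.zeros((4, 4), bool))
        with pytest.raises(ValueError, match="no spheroid"):
            compute_viability(np.ones((4, 4)), mask, K=1.0)

    def test_monotone_under_pi_scaling(self):
        disk = make_disk()
        pim = make_disk(radius=8)
        base = np.where(pim, 20.0, 1.0)
        mask = SpheroidMask(overall=disk, pi=pim)
        vals = [compute_viability(base * s, mask, K=100.0)[0]
                for s in (0.5, 1, 2, 4, 8, 16)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_background_subtraction_raises_viability(self):
        disk = make_disk()
        pim = make_disk(radius=8)
        pi = np.where(pim, 30.0, 5.0)  # nonzero background everywhere
        mask = SpheroidMask(overall=disk, pi=pim)
        v_raw, _, int_raw = compute_viability(pi, mask, K=100.0)
        v_sub, _, int_sub = compute_viability(pi, mask, K=100.0,
                                              subtract_background=True)
        assert int_sub == int_raw - 5.0 * pim.sum()
        assert v_sub > v_raw

    def test_locality_outside_mask(self, rng):
        disk = make_disk(shape=(40, 40), radius=10)
        pim = make_disk(shape=(40, 40), radius=5)
        pi = np.where(pim, 30.0, 2.0)
        mask = SpheroidMask(overall=disk, pi=pim)
        v0 = compute_viability(pi, mask, K=35.0)
        pi2 = pi.copy()
        pi2[~disk] = rng.random((~disk).sum()) * 10  # rewrite background
        assert compute_viability(pi2, mask, K=35.0) == v0


class TestRadius:
    def test_disk_radius(self):
        mask = SpheroidMask(overall=make_disk(shape=(128, 128), radius=50),
                            pi=np.zeros((128, 128), bool), pixel_size=1.0)
        assert measure_radius(mask) == pytest.approx(50.0, abs=0.5)

    def test_pixel_size_scaling_exact_ratio(self):
        overall = make_disk()
        m1 = SpheroidMask(overall=overall, pi=np.zeros_like(overall), pixel_size=0.65)
        m2 = SpheroidMask(overall=overall, pi=np.zeros_like(overall), pixel_size=1.3)
        assert measure_radius(m2) / measure_radius(m1) == pytest.approx(2.0)

    def test_empty_mask_raises(self):
        mask = SpheroidMask(overall=np.zeros((4, 4), bool), pi=np.zeros((4, 4), bool))
        with pytest.raises(ValueError):
            measure_radius(mask)


class TestScoreWell:
    def test_no_pi_signal_is_fully_viable_and_flagged(self, rng):
        disk = make_disk()
        gfp = np.where(disk, 800.0, 100.0) + rng.normal(0, 1, disk.shape)
        pi = np.full(disk.shape, 100.0) + rng.normal(0, 1, disk.shape)
        rec = score_well(gfp, pi)
        # a handful of noise pixels may clear median+2 sigma, but a
        # PI-dead well must never be scored as dying
        assert rec.viability > 0.95
        assert rec.area_px > 0

    def test_empty_well_flagged_not_raised(self):
        img = np.full((32, 32), 50.0)
        rec = score_well(img, img)
        assert np.isnan(rec.viability)
        assert "empty_mask" in rec.flags
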