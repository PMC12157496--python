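"""Spatial morphometrics: front extraction, Df, lacunarity, eccentricity."""

import math

import numpy as np
import pytest

from astroabm.lattice import CellKind
from astroabm.morphometrics import (
    box_counts,
    compute_metrics,
    default_scales,
    eccentricity,
    eccentricity_from_coords,
    fractal_dimension,
    lacunarity,
    lacunarity_per_scale,
    residualize,
    tumor_front,
)

from conftest import make_grid


# --------------------------------------------------------- brute-force oracles
def brute_box_count(mask, eps):
    """Independent naive box counter anchored at the bounding-box origin."""
    ys, xs = np.nonzero(mask)
    y0, x0 = ys.min(), xs.min()
    boxes = {(int((y - y0) // eps), int((x - x0) // eps)) for y, x in zip(ys, xs)}
    return len(boxes)


def brute_fractal_dimension(mask, sizes):
    logs_n = [math.log(brute_box_count(mask, e)) for e in sizes]
    logs_e = [math.log(e) for e in sizes]
    slope = np.polyfit(logs_e, logs_n, 1)[0]
    return -slope


def brute_lacunarity(mask, eps):
    """Window masses by explicit double loop over the given region."""
    h, w = mask.shape
    masses = []
    for i in range(0, h, eps):
        for j in range(0, w, eps):
            masses.append(int(mask[i : i + eps, j : j + eps].sum()))
    masses = np.array(masses, float)
    mu = masses.mean()
    return float(masses.var() / mu**2)


class TestTumorFront:
    def test_isolated_cell_is_front(self):
        occ = make_grid((7, 7), tumors=[(3, 3)])
        assert tumor_front(occ)[3, 3]

    def test_solid_block_has_ring_front(self):
        occ = make_grid((9, 9), tumors=[(x, y) for x in range(3, 6) for y in range(3, 6)])
        front = tumor_front(occ)
        assert front.sum() == 8
        assert not front[4, 4]  # center is interior

    def test_enclosed_by_astrocytes_not_front(self):
        occ = make_grid((5, 5), tumors=[(2, 2)],
                        anti=[(x, y) for x in range(1, 4) for y in range(1, 4)
                              if (x, y) != (2, 2)])
        assert not tumor_front(occ).any()

    def test_front_subset_of_tumor(self, rng):
        occ = make_grid((20, 20))
        occ.ravel()[rng.choice(400, 150, replace=False)] = CellKind.TUMOR
        front = tumor_front(occ)
        assert not (front & (occ != CellKind.TUMOR)).any()


class TestFractalDimension:
    def test_line_has_dimension_one(self):
        mask = np.zeros((70, 70), bool)
        mask[30, 3 : 3 + 64] = True
        assert fractal_dimension(mask) == pytest.approx(1.0, abs=0.05)

    def test_filled_block_has_dimension_two(self):
        mask = np.zeros((80, 80), bool)
        mask[8 : 8 + 64, 8 : 8 + 64] = True
        assert fractal_dimension(mask) == pytest.approx(2.0, abs=0.05)

    def test_disc_boundary_matches_brute_force(self):
        y, x = np.mgrid[:64, :64]
        r = np.hypot(y - 32, x - 32)
        boundary = (r <= 30) & (r > 29)
        sizes = default_scales(64)
        ours = fractal_dimension(boundary, sizes)
        brute = brute_fractal_dimension(boundary, sizes)
        assert ours == pytest.approx(brute, abs=1e-10)
        # finite-scale box counting of a thin ring runs slightly above 1
        assert 0.9 < ours < 1.25

    def test_box_counts_match_brute_force(self, rng):
        mask = rng.random((48, 48)) < 0.2
        sizes = [2, 4, 8, 16]
        ours = box_counts(mask, sizes)
        brute = [brute_box_count(mask, e) for e in sizes]
        assert list(ours) == brute

    def test_box_count_nonincreasing_in_scale(self, rng):
        mask = rng.random((64, 64)) < 0.3
        counts = box_counts(mask, [2, 4, 8, 16, 32])
        assert (np.diff(counts) <= 0).all()

    def test_translation_invariance(self):
        y, x = np.mgrid[:40, :40]
        blob = (np.hypot(y - 20, x - 20) <= 15) & (np.hypot(y - 20, x - 20) > 14)
        big = np.zeros((120, 120), bool)
        big[10:50, 10:50] = blob
        shifted = np.zeros((120, 120), bool)
        shifted[60:100, 55:95] = blob
        assert fractal_dimension(big) == pytest.approx(fractal_dimension(shifted), rel=1e-12)

    def test_empty_and_tiny_masks_are_missing(self):
        assert math.isnan(fractal_dimension(np.zeros((10, 10), bool)))
        tiny = np.zeros((10, 10), bool)
        tiny[4, 4] = True
        assert math.isnan(fractal_dimension(tiny))  # fewer than 3 scales


class TestLacunarity:
    def test_fully_occupied_region_is_zero(self):
        mask = np.ones((16, 16), bool)
        for eps, lam in lacunarity_per_scale(mask).items():
            assert lam == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_single_cell_example(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        assert lacunarity(mask, [2]) == pytest.approx(3.0)

    def test_checkerboard_unit_windows(self):
        mask = np.indices((8, 8)).sum(axis=0) % 2 == 0
        assert lacunarity(mask, [1]) == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        mask = rng.random((32, 32)) < 0.25
        for eps in (2, 4, 8):
            ours = lacunarity_per_scale(mask, [eps])[eps]
            assert ours == pytest.approx(brute_lacunarity(mask, eps), rel=1e-12)

    def test_mean_over_scales(self, rng):
        mask = rng.random((32, 32)) < 0.25
        per = lacunarity_per_scale(mask, [2, 4, 8])
        assert lacunarity(mask, [2, 4, 8]) == pytest.approx(np.mean(list(per.values())))

    def test_empty_mask_is_missing(self):
        assert math.isnan(lacunarity(np.zeros((8, 8), bool)))


class TestEccentricity:
    def test_collinear_is_one(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 2:18] = True
        assert eccentricity(mask) == pytest.approx(1.0)

    def test_disc_is_nearly_zero(self):
        y, x = np.mgrid[:41, :41]
        mask = np.hypot(y - 20, x - 20) <= 15
        assert eccentricity(mask) == pytest.approx(0.0, abs=0.02)

    def test_known_eigenvalue_ratio(self):
        # coordinate cloud with population covariance diag(4, 1)
        coords = np.array(
            [[2.0 * math.sqrt(2), 0], [-2.0 * math.sqrt(2), 0], [0, math.sqrt(2)], [0, -math.sqrt(2)]]
        )
        assert eccentricity_from_coords(coords) == pytest.approx(0.75)

    def test_rotation_and_translation_invariance(self):
        mask = np.zeros((50, 50), bool)
        mask[10:20, 5:40] = True
        rotated = np.zeros((50, 50), bool)
        rotated[5:40, 25:35] = True  # 90-degree rotation, translated
        assert eccentricity(mask) == pytest.approx(eccentricity(rotated), rel=1e-12)

    def test_degenerate_single_cell_is_zero(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert eccentricity(mask) == 0.0


class TestResidualize:
    def test_linear_metric_residuals_vanish(self, rng):
        count = rng.random((10, 6)) * 100
        metric = 3.0 * count + 2.0
        res = residualize(metric, count)
        assert np.abs(res).max() < 1e-9

    def test_independent_metric_is_centered(self, rng):
        count = np.tile(np.arange(8.0)[:, None], (1, 4))
        metric = rng.normal(5.0, 1.0, (8, 4))
        res = residualize(metric, count)
        assert np.abs(res.mean(axis=0)).max() < 1e-9

    def test_recovers_noise_variance(self):
        rng = np.random.default_rng(2024)
        count = rng.random((100, 3)) * 1000
        noise = rng.normal(0, 1.0, (100, 3))
        metric = 2.0 * count + noise
        res = residualize(metric, count)
        assert res.var() == pytest.approx(1.0, rel=0.2)

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            residualize(np.zeros((2, 5)), np.zeros((2, 5)))


def test_compute_metrics_on_solid_block():
    occ = make_grid((30, 30), tumors=[(x, y) for x in range(8, 24) for y in range(8, 24)])
    m = compute_metrics(occ, step=7)
    assert m.step == 7
    assert m.tumor_count == 256
    assert m.eccentricity == pytest.approx(0.0, abs=1e-9)
    assert 0.0 <= m.fractal_dimension <= 2.0
    assert m.lacunarity >= 0.0
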