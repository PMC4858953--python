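"""Neighborhoods, SA/SASA weights and spatially aware distances."""

import numpy as np
import pytest

from conftest import random_image
from msishrink import (
    SpectraImage,
    adaptive_weights,
    build_neighborhoods,
    distance_to_centroid,
    gaussian_weights,
    pairwise_spatial_distance,
)
from msishrink.exceptions import ParameterError


def full_grid(n_side=3, p=2, values=None, rng=None):
    coords = np.array([(i, j) for i in range(1, n_side + 1) for j in range(1, n_side + 1)])
    n = coords.shape[0]
    if values is None:
        values = rng.random((n, p)) if rng is not None else np.ones((n, p))
    return SpectraImage(
        intensities=np.asarray(values, dtype=float),
        coords=coords,
        sample_id=np.ones(n, dtype=int),
        mz=100.0 + np.arange(p, dtype=float),
    )


class TestNeighborhoods:
    def test_interior_pixel_full_window(self):
        nbhd = build_neighborhoods(full_grid(3), r=1)
        center = 4  # (2, 2)
        assert len(nbhd.neighbors[center]) == 9
        assert center in nbhd.neighbors[center]

    def test_corner_pixel_truncated(self):
        nbhd = build_neighborhoods(full_grid(3), r=1)
        assert len(nbhd.neighbors[0]) == 4

    def test_r_zero_is_singleton_self(self):
        nbhd = build_neighborhoods(full_grid(3), r=0)
        for n in range(9):
            assert nbhd.neighbors[n].tolist() == [n]
            assert nbhd.offsets[n].tolist() == [[0, 0]]

    def test_samples_do_not_mix(self):
        # two samples, adjacent coordinates
        img = SpectraImage(
            intensities=np.ones((4, 2)),
            coords=np.array([[1, 1], [1, 2], [1, 3], [1, 4]]),
            sample_id=np.array([1, 1, 2, 2]),
            mz=np.array([1.0, 2.0]),
        )
        nbhd = build_neighborhoods(img, r=1)
        assert set(nbhd.neighbors[1].tolist()) == {0, 1}
        assert set(nbhd.neighbors[2].tolist()) == {2, 3}


class TestGaussianWeights:
    def test_center_weight_is_strict_maximum(self):
        nbhd = build_neighborhoods(full_grid(3), r=1)
        ws = gaussian_weights(nbhd, sigma=0.7)
        center = 4
        offs = nbhd.offsets[center]
        w = ws.weights[center]
        self_idx = np.flatnonzero((offs == 0).all(axis=1))[0]
        assert np.all(w[self_idx] >= w + (np.arange(len(w)) != self_idx) * 1e-12)

    def test_r_zero_weight_one(self):
        nbhd = build_neighborhoods(full_grid(2), r=0)
        ws = gaussian_weights(nbhd)
        assert all(np.allclose(w, [1.0]) for w in ws.weights)

    def test_hand_evaluated_exponentials(self):
        nbhd = build_neighborhoods(full_grid(3), r=1)
        ws = gaussian_weights(nbhd, sigma=0.5)
        # full 3x3 window: exp(0), 4x exp(-2), 4x exp(-4), normalized
        raw = {0: 1.0, 1: np.exp(-2.0), 2: np.exp(-4.0)}
        offs = nbhd.offsets[4]
        expect = np.array([raw[(di * di + dj * dj)] for di, dj in offs])
        expect /= expect.sum()
        assert np.allclose(ws.weights[4], expect, rtol=1e-12)

    def test_weights_sum_to_one(self, rng):
        img = random_image(rng, n_side=5, irregular=True)
        nbhd = build_neighborhoods(img, r=2)
        ws = gaussian_weights(nbhd)
        for w in ws.weights:
            assert abs(w.sum() - 1.0) < 1e-12

    def test_bad_sigma_rejected(self):
        nbhd = build_neighborhoods(full_grid(2), r=1)
        with pytest.raises(ParameterError):
            gaussian_weights(nbhd, sigma=0.0)


class TestAdaptiveWeights:
    def test_identical_spectra_fall_back_to_gaussian(self):
        img = full_grid(3, values=np.ones((9, 2)))
        nbhd = build_neighborhoods(img, r=1)
        sasa = adaptive_weights(nbhd, img, sigma=0.5)
        sa = gaussian_weights(nbhd, sigma=0.5)
        for a, b in zip(sasa.weights, sa.weights):
            assert np.allclose(a, b)

    def test_outlier_neighbor_downweighted(self):
        vals = np.zeros((9, 2))
        vals[1] = [50.0, 50.0]  # wildly different neighbor of the center
        img = full_grid(3, values=vals)
        nbhd = build_neighborhoods(img, r=1)
        sasa = adaptive_weights(nbhd, img, sigma=0.5)
        sa = gaussian_weights(nbhd, sigma=0.5)
        center = 4
        pos = nbhd.neighbors[center].tolist().index(1)
        assert sasa.weights[center][pos] < sa.weights[center][pos]

    def test_matches_scalar_reference(self, rng):
        img = full_grid(3, rng=rng)
        nbhd = build_neighborhoods(img, r=1)
        sigma = 0.6
        got = adaptive_weights(nbhd, img, sigma=sigma)
        x = img.intensities
        for n in range(9):
            rows = nbhd.neighbors[n]
            offs = nbhd.offsets[n]
            lam = 0.0
            for a in range(len(rows)):
                for b in range(a + 1, len(rows)):
                    lam = max(lam, 0.5 * np.linalg.norm(x[rows[a]] - x[rows[b]]))
            w = []
            for (di, dj), row in zip(offs, rows):
                g = np.exp(-(di * di + dj * dj) / (2 * sigma**2))
                beta = np.exp(-np.linalg.norm(x[row] - x[n]) ** 2 / (2 * lam**2))
                w.append(g * beta)
            w = np.array(w) / np.sum(w)
            assert np.allclose(got.weights[n], w, rtol=1e-9)
            assert np.isclose(got.lambda_per_pixel[n], lam)


class TestPairwiseDistance:
    def test_same_pixel_distance_zero(self, rng):
        img = full_grid(3, rng=rng)
        nbhd = build_neighborhoods(img, r=1)
        assert pairwise_spatial_distance(img, nbhd, "sa", 4, 4) == pytest.approx(0.0)

    def test_r_zero_reduces_to_euclidean(self, rng):
        img = full_grid(3, rng=rng)
        nbhd = build_neighborhoods(img, r=0)
        for a, b in [(0, 5), (2, 7)]:
            want = np.linalg.norm(img.intensities[a] - img.intensities[b])
            for kind in ("sa", "sasa"):
                assert pairwise_spatial_distance(img, nbhd, kind, a, b) == pytest.approx(want)

    def test_strip_matches_nested_loop_oracle(self, rng):
        coords = np.array([[1, j] for j in range(1, 5)])
        x = rng.random((4, 3))
        img = SpectraImage(intensities=x, coords=coords,
                           sample_id=np.ones(4, dtype=int), mz=np.array([1.0, 2.0, 3.0]))
        nbhd = build_neighborhoods(img, r=1)
        sigma = 0.5
        a, b = 1, 2
        # scalar oracle: shared offsets of the two windows
        offs_a = {tuple(o): r for o, r in zip(nbhd.offsets[a].tolist(), nbhd.neighbors[a])}
        offs_b = {tuple(o): r for o, r in zip(nbhd.offsets[b].tolist(), nbhd.neighbors[b])}
        shared = sorted(set(offs_a) & set(offs_b))
        alpha = np.array([np.exp(-(di * di + dj * dj) / (2 * sigma**2)) for di, dj in shared])
        alpha /= alpha.sum()
        d2 = sum(
            w * np.sum((x[offs_a[o]] - x[offs_b[o]]) ** 2)
            for w, o in zip(alpha, shared)
        )
        got = pairwise_spatial_distance(img, nbhd, "sa", a, b, sigma=sigma)
        assert got == pytest.approx(np.sqrt(d2), rel=1e-9)


class TestDistanceToCentroid:
    def test_r_zero_is_plain_squared_euclidean(self, rng):
        img = full_grid(3, rng=rng)
        nbhd = build_neighborhoods(img, r=0)
        ws = gaussian_weights(nbhd)
        c = rng.random(2)
        got = distance_to_centroid(img, nbhd, ws, c)
        want = ((img.intensities - c) ** 2).sum(axis=1)
        assert np.allclose(got, want, rtol=1e-12)

    def test_constant_image_zero_distance(self):
        img = full_grid(3, values=np.full((9, 2), 3.5))
        nbhd = build_neighborhoods(img, r=1)
        ws = gaussian_weights(nbhd, sigma=0.5)
        got = distance_to_centroid(img, nbhd, ws, np.array([3.5, 3.5]))
        assert np.allclose(got, 0.0)

    def test_matches_scalar_loop(self, rng):
        img = full_grid(3, rng=rng)
        nbhd = build_neighborhoods(img, r=1)
        ws = gaussian_weights(nbhd, sigma=0.5)
        c = rng.random(2)
        scale = np.array([0.8, 1.3])
        got = distance_to_centroid(img, nbhd, ws, c, per_feature_scale=scale)
        for n in range(9):
            want = sum(
                w * np.sum(((img.intensities[row] - c) / scale) ** 2)
                for w, row in zip(ws.weights[n], nbhd.neighbors[n])
            )
            assert got[n] == pytest.approx(want, rel=1e-9)

    def test_convex_combination_bound(self, rng):
        img = random_image(rng, n_side=5, irregular=True)
        nbhd = build_neighborhoods(img, r=1)
        ws = gaussian_weights(nbhd)
        c = rng.random(img.n_features)
        spatial = distance_to_centroid(img, nbhd, ws, c)
        plain = ((img.intensities - c) ** 2).sum(axis=1)
        for n in range(img.n_pixels):
            nb = nbhd.neighbors[n]
            assert plain[nb].min() - 1e-9 <= spatial[n] <= plain[nb].max() + 1e-9

    def test_sasa_weight_decreases_with_deviation(self):
        # growing one neighbor's deviation from the center never raises its weight
        base = np.ones((9, 2))
        prev_weight = None
        for dev in (0.0, 1.0, 3.0, 10.0):
            vals = base.copy()
            vals[1] = 1.0 + dev
            vals[0] = 2.0  # keep lambda > 0 even at dev = 0
            img = full_grid(3, values=vals)
            nbhd = build_neighborhoods(img, r=1)
            ws = adaptive_weights(nbhd, img, sigma=0.5)
            center = 4
            pos = nbhd.neighbors[center].tolist().index(1)
            w = ws.weights[center][pos]
            if prev_weight is not None:
                assert w <= prev_weight + 1e-12
            prev_weight = w
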