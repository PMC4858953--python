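"""Pixel neighborhoods and spatially aware (SA / SASA) distances.

Spectra acquired at nearby pixels are correlated, so distances used for
segmentation and classification average spectral dissimilarity over a
square Chebyshev window of radius r around each pixel.  Two weighting
schemes are supported:

* SA — Gaussian weights exp(-(di^2 + dj^2) / (2 sigma^2)) that depend only
  on the offset from the window center;
* SASA — structurally adaptive weights that additionally multiply in
  beta = exp(-||x_neighbor - x_center||^2 / (2 lambda^2)), downweighting
  neighbors whose spectra differ strongly from the center, which preserves
  edges between morphological regions.  lambda is set per neighborhood to
  half the norm of the difference between its two most differing spectra.

Weights are always normalized to sum to 1 per pixel.  Windows truncate at
sample boundaries and irregular footprints (no padding); neighbors always
share the pixel's sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import pdist

from .exceptions import DimensionError, ParameterError
from .image import SpectraImage

__all__ = [
    "NeighborhoodIndex",
    "WeightSet",
    "build_neighborhoods",
    "gaussian_weights",
    "adaptive_weights",
    "pairwise_spatial_distance",
    "distance_to_centroid",
]

log = logging.getLogger(__name__)


@dataclass
class NeighborhoodIndex:
    """Same-sample neighbors within Chebyshev radius r of each pixel.

    ``neighbors[n]`` holds pixel row indices (the pixel itself included)
    and ``offsets[n]`` the matching (di, dj) integer offsets.
    """

    radius: int
    neighbors: list  # of int ndarrays
    offsets: list    # of (len, 2) int ndarrays

    @property
    def n_pixels(self) -> int:
        return len(self.neighbors)


@dataclass
class WeightSet:
    """Per-pixel spatial weights aligned with a :class:`NeighborhoodIndex`."""

    kind: str                      # "sa" or "sasa"
    weights: list                  # of float ndarrays, each summing to 1
    lambda_per_pixel: np.ndarray | None = None

    def to_sparse(self, nbhd: NeighborhoodIndex) -> sp.csr_matrix:
        """Row-stochastic (N x N) sparse matrix of the weights."""
        n = nbhd.n_pixels
        indptr = np.zeros(n + 1, dtype=int)
        for i, nb in enumerate(nbhd.neighbors):
            indptr[i + 1] = indptr[i] + len(nb)
        indices = np.concatenate(nbhd.neighbors) if n else np.empty(0, dtype=int)
        data = np.concatenate(self.weights) if n else np.empty(0)
        return sp.csr_matrix((data, indices, indptr), shape=(n, n))


def build_neighborhoods(img: SpectraImage, r: int) -> NeighborhoodIndex:
    """Index all same-sample pixels within Chebyshev distance r of each pixel.

    Grid positions absent from the image (edges, irregular footprints) are
    simply missing — windows truncate, nothing is padded or mirrored.
    """
    if r < 0:
        raise ParameterError("neighborhood radius must be nonnegative")
    index = img.pixel_index()
    samples = img.sample_id.tolist()
    window = [(di, dj) for di in range(-r, r + 1) for dj in range(-r, r + 1)]
    neighbors, offsets = [], []
    for n in range(img.n_pixels):
        s = samples[n]
        i, j = img.coords[n]
        rows, offs = [], []
        for di, dj in window:
            hit = index.get((s, int(i) + di, int(j) + dj))
            if hit is not None:
                rows.append(hit)
                offs.append((di, dj))
        neighbors.append(np.asarray(rows, dtype=int))
        offsets.append(np.asarray(offs, dtype=int).reshape(-1, 2))
    return NeighborhoodIndex(radius=r, neighbors=neighbors, offsets=offsets)


def _gaussian_offset_weights(offsets: np.ndarray, sigma: float) -> np.ndarray:
    d2 = (offsets ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * sigma ** 2))


def _resolve_sigma(nbhd: NeighborhoodIndex, sigma: float | None) -> float:
    if sigma is None:
        sigma = nbhd.radius / 2.0 if nbhd.radius > 0 else 1.0
    if sigma <= 0:
        raise ParameterError("gaussian bandwidth sigma must be positive")
    return sigma


def gaussian_weights(nbhd: NeighborhoodIndex, sigma: float | None = None) -> WeightSet:
    """SA weights: Gaussian in the squared offset, normalized per pixel.

    ``sigma`` defaults to r/2, putting the window edge near two bandwidths.
    For r = 0 every neighborhood is the singleton {self} with weight 1.
    """
    sigma = _resolve_sigma(nbhd, sigma)
    weights = []
    for offs in nbhd.offsets:
        w = _gaussian_offset_weights(offs, sigma)
        weights.append(w / w.sum())
    return WeightSet(kind="sa", weights=weights)


def _beta_factors(x_nb: np.ndarray, x_center: np.ndarray, lam: float) -> np.ndarray:
    d2 = ((x_nb - x_center) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * lam ** 2))


def _neighborhood_lambda(x_nb: np.ndarray) -> float:
    """Half the norm of the difference between the two most differing
    spectra in the neighborhood; 0 when all spectra coincide."""
    if x_nb.shape[0] < 2:
        return 0.0
    return 0.5 * float(pdist(x_nb).max())


def adaptive_weights(
    nbhd: NeighborhoodIndex, img: SpectraImage, sigma: float | None = None
) -> WeightSet:
    """SASA weights: Gaussian offset decay times the spectral beta factor.

    The beta factor is referenced to the neighborhood center (one beta per
    neighbor), with lambda computed per neighborhood from the observed
    spectra.  When all spectra in a neighborhood coincide (lambda = 0) the
    weights fall back to pure Gaussian weights.
    """
    sigma = _resolve_sigma(nbhd, sigma)
    x = img.intensities
    weights = []
    lambdas = np.zeros(nbhd.n_pixels)
    n_fallback = 0
    for n, (rows, offs) in enumerate(zip(nbhd.neighbors, nbhd.offsets)):
        g = _gaussian_offset_weights(offs, sigma)
        x_nb = x[rows]
        lam = _neighborhood_lambda(x_nb)
        lambdas[n] = lam
        if lam > 0:
            w = g * _beta_factors(x_nb, x[n], lam)
        else:
            w = g
            n_fallback += 1
        weights.append(w / w.sum())
    if n_fallback:
        log.info(
            "adaptive weights: %d neighborhoods with identical spectra fell "
            "back to Gaussian weights",
            n_fallback,
        )
    return WeightSet(kind="sasa", weights=weights, lambda_per_pixel=lambdas)


def pairwise_spatial_distance(
    img: SpectraImage,
    nbhd: NeighborhoodIndex,
    kind: str,
    pixel_a: int,
    pixel_b: int,
    sigma: float | None = None,
) -> float:
    """Spatially aware distance between the spectra at two pixels.

    d^2 = sum over offsets shared by both windows of
    alpha_delta * ||x_{a+delta} - x_{b+delta}||^2, where alpha is Gaussian
    (SA) or Gaussian times both pixels' beta factors (SASA), renormalized
    over the shared offsets.  Returns the (non-squared) distance.
    """
    if kind not in ("sa", "sasa"):
        raise ParameterError(f"weights kind must be 'sa' or 'sasa', got {kind!r}")
    sigma = _resolve_sigma(nbhd, sigma)
    x = img.intensities

    def offset_map(n):
        return {tuple(o): r for o, r in zip(nbhd.offsets[n].tolist(), nbhd.neighbors[n])}

    map_a, map_b = offset_map(pixel_a), offset_map(pixel_b)
    shared = sorted(set(map_a) & set(map_b))
    offs = np.asarray(shared, dtype=int).reshape(-1, 2)
    rows_a = np.array([map_a[o] for o in shared], dtype=int)
    rows_b = np.array([map_b[o] for o in shared], dtype=int)
    alpha = _gaussian_offset_weights(offs, sigma)
    if kind == "sasa":
        for pixel, rows in ((pixel_a, rows_a), (pixel_b, rows_b)):
            x_nb = x[nbhd.neighbors[pixel]]
            lam = _neighborhood_lambda(x_nb)
            if lam > 0:
                alpha = alpha * _beta_factors(x[rows], x[pixel], lam)
    alpha = alpha / alpha.sum()
    sq = ((x[rows_a] - x[rows_b]) ** 2).sum(axis=1)
    return float(np.sqrt((alpha * sq).sum()))


def distance_to_centroid(
    img: SpectraImage,
    nbhd: NeighborhoodIndex,
    weights: WeightSet,
    centroid: np.ndarray,
    per_feature_scale: np.ndarray | None = None,
) -> np.ndarray:
    """Squared spatially aware distance from every pixel to one centroid.

    d^2(x_n, c) = sum_nb alpha_nb * sum_p ((x_{nb,p} - c_p) / scale_p)^2 —
    a convex combination over the neighborhood of the plain (optionally
    standardized) squared distances.
    """
    centroid = np.asarray(centroid, dtype=float)
    if centroid.shape != (img.n_features,):
        raise DimensionError("centroid length does not match image features")
    z = img.intensities - centroid
    if per_feature_scale is not None:
        z = z / np.asarray(per_feature_scale, dtype=float)
    plain = (z ** 2).sum(axis=1)
    return weights.to_sparse(nbhd) @ plain


def spatial_sq_distances(
    img: SpectraImage,
    w_sparse: sp.csr_matrix,
    centroids: np.ndarray,
    per_feature_scale: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized (N x K) squared spatial distances to a centroid stack."""
    x = img.intensities
    scale = (
        np.ones(img.n_features)
        if per_feature_scale is None
        else np.asarray(per_feature_scale, dtype=float)
    )
    xs = x / scale
    cs = np.asarray(centroids, dtype=float) / scale
    # ||a - b||^2 expansion keeps this O(N P K) without a (N, K, P) temporary
    plain = (
        (xs ** 2).sum(axis=1)[:, None]
        - 2.0 * xs @ cs.T
        + (cs ** 2).sum(axis=1)[None, :]
    )
    np.maximum(plain, 0.0, out=plain)
    return w_sparse @ plain
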