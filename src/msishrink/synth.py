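"""Phantom MS images with known ground truth, and scoring against it.

The generator emulates the controlled ground-truth design used to
validate imaging segmentation methods: a label image with a handful of
spatial regions (background, a disk, a stripe by default), each region
enriched in its own small set of spectral features.  Intensities are a
flat baseline of 1, plus ``effect_size`` noise-SD units on a segment's
enriched features inside that segment, plus Gaussian noise (optionally
spatially smoothed to mimic correlated acquisition noise), clipped at
zero.  Everything is a deterministic function of the seed.

This reproduces the statistical structure the segmentation method relies
on — mean differences concentrated on a sparse feature subset over
contiguous regions — while remaining transparent enough that parameter
recovery can be verified analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment

from .exceptions import DimensionError, ParameterError
from .image import SpectraImage

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "default_geometry",
    "make_phantom",
    "segmentation_accuracy",
    "boundary_mask",
]


def default_geometry(height: int = 40, width: int = 40) -> np.ndarray:
    """Three-segment label image: background (0), a disk (1), a stripe (2)."""
    ii, jj = np.mgrid[0:height, 0:width]
    geom = np.zeros((height, width), dtype=int)
    ci, cj = 0.32 * height, 0.38 * width
    radius = 0.20 * min(height, width)
    geom[(ii - ci) ** 2 + (jj - cj) ** 2 <= radius ** 2] = 1
    geom[int(0.65 * height):int(0.85 * height), :] = 2
    return geom


@dataclass
class PhantomSpec:
    """Parameters of a synthetic ground-truth MS image."""

    grid: tuple = (40, 40)
    n_samples: int = 1
    geometry: np.ndarray | None = None   # label image, values 0..K_true-1
    k_true: int = 3
    p: int = 50
    enriched_per_segment: int = 5
    effect_size: float = 3.0             # mean shift in noise-SD units
    noise_sd: float = 1.0
    correlated_noise_radius: int = 0     # gaussian smoothing sigma, pixels
    noise: str = "gaussian"              # or "lognormal"
    seed: int = 0


@dataclass
class PhantomTruth:
    """A generated phantom with its ground truth."""

    img: SpectraImage
    labels: np.ndarray            # (N,) true segment per pixel, 0-based
    effect_table: pd.DataFrame    # columns segment, feature, shift
    spec: PhantomSpec = field(repr=False, default=None)

    def enriched_features(self, segment: int) -> list:
        sub = self.effect_table[self.effect_table["segment"] == segment]
        return sub["feature"].astype(int).tolist()


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate a phantom image from its specification."""
    if spec.effect_size <= 0:
        raise ParameterError("effect_size must be positive")
    if spec.noise_sd <= 0:
        raise ParameterError("noise_sd must be positive")
    geom = spec.geometry if spec.geometry is not None else default_geometry(*spec.grid)
    geom = np.asarray(geom, dtype=int)
    height, width = geom.shape
    k_true = int(geom.max()) + 1
    if spec.geometry is None and k_true != spec.k_true:
        raise ParameterError("k_true does not match the default geometry")
    if np.any(np.bincount(geom.ravel(), minlength=k_true) == 0):
        raise ParameterError("every segment must occupy at least one pixel")
    e = spec.enriched_per_segment
    if k_true * e > spec.p:
        raise ParameterError("not enough features for disjoint enriched sets")

    rng = np.random.default_rng(spec.seed)
    shift = spec.effect_size * spec.noise_sd
    effect_rows = [
        {"segment": k, "feature": k * e + q, "shift": shift}
        for k in range(k_true)
        for q in range(e)
    ]
    mean_img = np.ones((k_true, spec.p))
    for row in effect_rows:
        mean_img[row["segment"], row["feature"]] += shift

    per_sample = height * width
    n = per_sample * spec.n_samples
    flat_geom = geom.ravel()
    intensities = np.empty((n, spec.p))
    for m in range(spec.n_samples):
        noise = rng.standard_normal((height, width, spec.p))
        if spec.correlated_noise_radius > 0:
            # same bandwidth convention as the spatial weights: sigma = r/2
            sig = spec.correlated_noise_radius / 2.0
            noise = gaussian_filter(noise, sigma=(sig, sig, 0), mode="nearest")
            sd = noise.std()
            if sd > 0:
                noise /= sd
        block = mean_img[flat_geom] + spec.noise_sd * noise.reshape(per_sample, spec.p)
        if spec.noise == "lognormal":
            block = np.exp(np.log(np.maximum(mean_img[flat_geom], 1e-12))
                           + spec.noise_sd * noise.reshape(per_sample, spec.p))
        intensities[m * per_sample:(m + 1) * per_sample] = block
    np.maximum(intensities, 0.0, out=intensities)

    ii, jj = np.mgrid[1:height + 1, 1:width + 1]
    coords_one = np.column_stack([ii.ravel(), jj.ravel()])
    coords = np.tile(coords_one, (spec.n_samples, 1))
    sample_id = np.repeat(np.arange(1, spec.n_samples + 1), per_sample)
    mz = 100.0 + np.arange(spec.p, dtype=float)
    img = SpectraImage(intensities=intensities, coords=coords, sample_id=sample_id, mz=mz)
    labels = np.tile(flat_geom, spec.n_samples)
    return PhantomTruth(
        img=img,
        labels=labels,
        effect_table=pd.DataFrame(effect_rows, columns=["segment", "feature", "shift"]),
        spec=spec,
    )


def segmentation_accuracy(pred: np.ndarray, truth: np.ndarray):
    """Best-matching pixel accuracy between two labelings.

    Predicted labels are matched one-to-one to true labels by maximizing
    total agreement (Hungarian assignment on the contingency table);
    pixels of unmatched predicted labels all count as errors.  Returns
    (accuracy, mapping) with mapping[pred_label] = true_label.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise DimensionError("pred and truth must have equal length")
    pred_vals = np.unique(pred)
    true_vals = np.unique(truth)
    cont = np.zeros((pred_vals.size, true_vals.size), dtype=int)
    pi = np.searchsorted(pred_vals, pred)
    ti = np.searchsorted(true_vals, truth)
    np.add.at(cont, (pi, ti), 1)
    rows, cols = linear_sum_assignment(cont, maximize=True)
    matched = int(cont[rows, cols].sum())
    mapping = {
        int(pred_vals[r]) if np.issubdtype(pred_vals.dtype, np.integer) else pred_vals[r]:
        int(true_vals[c]) if np.issubdtype(true_vals.dtype, np.integer) else true_vals[c]
        for r, c in zip(rows, cols)
    }
    return matched / pred.size, mapping


def boundary_mask(truth_labels: np.ndarray, coords: np.ndarray, sample_id: np.ndarray) -> np.ndarray:
    """True where a pixel touches (4-neighborhood) a different true segment."""
    index = {
        (s, int(i), int(j)): n
        for n, (s, (i, j)) in enumerate(zip(sample_id.tolist(), coords.tolist()))
    }
    out = np.zeros(truth_labels.shape[0], dtype=bool)
    for n, (s, (i, j)) in enumerate(zip(sample_id.tolist(), coords.tolist())):
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = index.get((s, int(i) + di, int(j) + dj))
            if nb is not None and truth_labels[nb] != truth_labels[n]:
                out[n] = True
                break
    return out
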