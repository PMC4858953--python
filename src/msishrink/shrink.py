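"""Shrunken-centroid statistics for classes or segments.

Each class (or discovered segment) k is summarized by its centroid, the
mean spectrum over its member pixels.  The centroid is compared with the
overall centroid through a per-feature t-statistic

    t_kp = (xbar_kp - xbar_p) / (m_k * (tau_p + s0)),   m_k = sqrt(1/N_k - 1/N),

where tau_p is the pooled within-class standard deviation and m_k makes
the denominator the standard error of the numerator.  Soft thresholding
t'_kp = sign(t_kp) * max(|t_kp| - s, 0) shrinks the statistics toward
zero, and the shrunken centroid inverts the standardization:

    x'_kp = xbar_p + m_k * (tau_p + s0) * t'_kp.

Features with t'_kp = 0 are noninformative for class k — their shrunken
intensity is exactly the overall mean.  Features with t'_kp > 0 are
systematically enriched in class k, and t'_kp < 0 systematically absent,
relative to the overall mean spectrum.  The shrinkage parameter s trades
model complexity for interpretability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DimensionError, ParameterError
from .image import SpectraImage

__all__ = [
    "ShrunkenModel",
    "centroids",
    "pooled_sd",
    "soft_threshold",
    "shrunken_tstats",
    "shrunken_centroids",
    "fit_shrunken_model",
    "selected_features",
    "feature_report",
]


def _as_matrix(img) -> np.ndarray:
    if isinstance(img, SpectraImage):
        return img.intensities
    return np.asarray(img, dtype=float)


@dataclass
class ShrunkenModel:
    """Fitted shrunken-centroid summary of K classes over P features."""

    overall_centroid: np.ndarray      # (P,)
    class_centroids: np.ndarray       # (K, P)
    shrunken_centroids: np.ndarray    # (K, P)
    tstats: np.ndarray                # (K, P) shrunken t'_kp
    pooled_sd: np.ndarray             # (P,)
    counts: np.ndarray                # (K,)
    priors: np.ndarray                # (K,) sums to 1
    shrinkage: float                  # s >= 0
    sd_offset: float = 0.0            # s0 >= 0

    @property
    def n_classes(self) -> int:
        return self.class_centroids.shape[0]

    @property
    def n_features(self) -> int:
        return self.class_centroids.shape[1]

    def n_nonzero(self) -> int:
        """Number of (class, feature) cells with a surviving t-statistic."""
        return int(np.count_nonzero(self.tstats))


def centroids(img, labels: np.ndarray, n_classes: int | None = None):
    """Per-class mean spectra, the overall mean spectrum, and class sizes.

    ``labels`` are 0-based class indices.  The overall centroid is the mean
    over all pixels (not the mean of class means).
    """
    x = _as_matrix(img)
    labels = np.asarray(labels)
    n = x.shape[0]
    if labels.shape != (n,):
        raise DimensionError("labels must have one entry per pixel")
    k = int(labels.max()) + 1 if n_classes is None else n_classes
    if labels.min() < 0 or labels.max() >= k:
        raise ParameterError(f"labels must lie in 0..{k - 1}")
    counts = np.bincount(labels, minlength=k)
    if n_classes is None and np.any(counts == 0):
        raise ParameterError(
            f"classes {np.flatnonzero(counts == 0).tolist()} have no member pixels"
        )
    sums = np.zeros((k, x.shape[1]))
    np.add.at(sums, labels, x)
    class_cent = sums / np.maximum(counts, 1)[:, None]
    overall = x.mean(axis=0)
    return class_cent, overall, counts


def pooled_sd(img, labels: np.ndarray, class_centroids: np.ndarray) -> np.ndarray:
    """Pooled within-class standard deviation per feature.

    tau_p = sqrt( sum_k sum_{n in k} (x_np - xbar_kp)^2 / (N - K) ).
    """
    x = _as_matrix(img)
    labels = np.asarray(labels)
    n = x.shape[0]
    k = class_centroids.shape[0]
    if n <= k:
        raise ParameterError(f"pooled SD needs N > K (got N={n}, K={k})")
    resid = x - class_centroids[labels]
    return np.sqrt((resid ** 2).sum(axis=0) / (n - k))


def soft_threshold(t, s: float):
    """Soft-thresholding operator sign(t) * max(|t| - s, 0)."""
    if s < 0:
        raise ParameterError("shrinkage s must be nonnegative")
    t = np.asarray(t, dtype=float)
    out = np.sign(t) * np.maximum(np.abs(t) - s, 0.0)
    return out if out.ndim else float(out)


def _se_factor(counts: np.ndarray) -> np.ndarray:
    """m_k = sqrt(1/N_k - 1/N), the standard-error factor of the centroid
    difference; returns 0 for the degenerate single-class case N_k = N."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    with np.errstate(invalid="ignore"):
        m = np.sqrt(np.maximum(1.0 / counts - 1.0 / n, 0.0))
    return m


def shrunken_tstats(
    class_centroids: np.ndarray,
    overall_centroid: np.ndarray,
    pooled_sd: np.ndarray,
    counts: np.ndarray,
    s: float,
    sd_offset: float = 0.0,
) -> np.ndarray:
    """Soft-thresholded per-class, per-feature t-statistics t'_kp."""
    counts = np.asarray(counts)
    k = class_centroids.shape[0]
    if k == 1:
        # one class: centroid equals the overall mean, all statistics vanish
        return np.zeros_like(class_centroids)
    if np.any(counts == counts.sum()):
        raise ParameterError("a class containing every pixel leaves m_k undefined")
    denom_sd = pooled_sd + sd_offset
    if np.any(denom_sd <= 0):
        bad = np.flatnonzero(denom_sd <= 0).tolist()
        raise ParameterError(
            f"features {bad} have zero pooled SD; pass a positive sd_offset"
        )
    m = _se_factor(counts)
    t = (class_centroids - overall_centroid) / (m[:, None] * denom_sd)
    return soft_threshold(t, s)


def shrunken_centroids(
    overall_centroid: np.ndarray,
    pooled_sd: np.ndarray,
    counts: np.ndarray,
    tstats: np.ndarray,
    sd_offset: float = 0.0,
) -> np.ndarray:
    """Invert the t standardization: x'_kp = xbar_p + m_k (tau_p + s0) t'_kp."""
    m = _se_factor(counts)
    return overall_centroid + m[:, None] * (pooled_sd + sd_offset) * np.asarray(tstats)


def fit_shrunken_model(
    img,
    labels: np.ndarray,
    s: float,
    sd_offset: float = 0.0,
    priors: str | np.ndarray = "empirical",
    n_classes: int | None = None,
) -> ShrunkenModel:
    """One-pass fit of the full shrunken-centroid summary.

    ``priors`` is "empirical" (N_k/N), "uniform" (1/K), or an explicit
    K-vector summing to 1.
    """
    class_cent, overall, counts = centroids(img, labels, n_classes=n_classes)
    tau = pooled_sd(img, labels, class_cent)
    s0 = sd_offset
    if np.any(tau + s0 <= 0):
        # zero-variance features break the standardization; fall back to the
        # conventional median-SD offset for this fit
        med = float(np.median(tau[tau > 0])) if np.any(tau > 0) else 1.0
        s0 = med
    tprime = shrunken_tstats(class_cent, overall, tau, counts, s, s0)
    shrunk = shrunken_centroids(overall, tau, counts, tprime, s0)
    k = class_cent.shape[0]
    if isinstance(priors, str):
        if priors == "empirical":
            pri = counts / counts.sum()
        elif priors == "uniform":
            pri = np.full(k, 1.0 / k)
        else:
            raise ParameterError(f"unknown priors spec {priors!r}")
    else:
        pri = np.asarray(priors, dtype=float)
        if pri.shape != (k,) or not np.isclose(pri.sum(), 1.0):
            raise ParameterError("explicit priors must be a K-vector summing to 1")
    return ShrunkenModel(
        overall_centroid=overall,
        class_centroids=class_cent,
        shrunken_centroids=shrunk,
        tstats=tprime,
        pooled_sd=tau,
        counts=counts,
        priors=pri,
        shrinkage=float(s),
        sd_offset=float(s0),
    )


def selected_features(model: ShrunkenModel, mz: np.ndarray | None = None):
    """Informative features per class, split by direction.

    Returns a list (one entry per class) of dicts with keys ``enriched``
    (feature indices with t' > 0) and ``absent`` (t' < 0), each ranked by
    |t'| descending with ties broken by ascending m/z (or feature index).
    """
    if mz is None:
        mz = np.arange(model.n_features)
    out = []
    for k in range(model.n_classes):
        t = model.tstats[k]
        order = np.lexsort((mz, -np.abs(t)))
        enriched = [int(p) for p in order if t[p] > 0]
        absent = [int(p) for p in order if t[p] < 0]
        out.append({"enriched": enriched, "absent": absent})
    return out


def feature_report(model: ShrunkenModel, mz: np.ndarray | None = None) -> pd.DataFrame:
    """Tabulate the informative features: class, m/z, t', direction, rank."""
    if mz is None:
        mz = np.arange(model.n_features, dtype=float)
    sel = selected_features(model, mz)
    rows = []
    for k, lists in enumerate(sel):
        for direction in ("enriched", "absent"):
            for rank, p in enumerate(lists[direction], start=1):
                rows.append(
                    {
                        "class": k + 1,
                        "mz": float(mz[p]),
                        "t_prime": float(model.tstats[k, p]),
                        "direction": direction,
                        "rank": rank,
                    }
                )
    return pd.DataFrame(rows, columns=["class", "mz", "t_prime", "direction", "rank"])
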