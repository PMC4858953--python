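"""Unsupervised spatial shrunken centroids segmentation.

Starting from K initial segments, each iteration (1) recomputes segment
centroids and drops segments that have lost all their pixels, (2) refits
the shrunken-centroid summary at shrinkage s, (3) computes the spatially
aware squared distance of every pixel to every shrunken centroid, and
(4) reassigns each pixel to the segment with the highest membership
probability (uniform priors 1/K over the current segments).  Shrinkage is
what selects the number of segments: segments that are distinguished only
by noninformative features collapse onto the overall centroid, empty out
and are removed, so the final count of nonempty segments is data-driven.

``param_grid`` / ``select_params`` implement the selection heuristic:
run several initial K over an increasing s grid and pick the smallest s
at which the final segment count agrees across the K values and has
stopped decreasing.

Non-spatial baselines (k-means on spectra, k-means on principal
components) and the spatially aware clustering analogues are provided for
comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .image import SpectraImage
from .inference import MembershipMatrix, membership_from_distances
from .shrink import ShrunkenModel, fit_shrunken_model
from .spatial import (
    NeighborhoodIndex,
    WeightSet,
    adaptive_weights,
    build_neighborhoods,
    gaussian_weights,
    spatial_sq_distances,
)

__all__ = [
    "SegmentationResult",
    "ParamSelection",
    "fit_segmentation",
    "drop_empty",
    "param_grid",
    "select_params",
    "baselines",
]

log = logging.getLogger(__name__)


@dataclass
class SegmentationResult:
    """Outcome of one spatial shrunken centroids segmentation run."""

    model: ShrunkenModel
    membership: MembershipMatrix
    history: list            # per-iteration count of label changes
    n_segments_final: int
    params: dict = field(default_factory=dict)
    converged: bool = False

    @property
    def labels(self) -> np.ndarray:
        return self.membership.labels


@dataclass
class ParamSelection:
    """Chosen (K, s) from a parameter grid, with the stabilization flag."""

    k_init: int
    s: float
    n_segments: int
    stabilized: bool


def drop_empty(labels: np.ndarray, n_segments: int):
    """Remove empty segments and renumber the rest, preserving order.

    Returns (new_labels, n_remaining, mapping) where mapping[old] = new
    for surviving segments.
    """
    counts = np.bincount(labels, minlength=n_segments)
    keep = np.flatnonzero(counts > 0)
    mapping = {int(old): new for new, old in enumerate(keep)}
    lut = np.full(n_segments, -1, dtype=int)
    lut[keep] = np.arange(keep.size)
    return lut[labels], int(keep.size), mapping


def _make_weights(
    img: SpectraImage, nbhd: NeighborhoodIndex, kind: str, sigma: float | None
) -> WeightSet:
    if kind == "sa":
        return gaussian_weights(nbhd, sigma)
    if kind == "sasa":
        return adaptive_weights(nbhd, img, sigma)
    raise ParameterError(f"weights kind must be 'sa' or 'sasa', got {kind!r}")


def _init_labels(
    img: SpectraImage, k: int, init: str, seed: int, r: int, sigma: float | None
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    if init == "random":
        return rng.integers(0, k, size=img.n_pixels)
    if init == "kmeans":
        return baselines(img, k, "kmeans", seed=seed)
    if init == "sa_cluster":
        return baselines(img, k, "sa_cluster", r=r, seed=seed)
    raise ParameterError(f"unknown init {init!r}")


def _fit_step(img, labels, k_cur, s, sd_offset, priors):
    """Fit the shrunken model for the current labels and eliminate
    spurious segments.

    A segment whose t-statistics are all shrunk to zero has no informative
    feature left — its shrunken centroid coincides with the overall
    centroid, so no feature matters when assigning pixels to it.  Such
    segments are spurious by construction and are removed, unless every
    segment is noninformative (the full-shrinkage limit, where the
    centroids coincide and tie-breaking collapses the segmentation
    instead).  Returns (reduced model, kept segment indices).
    """
    model = fit_shrunken_model(
        img, labels, s=s, sd_offset=sd_offset,
        priors=priors if priors in ("uniform", "empirical") else "uniform",
        n_classes=k_cur,
    )
    informative = np.any(model.tstats != 0, axis=1)
    if informative.all() or not informative.any():
        return model, np.arange(k_cur)
    keep = np.flatnonzero(informative)
    counts = model.counts[keep]
    if priors == "empirical":
        pri = counts / counts.sum()
    else:
        pri = np.full(keep.size, 1.0 / keep.size)
    reduced = ShrunkenModel(
        overall_centroid=model.overall_centroid,
        class_centroids=model.class_centroids[keep],
        shrunken_centroids=model.shrunken_centroids[keep],
        tstats=model.tstats[keep],
        pooled_sd=model.pooled_sd,
        counts=counts,
        priors=pri,
        shrinkage=model.shrinkage,
        sd_offset=model.sd_offset,
    )
    return reduced, keep


def fit_segmentation(
    img: SpectraImage,
    k: int,
    s: float,
    r: int = 1,
    weights: str = "sa",
    init: str = "kmeans",
    max_iter: int = 20,
    seed: int = 0,
    sigma: float | None = None,
    sd_offset: float = 0.0,
    priors: str = "uniform",
    nbhd: NeighborhoodIndex | None = None,
    weight_set: WeightSet | None = None,
) -> SegmentationResult:
    """Iterative spatial shrunken centroids segmentation.

    ``nbhd`` and ``weight_set`` may be passed to reuse a precomputed
    neighborhood index and weights across fits on the same image (they
    depend only on the image geometry/spectra, not on K or s).
    """
    if k < 2:
        raise ParameterError("need at least K=2 initial segments")
    if k >= img.n_pixels:
        raise ParameterError("K must be smaller than the number of pixels")
    if nbhd is None:
        nbhd = build_neighborhoods(img, r)
    if weight_set is None:
        weight_set = _make_weights(img, nbhd, weights, sigma)
    w_sparse = weight_set.to_sparse(nbhd)

    labels = np.asarray(_init_labels(img, k, init, seed, r, sigma), dtype=int)
    k_cur = k
    history: list[int] = []
    converged = False
    model = None
    member = None
    for it in range(max_iter):
        labels, k_cur, _ = drop_empty(labels, k_cur)
        if k_cur == 1:
            warnings.warn("all pixels collapsed into a single segment")
            model = fit_shrunken_model(img, labels, s=s, sd_offset=sd_offset,
                                       priors="uniform", n_classes=1)
            member = MembershipMatrix(
                probs=np.ones((img.n_pixels, 1)),
                scores=np.zeros((img.n_pixels, 1)),
                labels=labels,
                priors=np.ones(1),
            )
            history.append(0)
            converged = True
            break
        model, keep = _fit_step(img, labels, k_cur, s, sd_offset, priors)
        # spurious segments whose every t' is zero have no feature that
        # matters for assignment; regularization has removed them
        lut = np.full(k_cur, -1, dtype=int)
        lut[keep] = np.arange(keep.size)
        k_cur = keep.size
        scale = model.pooled_sd + model.sd_offset
        d = spatial_sq_distances(img, w_sparse, model.shrunken_centroids, scale)
        member = membership_from_distances(d, model.priors)
        changes = int(np.count_nonzero(member.labels != lut[labels]))
        history.append(changes)
        log.info(
            "segmentation iter %d: %d label changes, %d nonempty segments",
            it + 1, changes, int(np.unique(member.labels).size),
        )
        labels = member.labels
        if changes == 0 or changes < 1e-3 * img.n_pixels:
            converged = True
            if changes > 0:
                # the final reassignment may have emptied a segment; refit so
                # the reported model and probabilities match the final labels
                labels, k_cur, _ = drop_empty(labels, k_cur)
                if k_cur == 1:
                    model = fit_shrunken_model(img, labels, s=s, sd_offset=sd_offset,
                                               priors="uniform", n_classes=1)
                    member = MembershipMatrix(
                        probs=np.ones((img.n_pixels, 1)),
                        scores=np.zeros((img.n_pixels, 1)),
                        labels=labels,
                        priors=np.ones(1),
                    )
                    break
                model, keep = _fit_step(img, labels, k_cur, s, sd_offset, priors)
                k_cur = keep.size
                scale = model.pooled_sd + model.sd_offset
                d = spatial_sq_distances(img, w_sparse, model.shrunken_centroids, scale)
                member = membership_from_distances(d, model.priors)
            break

    final_labels = member.labels
    n_final = int(np.unique(final_labels).size)
    return SegmentationResult(
        model=model,
        membership=member,
        history=history,
        n_segments_final=n_final,
        params={
            "k_init": k, "s": s, "r": r, "weights": weight_set.kind,
            "init": init, "max_iter": max_iter, "seed": seed,
        },
        converged=converged,
    )


def param_grid(
    img: SpectraImage,
    k_list,
    s_list,
    r: int = 1,
    weights: str = "sa",
    seed: int = 0,
    **fit_kw,
) -> pd.DataFrame:
    """One segmentation per (K, s) cell; table sorted by (K, s).

    Failures in individual cells are recorded in the ``error`` column
    rather than aborting the grid.
    """
    k_list = sorted(set(int(k) for k in k_list))
    s_list = sorted(set(float(s) for s in s_list))
    if not k_list or not s_list:
        raise ParameterError("k_list and s_list must be nonempty")
    nbhd = build_neighborhoods(img, r)
    wset = _make_weights(img, nbhd, weights, fit_kw.get("sigma"))
    rows = []
    for k in k_list:
        for s in s_list:
            row = {"k_init": k, "s": s}
            try:
                res = fit_segmentation(
                    img, k, s, r=r, weights=weights, seed=seed,
                    nbhd=nbhd, weight_set=wset, **fit_kw,
                )
                row["n_segments_final"] = res.n_segments_final
                row["mean_max_prob"] = float(res.membership.max_probability().mean())
                row["converged"] = res.converged
                row["error"] = ""
            except Exception as exc:  # record, keep going
                row["n_segments_final"] = -1
                row["mean_max_prob"] = np.nan
                row["converged"] = False
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def select_params(grid_table: pd.DataFrame) -> ParamSelection:
    """Pick (K, s) from a parameter-grid table.

    Chooses the smallest s at which the final segment count (a) agrees
    across all initial K and (b) is unchanged at the next larger s.  If no
    s qualifies, falls back to the largest s where the K rows agree and
    flags the selection as not stabilized.
    """
    tab = grid_table[grid_table["error"] == ""] if "error" in grid_table else grid_table
    pivot = tab.pivot_table(
        index="s", columns="k_init", values="n_segments_final", aggfunc="first"
    ).sort_index()
    s_values = pivot.index.to_numpy()
    k_values = pivot.columns.to_numpy()
    agree = pivot.nunique(axis=1).to_numpy() == 1
    common = pivot.iloc[:, 0].to_numpy()
    for i in range(len(s_values) - 1):
        if agree[i] and agree[i + 1] and common[i] == common[i + 1]:
            return ParamSelection(
                k_init=int(k_values.min()),
                s=float(s_values[i]),
                n_segments=int(common[i]),
                stabilized=True,
            )
    if np.any(agree):
        i = int(np.flatnonzero(agree)[-1])
        return ParamSelection(
            k_init=int(k_values.min()),
            s=float(s_values[i]),
            n_segments=int(common[i]),
            stabilized=False,
        )
    # no agreement anywhere: report the largest-s row of the smallest K
    return ParamSelection(
        k_init=int(k_values.min()),
        s=float(s_values[-1]),
        n_segments=int(pivot.iloc[-1, 0]),
        stabilized=False,
    )


def baselines(
    img: SpectraImage,
    k: int,
    variant: str,
    n_pcs: int = 5,
    r: int = 1,
    seed: int = 0,
    max_iter: int = 100,
    sigma: float | None = None,
) -> np.ndarray:
    """Reference segmentations: k-means, PCA + k-means, SA/SASA clustering.

    The SA/SASA variants run a k-means-style loop under the spatially
    aware distance: centroids are plain segment means and pixels are
    assigned by the spatial squared distance to each centroid (unit
    feature scale).
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    if k < 2:
        raise ParameterError("baselines need K >= 2")
    x = img.intensities
    if variant == "kmeans":
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        return km.fit_predict(x)
    if variant == "pca_kmeans":
        scores = PCA(n_components=min(n_pcs, x.shape[1]), random_state=seed).fit_transform(x)
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        return km.fit_predict(scores)
    if variant in ("sa_cluster", "sasa_cluster"):
        nbhd = build_neighborhoods(img, r)
        kind = "sa" if variant == "sa_cluster" else "sasa"
        wset = _make_weights(img, nbhd, kind, sigma)
        w_sparse = wset.to_sparse(nbhd)
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(x)
        k_cur = k
        for _ in range(max_iter):
            labels, k_cur, _ = drop_empty(labels, k_cur)
            if k_cur == 1:
                break
            sums = np.zeros((k_cur, x.shape[1]))
            np.add.at(sums, labels, x)
            cent = sums / np.bincount(labels, minlength=k_cur)[:, None]
            d = spatial_sq_distances(img, w_sparse, cent)
            new = np.argmin(d, axis=1)
            if np.array_equal(new, labels):
                break
            labels = new
        return labels
    raise ParameterError(f"unknown baseline variant {variant!r}")
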