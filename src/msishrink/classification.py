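"""Supervised spatial shrunken centroids classification.

Fitting is a single pass: centroids, pooled SDs and shrunken t-statistics
from the annotated training pixels.  Prediction computes spatially aware
distances from each pixel of the target image to the shrunken centroids
(spatial weights built on the target image's own geometry) and converts
them to class probabilities with the training priors.

The shrinkage parameter s is selected by leave-one-sample-out
cross-validation: each sample (slide) is an experimental unit, so no
pixel of a held-out sample ever influences its fold's training fit —
pixel-level folds would leak through spatial autocorrelation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DimensionError, ParameterError
from .image import SpectraImage
from .inference import MembershipMatrix, membership_from_distances
from .shrink import ShrunkenModel, fit_shrunken_model
from .spatial import adaptive_weights, build_neighborhoods, gaussian_weights, spatial_sq_distances

__all__ = ["ClassifierModel", "CVReport", "fit_classifier", "predict", "cross_validate"]

log = logging.getLogger(__name__)


@dataclass
class ClassifierModel:
    """Spatial shrunken centroids classifier fit on annotated pixels."""

    model: ShrunkenModel
    class_names: list
    r: int
    weights: str
    s: float
    sigma: float | None = None
    mz: np.ndarray | None = None


@dataclass
class CVReport:
    """Leave-one-sample-out cross-validation results over an s grid."""

    table: pd.DataFrame          # fold, sample, s, n_correct, n_total, accuracy
    mean_accuracy: pd.Series     # indexed by s
    chosen_s: float
    folds: list = field(default_factory=list)


def _encode_labels(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    names = np.unique(labels)
    lut = {name: k for k, name in enumerate(names.tolist())}
    return np.array([lut[v] for v in labels.tolist()], dtype=int), names.tolist()


def fit_classifier(
    img: SpectraImage,
    labels,
    s: float,
    r: int = 1,
    weights: str = "sa",
    priors: str | np.ndarray = "empirical",
    sd_offset: float = 0.0,
    sigma: float | None = None,
) -> ClassifierModel:
    """Fit shrunken centroids of the known classes (no iteration)."""
    enc, names = _encode_labels(labels)
    if len(names) < 2:
        raise ParameterError("need at least two classes")
    counts = np.bincount(enc)
    if np.any(counts < 2):
        small = [names[k] for k in np.flatnonzero(counts < 2)]
        raise ParameterError(f"classes {small} have fewer than 2 pixels")
    model = fit_shrunken_model(img, enc, s=s, sd_offset=sd_offset, priors=priors)
    return ClassifierModel(
        model=model, class_names=names, r=r, weights=weights, s=s,
        sigma=sigma, mz=np.asarray(img.mz, dtype=float),
    )


def predict(clf: ClassifierModel, img: SpectraImage, mz_tol: float | None = None) -> MembershipMatrix:
    """Per-pixel class probabilities and labels on a (possibly new) image.

    Features must match the training m/z axis; with ``mz_tol`` set, axes
    are accepted if every m/z agrees within the tolerance.
    """
    if clf.mz is not None:
        if img.n_features != clf.mz.size:
            raise DimensionError(
                f"image has {img.n_features} features, model expects {clf.mz.size}"
            )
        tol = 0.0 if mz_tol is None else mz_tol
        if np.any(np.abs(img.mz - clf.mz) > tol):
            raise DimensionError("m/z axis differs from the training axis")
    nbhd = build_neighborhoods(img, clf.r)
    if clf.weights == "sa":
        wset = gaussian_weights(nbhd, clf.sigma)
    else:
        wset = adaptive_weights(nbhd, img, clf.sigma)
    scale = clf.model.pooled_sd + clf.model.sd_offset
    d = spatial_sq_distances(img, wset.to_sparse(nbhd), clf.model.shrunken_centroids, scale)
    return membership_from_distances(d, clf.model.priors)


def cross_validate(
    img: SpectraImage,
    labels,
    s_list,
    r: int = 1,
    weights: str = "sa",
    priors: str = "empirical",
    sd_offset: float = 0.0,
    sigma: float | None = None,
) -> CVReport:
    """Leave-one-sample-out cross-validation of the shrinkage parameter.

    Every sample is held out once; the classifier is fit on the remaining
    samples at each s and scored by pixel accuracy on the held-out sample.
    Folds whose training part lacks a class are skipped with a warning.
    The chosen s maximizes mean held-out accuracy; ties resolve toward
    larger s (stronger shrinkage, fewer features).
    """
    labels = np.asarray(labels)
    s_list = sorted(set(float(s) for s in s_list))
    samples = img.samples
    if samples.size < 2:
        raise ParameterError("cross-validation needs at least 2 samples")
    rows = []
    used_folds = []
    for fold, held in enumerate(samples.tolist()):
        test_mask = img.sample_id == held
        train_mask = ~test_mask
        if np.unique(labels[train_mask]).size < np.unique(labels).size:
            log.warning("fold %r skipped: training part is missing a class", held)
            continue
        used_folds.append(held)
        train_img = img.subset(train_mask)
        test_img = img.subset(test_mask)
        y_test = labels[test_mask]
        for s in s_list:
            clf = fit_classifier(
                train_img, labels[train_mask], s=s, r=r, weights=weights,
                priors=priors, sd_offset=sd_offset, sigma=sigma,
            )
            member = predict(clf, test_img)
            pred = np.array([clf.class_names[k] for k in member.labels])
            n_correct = int(np.count_nonzero(pred == y_test.astype(pred.dtype)))
            rows.append(
                {
                    "fold": fold, "sample": held, "s": s,
                    "n_correct": n_correct, "n_total": int(y_test.size),
                    "accuracy": n_correct / y_test.size,
                }
            )
    if not rows:
        raise ParameterError("every fold was skipped; check class/sample layout")
    table = pd.DataFrame(rows)
    grouped = table.groupby("s")
    mean_acc = grouped["n_correct"].sum() / grouped["n_total"].sum()
    best = mean_acc.max()
    chosen_s = float(max(s for s, a in mean_acc.items() if np.isclose(a, best)))
    return CVReport(table=table, mean_accuracy=mean_acc, chosen_s=chosen_s, folds=used_folds)
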