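"""Discriminant scores, membership probabilities and hard assignment.

By analogy with linear discriminant analysis, each class k is treated as
a Gaussian with a shared diagonal covariance, so that with the spatially
aware squared distance d^2_k (already standardized per feature by
tau_p + s0) the discriminant score is

    score_k = d^2_k - 2 log pi_k,

lower being better, and the membership probability the softmax

    p_k = exp(-score_k / 2) / sum_l exp(-score_l / 2).

The spatial averaging means the scores are not exactly Gaussian
log-likelihoods; the softmax values are reported as membership
probabilities in the empirical sense and computed with max-subtraction
for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = [
    "MembershipMatrix",
    "discriminant_scores",
    "class_probabilities",
    "assign",
]


@dataclass
class MembershipMatrix:
    """Per-pixel class membership: probabilities, scores and labels."""

    probs: np.ndarray    # (N, K), rows sum to 1
    scores: np.ndarray   # (N, K) discriminant scores
    labels: np.ndarray   # (N,) 0-based argmax class per pixel
    priors: np.ndarray   # (K,)

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]

    def max_probability(self) -> np.ndarray:
        """Confidence of the assigned class per pixel."""
        return self.probs.max(axis=1)

    def to_frame(self, coords: np.ndarray, sample_id: np.ndarray) -> pd.DataFrame:
        """Long-form table (sample, i, j, label, p_1..p_K), labels 1-based."""
        data = {
            "sample": sample_id,
            "i": coords[:, 0],
            "j": coords[:, 1],
            "label": self.labels + 1,
        }
        for k in range(self.n_classes):
            data[f"p_{k + 1}"] = self.probs[:, k]
        return pd.DataFrame(data)


def discriminant_scores(spatial_sq_dists: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """score[n, k] = d^2[n, k] - 2 log pi_k; lower is better.

    ``spatial_sq_dists`` must already include the per-feature
    standardization by tau_p + s0.
    """
    d = np.asarray(spatial_sq_dists, dtype=float)
    priors = np.asarray(priors, dtype=float)
    if np.any(priors <= 0):
        raise ParameterError("all class priors must be positive")
    if d.ndim != 2 or d.shape[1] != priors.shape[0]:
        raise ParameterError("distances must be (N, K) with K matching priors")
    return d - 2.0 * np.log(priors)[None, :]


def class_probabilities(scores: np.ndarray) -> np.ndarray:
    """Row-stochastic softmax of exp(-score/2), max-stabilized."""
    s = np.asarray(scores, dtype=float)
    logp = -0.5 * s
    logp = logp - logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True)


def assign(probs: np.ndarray) -> np.ndarray:
    """Argmax class per pixel; ties resolve to the lowest class index."""
    return np.argmax(np.asarray(probs), axis=1)


def membership_from_distances(
    spatial_sq_dists: np.ndarray, priors: np.ndarray
) -> MembershipMatrix:
    """Convenience: distances -> scores -> probabilities -> labels."""
    scores = discriminant_scores(spatial_sq_dists, priors)
    probs = class_probabilities(scores)
    return MembershipMatrix(
        probs=probs,
        scores=scores,
        labels=assign(probs),
        priors=np.asarray(priors, dtype=float),
    )
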