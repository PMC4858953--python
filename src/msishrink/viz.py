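"""Figure outputs: probability-transparency maps, ion images, curves.

Every plot writes a PNG and a TSV sidecar with the plotted numbers, so
figures are views and the numbers remain the record.
"""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_probability_map",
    "plot_segment_curve",
    "plot_tstats",
    "plot_ion_image",
]


def _grid_extent(coords: np.ndarray):
    i0, j0 = coords.min(axis=0)
    i1, j1 = coords.max(axis=0)
    return int(i0), int(i1), int(j0), int(j1)


def _raster(coords: np.ndarray, values: np.ndarray, fill=np.nan) -> np.ndarray:
    i0, i1, j0, j1 = _grid_extent(coords)
    out = np.full((i1 - i0 + 1, j1 - j0 + 1) + values.shape[1:], fill, dtype=float)
    out[coords[:, 0] - i0, coords[:, 1] - j0] = values
    return out


def plot_probability_map(membership, coords: np.ndarray, path: str, title: str = "") -> str:
    """Segment map with per-pixel transparency equal to the max probability.

    Accepts a :class:`~msishrink.inference.MembershipMatrix` or a
    :class:`~msishrink.segmentation.SegmentationResult`.  Low-confidence
    pixels fade out, so uncertain regions (typically segment boundaries)
    are visually distinguishable from confident interiors.
    """
    if hasattr(membership, "membership"):
        membership = membership.membership
    labels = membership.labels
    alpha = membership.max_probability()
    k = membership.n_classes
    cmap = plt.get_cmap("tab10" if k <= 10 else "tab20")
    rgba = np.array([cmap(l % cmap.N) for l in labels])
    rgba[:, 3] = alpha
    img = _raster(coords, rgba, fill=0.0)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(img, origin="upper", interpolation="nearest")
    ax.set_xlabel("j")
    ax.set_ylabel("i")
    ax.set_title(title or "segment membership (alpha = max probability)")
    handles = [plt.Rectangle((0, 0), 1, 1, color=cmap(kk % cmap.N)) for kk in range(k)]
    ax.legend(handles, [f"segment {kk + 1}" for kk in range(k)],
              loc="center left", bbox_to_anchor=(1.01, 0.5), fontsize="small")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    pd.DataFrame(
        {"i": coords[:, 0], "j": coords[:, 1], "label": labels + 1, "max_prob": alpha}
    ).to_csv(os.path.splitext(path)[0] + ".tsv", sep="\t", index=False)
    return path


def plot_segment_curve(grid_table: pd.DataFrame, path: str, chosen=None) -> str:
    """Final segment count versus shrinkage s, one line per initial K."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for k, sub in grid_table.groupby("k_init"):
        sub = sub.sort_values("s")
        ax.plot(sub["s"], sub["n_segments_final"], marker="o", label=f"K = {k}")
    if chosen is not None:
        ax.scatter([chosen.s], [chosen.n_segments], s=120, facecolors="none",
                   edgecolors="red", zorder=5, label="chosen")
    ax.set_xlabel("shrinkage s")
    ax.set_ylabel("final nonempty segments")
    ax.legend()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    grid_table.to_csv(os.path.splitext(path)[0] + ".tsv", sep="\t", index=False)
    return path


def plot_tstats(model, mz: np.ndarray, path: str) -> str:
    """Shrunken t-statistics per feature, one panel per class/segment."""
    k = model.n_classes
    fig, axes = plt.subplots(k, 1, figsize=(6, 1.8 * k), sharex=True, squeeze=False)
    rows = []
    for kk in range(k):
        ax = axes[kk, 0]
        ax.stem(mz, model.tstats[kk], basefmt=" ", markerfmt=".")
        ax.set_ylabel(f"t' (seg {kk + 1})")
        for p, t in enumerate(model.tstats[kk]):
            rows.append({"class": kk + 1, "mz": float(mz[p]), "t_prime": float(t)})
    axes[-1, 0].set_xlabel("m/z")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    pd.DataFrame(rows).to_csv(os.path.splitext(path)[0] + ".tsv", sep="\t", index=False)
    return path


def plot_ion_image(img, feature: int, path: str, sample=None) -> str:
    """False-color intensity map of a single m/z feature."""
    mask = np.ones(img.n_pixels, dtype=bool) if sample is None else img.sample_id == sample
    coords = img.coords[mask]
    vals = img.intensities[mask, feature]
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(_raster(coords, vals), origin="upper", interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(f"m/z {img.mz[feature]:.4g}")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    pd.DataFrame(
        {"i": coords[:, 0], "j": coords[:, 1], "intensity": vals}
    ).to_csv(os.path.splitext(path)[0] + ".tsv", sep="\t", index=False)
    return path
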