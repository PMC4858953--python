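"""In-memory container for a peak-picked MS imaging dataset.

A :class:`SpectraImage` holds the pixels-by-features intensity matrix of a
mass spectrometry imaging experiment together with the integer grid
coordinates of each pixel, the sample each pixel belongs to, and the m/z
axis.  Samples need not be rectangular: pixels are stored as an explicit
coordinate list, so irregular footprints (tissue outlines, cropped regions)
are first-class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DimensionError, FormatError, UniquenessError

__all__ = ["SpectraImage"]


@dataclass
class SpectraImage:
    """Pixel spectra on an integer grid.

    Parameters
    ----------
    intensities : ndarray, shape (N, P)
        Nonnegative feature intensities, one row per pixel.
    coords : ndarray, shape (N, 2)
        Integer (i, j) grid positions, 1-based by convention.
    sample_id : ndarray, shape (N,)
        Sample membership of each pixel (integers or strings).
    mz : ndarray, shape (P,)
        Strictly ascending m/z value of each feature column.
    feature_names : list of str, optional
        Human-readable feature labels.
    """

    intensities: np.ndarray
    coords: np.ndarray
    sample_id: np.ndarray
    mz: np.ndarray
    feature_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.coords = np.asarray(self.coords)
        self.sample_id = np.asarray(self.sample_id)
        self.mz = np.asarray(self.mz, dtype=float)
        if self.intensities.ndim != 2:
            raise DimensionError("intensities must be a 2-D (pixels x features) matrix")
        n, p = self.intensities.shape
        if self.coords.shape != (n, 2):
            raise DimensionError(
                f"coords shape {self.coords.shape} does not match {n} pixels"
            )
        if not np.issubdtype(self.coords.dtype, np.integer):
            rounded = np.rint(np.asarray(self.coords, dtype=float))
            if not np.array_equal(rounded, np.asarray(self.coords, dtype=float)):
                raise FormatError("coords must be integer grid positions")
            self.coords = rounded.astype(int)
        if self.sample_id.shape != (n,):
            raise DimensionError("sample_id must have one entry per pixel")
        if self.mz.shape != (p,):
            raise DimensionError(
                f"mz length {self.mz.shape} does not match {p} intensity columns"
            )
        if p > 1 and not np.all(np.diff(self.mz) > 0):
            raise FormatError("mz axis must be strictly ascending")
        if not np.all(np.isfinite(self.intensities)):
            raise FormatError("intensities must all be finite")
        keys = {(s, i, j) for s, (i, j) in zip(self.sample_id.tolist(), self.coords.tolist())}
        if len(keys) != n:
            raise UniquenessError("duplicate (sample, i, j) pixel locations")
        if self.feature_names is not None and len(self.feature_names) != p:
            raise DimensionError("feature_names length must equal number of features")

    # -- basic geometry -------------------------------------------------

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def samples(self) -> np.ndarray:
        """Unique sample identifiers in first-appearance order."""
        _, idx = np.unique(self.sample_id, return_index=True)
        return self.sample_id[np.sort(idx)]

    def pixel_index(self) -> dict:
        """Map (sample, i, j) -> row number."""
        return {
            (s, i, j): n
            for n, (s, (i, j)) in enumerate(zip(self.sample_id.tolist(), self.coords.tolist()))
        }

    def subset(self, mask: np.ndarray) -> "SpectraImage":
        """Return the image restricted to the pixels where ``mask`` is True."""
        mask = np.asarray(mask)
        return SpectraImage(
            intensities=self.intensities[mask],
            coords=self.coords[mask],
            sample_id=self.sample_id[mask],
            mz=self.mz.copy(),
            feature_names=self.feature_names,
        )

    def allclose(self, other: "SpectraImage", rtol: float = 1e-6, atol: float = 1e-9) -> bool:
        return (
            self.intensities.shape == other.intensities.shape
            and np.allclose(self.intensities, other.intensities, rtol=rtol, atol=atol)
            and np.array_equal(self.coords, other.coords)
            and np.array_equal(self.sample_id.astype(str), other.sample_id.astype(str))
            and np.allclose(self.mz, other.mz, rtol=rtol, atol=atol)
        )
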