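"""Reading, writing and plumbing-level preprocessing of MS imaging data.

Supported on-disk forms:

* imzML 1.1 (paired ``.imzML`` XML + ``.ibd`` binary), continuous or
  processed mode, via :mod:`pyimzml`;
* a delimited text pair: an intensity table whose header row is the m/z
  axis, plus a coordinate table with ``sample``, ``i``, ``j`` columns.

Preprocessing here is deliberately minimal — total-ion-current
normalization and m/z binning only.  Peak picking, baseline reduction and
smoothing are upstream concerns: the statistical method expects already
detected, aligned and quantified features.
"""

from __future__ import annotations

import os
import warnings

import numpy as np
import pandas as pd

from .exceptions import DimensionError, FormatError, ParameterError
from .image import SpectraImage

__all__ = [
    "read_imzml",
    "write_imzml",
    "read_matrix",
    "write_matrix",
    "tic_normalize",
    "bin_mz",
]


def read_imzml(path: str | os.PathLike) -> SpectraImage:
    """Read an imzML/ibd pair into a :class:`SpectraImage`.

    Continuous-mode files share one m/z axis.  Processed-mode spectra are
    placed onto the union grid of all observed m/z values; grid points a
    pixel never measured are filled with zero.  The imzML z position is
    interpreted as the sample index (see :func:`write_imzml`).
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"imzML file not found: {path}")
    ibd = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(ibd):
        raise FileNotFoundError(f"missing ibd binary for {path}: expected {ibd}")
    if os.path.getsize(path) == 0:
        raise FormatError(f"empty imzML file: {path}")
    try:
        parser = ImzMLParser(path)
    except Exception as exc:  # malformed XML etc.
        raise FormatError(f"could not parse imzML file {path}: {exc}") from exc

    n = len(parser.coordinates)
    if n == 0:
        raise FormatError(f"imzML file {path} contains no spectra")
    spectra = []
    for idx in range(n):
        mzs, ints = parser.getspectrum(idx)
        mzs = np.asarray(mzs, dtype=float)
        ints = np.asarray(ints, dtype=float)
        if mzs.size > 1 and np.any(np.diff(mzs) < 0):
            raise FormatError(f"non-monotone m/z axis in spectrum {idx} of {path}")
        spectra.append((mzs, ints))

    first = spectra[0][0]
    continuous = all(
        s[0].shape == first.shape and np.array_equal(s[0], first) for s in spectra
    )
    if continuous:
        mz = first
        intensities = np.vstack([s[1] for s in spectra])
    else:
        mz = np.unique(np.concatenate([s[0] for s in spectra]))
        intensities = np.zeros((n, mz.size))
        for row, (mzs, ints) in enumerate(spectra):
            cols = np.searchsorted(mz, mzs)
            np.add.at(intensities[row], cols, ints)

    coords = np.array([(c[0], c[1]) for c in parser.coordinates], dtype=int)
    sample = np.array([c[2] if len(c) > 2 else 1 for c in parser.coordinates], dtype=int)
    return SpectraImage(intensities=intensities, coords=coords, sample_id=sample, mz=mz)


def write_imzml(img: SpectraImage, path: str | os.PathLike) -> str:
    """Write a continuous-mode imzML/ibd pair (64-bit m/z, 32-bit intensity).

    The sample index of each pixel is stored as the z position so that
    multi-sample images survive a round trip.  Non-integer sample ids are
    mapped to 1..M with a warning.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = os.fspath(path)
    if img.n_pixels == 0:
        raise ParameterError("cannot write an image with zero pixels")
    if np.issubdtype(img.sample_id.dtype, np.integer):
        z = img.sample_id.astype(int)
    else:
        uniq = list(dict.fromkeys(img.sample_id.tolist()))
        warnings.warn(
            "non-integer sample ids mapped to integer z positions 1..M for imzML"
        )
        lut = {s: m + 1 for m, s in enumerate(uniq)}
        z = np.array([lut[s] for s in img.sample_id.tolist()], dtype=int)
    try:
        with ImzMLWriter(path, mode="continuous") as writer:
            for row in range(img.n_pixels):
                i, j = img.coords[row]
                writer.addSpectrum(
                    img.mz, img.intensities[row], coords=(int(i), int(j), int(z[row]))
                )
    except OSError as exc:
        raise OSError(f"cannot write imzML to {path}: {exc}") from exc
    return path


def _read_table(path: str | os.PathLike, **kw) -> pd.DataFrame:
    sep = "\t" if os.fspath(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, **kw)


def read_matrix(
    intensity_path: str | os.PathLike, coords_path: str | os.PathLike
) -> SpectraImage:
    """Read a plain-text intensity matrix plus coordinate table.

    The intensity file is a delimited numeric table whose header row holds
    the m/z values; the coords file has columns ``sample``, ``i``, ``j``,
    one row per intensity row, in the same order.  Columns are reordered to
    an ascending m/z axis if needed.
    """
    inten = _read_table(intensity_path)
    coords = _read_table(coords_path)
    try:
        mz = np.array([float(c) for c in inten.columns])
    except ValueError as exc:
        raise FormatError(
            f"intensity header of {intensity_path} must be numeric m/z values"
        ) from exc
    x = inten.to_numpy(dtype=float)
    if len(coords) != len(inten):
        raise DimensionError(
            f"{intensity_path} has {len(inten)} rows but {coords_path} has {len(coords)}"
        )
    for col in ("sample", "i", "j"):
        if col not in coords.columns:
            raise FormatError(f"coords file {coords_path} is missing column '{col}'")
    order = np.argsort(mz, kind="stable")
    if not np.array_equal(order, np.arange(mz.size)):
        mz = mz[order]
        x = x[:, order]
    return SpectraImage(
        intensities=x,
        coords=coords[["i", "j"]].to_numpy(dtype=int),
        sample_id=coords["sample"].to_numpy(),
        mz=mz,
    )


def write_matrix(
    img: SpectraImage,
    intensity_path: str | os.PathLike,
    coords_path: str | os.PathLike,
) -> tuple[str, str]:
    """Write the delimited-text counterpart of :func:`read_matrix`."""
    sep = "\t" if os.fspath(intensity_path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame(img.intensities, columns=[repr(float(v)) for v in img.mz]).to_csv(
        intensity_path, sep=sep, index=False
    )
    sep_c = "\t" if os.fspath(coords_path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame(
        {"sample": img.sample_id, "i": img.coords[:, 0], "j": img.coords[:, 1]}
    ).to_csv(coords_path, sep=sep_c, index=False)
    return os.fspath(intensity_path), os.fspath(coords_path)


def tic_normalize(img: SpectraImage, target: float | None = None) -> SpectraImage:
    """Scale each spectrum to a common total ion current.

    ``target`` defaults to the mean TIC over all pixels of all samples, so
    that intensities stay comparable across pixels and across samples.
    Relative within-spectrum intensities are unchanged.
    """
    tic = img.intensities.sum(axis=1)
    zero = np.flatnonzero(tic <= 0)
    if zero.size:
        raise ParameterError(
            f"cannot TIC-normalize: zero-TIC pixels at rows {zero.tolist()}"
        )
    if target is None:
        target = float(tic.mean())
    if target <= 0:
        raise ParameterError("TIC target must be positive")
    scaled = img.intensities * (target / tic)[:, None]
    return SpectraImage(
        intensities=scaled,
        coords=img.coords,
        sample_id=img.sample_id,
        mz=img.mz,
        feature_names=img.feature_names,
    )


def bin_mz(img: SpectraImage, resolution: float) -> SpectraImage:
    """Aggregate features into consecutive m/z bins of a fixed width.

    Bins of width ``resolution`` tile [min(mz), max(mz)]; a bin's intensity
    is the sum of its member features and its reported m/z is the bin
    center.  Empty bins are dropped.  Per-pixel total intensity is
    conserved exactly.
    """
    if resolution <= 0:
        raise ParameterError("bin resolution must be positive")
    mz = img.mz
    span = mz[-1] - mz[0]
    if resolution > span:
        if span > 0:
            warnings.warn(
                f"resolution {resolution} exceeds the m/z range {span}; "
                "collapsing to a single bin"
            )
        idx = np.zeros(mz.size, dtype=int)
    else:
        idx = np.floor((mz - mz[0]) / resolution).astype(int)
        # the maximum m/z lands exactly on the upper edge; keep it in-range
        n_bins = int(np.ceil(span / resolution))
        idx = np.minimum(idx, n_bins - 1)
    used = np.unique(idx)
    new_p = used.size
    col_of = {b: c for c, b in enumerate(used.tolist())}
    cols = np.array([col_of[b] for b in idx.tolist()])
    out = np.zeros((img.n_pixels, new_p))
    np.add.at(out.T, cols, img.intensities.T)
    centers = mz[0] + (used + 0.5) * resolution
    return SpectraImage(
        intensities=out, coords=img.coords, sample_id=img.sample_id, mz=centers
    )
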