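"""Structure-tensor orientation/anisotropy fields and texture metrics.

The structure tensor of an intensity map f(x, y) is the window-averaged
outer product of its smoothed gradient,

    T = [[<fx fx>, <fx fy>],
         [<fx fy>, <fy fy>]],

whose eigen-system encodes the local orientation (eigenvector of the
largest eigenvalue) and the degree of alignment.  Anisotropy is the
normalized eigenvalue contrast (lmax - lmin) / (lmax + lmin): 0 for
isotropic texture, 1 for perfectly aligned texture.

Axial convention: fibre orientation is defined modulo 180 degrees and all
angle averaging doubles the angle first (orientation is an axis, not a
direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

ANGLE_BINS_DEFAULT = 180  # 1-degree bins over the folded [0, 180) range
ENTROPY_BINS_DEFAULT = 256  # 8-bit intensity convention


@dataclass
class StructureTensorField:
    """Per-pixel symmetric 2x2 structure tensor, components txx, txy, tyy.

    ``txx`` is the (row-gradient)^2 component and ``tyy`` the
    (column-gradient)^2 component; both are nonnegative, and the tensor is
    positive semidefinite at every pixel.
    """

    txx: np.ndarray
    txy: np.ndarray
    tyy: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.txx.shape


def structure_tensor_field(
    intensity: np.ndarray, derivative_sigma: float = 1.0, window_sigma: float = 1.0
) -> StructureTensorField:
    """Compute the structure tensor of a 2D raster.

    Gradients use Gaussian-derivative filters of scale ``derivative_sigma``;
    the outer product is then averaged over a Gaussian window of scale
    ``window_sigma``.  Borders are reflect-padded.  A constant raster yields
    the zero tensor everywhere.
    """
    arr = np.asarray(intensity, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("intensity must be a 2D raster of at least 2x2")
    if derivative_sigma > 0:
        gr = ndimage.gaussian_filter(arr, derivative_sigma, order=(1, 0), mode="reflect")
        gc = ndimage.gaussian_filter(arr, derivative_sigma, order=(0, 1), mode="reflect")
    else:
        gr, gc = np.gradient(arr)

    def smooth(a: np.ndarray) -> np.ndarray:
        if window_sigma > 0:
            return ndimage.gaussian_filter(a, window_sigma, mode="reflect")
        return a

    return StructureTensorField(txx=smooth(gr * gr), txy=smooth(gr * gc), tyy=smooth(gc * gc))


def anisotropy(txx, txy, tyy):
    """Normalized eigenvalue contrast (lmax - lmin)/(lmax + lmin) of a 2x2
    symmetric tensor; 0 when the tensor is zero (flat regions count as
    maximally unordered).  Works element-wise on arrays.

    For a symmetric 2x2 tensor, lmax - lmin = sqrt((txx - tyy)^2 + 4 txy^2)
    and lmax + lmin = txx + tyy.
    """
    txx = np.asarray(txx, dtype=float)
    txy = np.asarray(txy, dtype=float)
    tyy = np.asarray(tyy, dtype=float)
    trace = txx + tyy
    contrast = np.sqrt((txx - tyy) ** 2 + 4.0 * txy**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(trace > 0, contrast / np.where(trace > 0, trace, 1.0), 0.0)
    return np.clip(out, 0.0, 1.0) if out.ndim else float(np.clip(out, 0.0, 1.0))


def _mask_indices(shape: tuple[int, int], mask) -> np.ndarray:
    """Normalize a pixel-set argument to a boolean raster."""
    if mask is None:
        return np.ones(shape, dtype=bool)
    m = np.asarray(mask)
    if m.dtype == bool:
        if m.shape != shape:
            raise ValueError("mask shape does not match field shape")
        return m
    # (N, 2) array of (row, col) indices
    out = np.zeros(shape, dtype=bool)
    out[m[:, 0], m[:, 1]] = True
    return out


def total_anisotropy(field: StructureTensorField, mask=None) -> float:
    """Anisotropy of the mean structure tensor over a pixel set.

    Averaging the tensor before the eigen-analysis makes this a *global*
    alignment measure: equally strong orderings in orthogonal directions
    cancel, driving the value toward 0 even though each patch is locally
    ordered.
    """
    m = _mask_indices(field.shape, mask)
    if not m.any():
        raise ValueError("empty mask")
    return float(anisotropy(field.txx[m].mean(), field.txy[m].mean(), field.tyy[m].mean()))


def local_anisotropy_map(field: StructureTensorField) -> np.ndarray:
    """Per-pixel anisotropy of the 3x3-window-averaged tensor."""
    w = {
        k: ndimage.uniform_filter(getattr(field, k), size=3, mode="reflect")
        for k in ("txx", "txy", "tyy")
    }
    return anisotropy(w["txx"], w["txy"], w["tyy"])


def local_anisotropy(field: StructureTensorField, mask=None) -> float:
    """Mean over the pixel set of the anisotropy of each pixel's 3x3-window
    mean tensor.  Unlike :func:`total_anisotropy` it is insensitive to the
    overall direction of the pixels in the set, measuring purely local
    alignment.
    """
    m = _mask_indices(field.shape, mask)
    if not m.any():
        raise ValueError("empty mask")
    return float(local_anisotropy_map(field)[m].mean())


def orientation_angles(field: StructureTensorField) -> np.ndarray:
    """Per-pixel principal orientation in degrees, folded into [0, 180).

    The principal axis of the structure tensor is the direction of maximal
    intensity variation; the *fibre* orientation is perpendicular to it.
    For T built from gradients (gr, gc), the doubled gradient-axis angle in
    the (col, row) frame satisfies tan(2a) = 2 txy / (tyy - txx); the fibre
    axis is that plus 90 degrees.
    """
    two_theta = np.arctan2(2.0 * field.txy, field.tyy - field.txx)
    grad_axis = np.degrees(two_theta) / 2.0
    return (grad_axis + 90.0) % 180.0


def angle_metrics(
    field: StructureTensorField, mask=None, n_bins: int = ANGLE_BINS_DEFAULT
) -> tuple[float, float]:
    """Coherence-weighted circular mean orientation and the angle-spectrum
    distribution index (SDI).

    The SDI is mean/max of the folded orientation histogram (``n_bins``
    unweighted counts over [0, 180)): 1/n_bins when all pixels share one
    orientation, and 1 for a flat (fully disordered) spectrum.  All-zero
    tensors in the mask yield SDI 1 by the flat-spectrum convention, with
    the mean angle undefined (returned as 0.0).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    m = _mask_indices(field.shape, mask)
    if not m.any():
        raise ValueError("empty mask")
    coher = anisotropy(field.txx, field.txy, field.tyy)[m]
    trace = (field.txx + field.tyy)[m]
    angles = orientation_angles(field)[m]
    live = trace > 0
    if not live.any():
        return 0.0, 1.0
    angles, coher = angles[live], coher[live]
    # axial circular mean: double the angle, average unit vectors weighted
    # by coherence, halve back
    rad2 = np.radians(2.0 * angles)
    w = coher if coher.sum() > 0 else np.ones_like(coher)
    mean_vec = np.array([(w * np.cos(rad2)).sum(), (w * np.sin(rad2)).sum()])
    mean_angle = (np.degrees(np.arctan2(mean_vec[1], mean_vec[0])) / 2.0) % 180.0
    counts, _ = np.histogram(angles, bins=n_bins, range=(0.0, 180.0))
    sdi = counts.mean() / counts.max() if counts.max() > 0 else 1.0
    return float(mean_angle), float(sdi)


def intensity_stats(
    intensity: np.ndarray, mask=None, n_bins: int = ENTROPY_BINS_DEFAULT
) -> tuple[float, float, float]:
    """Mean, standard deviation and Shannon entropy (bits) of masked pixels.

    Entropy uses an ``n_bins`` histogram over [0, 1] (the loaded intensity
    range), with 0 log 0 := 0; it is bounded by log2(n_bins), attained only
    for a flat histogram.
    """
    arr = np.asarray(intensity, dtype=float)
    m = _mask_indices(arr.shape, mask)
    if not m.any():
        raise ValueError("empty mask")
    vals = arr[m]
    counts, _ = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    return float(vals.mean()), float(vals.std()), entropy
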