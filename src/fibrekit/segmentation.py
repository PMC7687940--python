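"""Fibre/cell segmentation by colour clustering of a pseudo-H&E composite.

The SHG, PL and transmission channels are stacked into a composite "RGB"
image and each pixel vector is normalized to unit length, which removes
the overall intensity and leaves only the channel ratio: collagen pixels
(strong SHG) have a large red component, cellular pixels sit in the
green/blue region.  Mini-batch K-means clusters the unit vectors and each
centroid is classified as fibrous or cellular by which side of a
red-component boundary it falls on.  The pixel classes are then refined
with the extracted fibre network (pixels near network edges are forced
into the fibre class) and split into connected segments with shape
descriptors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from sklearn.cluster import MiniBatchKMeans

from fibrekit.fibre_network import FibreNetwork
from fibrekit.image_io import MultiChannelImage

logger = logging.getLogger(__name__)


@dataclass
class Segment:
    """A connected labelled region, either fibrous or cellular.

    shape in [0, 1] compares the region's perimeter with the circumference
    of the equal-area circle: 0 for a disc, approaching 1 for elongated or
    highly folded regions.  eccentricity in [0, 1] is that of the ellipse
    with matching second central moments.
    """

    mask: np.ndarray
    kind: str  # "fibre" | "cell"
    area_px: int
    perimeter_px: float
    shape: float
    eccentricity: float

    def __post_init__(self) -> None:
        if self.kind not in ("fibre", "cell"):
            raise ValueError(f"kind must be 'fibre' or 'cell', got {self.kind!r}")
        if self.area_px <= 0:
            raise ValueError("segment mask is empty")


def composite_rgb(img: MultiChannelImage) -> np.ndarray:
    """Stack (SHG, PL, transmission) into unit pixel vectors.

    Returns an (H, W, 3) array; zero-intensity pixels map to (0, 0, 0) and
    count as background throughout segmentation.
    """
    stack = np.stack([img.shg, img.pl, img.trans], axis=-1)
    norm = np.linalg.norm(stack, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norm > 0, stack / np.where(norm > 0, norm, 1.0), 0.0)
    return unit


def kmeans_segment(
    rgb: np.ndarray,
    k: int = 8,
    red_boundary: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster unit pixel vectors and split clusters at a red boundary.

    Each of the ``k`` mini-batch K-means centroids is renormalized to unit
    length and classified as fibrous when its red (SHG) component exceeds
    ``red_boundary``, else cellular.  Background (zero-vector) pixels join
    neither mask.  Reproducible for a fixed ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0.0 < red_boundary < 1.0:
        raise ValueError("red_boundary must lie in (0, 1)")
    h, w, _ = rgb.shape
    flat = rgb.reshape(-1, 3)
    background = np.linalg.norm(flat, axis=1) == 0
    fg = flat[~background]
    if fg.size == 0:
        empty = np.zeros((h, w), dtype=bool)
        return empty, empty.copy()
    n_distinct = len(np.unique(fg, axis=0))
    if n_distinct < k:
        logger.warning("only %d distinct pixel vectors; reducing k from %d", n_distinct, k)
        k = max(1, n_distinct)
    km = MiniBatchKMeans(n_clusters=k, random_state=seed, n_init=3, batch_size=4096)
    assign = km.fit_predict(fg)
    centroids = km.cluster_centers_
    cnorm = np.linalg.norm(centroids, axis=1, keepdims=True)
    unit_centroids = centroids / np.where(cnorm > 0, cnorm, 1.0)
    fibrous_cluster = unit_centroids[:, 0] > red_boundary

    labels = np.full(flat.shape[0], -1, dtype=int)
    labels[~background] = assign
    label_img = labels.reshape(h, w)
    fibre_mask = np.isin(label_img, np.nonzero(fibrous_cluster)[0])
    cell_mask = np.isin(label_img, np.nonzero(~fibrous_cluster)[0])
    return fibre_mask, cell_mask


def calibrate_red_boundary(
    rgb_images: list[np.ndarray], fibre_truth: list[np.ndarray], grid: int = 99
) -> float:
    """Fit the red boundary on a labelled subset.

    Scans thresholds on the red component of unit pixel vectors and returns
    the one maximizing the Jaccard overlap with the supplied ground-truth
    fibre masks.  The boundary is dataset-dependent by construction, so it
    should be refit whenever the imaging configuration changes.
    """
    reds = np.concatenate([im[..., 0].ravel() for im in rgb_images])
    truth = np.concatenate([t.ravel().astype(bool) for t in fibre_truth])
    fgmask = np.concatenate(
        [np.linalg.norm(im.reshape(-1, 3), axis=1) > 0 for im in rgb_images]
    )
    reds, truth = reds[fgmask], truth[fgmask]
    best_thr, best_j = 0.5, -1.0
    for thr in np.linspace(0.01, 0.99, grid):
        pred = reds > thr
        inter = np.logical_and(pred, truth).sum()
        union = np.logical_or(pred, truth).sum()
        j = inter / union if union else 0.0
        if j > best_j:
            best_thr, best_j = float(thr), j
    return best_thr


def _region_to_segment(region, shape_hw: tuple[int, int], kind: str) -> Segment:
    mask = np.zeros(shape_hw, dtype=bool)
    rr, cc = region.coords[:, 0], region.coords[:, 1]
    mask[rr, cc] = True
    perimeter = float(region.perimeter)
    shape_metric = segment_shape(int(region.area), perimeter)
    ecc = segment_eccentricity(mask)
    return Segment(
        mask=mask,
        kind=kind,
        area_px=int(region.area),
        perimeter_px=perimeter,
        shape=shape_metric,
        eccentricity=ecc,
    )


def refine_with_network(
    fibre_mask: np.ndarray,
    cell_mask: np.ndarray,
    net: FibreNetwork,
    min_area: int = 64,
    dilation_radius: int = 2,
) -> list[Segment]:
    """Refine the clustered masks with the traced network and split into segments.

    Pixels within ``dilation_radius`` of any network edge are forced into
    the fibre class (the SHG network is the stronger evidence for
    collagen).  Connected components (8-connectivity) smaller than
    ``min_area`` px are dropped.  Returns disjoint fibre and cell segments
    with computed shape descriptors.
    """
    if np.logical_and(fibre_mask, cell_mask).any():
        raise ValueError("fibre and cell masks must be disjoint")
    fibre = fibre_mask.copy()
    cell = cell_mask.copy()
    if net.n_nodes and net.edges:
        rail = np.zeros(fibre.shape, dtype=bool)
        for u, v in net.edges:
            r0, c0 = net.nodes[u]
            r1, c1 = net.nodes[v]
            n_pts = int(max(abs(r1 - r0), abs(c1 - c0))) + 2
            rr = np.clip(np.round(np.linspace(r0, r1, n_pts)).astype(int), 0, fibre.shape[0] - 1)
            cc = np.clip(np.round(np.linspace(c0, c1, n_pts)).astype(int), 0, fibre.shape[1] - 1)
            rail[rr, cc] = True
        if dilation_radius > 0:
            rail = ndimage.binary_dilation(rail, structure=morphology.disk(dilation_radius))
        fibre |= rail
        cell &= ~rail

    segments: list[Segment] = []
    for mask, kind in ((fibre, "fibre"), (cell, "cell")):
        labels = measure.label(mask, connectivity=2)
        for region in measure.regionprops(labels):
            if region.area < min_area:
                continue
            segments.append(_region_to_segment(region, mask.shape, kind))
    return segments


def segment_shape(area_px: int | float, perimeter_px: float) -> float:
    """Shape metric 1 - 2*sqrt(pi*A)/P, clamped to [0, 1].

    The subtracted term is the ratio of the equal-area circle's
    circumference to the actual perimeter: 1 for a disc (metric 0), small
    for elongated or folded boundaries (metric near 1).
    """
    if area_px <= 0 or perimeter_px <= 0:
        raise ValueError("area and perimeter must be positive")
    return float(np.clip(1.0 - 2.0 * math.sqrt(math.pi * area_px) / perimeter_px, 0.0, 1.0))


def segment_eccentricity(mask: np.ndarray) -> float:
    """Eccentricity of the ellipse with the mask's second central moments.

    0 for a disc, 1 for a degenerate (collinear) pixel run.
    """
    coords = np.argwhere(mask)
    if len(coords) < 3:
        return 1.0
    labels = measure.label(mask, connectivity=2)
    regions = measure.regionprops(labels)
    if len(regions) != 1:
        # moments of the union of pixels, irrespective of connectivity
        centred = coords - coords.mean(axis=0)
        cov = centred.T @ centred / len(coords)
        evals = np.sort(np.linalg.eigvalsh(cov))
        if evals[1] <= 0:
            return 1.0
        return float(math.sqrt(max(0.0, 1.0 - evals[0] / evals[1])))
    try:
        return float(regions[0].eccentricity)
    except ValueError:
        return 1.0


def coverage_and_area(
    segments: list[Segment], kind: str, image_area: int
) -> tuple[float, float]:
    """Total pixel area of segments of one kind and its fraction of the image."""
    area = float(sum(s.area_px for s in segments if s.kind == kind))
    return area / image_area, area


def bounding_box_coverage(seg: Segment) -> float:
    """Per-segment variant: segment area over its bounding-box area."""
    coords = np.argwhere(seg.mask)
    extent = coords.max(axis=0) - coords.min(axis=0) + 1
    return seg.area_px / float(extent[0] * extent[1])


def segment_label_map(segments: list[Segment]) -> np.ndarray:
    """Render segments as a uint16 label map: 0 background, odd ids fibre,
    even ids cell."""
    if not segments:
        return np.zeros((0, 0), dtype=np.uint16)
    out = np.zeros(segments[0].mask.shape, dtype=np.uint16)
    next_id = {"fibre": 1, "cell": 2}
    for seg in segments:
        out[seg.mask] = next_id[seg.kind]
        next_id[seg.kind] += 2
    return out
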