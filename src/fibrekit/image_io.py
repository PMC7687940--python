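"""Reading, writing and pre-processing of multi-channel microscopy fields.

A field of view is stored as a multi-page TIFF in the page order
SHG, PL, transmission, accompanied by a JSON sidecar recording
``field_id``, ``label``, ``pixel_size_um`` and ``channel_order``.
Intensities are rescaled to [0, 1] per channel at load: integer data is
divided by its dtype maximum, float data by the channel maximum.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

logger = logging.getLogger(__name__)

#: physical pixel edge of the reference acquisition: a 0.471 mm field of view
#: sampled at 512 x 512 pixels.
DEFAULT_PIXEL_SIZE_UM = 471.0 / 512.0

CHANNEL_ORDER = ("shg", "pl", "trans")


class GeometryError(ValueError):
    """Channel rasters disagree in shape."""


class FormatError(ValueError):
    """File cannot be interpreted as a multi-channel field."""


@dataclass
class MultiChannelImage:
    """One field of view: SHG, PL and laser-transmission intensity rasters.

    All three rasters share one shape; intensities are finite, nonnegative
    and (after loading through :func:`read_field`) scaled to [0, 1].
    """

    shg: np.ndarray
    pl: np.ndarray
    trans: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    field_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.shg = np.asarray(self.shg, dtype=float)
        self.pl = np.asarray(self.pl, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        if not (self.shg.shape == self.pl.shape == self.trans.shape):
            raise GeometryError(
                f"channel shapes differ: shg {self.shg.shape}, "
                f"pl {self.pl.shape}, trans {self.trans.shape}"
            )
        if self.shg.ndim != 2:
            raise GeometryError(f"expected 2D rasters, got ndim={self.shg.ndim}")
        for name in CHANNEL_ORDER:
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite intensities in channel {name!r}")
            if np.any(arr < 0):
                raise ValueError(f"negative intensities in channel {name!r}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.shg.shape

    def channels(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in CHANNEL_ORDER}


def _rescale(page: np.ndarray) -> np.ndarray:
    """Scale one raster to [0, 1]: by dtype max for integers, channel max for floats."""
    arr = np.asarray(page)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    arr = arr.astype(float)
    peak = arr.max() if arr.size else 0.0
    return arr / peak if peak > 0 else arr


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_field(path: str | Path) -> MultiChannelImage:
    """Read one field of view from a multi-page TIFF plus optional JSON sidecar.

    The container must hold at least SHG and PL pages of equal shape; a
    missing transmission page is replaced by an all-ones raster with a
    logged warning.  Intensities are rescaled to [0, 1] per channel.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several exception types
        raise FormatError(f"cannot read {path} as TIFF: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError(f"{path}: expected a stack of 2D pages, got shape {pages.shape}")
    if len(pages) < 2:
        raise FormatError(f"{path}: need at least SHG and PL pages, found {len(pages)}")
    if len(pages) > 3:
        raise FormatError(f"{path}: more than 3 pages ({len(pages)})")

    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    shg = _rescale(pages[0])
    pl = _rescale(pages[1])
    if len(pages) == 3:
        trans = _rescale(pages[2])
    else:
        logger.warning("%s: no transmission page, substituting all-ones raster", path)
        trans = np.ones_like(shg)

    return MultiChannelImage(
        shg=shg,
        pl=pl,
        trans=trans,
        pixel_size_um=float(meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM)),
        field_id=str(meta.get("field_id", path.stem)),
        label=meta.get("label"),
    )


def write_field(img: MultiChannelImage, path: str | Path, dtype=np.uint16) -> Path:
    """Write a field as a multi-page TIFF (SHG, PL, transmission) plus sidecar.

    Float intensities in [0, 1] are quantized to the requested integer dtype
    so that ``read_field(write_field(x))`` round-trips exactly on the
    quantized grid.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    peak = np.iinfo(dtype).max
    stack = np.stack(
        [np.clip(np.round(getattr(img, name) * peak), 0, peak).astype(dtype) for name in CHANNEL_ORDER]
    )
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "field_id": img.field_id,
        "label": img.label,
        "pixel_size_um": img.pixel_size_um,
        "channel_order": list(CHANNEL_ORDER),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def denoise(img: MultiChannelImage, sigma: float = 1.0, median_radius: int = 1) -> MultiChannelImage:
    """Reduce shot and white noise: median filter then Gaussian smoothing.

    The median filter (window of ``2*median_radius + 1``) suppresses
    impulsive shot noise; the Gaussian (scale ``sigma`` px) suppresses
    white noise.  ``sigma=0, median_radius=0`` is the identity.  Borders
    are reflect-padded.
    """
    if sigma < 0 or median_radius < 0:
        raise ValueError("sigma and median_radius must be >= 0")

    def _clean(arr: np.ndarray) -> np.ndarray:
        out = arr
        if median_radius > 0:
            out = ndimage.median_filter(out, size=2 * median_radius + 1, mode="reflect")
        if sigma > 0:
            out = ndimage.gaussian_filter(out, sigma=sigma, mode="reflect")
        return np.clip(out, 0.0, None)

    return replace(img, shg=_clean(img.shg), pl=_clean(img.pl), trans=_clean(img.trans))


def plane_consensus(planes: list[MultiChannelImage]) -> MultiChannelImage:
    """Per-pixel median across focal planes, channel by channel.

    Emulates the acquisition-time comparison of images taken at three
    nearby focal planes to suppress plane-specific noise.  A single plane
    is returned unchanged.
    """
    if not planes:
        raise ValueError("plane_consensus needs at least one plane")
    if len(planes) == 1:
        return planes[0]
    ref = planes[0]
    for p in planes[1:]:
        if p.shape != ref.shape:
            raise GeometryError("focal planes differ in shape")
    merged = {
        name: np.median(np.stack([getattr(p, name) for p in planes]), axis=0)
        for name in CHANNEL_ORDER
    }
    return replace(ref, **merged)
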