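"""Phantom multi-channel fields with known ground truth.

Phantoms emulate the structure of SHG/PL tissue fields without modelling
image formation: the SHG channel holds rasterized sine-perturbed curves
("fibres") whose end-to-end displacement over arc length matches a
requested waviness target, the PL channel holds smooth cellular blobs, and
the transmission channel is an attenuation proxy 1 - alpha*(SHG + PL).
Gaussian read noise plus Poisson shot noise is added on top.  Ground-truth
stroke paths and blob masks are returned for oracle tests, and generation
is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy import ndimage, optimize

from fibrekit.image_io import MultiChannelImage

TRANSMISSION_ALPHA = 0.5


@dataclass
class PhantomSpec:
    """Generator parameters for one phantom class.

    Angles in degrees; lengths and radii in px; intensities on the [0, 1]
    image scale.  ``fibre_waviness_target`` is the displacement-over-length
    ratio the drawn strokes realize (1 = straight).
    """

    image_size: int = 256
    n_fibres: int = 20
    fibre_angle_mean: float = 90.0
    fibre_angle_spread: float = 45.0
    fibre_length_range: tuple[float, float] = (60.0, 140.0)
    fibre_waviness_target: float = 0.95
    fibre_width: float = 2.0
    fibre_intensity: float = 0.9
    n_cell_blobs: int = 4
    blob_radius_range: tuple[float, float] = (12.0, 30.0)
    blob_intensity: float = 0.8
    background_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibres < 0 or self.n_cell_blobs < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 < self.fibre_waviness_target <= 1.0:
            raise ValueError("fibre_waviness_target must lie in (0, 1]")
        if self.fibre_intensity < 0 or self.blob_intensity < 0:
            raise ValueError("intensities must be >= 0")
        if self.fibre_angle_spread < 0:
            raise ValueError("fibre_angle_spread must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually drew."""

    stroke_paths: list[np.ndarray] = dc_field(default_factory=list)  # (N, 2) row/col polylines
    stroke_lengths: list[float] = dc_field(default_factory=list)  # analytic arc lengths
    stroke_angles: list[float] = dc_field(default_factory=list)  # end-to-end, deg in [0, 180)
    fibre_mask: np.ndarray | None = None
    blob_mask: np.ndarray | None = None


def _wave_amplitude(length: float, waviness: float, n_periods: float = 2.0) -> float:
    """Amplitude of a transverse sine perturbation y = A sin(2*pi*n*t/L)
    such that chord/arc-length equals the waviness target.

    The chord is ``length``; the arc length of the perturbed curve is
    integral of sqrt(1 + (A*w*cos(w*t))^2) dt with w = 2*pi*n/L.  Solved by
    bisection; waviness 1 gives A = 0 (a straight stroke).
    """
    if waviness >= 1.0:
        return 0.0
    w = 2.0 * math.pi * n_periods / length
    t = np.linspace(0.0, length, 512)

    def arc_ratio(amp: float) -> float:
        return float(np.trapezoid(np.sqrt(1.0 + (amp * w * np.cos(w * t)) ** 2), t)) / length

    target_ratio = 1.0 / waviness
    hi = length
    return float(optimize.brentq(lambda a: arc_ratio(a) - target_ratio, 0.0, hi, xtol=1e-6))


def _sample_stroke(
    rng: np.random.Generator, spec: PhantomSpec
) -> tuple[np.ndarray, float, float]:
    """One sine-perturbed polyline: (points, analytic arc length, angle)."""
    length = float(rng.uniform(*spec.fibre_length_range))
    angle = float(rng.normal(spec.fibre_angle_mean, spec.fibre_angle_spread)) % 180.0
    amp = _wave_amplitude(length, spec.fibre_waviness_target)
    n_pts = max(16, int(length))
    t = np.linspace(0.0, length, n_pts)
    w = 2.0 * math.pi * 2.0 / length
    # whole periods with zero phase keep both endpoints on the chord, so
    # displacement equals the chord length and waviness matches the target
    dev = amp * np.sin(w * t)
    rad = math.radians(angle)
    u = np.array([math.sin(rad), math.cos(rad)])  # chord direction (row, col)
    v = np.array([-u[1], u[0]])  # transverse direction
    size = spec.image_size
    margin = 2.0 * spec.fibre_width
    lo = margin
    hi = size - margin
    start = rng.uniform(lo, hi, size=2)
    pts = start[None, :] + t[:, None] * u[None, :] + dev[:, None] * v[None, :]
    arc = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    return pts, arc, angle


def _rasterize_strokes(
    paths: list[np.ndarray], size: int, width: float, intensity: float
) -> tuple[np.ndarray, np.ndarray]:
    """Stamp polylines onto a raster with a soft round profile of the given
    full width; returns (intensity raster, boolean stroke mask)."""
    hits = np.zeros((size, size), dtype=bool)
    for pts in paths:
        seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        total = seg_len.sum()
        n_samples = max(2, int(total * 2))
        dense_t = np.linspace(0, len(pts) - 1, n_samples)
        idx = dense_t.astype(int).clip(0, len(pts) - 2)
        frac = dense_t - idx
        dense = pts[idx] * (1 - frac[:, None]) + pts[idx + 1] * frac[:, None]
        rr = np.round(dense[:, 0]).astype(int)
        cc = np.round(dense[:, 1]).astype(int)
        keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        hits[rr[keep], cc[keep]] = True
    radius = max(0, int(round((width - 1) / 2)))
    mask = hits
    if radius > 0:
        mask = ndimage.binary_dilation(hits, structure=_disk(radius))
    img = ndimage.gaussian_filter(mask.astype(float), sigma=width / 3.0)
    peak = img.max()
    if peak > 0:
        img = img / peak * intensity
    return img, mask


def _disk(radius: int) -> np.ndarray:
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return x * x + y * y <= radius * radius


def _draw_blobs(
    rng: np.random.Generator, spec: PhantomSpec
) -> tuple[np.ndarray, np.ndarray]:
    size = spec.image_size
    img = np.zeros((size, size), dtype=float)
    mask = np.zeros((size, size), dtype=bool)
    rows = np.arange(size)[:, None]
    cols = np.arange(size)[None, :]
    for _ in range(spec.n_cell_blobs):
        radius = float(rng.uniform(*spec.blob_radius_range))
        radius = min(radius, size / 2.0 - 1.0)  # keep blobs placeable on small rasters
        center = rng.uniform(radius, size - radius, size=2)
        d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
        img += spec.blob_intensity * np.exp(-d2 / (2.0 * (radius / 1.5) ** 2))
        mask |= d2 <= radius * radius
    return np.clip(img, 0.0, 1.0), mask


def make_phantom(spec: PhantomSpec) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one phantom field of view plus its ground truth.

    The analytic stroke arc length matches the drawn polyline within 2%,
    and displacement/arc-length matches ``spec.fibre_waviness_target`` by
    construction of the sine amplitude.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    truth = GroundTruth()

    paths = []
    for _ in range(spec.n_fibres):
        pts, arc, angle = _sample_stroke(rng, spec)
        paths.append(pts)
        truth.stroke_paths.append(pts)
        truth.stroke_lengths.append(arc)
        truth.stroke_angles.append(angle)
    shg, fibre_mask = (
        _rasterize_strokes(paths, size, spec.fibre_width, spec.fibre_intensity)
        if paths
        else (np.zeros((size, size)), np.zeros((size, size), dtype=bool))
    )
    pl, blob_mask = _draw_blobs(rng, spec)
    truth.fibre_mask = fibre_mask
    truth.blob_mask = blob_mask

    trans = np.clip(1.0 - TRANSMISSION_ALPHA * (shg + pl), 0.0, 1.0)

    def add_noise(channel: np.ndarray) -> np.ndarray:
        noisy = channel + rng.normal(0.0, spec.background_noise_sd, channel.shape)
        if spec.background_noise_sd > 0:
            # shot noise: Poisson at a nominal 200-photon full scale
            photons = rng.poisson(np.clip(noisy, 0, None) * 200.0)
            noisy = photons / 200.0
        return np.clip(noisy, 0.0, 1.0)

    img = MultiChannelImage(
        shg=add_noise(shg),
        pl=add_noise(pl),
        trans=add_noise(trans),
        field_id=f"phantom-{spec.seed}",
    )
    return img, truth


def four_class_presets(image_size: int = 256) -> dict[str, PhantomSpec]:
    """Four phantom classes loosely echoing the diagnosis groups.

    "normal": many short fibres in all orientations, small sparse blobs;
    "insitu": bounded blob clusters with mid-length fibres around them;
    "mixed": strongly aligned, long, wavier fibres with moderate blobs;
    "solid": large merged blob coverage with few long fibres.  The presets
    differ strongly in several metric families so a classifier can recover
    the class structure; they make no claim of biological fidelity.
    """
    return {
        "normal": PhantomSpec(
            image_size=image_size,
            n_fibres=30,
            fibre_angle_spread=60.0,
            fibre_length_range=(40.0, 80.0),
            fibre_waviness_target=0.9,
            n_cell_blobs=3,
            blob_radius_range=(8.0, 16.0),
        ),
        "insitu": PhantomSpec(
            image_size=image_size,
            n_fibres=18,
            fibre_angle_spread=30.0,
            fibre_length_range=(60.0, 120.0),
            fibre_waviness_target=0.95,
            n_cell_blobs=6,
            blob_radius_range=(14.0, 24.0),
        ),
        "mixed": PhantomSpec(
            image_size=image_size,
            n_fibres=12,
            fibre_angle_spread=10.0,
            fibre_length_range=(100.0, 180.0),
            fibre_waviness_target=0.85,
            n_cell_blobs=5,
            blob_radius_range=(18.0, 30.0),
        ),
        "solid": PhantomSpec(
            image_size=image_size,
            n_fibres=5,
            fibre_angle_spread=20.0,
            fibre_length_range=(120.0, 200.0),
            fibre_waviness_target=0.97,
            n_cell_blobs=10,
            blob_radius_range=(24.0, 40.0),
        ),
    }


def make_cohort(
    class_specs: dict[str, PhantomSpec], n_per_class: int, seed: int = 0
) -> list[MultiChannelImage]:
    """Generate a labelled phantom cohort.

    Per-image seeds are derived from the master seed, so the cohort is
    reproducible as a whole; the returned images carry their class name in
    ``label`` and are ready for the metric pipeline and the classifier.
    """
    if len(class_specs) < 2:
        raise ValueError("need at least 2 classes")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(class_specs) * n_per_class)]
    images = []
    i = 0
    for label in sorted(class_specs):
        spec = class_specs[label]
        for j in range(n_per_class):
            img, _ = make_phantom(replace(spec, seed=child_seeds[i]))
            img.field_id = f"{label}-{j:03d}"
            img.label = label
            images.append(img)
            i += 1
    return images
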