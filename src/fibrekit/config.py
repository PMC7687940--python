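"""Run configuration: every tunable of the pipeline in one serializable object."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults.

    Pre-processing:
        denoise_sigma: Gaussian scale (px) for white-noise smoothing.
        median_radius: median-filter radius (px) for shot-noise removal.
    Structure tensor:
        derivative_sigma / window_sigma: Gaussian-derivative and averaging
        scales (px); angle_bins: folded orientation histogram bins (1-degree
        bins over [0, 180)); entropy_bins: intensity histogram bins (8-bit
        convention).
    Network tracer:
        fire_intensity_threshold: None selects Otsu at run time;
        fire_nucleation_spacing, fire_step, fire_edge_threshold in px;
        fire_angle_tol in degrees.
    Segmentation:
        kmeans_k clusters; red_boundary on the unit-centroid red component;
        min_segment_area (px); network_dilation_radius (px).
    Metrics:
        area_weighted_averaging: weight per-segment metrics by area instead
        of the default unweighted mean; include_fibre_density: feed the
        auxiliary density metric to the classifier.
    Classification:
        k_folds for stratified CV; gaussianize method ("quantile" rank-based
        normal transform or "power" Yeo-Johnson); connectivity_mode
        ("algebraic" or "node") for the network connectivity metric.
    """

    denoise_sigma: float = 1.0
    median_radius: int = 1
    derivative_sigma: float = 1.0
    window_sigma: float = 1.0
    angle_bins: int = 180
    entropy_bins: int = 256
    fire_intensity_threshold: float | None = None
    fire_nucleation_spacing: float = 10.0
    fire_step: float = 3.0
    fire_edge_threshold: float = 5.0
    fire_angle_tol: float = 70.0
    kmeans_k: int = 8
    red_boundary: float = 0.5
    min_segment_area: int = 64
    network_dilation_radius: int = 2
    area_weighted_averaging: bool = False
    include_fibre_density: bool = False
    k_folds: int = 6
    gaussianize: str = "quantile"
    connectivity_mode: str = "algebraic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussianize not in ("quantile", "power"):
            raise ValueError("gaussianize must be 'quantile' or 'power'")
        if self.connectivity_mode not in ("algebraic", "node"):
            raise ValueError("connectivity_mode must be 'algebraic' or 'node'")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        """Load from a JSON file path or literal JSON text; unknown keys are
        rejected so typos fail loudly."""
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
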