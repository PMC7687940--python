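"""Assembly of the per-image global metric database.

Each processed field of view yields a record of 29 canonical metrics
grouped into network, content, texture and shape families: nine
fibre/network metrics plus, for each of the fibre and cell segment
classes, ten segment metrics (coverage, area, shape, eccentricity, angle
SDI, total and local anisotropy, and intensity mean/STD/entropy).  Texture
metrics for the fibre class are measured on the SHG channel and for the
cell class on the PL channel.  Fibre density is an auxiliary metric kept
outside the canonical 29.

Undefined metrics (e.g. segment-class averages when no segment of that
class exists) carry NaN sentinels and are written as empty CSV cells,
never as silent zeros.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from fibrekit.config import RunConfig
from fibrekit.fibre_network import (
    FireParams,
    extract_network,
    fibre_metrics,
    identify_fibres,
    network_metrics,
)
from fibrekit.image_io import MultiChannelImage, denoise
from fibrekit.segmentation import (
    composite_rgb,
    coverage_and_area,
    kmeans_segment,
    refine_with_network,
)
from fibrekit.tensor_texture import (
    angle_metrics,
    intensity_stats,
    local_anisotropy,
    structure_tensor_field,
    total_anisotropy,
)

logger = logging.getLogger(__name__)

SENTINEL = float("nan")

_NETWORK_METRICS = (
    "No. Fibres",
    "No. Cells",
    "Fibre Waviness",
    "Fibre Lengths",
    "Fibre Angles",
    "Fibre Network Degree",
    "Fibre Network Eigenvalue",
    "Fibre Network Connectivity",
    "Fibre Network Cross-Link Density",
)

_SEGMENT_METRICS = (
    "Coverage",
    "Area",
    "Shape",
    "Eccentricity",
    "Angle SDI",
    "Anisotropy",
    "Local Anisotropy",
    "Intensity Mean",
    "Intensity STD",
    "Intensity Entropy",
)

#: The 29 canonical global metrics, in stable database column order.
CANONICAL_METRICS: tuple[str, ...] = _NETWORK_METRICS + tuple(
    f"{kind} Segment {name}"
    for kind in ("Fibre", "Cell")
    for name in _SEGMENT_METRICS
)

AUXILIARY_METRICS: tuple[str, ...] = ("Fibre Density",)


@dataclass
class MetricRecord:
    """The global metrics of one field of view."""

    field_id: str
    label: str | None
    metrics: dict[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = set(CANONICAL_METRICS) | set(AUXILIARY_METRICS)
        unknown = set(self.metrics) - allowed
        if unknown:
            raise ValueError(f"unknown metric names: {sorted(unknown)}")
        for name in CANONICAL_METRICS + AUXILIARY_METRICS:
            self.metrics.setdefault(name, SENTINEL)

    def __getitem__(self, name: str) -> float:
        return self.metrics[name]

    @property
    def canonical(self) -> dict[str, float]:
        return {name: self.metrics[name] for name in CANONICAL_METRICS}


def fibre_density(shg: np.ndarray, fibre_mask: np.ndarray) -> float:
    """Fraction of total SHG intensity that falls inside the fibre region."""
    total = float(np.asarray(shg, dtype=float).sum())
    if total <= 0:
        return SENTINEL
    return float(np.asarray(shg, dtype=float)[np.asarray(fibre_mask, dtype=bool)].sum() / total)


def _segment_class_metrics(
    kind: str,
    segments,
    tensor_field,
    intensity: np.ndarray,
    image_area: int,
    cfg: RunConfig,
) -> dict[str, float]:
    """Average the per-segment metrics of one class into global values."""
    prefix = f"{kind.capitalize()} Segment"
    mine = [s for s in segments if s.kind == kind]
    out: dict[str, float] = {}
    coverage, area = coverage_and_area(segments, kind, image_area)
    out[f"{prefix} Coverage"] = coverage
    out[f"{prefix} Area"] = area
    if not mine:
        for name in _SEGMENT_METRICS[2:]:
            out[f"{prefix} {name}"] = SENTINEL
        return out

    shapes, eccs, sdis, anis, loc_anis, means, stds, ents = ([] for _ in range(8))
    weights = []
    for seg in mine:
        weights.append(seg.area_px if cfg.area_weighted_averaging else 1.0)
        shapes.append(seg.shape)
        eccs.append(seg.eccentricity)
        _, sdi = angle_metrics(tensor_field, seg.mask, n_bins=cfg.angle_bins)
        sdis.append(sdi)
        anis.append(total_anisotropy(tensor_field, seg.mask))
        loc_anis.append(local_anisotropy(tensor_field, seg.mask))
        mean, std, ent = intensity_stats(intensity, seg.mask, n_bins=cfg.entropy_bins)
        means.append(mean)
        stds.append(std)
        ents.append(ent)
    w = np.asarray(weights, dtype=float)
    w /= w.sum()

    def avg(vals) -> float:
        return float(np.dot(w, np.asarray(vals, dtype=float)))

    out[f"{prefix} Shape"] = avg(shapes)
    out[f"{prefix} Eccentricity"] = avg(eccs)
    out[f"{prefix} Angle SDI"] = avg(sdis)
    out[f"{prefix} Anisotropy"] = avg(anis)
    out[f"{prefix} Local Anisotropy"] = avg(loc_anis)
    out[f"{prefix} Intensity Mean"] = avg(means)
    out[f"{prefix} Intensity STD"] = avg(stds)
    out[f"{prefix} Intensity Entropy"] = avg(ents)
    return out


def compute_record(img: MultiChannelImage, cfg: RunConfig | None = None) -> MetricRecord:
    """Run the full per-image pipeline and assemble the metric record.

    Stages: denoise -> structure-tensor fields -> fibre-network extraction
    -> colour-cluster segmentation refined by the network -> per-segment
    metrics averaged into the 29 global metrics plus auxiliary fibre
    density.  A failed stage logs a diagnostic and leaves its metrics as
    sentinels rather than aborting the record.
    """
    cfg = cfg or RunConfig()
    record = MetricRecord(field_id=img.field_id, label=img.label)
    m = record.metrics
    try:
        clean = denoise(img, sigma=cfg.denoise_sigma, median_radius=cfg.median_radius)
        fire = FireParams(
            intensity_threshold=cfg.fire_intensity_threshold,
            nucleation_spacing=cfg.fire_nucleation_spacing,
            step=cfg.fire_step,
            edge_threshold=cfg.fire_edge_threshold,
            angle_tol=cfg.fire_angle_tol,
        )
        net = extract_network(clean.shg, fire)
        fibres, _ = identify_fibres(net, angle_tol=cfg.fire_angle_tol)
        fm = fibre_metrics(fibres)
        nm = network_metrics(net, fibres, connectivity_mode=cfg.connectivity_mode)
        m["No. Fibres"] = fm["n_fibres"]
        m["Fibre Waviness"] = fm["mean_waviness"]
        m["Fibre Lengths"] = fm["mean_length"]
        m["Fibre Angles"] = fm["mean_angle"]
        m["Fibre Network Degree"] = nm["degree"]
        m["Fibre Network Eigenvalue"] = nm["max_eigenvalue"]
        m["Fibre Network Connectivity"] = nm["connectivity"]
        m["Fibre Network Cross-Link Density"] = nm["crosslink_density"]
    except Exception:
        logger.exception("field %s: network stage failed", img.field_id)
        net, fibres = None, []

    try:
        rgb = composite_rgb(clean)
        fibre_mask, cell_mask = kmeans_segment(
            rgb, k=cfg.kmeans_k, red_boundary=cfg.red_boundary, seed=cfg.seed
        )
        segments = (
            refine_with_network(
                fibre_mask,
                cell_mask,
                net,
                min_area=cfg.min_segment_area,
                dilation_radius=cfg.network_dilation_radius,
            )
            if net is not None
            else []
        )
        m["No. Cells"] = float(sum(1 for s in segments if s.kind == "cell"))

        tensor_shg = structure_tensor_field(
            clean.shg, derivative_sigma=cfg.derivative_sigma, window_sigma=cfg.window_sigma
        )
        tensor_pl = structure_tensor_field(
            clean.pl, derivative_sigma=cfg.derivative_sigma, window_sigma=cfg.window_sigma
        )
        image_area = img.shape[0] * img.shape[1]
        m.update(
            _segment_class_metrics("fibre", segments, tensor_shg, clean.shg, image_area, cfg)
        )
        m.update(_segment_class_metrics("cell", segments, tensor_pl, clean.pl, image_area, cfg))

        final_fibre_mask = np.zeros(img.shape, dtype=bool)
        for seg in segments:
            if seg.kind == "fibre":
                final_fibre_mask |= seg.mask
        m["Fibre Density"] = fibre_density(clean.shg, final_fibre_mask)
    except Exception:
        logger.exception("field %s: segmentation stage failed", img.field_id)

    return record


_ID_COLUMNS = ("field_id", "label")


def write_database(records: list[MetricRecord], path: str | Path) -> Path:
    """Write records as CSV: one row per image, stable column order,
    sentinels rendered as empty cells.  Round-trips via
    :func:`read_database`.  A column-name manifest JSON is written
    alongside."""
    if not records:
        raise ValueError("no records to write")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    columns = list(_ID_COLUMNS) + list(CANONICAL_METRICS) + list(AUXILIARY_METRICS)
    rows = [
        {"field_id": r.field_id, "label": r.label, **r.metrics}
        for r in records
    ]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False)
    manifest = {
        "id_columns": list(_ID_COLUMNS),
        "canonical_metrics": list(CANONICAL_METRICS),
        "auxiliary_metrics": list(AUXILIARY_METRICS),
    }
    path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=1))
    return path


def read_database(path: str | Path) -> list[MetricRecord]:
    """Read a metric database written by :func:`write_database`."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        metrics = {
            name: float(row[name]) if pd.notna(row[name]) else SENTINEL
            for name in CANONICAL_METRICS + AUXILIARY_METRICS
            if name in row
        }
        label = row.get("label")
        records.append(
            MetricRecord(
                field_id=str(row["field_id"]),
                label=None if pd.isna(label) else str(label),
                metrics=metrics,
            )
        )
    return records


def database_frame(records: list[MetricRecord], include_density: bool = False) -> pd.DataFrame:
    """Records as a DataFrame of features for the classifier stage."""
    cols = list(CANONICAL_METRICS) + (list(AUXILIARY_METRICS) if include_density else [])
    data = {c: [r.metrics[c] for r in records] for c in cols}
    df = pd.DataFrame(data)
    df.insert(0, "field_id", [r.field_id for r in records])
    df.insert(1, "label", [r.label for r in records])
    return df
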