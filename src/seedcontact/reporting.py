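"""Replicate aggregation, radicle polyline length and the batch driver.

Replicate summaries report the mean and the standard error of the mean
(sample standard deviation with the n-1 denominator divided by sqrt(n)),
the convention behind error bars on per-treatment contact measurements.
Radicle (embryonic root) lengths are measured along user-supplied polylines
of voxel coordinates, mirroring manual polyline tools in CT software.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import contact as contact_mod
from . import iceberg as iceberg_mod
from .segmentation import close_seed, segment_phases, select_seed
from .volume_io import PHASE_SOIL, AnalysisConfig, read_volume

__all__ = [
    "ReplicateSummary",
    "Polyline",
    "BatchResult",
    "summarize_replicates",
    "polyline_length",
    "analyze_volume",
    "run_batch",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReplicateSummary:
    n: int
    mean: float
    sem: float
    values: tuple
    single_replicate: bool = False


@dataclass(frozen=True)
class Polyline:
    """Ordered 3-D point list in voxel units with the scan's voxel size."""

    points: tuple
    voxel_size_um: float

    def __post_init__(self) -> None:
        pts = tuple(tuple(float(c) for c in p) for p in self.points)
        if len(pts) < 2:
            raise ValueError("a polyline needs at least 2 points")
        if any(len(p) != 3 for p in pts):
            raise ValueError("polyline points must be 3-D")
        for a, b in zip(pts, pts[1:]):
            if a == b:
                raise ValueError(f"consecutive duplicate point {a}")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        object.__setattr__(self, "points", pts)


def summarize_replicates(values: Sequence[float]) -> ReplicateSummary:
    """Mean and standard error of the mean over replicate measurements.

    SEM uses the n-1 sample standard deviation; a single replicate yields
    SEM 0 with a flag rather than an error.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("cannot summarise an empty replicate list")
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("replicate values must be finite")
    n = len(vals)
    mean = float(np.mean(vals))
    if n == 1:
        return ReplicateSummary(n=1, mean=mean, sem=0.0, values=tuple(vals),
                                single_replicate=True)
    sem = float(np.std(vals, ddof=1) / math.sqrt(n))
    return ReplicateSummary(n=n, mean=mean, sem=sem, values=tuple(vals))


def polyline_length(line: Polyline) -> float:
    """Total polyline length in mm: summed Euclidean segment lengths times
    the voxel size."""
    pts = np.asarray(line.points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
    return float(seg * line.voxel_size_um / 1000.0)


# ---------------------------------------------------------------------------
# batch driver

_METRIC_COLUMNS = [
    "surface_area_mm2",
    "contact_area_mm2",
    "contact_pct",
    "volume_effect_short_pct",
    "volume_effect_long_pct",
    "surface_effect_short_pct",
    "surface_effect_long_pct",
    "change_volume_pct",
    "change_surface_pct",
]


@dataclass
class BatchResult:
    results: pd.DataFrame  # one row per successfully analysed volume
    summary: pd.DataFrame  # mean/SEM per metric over successful volumes
    errors: List[dict] = field(default_factory=list)


def analyze_volume(path: Union[str, Path], config: AnalysisConfig) -> dict:
    """Full pipeline on one column: segment, select and close the seed,
    contact and two-ring metrics.  Returns a flat metric record."""
    vol = read_volume(path, voxel_size_um=config.voxel_size_um)
    labels = segment_phases(vol, thresholds=config.thresholds)
    raw_seed = select_seed(labels, film_opening_radius=config.film_opening_radius)
    closed = close_seed(
        raw_seed,
        closing_radius_voxels=config.closing_radius_voxels,
        voxel_size_um=vol.voxel_size_um,
        surface_method=config.surface_method,
    )
    soil = labels.phase_mask(PHASE_SOIL) & ~closed.closed_mask
    result = contact_mod.compute_contact(
        closed.closed_mask,
        soil,
        vol.voxel_size_um,
        connectivity=config.connectivity,
        surface_method=config.surface_method,
    )
    ice = iceberg_mod.compute_iceberg(
        closed.closed_mask,
        labels,
        result,
        widths=config.ring_widths_voxels,
        voxel_size_um=vol.voxel_size_um,
    )
    return {
        "volume": str(path),
        "surface_area_mm2": result.surface_area_mm2,
        "contact_area_mm2": result.contact_area_mm2,
        "contact_pct": result.contact_pct,
        "seed_volume_increase_pct": closed.volume_increase_pct,
        "seed_surface_change_pct": closed.surface_change_pct,
        "volume_effect_short_pct": ice.short.composition.volume_effect_pct,
        "volume_effect_long_pct": ice.long.composition.volume_effect_pct,
        "surface_effect_short_pct": ice.short.surface.surface_effect_pct,
        "surface_effect_long_pct": ice.long.surface.surface_effect_pct,
        "change_volume_pct": ice.change_volume_pct,
        "change_surface_pct": ice.change_surface_pct,
    }


def run_batch(config: AnalysisConfig, volumes: Sequence[Union[str, Path]]) -> BatchResult:
    """Analyse a list of scan columns and summarise replicates per metric.

    Failures are isolated per column (logged, recorded in ``errors``);
    the batch only fails as a whole when every column fails.  Row order is
    deterministic (input order; summary rows in fixed metric order).
    """
    if not volumes:
        raise ValueError("empty volume list")
    rows, errors = [], []
    for path in volumes:
        try:
            rows.append(analyze_volume(path, config))
        except Exception as exc:  # noqa: BLE001 - isolation contract
            log.warning("volume %s failed: %s", path, exc)
            errors.append({"volume": str(path), "error": str(exc)})
    if not rows:
        raise RuntimeError(
            "all volumes failed: " + "; ".join(e["error"] for e in errors)
        )
    results = pd.DataFrame(rows)
    summary_rows = []
    for metric in _METRIC_COLUMNS:
        vals = [v for v in results[metric] if v is not None and math.isfinite(v)]
        if not vals:
            continue
        s = summarize_replicates(vals)
        summary_rows.append({"metric": metric, "n": s.n, "mean": s.mean, "sem": s.sem})
    return BatchResult(results=results, summary=pd.DataFrame(summary_rows), errors=errors)
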