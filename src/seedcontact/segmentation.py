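"""Three-phase segmentation and closed-seed extraction.

A germinating seed opens as it imbibes, so the raw seed segmentation
contains internal air space; the contact denominator must instead be the
*closed* surface of a cavity-free object.  ``close_seed`` seals narrow
openings with a morphological closing and then fills every background
component not connected to the grid boundary, reporting how much the
volume grew and the surface changed in the process.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu
from skimage.morphology import ball

from .contact import surface_area
from .volume_io import PHASE_AIR, PHASE_SEED, PHASE_SOIL, GreyVolume, PhaseLabelMap

__all__ = ["ClosedSeedResult", "segment_phases", "select_seed", "close_seed"]

#: Band-to-phase assignment for increasing greyscale: air darkest, the seed
#: (organic material) in the middle band, mineral soil brightest.
DEFAULT_BAND_ORDER = ("air", "seed", "soil")

_PHASE_BY_NAME = {"air": PHASE_AIR, "soil": PHASE_SOIL, "seed": PHASE_SEED}


@dataclass
class ClosedSeedResult:
    """Raw vs closed seed mask plus the volume/surface change bookkeeping.

    ``volume_increase_pct`` = 100 x (|closed| - |raw|) / |raw|;
    ``surface_change_pct`` is signed, negative meaning the closed surface is
    smaller than the raw one (the usual case, since filled cavities no
    longer contribute interior surface).
    """

    closed_mask: np.ndarray
    raw_mask: np.ndarray
    volume_increase_pct: float
    surface_change_pct: float
    voxel_size_um: float


def segment_phases(
    vol: GreyVolume,
    thresholds: Optional[Tuple[float, float]] = None,
    band_order: Sequence[str] = DEFAULT_BAND_ORDER,
) -> PhaseLabelMap:
    """Split a greyscale volume into air / soil / seed by two cut points.

    With explicit ``thresholds`` (t1 < t2): value < t1 falls in the first
    band, t1 <= value < t2 in the second, value >= t2 in the third; the
    ``band_order`` names map bands to phases (default dark-to-bright
    air, seed, soil).  Without thresholds a 3-class multi-Otsu histogram
    threshold is estimated.
    """
    if sorted(band_order) != sorted(_PHASE_BY_NAME):
        raise ValueError(f"band_order must be a permutation of {tuple(_PHASE_BY_NAME)}")
    data = vol.data
    if thresholds is None:
        if np.unique(data).size < 3:
            raise ValueError("degenerate histogram: need >= 3 distinct greyscale values "
                             "for automatic 3-class thresholding")
        try:
            t1, t2 = threshold_multiotsu(data, classes=3)
        except ValueError as exc:
            raise ValueError(f"degenerate histogram: {exc}") from exc
    else:
        t1, t2 = thresholds
        if not t1 < t2:
            raise ValueError(f"thresholds must satisfy t1 < t2, got ({t1}, {t2})")
    bands = np.digitize(data, [t1, t2])
    labels = np.empty(data.shape, dtype=np.uint8)
    for band, name in enumerate(band_order):
        labels[bands == band] = _PHASE_BY_NAME[name]
    return PhaseLabelMap(labels=labels, voxel_size_um=vol.voxel_size_um)


def select_seed(
    labels: PhaseLabelMap,
    marker: Optional[Tuple[int, int, int]] = None,
    film_opening_radius: int = 0,
) -> np.ndarray:
    """Pick one 26-connected component of the seed phase.

    With a ``marker`` voxel, the component containing it; otherwise the
    largest seed-phase component (the scanned seed dominates stray
    seed-intensity debris).

    ``film_opening_radius > 0`` additionally strips thin partial-volume
    films: at soil-air interfaces the blurred greyscale passes through the
    seed intensity band, depositing a voxel-thin seed-labelled skin over
    the soil that can connect to the real seed and masquerade as seed
    surface.  A morphological opening of the given radius removes sheets up
    to ~2r thick while leaving the (much thicker) seed body intact; the
    largest remaining component is returned.
    """
    seed_mask = labels.phase_mask(PHASE_SEED)
    if not seed_mask.any():
        raise ValueError("no seed phase present in the label map")
    comp, n = ndimage.label(seed_mask, structure=np.ones((3, 3, 3), dtype=bool))
    if marker is not None:
        marker = tuple(int(c) for c in marker)
        if not seed_mask[marker]:
            raise ValueError(f"marker {marker} is not on a seed-phase voxel")
        selected = comp == comp[marker]
    else:
        counts = np.bincount(comp.ravel())[1:]  # skip background
        selected = comp == (int(np.argmax(counts)) + 1)
    if film_opening_radius > 0:
        opened = ndimage.binary_opening(
            selected, structure=ball(film_opening_radius)
        )
        if opened.any():
            comp2, _ = ndimage.label(opened, structure=np.ones((3, 3, 3), dtype=bool))
            counts2 = np.bincount(comp2.ravel())[1:]
            selected = comp2 == (int(np.argmax(counts2)) + 1)
    return selected


def _has_enclosed_background(mask: np.ndarray) -> bool:
    """True if any 6-connected background component fails to reach the grid
    boundary (i.e. the mask still encloses a cavity)."""
    filled = ndimage.binary_fill_holes(mask)
    return bool((filled & ~mask).any())


def close_seed(
    raw_mask: np.ndarray,
    closing_radius_voxels: int = 3,
    voxel_size_um: float = 20.0,
    surface_method: str = "face_count",
) -> ClosedSeedResult:
    """Close the seed: morphological closing then boundary-connected hole fill.

    A ball-shaped structuring element of the given radius seals openings up
    to roughly twice the radius wide; the subsequent fill (6-connected
    background, the standard dual of a 26-connected foreground) turns every
    enclosed air space into seed.  Radius 0 skips the closing and only
    fills.  The raw mask is always a subset of the result.
    """
    raw_mask = np.asarray(raw_mask).astype(bool, copy=False)
    if raw_mask.ndim != 3:
        raise ValueError("raw_mask must be 3-D")
    if not raw_mask.any():
        raise ValueError("empty seed mask cannot be closed")
    r = int(closing_radius_voxels)
    if r < 0:
        raise ValueError("closing radius must be non-negative")
    if 2 * r + 1 > min(raw_mask.shape):
        raise ValueError(
            f"closing element of radius {r} exceeds the grid {raw_mask.shape}"
        )
    if r > 0:
        # Pad so the closing is not truncated at the grid boundary.
        padded = np.pad(raw_mask, r + 1, constant_values=False)
        closed = ndimage.binary_closing(padded, structure=ball(r))
        sl = (slice(r + 1, -(r + 1)),) * 3
        closed = closed[sl] | raw_mask
    else:
        closed = raw_mask.copy()
    closed = ndimage.binary_fill_holes(closed)

    n_raw = int(raw_mask.sum())
    n_closed = int(closed.sum())
    a_raw = surface_area(raw_mask, voxel_size_um, method=surface_method)
    a_closed = surface_area(closed, voxel_size_um, method=surface_method)
    return ClosedSeedResult(
        closed_mask=closed,
        raw_mask=raw_mask,
        volume_increase_pct=100.0 * (n_closed - n_raw) / n_raw,
        surface_change_pct=100.0 * (a_closed - a_raw) / a_raw,
        voxel_size_um=voxel_size_um,
    )
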