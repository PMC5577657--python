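"""Seed-soil contact quantification.

The contact percentage is the fraction of the closed seed surface touched by
soil after the soil mask is dilated by one voxel, so that grain-seed
adjacency (including diagonal adjacency at 26-connectivity) produces an
overlap with the undilated seed.  The surface is discretised into the
exposed faces of the foreground voxels (6-neighbourhood), and both the
numerator and the denominator of the percentage are counted on that same
face discretisation — the ratio is therefore independent of the systematic
bias any absolute-area estimator carries.

Absolute areas in mm² are additionally reported, either from the face count
(which overestimates a smooth surface by a known ~1.5x voxelisation factor)
or from a marching-cubes iso-surface triangulation (within a few percent of
the true area for smooth objects resolved at >= ~15 voxels radius).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "ContactResult",
    "structuring_element",
    "dilate_mask",
    "surface_faces",
    "count_surface_faces",
    "surface_area",
    "compute_contact",
]

#: Outward unit directions of the six voxel faces, (dz, dy, dx).
FACE_DIRECTIONS = np.array(
    [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)],
    dtype=np.int64,
)

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def structuring_element(connectivity: int) -> np.ndarray:
    """3x3x3 structuring element for a 6/18/26 neighbourhood."""
    try:
        rank = _CONNECTIVITY_RANK[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}") from None
    return ndimage.generate_binary_structure(3, rank)


@dataclass(frozen=True)
class ContactResult:
    """Closed seed surface, contact area and their ratio.

    ``contact_pct`` = 100 x contact faces / surface faces; the areas are on
    the scale of the configured estimator, with
    ``contact_area_mm2 = contact_pct/100 x surface_area_mm2`` so numerator
    and denominator share one discretisation.
    """

    surface_area_mm2: float
    contact_area_mm2: float
    contact_pct: float
    surface_face_count: int
    contact_face_count: int
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.contact_pct <= 100.0:
            raise ValueError(f"contact_pct outside [0, 100]: {self.contact_pct}")
        if self.contact_area_mm2 > self.surface_area_mm2 * (1 + 1e-12):
            raise ValueError("contact area exceeds surface area")


def _as_bool3d(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"{name} must be 3-D, got {mask.ndim}-D")
    return mask.astype(bool, copy=False)


def dilate_mask(mask: np.ndarray, steps: int, connectivity: int = 26) -> np.ndarray:
    """Iterated binary dilation clipped to the grid bounds.

    ``steps`` applications of the 6/18/26 structuring element; the input is
    never modified.
    """
    mask = _as_bool3d(mask)
    if steps < 1:
        raise ValueError(f"steps must be >= 1, got {steps}")
    if not mask.any():
        raise ValueError("cannot dilate an empty mask")
    return ndimage.binary_dilation(mask, structure=structuring_element(connectivity), iterations=steps)


def _face_exposure(mask: np.ndarray) -> list:
    """Per direction, the boolean grid of foreground voxels whose neighbour in
    that direction is background or outside the grid."""
    padded = np.pad(mask, 1, constant_values=False)
    out = []
    for dz, dy, dx in FACE_DIRECTIONS:
        neigh = padded[
            1 + dz : 1 + dz + mask.shape[0],
            1 + dy : 1 + dy + mask.shape[1],
            1 + dx : 1 + dx + mask.shape[2],
        ]
        out.append(mask & ~neigh)
    return out

def surface_faces(mask: np.ndarray) -> np.ndarray:
    """Enumerate the boundary faces of a voxel mask.

    Returns an (n, 6) integer array of rows ``(z, y, x, dz, dy, dx)``: the
    owning foreground voxel and the outward face direction.  One row per
    (voxel, 6-neighbour) pair whose neighbour is background or out of grid.
    """
    mask = _as_bool3d(mask)
    if not mask.any():
        raise ValueError("empty mask has no surface")
    rows = []
    for direction, exposed in zip(FACE_DIRECTIONS, _face_exposure(mask)):
        coords = np.argwhere(exposed)
        if coords.size:
            rows.append(np.hstack([coords, np.broadcast_to(direction, (len(coords), 3))]))
    return np.vstack(rows).astype(np.int64)


def count_surface_faces(mask: np.ndarray) -> int:
    """Total 6-connected boundary face count (fast path, no enumeration)."""
    mask = _as_bool3d(mask)
    if not mask.any():
        raise ValueError("empty mask has no surface")
    return int(sum(exposed.sum() for exposed in _face_exposure(mask)))


def surface_area(mask: np.ndarray, voxel_size_um: float, method: str = "face_count") -> float:
    """Surface area of a voxel mask in mm².

    ``face_count``: boundary faces x (voxel edge in mm)².  ``mesh``: area of
    the marching-cubes iso-surface at level 0.5 of the binary grid.
    """
    mask = _as_bool3d(mask)
    if not mask.any():
        raise ValueError("empty mask has no surface")
    s_mm = voxel_size_um / 1000.0
    if method == "face_count":
        return count_surface_faces(mask) * s_mm * s_mm
    if method == "mesh":
        # Anti-alias the binary grid (sigma 1 voxel) before triangulation:
        # marching cubes on a raw 0/1 grid inherits ~8-10% staircase bias,
        # while the smoothed 0.5-level set tracks smooth surfaces to <1%.
        padded = np.pad(mask, 2, constant_values=False).astype(np.float32)
        smoothed = ndimage.gaussian_filter(padded, sigma=1.0)
        verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5, spacing=(s_mm,) * 3)
        return float(measure.mesh_surface_area(verts, faces))
    raise ValueError(f"unknown surface method {method!r}")


def compute_contact(
    seed_closed: np.ndarray,
    soil: np.ndarray,
    voxel_size_um: float,
    connectivity: int = 26,
    surface_method: str = "face_count",
) -> ContactResult:
    """Contact percentage of the closed seed surface with +1-voxel-dilated soil.

    The soil mask is dilated by one step at the given connectivity so that
    it overlaps the undilated seed wherever a grain is adjacent; a surface
    face of the seed counts as a contact face iff its owning seed voxel lies
    inside the dilated soil.

    Parameters
    ----------
    seed_closed:
        Closed (cavity-free) seed mask.
    soil:
        Soil mask, same shape, disjoint from the seed.
    """
    seed_closed = _as_bool3d(seed_closed, "seed mask")
    soil = _as_bool3d(soil, "soil mask")
    if seed_closed.shape != soil.shape:
        raise ValueError(f"shape mismatch: seed {seed_closed.shape} vs soil {soil.shape}")
    if (seed_closed & soil).any():
        raise ValueError("seed and soil masks overlap; they must be disjoint phases")
    if not seed_closed.any():
        raise ValueError("empty seed mask")

    exposure = _face_exposure(seed_closed)
    n_surface = int(sum(e.sum() for e in exposure))
    if soil.any():
        soil_dil = dilate_mask(soil, steps=1, connectivity=connectivity)
        owner_in_contact = seed_closed & soil_dil
        n_contact = int(sum((e & owner_in_contact).sum() for e in exposure))
    else:
        n_contact = 0
    pct = 100.0 * n_contact / n_surface
    area = surface_area(seed_closed, voxel_size_um, method=surface_method)
    return ContactResult(
        surface_area_mm2=area,
        contact_area_mm2=pct / 100.0 * area,
        contact_pct=pct,
        surface_face_count=n_surface,
        contact_face_count=n_contact,
        method=surface_method,
    )
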