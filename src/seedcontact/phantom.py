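"""Synthetic CT-like phantoms of seeds in granular soil.

No public CT scans of seeds in seedbeds exist at the relevant scale, so
validation rests on parametric scenes with known ground truth:

* a seed — a sphere (a pelleted and coated seed, ~4 mm diameter) or a
  star-shaped prism (a naked sugar-beet seed, ~4 x 3 x 3 mm) — placed
  centrally, optionally with an internal air cavity vented by a narrow
  crack, as in a germinating seed that has started to open;
* soil — solid, a plane-bounded half-space / spherical cap with an
  analytically known contact fraction, or a random packing of spherical
  grains respecting the < 1 mm sieve cap of a prepared seedbed;
* greyscale — per-phase means (air darkest, seed intermediate, mineral
  soil brightest) plus Gaussian noise and an optional Gaussian blur
  emulating the partial-volume effect.

The true label map, the analytic contact fraction (cap models) and
per-distance shell composition tallies are recorded before any greyscale
degradation, so every downstream metric can be checked against generation
truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

from .volume_io import PHASE_AIR, PHASE_SEED, PHASE_SOIL, GreyVolume, PhaseLabelMap

__all__ = [
    "GreyLevels",
    "CavitySpec",
    "SolidSoil",
    "CapSoil",
    "GrainPackingSoil",
    "PhantomSpec",
    "PhantomTruth",
    "sphere_mask",
    "star_seed",
    "pack_grains",
    "generate_phantom",
]

#: Sieve cap on grain size: the seedbed soil is sieved to < 1 mm diameter.
SIEVE_CAP_UM = 1000.0

#: Clearance (voxels) required between the seed and every grid boundary so
#: that the long-range (15-voxel) ring is never clipped.
LONG_RANGE_CLEARANCE = 15


@dataclass(frozen=True)
class GreyLevels:
    """Per-phase greyscale means on an 8-bit-like scale plus noise SD.

    Defaults give three cleanly separated histogram modes (air 10,
    organic seed material 120, mineral soil 220, SD 8) so automatic
    multi-Otsu thresholding recovers the phases."""

    air: float = 10.0
    seed: float = 120.0
    soil: float = 220.0
    noise_sd: float = 8.0


@dataclass(frozen=True)
class CavitySpec:
    """Internal spherical air cavity, optionally vented by a straight crack
    channel to the exterior (the air space a germinating seed opens up).

    The crack runs along +z, laterally offset from the seed centre by
    ``crack_offset_um`` (default 0.4 x the seed radius for a spherical
    seed) so that it exits through the seed's flank — a coat split does
    not pass through a geometric pole, and an exit at the digitized
    sphere's extreme pole voxel could never be resealed exactly."""

    radius_um: float
    crack_width_um: float = 0.0
    crack_offset_um: Optional[float] = None


@dataclass(frozen=True)
class SolidSoil:
    """All non-seed space is soil; contact fraction 1."""


@dataclass(frozen=True)
class CapSoil:
    """Soil fills the half-space below the plane tangent to the spherical
    cap of half-angle ``theta_deg`` (measured from the bottom pole of a
    spherical seed).  The analytic contact fraction is (1 - cos theta)/2;
    theta = 90 degrees is the equatorial half-space."""

    theta_deg: float


@dataclass(frozen=True)
class GrainPackingSoil:
    """Random sequential addition of spherical grains around the seed."""

    radii_um: Tuple[float, float] = (100.0, 500.0)
    target_solid_fraction: float = 0.30
    overlap_tolerance: float = 0.0


SoilModel = Union[SolidSoil, CapSoil, GrainPackingSoil]


@dataclass
class PhantomSpec:
    """Parametric description of a seed-in-soil scene.

    Defaults mirror a 20 µm isotropic scan of a ~4 mm seed; the grid must
    leave at least 15 voxels (the long-range ring width) between the seed
    and every boundary.
    """

    grid_shape: Tuple[int, int, int]
    voxel_size_um: float = 20.0
    seed_shape: str = "sphere"  # "sphere" | "star"
    seed_radius_um: float = 2000.0
    star_dims_um: Tuple[float, float, float] = (4000.0, 3000.0, 3000.0)
    star_points: int = 5
    cavity: Optional[CavitySpec] = None
    soil_model: SoilModel = field(default_factory=SolidSoil)
    grey_levels: GreyLevels = field(default_factory=GreyLevels)
    blur_sigma_voxels: float = 0.0
    rng_seed: int = 0
    seed_center: Optional[Tuple[int, int, int]] = None  # default: grid centre

    def __post_init__(self) -> None:
        if self.seed_shape not in ("sphere", "star"):
            raise ValueError(f"seed_shape must be 'sphere' or 'star', got {self.seed_shape!r}")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if isinstance(self.soil_model, GrainPackingSoil):
            lo, hi = self.soil_model.radii_um
            if 2 * hi > SIEVE_CAP_UM:
                raise ValueError(
                    f"grain diameter {2 * hi} µm violates sieve cap ({SIEVE_CAP_UM} µm)"
                )


@dataclass
class PhantomTruth:
    """Generation-time ground truth, recorded before noise and blur."""

    labels: PhaseLabelMap
    closed_seed_mask: np.ndarray
    analytic_contact_fraction: Optional[float]
    shell_soil_counts: Dict[int, Tuple[int, int]]  # distance -> (soil, air) voxels
    achieved_solid_fraction: Optional[float] = None


def sphere_mask(shape: Tuple[int, int, int], center: Tuple[float, float, float],
                radius_voxels: float) -> np.ndarray:
    """Digitize a sphere: voxels whose centre lies within the radius."""
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    return (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_voxels**2


def star_seed(
    dims_um: Tuple[float, float, float],
    points: int = 5,
    voxel_size_um: float = 20.0,
    inner_ratio: float = 0.4,
) -> np.ndarray:
    """Digitize a star-polygon prism with the requested bounding box.

    The star cross-section (default 5 lobes, inner/outer radius ratio 0.4)
    lies in the (y, x) plane and is extruded along z, so dims (4000, 3000,
    3000) µm at 20 µm yield a 200 x 150 x 150 voxel prism.  The result is a
    single 26-connected component whose surface area exceeds that of the
    volume-equivalent sphere.
    """
    if points < 2:
        raise ValueError("a star needs at least 2 points")
    nz, ny, nx = (int(round(d / voxel_size_um)) for d in dims_um)
    if min(nz, ny, nx) < 6:
        raise ValueError(
            f"dims {dims_um} µm at {voxel_size_um} µm are too small to render lobes "
            f"(< 6 voxels across)"
        )
    angles = np.pi / 2 + np.arange(2 * points) * np.pi / points
    radii = np.where(np.arange(2 * points) % 2 == 0, 1.0, inner_ratio)
    ys = radii * np.sin(angles)
    xs = radii * np.cos(angles)

    def _rescale(v: np.ndarray, n: int) -> np.ndarray:
        return (v - v.min()) / (v.max() - v.min()) * (n - 1)

    ys, xs = _rescale(ys, ny), _rescale(xs, nx)
    mask2d = np.zeros((ny, nx), dtype=bool)
    rr, cc = draw_polygon(ys, xs, shape=(ny, nx))
    mask2d[rr, cc] = True
    # Rasterize the outline as well: thin lobe tips can be missed by the
    # interior fill, and the vertices must render so the bounding box is
    # exactly the requested one and the cross-section stays connected.
    yi, xi = np.round(ys).astype(int), np.round(xs).astype(int)
    for i in range(len(yi)):
        j = (i + 1) % len(yi)
        rr, cc = draw_line(yi[i], xi[i], yi[j], xi[j])
        mask2d[rr, cc] = True
    return np.broadcast_to(mask2d, (nz, ny, nx)).copy()


def pack_grains(
    region: np.ndarray,
    radii_um: Tuple[float, float],
    target_solid_fraction: float,
    rng_seed: int,
    voxel_size_um: float = 20.0,
    overlap_tolerance: float = 0.0,
    max_attempts: int = 20000,
) -> Tuple[np.ndarray, float]:
    """Random sequential addition of spherical grains into ``region``.

    Grains are non-overlapping up to ``overlap_tolerance`` (a fractional
    relaxation of the centre-distance constraint that lets grains fuse into
    aggregates), clipped to the region, and added until the achieved solid
    fraction is within 2 percentage points of the target or attempts run
    out.  Returns the grain mask and the achieved fraction.
    """
    region = np.asarray(region).astype(bool, copy=False)
    if not region.any():
        raise ValueError("empty packing region")
    lo, hi = radii_um
    if not 0 < lo <= hi:
        raise ValueError(f"invalid radius range {radii_um}")
    if 2 * hi > SIEVE_CAP_UM:
        raise ValueError(f"grain diameter {2 * hi} µm violates sieve cap ({SIEVE_CAP_UM} µm)")
    if target_solid_fraction < 0 or target_solid_fraction > 0.64:
        raise ValueError(
            f"target solid fraction {target_solid_fraction} outside feasible (0, 0.64]"
        )
    mask = np.zeros(region.shape, dtype=bool)
    if target_solid_fraction == 0:
        return mask, 0.0

    rng = np.random.default_rng(rng_seed)
    region_count = int(region.sum())
    flat_region = np.flatnonzero(region.ravel())
    centers: list = []
    radii: list = []
    n_filled = 0
    attempts = 0
    while attempts < max_attempts and n_filled < target_solid_fraction * region_count:
        attempts += 1
        idx = flat_region[rng.integers(len(flat_region))]
        c = np.array(np.unravel_index(idx, region.shape), dtype=float)
        r_vox = rng.uniform(lo, hi) / voxel_size_um
        if centers:
            d = np.linalg.norm(np.asarray(centers) - c, axis=1)
            if (d < (np.asarray(radii) + r_vox) * (1.0 - overlap_tolerance)).any():
                continue
        # Rasterize into the local bounding box, clipped to the region.
        rc = int(math.ceil(r_vox))
        sl = tuple(
            slice(max(int(c[a]) - rc, 0), min(int(c[a]) + rc + 1, region.shape[a]))
            for a in range(3)
        )
        zz, yy, xx = np.ogrid[sl[0], sl[1], sl[2]]
        ball = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r_vox**2
        new = ball & region[sl] & ~mask[sl]
        n_new = int(new.sum())
        if n_filled + n_new > (target_solid_fraction + 0.02) * region_count:
            continue  # this grain would overshoot; try a different draw
        mask[sl] |= new
        n_filled += n_new
        centers.append(c)
        radii.append(r_vox)
    return mask, n_filled / region_count


def _carve_cavity(
    solid_seed: np.ndarray,
    cavity: CavitySpec,
    center: Tuple[int, int, int],
    voxel_size_um: float,
    default_offset_um: float = 0.0,
) -> np.ndarray:
    """Seed-with-cavity mask: subtract the internal cavity and, if a crack
    width is given, a square channel running from the cavity to the
    exterior along +z, laterally offset so it exits through the flank."""
    shape = solid_seed.shape
    r_cav = cavity.radius_um / voxel_size_um
    carved = solid_seed & ~sphere_mask(shape, center, r_cav)
    if cavity.crack_width_um > 0:
        half_w = max(cavity.crack_width_um / voxel_size_um / 2.0, 0.5)
        offset_um = (
            cavity.crack_offset_um if cavity.crack_offset_um is not None else default_offset_um
        )
        cz, cy, cx = center
        cy = cy + offset_um / voxel_size_um
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        channel = (
            (np.abs(yy - cy) <= half_w)
            & (np.abs(xx - cx) <= half_w)
            & (zz >= cz)
        )
        carved &= ~channel
    return carved


def generate_phantom(spec: PhantomSpec) -> Tuple[GreyVolume, PhantomTruth]:
    """Generate a CT-like grey volume and its ground truth.

    Deterministic for a fixed ``rng_seed``.  The labels, shell tallies and
    (for cap soil on a spherical seed) the analytic contact fraction
    (1 - cos theta)/2 describe the scene before noise and blur are applied.
    """
    shape = tuple(int(s) for s in spec.grid_shape)
    center = (
        tuple(int(c) for c in spec.seed_center)
        if spec.seed_center is not None
        else tuple(s // 2 for s in shape)
    )

    # --- seed -----------------------------------------------------------
    if spec.seed_shape == "sphere":
        r_vox = spec.seed_radius_um / spec.voxel_size_um
        solid_seed = sphere_mask(shape, center, r_vox)
    else:
        prism = star_seed(spec.star_dims_um, spec.star_points, spec.voxel_size_um)
        solid_seed = np.zeros(shape, dtype=bool)
        sl = []
        for a in range(3):
            start = center[a] - prism.shape[a] // 2
            if start < 0 or start + prism.shape[a] > shape[a]:
                raise ValueError("star seed does not fit inside the grid")
            sl.append(slice(start, start + prism.shape[a]))
        solid_seed[tuple(sl)] = prism

    coords = np.argwhere(solid_seed)
    if coords.size == 0:
        raise ValueError("seed does not intersect the grid")
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    if (lo < LONG_RANGE_CLEARANCE).any() or (
        hi >= np.array(shape) - LONG_RANGE_CLEARANCE
    ).any():
        raise ValueError(
            f"seed must keep >= {LONG_RANGE_CLEARANCE} voxels of clearance to every "
            f"grid boundary (long-range ring); bounding box {lo.tolist()}..{hi.tolist()} "
            f"in grid {shape}"
        )

    default_offset = 0.4 * spec.seed_radius_um if spec.seed_shape == "sphere" else 0.0
    seed_phase = (
        _carve_cavity(solid_seed, spec.cavity, center, spec.voxel_size_um, default_offset)
        if spec.cavity is not None
        else solid_seed
    )

    # --- soil -----------------------------------------------------------
    analytic_fraction: Optional[float] = None
    achieved: Optional[float] = None
    model = spec.soil_model
    if isinstance(model, SolidSoil):
        soil = ~solid_seed
        analytic_fraction = 1.0
    elif isinstance(model, CapSoil):
        theta = math.radians(model.theta_deg)
        if spec.seed_shape == "sphere":
            r_vox = spec.seed_radius_um / spec.voxel_size_um
            plane_z = center[0] + r_vox * math.cos(theta)
            analytic_fraction = (1.0 - math.cos(theta)) / 2.0
        else:
            plane_z = center[0]  # no closed form for the star; plane at centre
        zz = np.arange(shape[0])[:, None, None]
        soil = (zz >= plane_z) & ~solid_seed
    elif isinstance(model, GrainPackingSoil):
        soil, achieved = pack_grains(
            ~solid_seed,
            model.radii_um,
            model.target_solid_fraction,
            rng_seed=spec.rng_seed,
            voxel_size_um=spec.voxel_size_um,
            overlap_tolerance=model.overlap_tolerance,
        )
    else:  # pragma: no cover - exhaustiveness guard
        raise TypeError(f"unknown soil model {model!r}")

    labels_arr = np.full(shape, PHASE_AIR, dtype=np.uint8)
    labels_arr[soil] = PHASE_SOIL
    labels_arr[seed_phase] = PHASE_SEED
    labels = PhaseLabelMap(labels=labels_arr, voxel_size_um=spec.voxel_size_um)

    # --- shell tallies (Chebyshev distance from the solid seed) ---------
    dist = ndimage.distance_transform_cdt(~solid_seed, metric="chessboard")
    shell_counts: Dict[int, Tuple[int, int]] = {}
    for d in range(1, LONG_RANGE_CLEARANCE + 1):
        band = dist == d
        shell_counts[d] = (
            int((labels_arr[band] == PHASE_SOIL).sum()),
            int((labels_arr[band] == PHASE_AIR).sum()),
        )

    # --- greyscale ------------------------------------------------------
    g = spec.grey_levels
    means = np.array([g.air, g.soil, g.seed], dtype=np.float32)
    rng = np.random.default_rng(spec.rng_seed)
    grey = means[labels_arr] + rng.normal(0.0, g.noise_sd, size=shape).astype(np.float32)
    if spec.blur_sigma_voxels > 0:
        grey = ndimage.gaussian_filter(grey, sigma=spec.blur_sigma_voxels)

    vol = GreyVolume(
        data=grey.astype(np.float32),
        voxel_size_um=spec.voxel_size_um,
        provenance=f"phantom seed={spec.seed_shape} soil={type(model).__name__} "
        f"rng_seed={spec.rng_seed}",
    )
    truth = PhantomTruth(
        labels=labels,
        closed_seed_mask=solid_seed,
        analytic_contact_fraction=analytic_fraction,
        shell_soil_counts=shell_counts,
        achieved_solid_fraction=achieved,
    )
    return vol, truth
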