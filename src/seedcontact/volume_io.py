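"""Reading and writing of 3-D greyscale volumes and phase label maps.

Volumes are stored in (z, y, x) axis order with z the scan axis, matching
slice-stack acquisition.  All geometry is assumed isotropic: one voxel edge
length in micrometres describes all three axes, and every downstream
dilation/ring computation relies on that.  TIFF spacing metadata is treated
as untrustworthy; an explicit sidecar or argument wins over header values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import tifffile
import yaml

__all__ = [
    "PHASE_AIR",
    "PHASE_SOIL",
    "PHASE_SEED",
    "GreyVolume",
    "PhaseLabelMap",
    "AnalysisConfig",
    "read_volume",
    "write_volume",
    "load_config",
]

#: Phase codes used throughout: 0 = air, 1 = soil, 2 = seed.
PHASE_AIR = 0
PHASE_SOIL = 1
PHASE_SEED = 2

_TIFF_SUFFIXES = {".tif", ".tiff"}
_ITK_SUFFIXES = {".mha", ".mhd", ".nrrd"}

#: Relative tolerance for calling header spacing isotropic / consistent.
_SPACING_RTOL = 1e-6


def _check_geometry(shape: tuple, voxel_size_um: float) -> None:
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError(f"volume must be 3-D with all dimensions >= 1, got shape {shape}")
    if not np.isfinite(voxel_size_um) or voxel_size_um <= 0:
        raise ValueError(f"voxel_size_um must be a positive real, got {voxel_size_um}")


@dataclass
class GreyVolume:
    """A raw reconstructed CT scan: a 3-D scalar grid plus isotropic voxel size.

    Parameters
    ----------
    data:
        3-D array in (z, y, x) order.
    voxel_size_um:
        Edge length of the cubic voxel in micrometres (e.g. 20 for the
        typical seed-scale scan resolution).
    provenance:
        Free-text description of where the volume came from.
    """

    data: np.ndarray
    voxel_size_um: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_geometry(self.data.shape, self.voxel_size_um)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0


@dataclass
class PhaseLabelMap:
    """Three-phase categorical grid: 0 = air, 1 = soil, 2 = seed."""

    labels: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        _check_geometry(self.labels.shape, self.voxel_size_um)
        bad = np.setdiff1d(np.unique(self.labels), [PHASE_AIR, PHASE_SOIL, PHASE_SEED])
        if bad.size:
            raise ValueError(f"label map contains values outside {{0, 1, 2}}: {bad.tolist()}")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def phase_mask(self, phase: int) -> np.ndarray:
        return self.labels == phase


_VALID_CONNECTIVITY = (6, 18, 26)
_VALID_SURFACE_METHODS = ("face_count", "mesh")


@dataclass
class AnalysisConfig:
    """Knobs for the segmentation -> contact -> ring pipeline.

    ``ring_widths_voxels`` defaults to (5, 15): at 20 µm voxels these are the
    100 µm short-range and 300 µm long-range rings.
    """

    thresholds: Optional[tuple] = None
    closing_radius_voxels: int = 3
    connectivity: int = 26
    ring_widths_voxels: tuple = (5, 15)
    surface_method: str = "face_count"
    rng_seed: int = 0
    voxel_size_um: Optional[float] = None
    film_opening_radius: int = 1

    def __post_init__(self) -> None:
        if self.connectivity not in _VALID_CONNECTIVITY:
            raise ValueError(
                f"connectivity must be one of {_VALID_CONNECTIVITY}, got {self.connectivity}"
            )
        if self.surface_method not in _VALID_SURFACE_METHODS:
            raise ValueError(
                f"surface_method must be one of {_VALID_SURFACE_METHODS}, got {self.surface_method!r}"
            )
        if self.closing_radius_voxels < 0:
            raise ValueError("closing_radius_voxels must be non-negative")
        w = tuple(int(v) for v in self.ring_widths_voxels)
        if len(w) != 2 or w[0] < 1 or w[0] >= w[1]:
            raise ValueError(f"ring widths must be a strictly increasing positive pair, got {w}")
        self.ring_widths_voxels = w
        if self.thresholds is not None:
            t1, t2 = self.thresholds
            if not t1 < t2:
                raise ValueError(f"thresholds must satisfy t1 < t2, got ({t1}, {t2})")
            self.thresholds = (float(t1), float(t2))


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _read_sidecar(path: Path) -> Optional[float]:
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        return float(meta["voxel_size_um"])
    return None


def _resolve_voxel_size(
    header: Optional[float], argument: Optional[float], source: str
) -> float:
    """Explicit argument wins over header/sidecar, with a warning on conflict."""
    if argument is not None and header is not None:
        if abs(argument - header) > _SPACING_RTOL * max(abs(argument), abs(header)):
            warnings.warn(
                f"voxel size {header} µm from {source} conflicts with argument "
                f"{argument} µm; using the argument",
                stacklevel=3,
            )
        return float(argument)
    if argument is not None:
        return float(argument)
    if header is not None:
        return float(header)
    raise ValueError(
        "voxel size absent from both file header/sidecar and argument; "
        "pass voxel_size_um explicitly"
    )


def _read_itk(path: Path, voxel_size_um: Optional[float]) -> GreyVolume:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    spacing = np.asarray(img.GetSpacing(), dtype=float)  # (x, y, z), millimetres
    if np.ptp(spacing) > _SPACING_RTOL * spacing.max():
        raise ValueError(f"anisotropic header spacing {spacing.tolist()} is not supported")
    header_um = float(spacing[0]) * 1000.0
    data = sitk.GetArrayFromImage(img)  # already (z, y, x)
    vs = _resolve_voxel_size(header_um, voxel_size_um, f"{path.suffix} header")
    return GreyVolume(data=data, voxel_size_um=vs, provenance=str(path))


def _read_tiff_stack(path: Path, voxel_size_um: Optional[float]) -> GreyVolume:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"expected a 2-D/3-D TIFF, got {data.ndim}-D data in {path}")
    vs = _resolve_voxel_size(_read_sidecar(path), voxel_size_um, "sidecar")
    return GreyVolume(data=data, voxel_size_um=vs, provenance=str(path))


def _read_slice_dir(path: Path, voxel_size_um: Optional[float]) -> GreyVolume:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES)
    if not files:
        raise FileNotFoundError(f"no TIFF slices found in directory {path}")
    slices = []
    for f in files:
        sl = tifffile.imread(str(f))
        if sl.ndim != 2:
            raise ValueError(f"slice {f.name} is not 2-D")
        if slices and sl.shape != slices[0].shape:
            raise ValueError(
                f"inconsistent slice dimensions: {f.name} is {sl.shape}, "
                f"expected {slices[0].shape}"
            )
        slices.append(sl)
    data = np.stack(slices, axis=0)
    vs = _resolve_voxel_size(_read_sidecar(path), voxel_size_um, "sidecar")
    return GreyVolume(data=data, voxel_size_um=vs, provenance=str(path))


def read_volume(path: Union[str, Path], voxel_size_um: Optional[float] = None) -> GreyVolume:
    """Read a 3-D volume from a multi-page TIFF, a TIFF slice directory, or
    a MetaImage/NRRD file.

    Slices in a directory are stacked in lexicographic filename order.  The
    voxel size is taken from the format header (MetaImage/NRRD) or a JSON
    sidecar (TIFF) when present; an explicit ``voxel_size_um`` argument
    overrides either, with a warning on conflict.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if path.is_dir():
        return _read_slice_dir(path, voxel_size_um)
    if path.suffix.lower() in _ITK_SUFFIXES:
        return _read_itk(path, voxel_size_um)
    return _read_tiff_stack(path, voxel_size_um)


def write_volume(vol: Union[GreyVolume, PhaseLabelMap], path: Union[str, Path]) -> Path:
    """Write a volume or label map with value-exact round trip.

    TIFF output stores the voxel size in a JSON sidecar next to the file
    (TIFF resolution tags are not trusted for 3-D spacing); MetaImage/NRRD
    store it in the header as millimetre spacing.
    """
    path = Path(path)
    data = vol.labels if isinstance(vol, PhaseLabelMap) else vol.data
    if np.issubdtype(data.dtype, np.floating) and not np.isfinite(data).all():
        raise ValueError("non-finite greyscale values cannot be written")
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, PhaseLabelMap) and data.dtype != np.uint8:
        data = data.astype(np.uint8)
    if path.suffix.lower() in _ITK_SUFFIXES:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(data)
        img.SetSpacing([vol.voxel_size_um / 1000.0] * 3)
        sitk.WriteImage(img, str(path))
    else:
        tifffile.imwrite(str(path), data)
        _sidecar_path(path).write_text(
            json.dumps({"voxel_size_um": vol.voxel_size_um}) + "\n"
        )
    return path


def load_config(path: Union[str, Path]) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML/JSON key-value file.

    Absent keys take the defaults (26-connectivity, ring widths 5 and 15
    voxels, face-count surface estimation, closing radius 3).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config must be a key-value mapping, got {type(raw).__name__}")
    known = {f for f in AnalysisConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}", stacklevel=2)
    kwargs = {k: v for k, v in raw.items() if k in known}
    for key in ("thresholds", "ring_widths_voxels"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return AnalysisConfig(**kwargs)
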