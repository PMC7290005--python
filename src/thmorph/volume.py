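"""Volumes, reference cuboids and on-disk formats.

A :class:`Volume3D` is a 3D scalar intensity grid in fixed ``(z, y, x)``
axis order with per-axis physical voxel spacing in micrometres.  The voxel
with index ``i`` along an axis occupies the half-open physical interval
``[origin + i*s, origin + (i+1)*s)`` and its *center* sits at
``origin + (i + 0.5)*s``.  All geometric predicates in the package
(cropping, sphere membership, slab membership) are evaluated at voxel
centers, which keeps every operation unambiguous under anisotropic
spacing.

Volumes are stored on disk as single-channel multi-page TIFF stacks (one
page per z-plane, 16-bit unsigned as the canonical form) accompanied by a
JSON sidecar that carries the physical metadata TIFF cannot: voxel
spacing, the anatomical rostro-caudal axis mapping, and the midline used
to interpret bilateral regions of interest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Volume3D",
    "ReferenceCuboid",
    "MetadataError",
    "FormatError",
    "EmptyROIError",
    "read_volume",
    "write_volume",
    "read_rois",
    "write_rois",
    "crop",
]

AXIS_NAMES = ("z", "y", "x")


class MetadataError(ValueError):
    """Sidecar metadata missing, malformed, or violating an invariant."""


class FormatError(ValueError):
    """TIFF stack structurally inconsistent (e.g. pages of unequal size)."""


class EmptyROIError(ValueError):
    """A reference cuboid selects no voxel centers of the volume."""


@dataclass
class Volume3D:
    """A 3D intensity grid with physical-coordinate metadata.

    Parameters
    ----------
    data:
        Non-negative scalar grid, axis order ``(z, y, x)``.
    spacing_um:
        Physical voxel spacing per axis in µm, same order; strictly positive.
    rostrocaudal_axis:
        Which array axis runs rostro-caudally (0=z, 1=y, 2=x).
    rostral_sign:
        ``-1`` if rostral lies at the low index end (the default scanning
        convention here), ``+1`` if the coordinate increases rostrally.
    midline_axis:
        Axis of the sagittal midline plane (default x).
    midline_um:
        Physical coordinate of the midline plane; ``None`` means the
        volume center along ``midline_axis``.
    origin_um:
        Physical coordinate of the low corner of voxel (0,0,0); non-zero
        after cropping so coordinates map back to the parent frame.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    rostrocaudal_axis: int = 1
    rostral_sign: int = -1
    midline_axis: int = 2
    midline_um: float | None = None
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise MetadataError(f"expected a 3D grid, got ndim={self.data.ndim}")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise MetadataError(f"voxel spacing must be 3 positive reals, got {self.spacing_um}")
        if self.rostrocaudal_axis not in (0, 1, 2):
            raise MetadataError("rostrocaudal_axis must be 0, 1 or 2")
        if self.rostral_sign not in (-1, 1):
            raise MetadataError("rostral_sign must be -1 or +1")
        self.origin_um = tuple(float(o) for o in self.origin_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size of the grid per axis."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_um))  # type: ignore[return-value]

    def midline_coordinate_um(self) -> float:
        if self.midline_um is not None:
            return self.midline_um
        a = self.midline_axis
        return self.origin_um[a] + 0.5 * self.shape[a] * self.spacing_um[a]

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        s = self.spacing_um[axis]
        return self.origin_um[axis] + (np.arange(self.shape[axis]) + 0.5) * s

    def index_to_um(self, idx: np.ndarray) -> np.ndarray:
        """Map ``(n, 3)`` voxel indices to physical center coordinates (µm)."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin_um) + (idx + 0.5) * np.asarray(self.spacing_um)

    def metadata_dict(self) -> dict:
        return {
            "spacing_um": list(self.spacing_um),
            "rostrocaudal_axis": AXIS_NAMES[self.rostrocaudal_axis],
            "rostral_sign": self.rostral_sign,
            "midline_axis": AXIS_NAMES[self.midline_axis],
            "midline_coordinate_um": self.midline_coordinate_um(),
            "origin_um": list(self.origin_um),
            "provenance": self.provenance,
        }


@dataclass
class ReferenceCuboid:
    """Axis-aligned counting region in physical coordinates.

    ``min_um``/``max_um`` are the half-open cuboid bounds per ``(z, y, x)``
    axis; ``laterality`` records the counting convention: substantia nigra
    regions are counted per side (``left``/``right``) while the other cell
    groups use a single midline-straddling cuboid (``bilateral_midline``).
    """

    name: str
    min_um: tuple[float, float, float]
    max_um: tuple[float, float, float]
    laterality: str = "bilateral_midline"

    def __post_init__(self) -> None:
        self.min_um = tuple(float(v) for v in self.min_um)
        self.max_um = tuple(float(v) for v in self.max_um)
        if len(self.min_um) != 3 or len(self.max_um) != 3:
            raise ValueError("cuboid bounds must be coordinate triples")
        if any(lo >= hi for lo, hi in zip(self.min_um, self.max_um)):
            raise ValueError(f"cuboid {self.name!r}: min must be < max on every axis")
        if self.laterality not in ("left", "right", "bilateral_midline"):
            raise ValueError(f"unknown laterality {self.laterality!r}")

    def straddles(self, axis: int, coordinate: float) -> bool:
        return self.min_um[axis] < coordinate < self.max_um[axis]

    def overlaps(self, other: "ReferenceCuboid") -> bool:
        return all(
            self.min_um[a] < other.max_um[a] and other.min_um[a] < self.max_um[a]
            for a in range(3)
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "min_um": list(self.min_um),
            "max_um": list(self.max_um),
            "laterality": self.laterality,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceCuboid":
        return cls(
            name=d["name"],
            min_um=tuple(d["min_um"]),
            max_um=tuple(d["max_um"]),
            laterality=d.get("laterality", "bilateral_midline"),
        )


def _axis_index(name) -> int:
    if isinstance(name, int):
        if name not in (0, 1, 2):
            raise MetadataError(f"axis index out of range: {name}")
        return name
    try:
        return AXIS_NAMES.index(str(name))
    except ValueError:
        raise MetadataError(f"unknown axis name {name!r}") from None


def write_volume(volume: Volume3D, path, sidecar_path=None) -> None:
    """Write a multi-page TIFF plus JSON metadata sidecar.

    16-bit unsigned is the canonical on-disk dtype; float grids are written
    as 32-bit float pages (lossless for in-memory pipelines but not the
    archival form).
    """
    path = Path(path)
    data = volume.data
    if data.dtype not in (np.uint16, np.float32):
        data = data.astype(np.float32) if np.issubdtype(data.dtype, np.floating) else data.astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar_path = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    sidecar_path.write_text(json.dumps(volume.metadata_dict(), indent=2))


def read_volume(path, sidecar_path=None) -> Volume3D:
    """Read a TIFF stack and its JSON sidecar into a :class:`Volume3D`."""
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    if not sidecar_path.exists():
        raise MetadataError(f"missing metadata sidecar {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise MetadataError(f"invalid sidecar JSON: {exc}") from exc
    if "spacing_um" not in meta:
        raise MetadataError("sidecar lacks required key 'spacing_um'")

    try:
        data = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several error types for bad stacks
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"expected a single-channel z-stack, got shape {data.shape}")

    return Volume3D(
        data=data,
        spacing_um=tuple(meta["spacing_um"]),
        rostrocaudal_axis=_axis_index(meta.get("rostrocaudal_axis", "y")),
        rostral_sign=int(meta.get("rostral_sign", -1)),
        midline_axis=_axis_index(meta.get("midline_axis", "x")),
        midline_um=meta.get("midline_coordinate_um"),
        origin_um=tuple(meta.get("origin_um", (0.0, 0.0, 0.0))),
        provenance=meta.get("provenance", ""),
    )


def write_rois(rois: list[ReferenceCuboid], path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in rois], indent=2))


def read_rois(path) -> list[ReferenceCuboid]:
    return [ReferenceCuboid.from_dict(d) for d in json.loads(Path(path).read_text())]


def roi_slices(volume: Volume3D, roi: ReferenceCuboid) -> tuple[slice, slice, slice]:
    """Index slices selecting the voxels whose centers fall inside ``roi``.

    Membership is half-open: a center c belongs iff ``min <= c < max``.
    Raises :class:`EmptyROIError` when no voxel center qualifies.
    """
    slices = []
    for a in range(3):
        s = volume.spacing_um[a]
        o = volume.origin_um[a]
        # first index with center >= min; first index with center >= max
        lo = int(np.ceil((roi.min_um[a] - o) / s - 0.5))
        hi = int(np.ceil((roi.max_um[a] - o) / s - 0.5))
        lo = max(lo, 0)
        hi = min(hi, volume.shape[a])
        if hi <= lo:
            raise EmptyROIError(f"cuboid {roi.name!r} selects no voxels on axis {AXIS_NAMES[a]}")
        slices.append(slice(lo, hi))
    return tuple(slices)  # type: ignore[return-value]


def crop(volume: Volume3D, roi: ReferenceCuboid) -> Volume3D:
    """Crop to the voxels whose centers lie inside the cuboid.

    The returned volume's ``origin_um`` is shifted so physical coordinates
    are preserved — a structure keeps its µm position across crops.
    """
    sl = roi_slices(volume, roi)
    new_origin = tuple(
        volume.origin_um[a] + sl[a].start * volume.spacing_um[a] for a in range(3)
    )
    return replace(
        volume,
        data=volume.data[sl],
        origin_um=new_origin,
        midline_um=volume.midline_coordinate_um(),
        provenance=volume.provenance + f" | crop:{roi.name}",
    )
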