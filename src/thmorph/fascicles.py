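"""Pathway-unit quantification of the mesotelencephalic fascicle tract.

The abundance index for the tract is measured in a thin coronal slab laid
orthogonally to the rostro-caudal axis at the rostral limit of the A11–13
cell groups, spanning the full width of the tract.  The slab thickness may
not exceed the diameter of a single measuring sphere.  Each connected
intersection window between the slab and an admitted TH+ fascicle spawns
one or more measuring spheres — more for massive bundles — and the sphere
total is the "pathway units" statistic.  It is an abundance index of
fascicles, not a count of individual neurites (thin single fibers are
below the detection regime by design and are additionally rejected by the
in-plane diameter rule).

A defasciculation summary (tract width from the window centroid spread,
fraction of signal in above-cut bundles) quantifies tract widening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .counting import SphereParams, greedy_pack
from .segmentation import LabeledMask
from .volume import ReferenceCuboid, Volume3D, roi_slices

__all__ = [
    "SlabSpec",
    "IntersectionWindow",
    "PathwayUnitsResult",
    "DefasciculationMetrics",
    "SlabConstraintError",
    "LocalizationError",
    "locate_rostral_limit",
    "place_slab",
    "find_intersection_windows",
    "count_pathway_units",
    "defasciculation_metrics",
    "measure_pathway_units",
]


class SlabConstraintError(ValueError):
    """Slab thickness exceeds the measuring-sphere diameter."""


class LocalizationError(ValueError):
    """Rostral limit requested from an empty mask."""


@dataclass
class SlabSpec:
    """Geometry and admission rules of the measuring slab.

    ``rostral_limit_um`` of ``None`` means the limit is located
    automatically from a segmented A11–13 mask.  ``lateral_bounds_um``
    optionally restricts the two non-rostro-caudal axes as
    ``{axis_index: (lo, hi)}``; by default the slab spans the full volume
    cross-section (over-extension beyond the tract adds no units).
    """

    thickness_um: float = 12.0
    rostral_limit_um: float | None = None
    lateral_bounds_um: dict | None = None
    sphere_params: SphereParams = field(default_factory=SphereParams)
    min_fascicle_diameter_um: float = 10.0
    min_fascicle_intensity: float | None = None

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("slab thickness must be positive")
        if self.thickness_um > self.sphere_params.sphere_diameter_um:
            raise SlabConstraintError(
                f"slab thickness {self.thickness_um} um exceeds the measuring-sphere "
                f"diameter {self.sphere_params.sphere_diameter_um} um")


@dataclass
class IntersectionWindow:
    """One connected fascicle–slab intersection component."""

    indices: np.ndarray  # (n, 3) voxel indices in the mask frame
    voxel_count: int
    mean_intensity: float
    centroid_um: np.ndarray
    inplane_diameter_um: float  # equivalent-disc diameter of the in-plane footprint


@dataclass
class DefasciculationMetrics:
    """Tract-width and bundling summary over the slab windows."""

    tract_width_um: float
    bundled_fraction: float | None  # None when no admitted voxels (undefined)

    @property
    def bundled_fraction_defined(self) -> bool:
        return self.bundled_fraction is not None


@dataclass
class PathwayUnitsResult:
    """Per-window sphere counts and their total."""

    window_units: list[int]
    total_units: int
    slab: ReferenceCuboid
    spec: SlabSpec
    defasciculation: DefasciculationMetrics | None = None


def locate_rostral_limit(a1113_mask: LabeledMask) -> float:
    """Most-rostral physical coordinate of any A11–13 mask voxel center."""
    idx = np.argwhere(a1113_mask.labels > 0)
    if len(idx) == 0:
        raise LocalizationError("cannot locate a rostral limit on an empty mask")
    frame = a1113_mask.frame
    rc = frame.rostrocaudal_axis
    coords = frame.index_to_um(idx)[:, rc]
    return float(coords.min() if frame.rostral_sign < 0 else coords.max())


def place_slab(volume: Volume3D, spec: SlabSpec,
               rostral_limit_um: float | None = None) -> ReferenceCuboid:
    """Cuboid of the given thickness extending rostrally from the limit.

    The slab starts at the rostral limit and extends ``thickness_um`` in
    the rostral direction (away from the A11–13 cell group), so somata
    never fall inside it; laterally it spans the configured bounds or the
    full volume cross-section.
    """
    if spec.thickness_um > spec.sphere_params.sphere_diameter_um:
        raise SlabConstraintError("slab thickness exceeds sphere diameter")
    limit = rostral_limit_um if rostral_limit_um is not None else spec.rostral_limit_um
    if limit is None:
        raise ValueError("no rostral limit given and none configured")
    rc = volume.rostrocaudal_axis
    lo = list(volume.origin_um)
    hi = [o + e for o, e in zip(volume.origin_um, volume.extent_um)]
    if spec.lateral_bounds_um:
        for a, (a_lo, a_hi) in spec.lateral_bounds_um.items():
            lo[int(a)], hi[int(a)] = float(a_lo), float(a_hi)
    if volume.rostral_sign > 0:
        lo[rc], hi[rc] = limit, limit + spec.thickness_um
    else:
        lo[rc], hi[rc] = limit - spec.thickness_um, limit
    return ReferenceCuboid(name="measuring_slab", min_um=tuple(lo), max_um=tuple(hi),
                           laterality="bilateral_midline")


def _inplane_equiv_diameter(indices: np.ndarray, frame: Volume3D) -> float:
    """Equivalent-disc diameter of the window footprint orthogonal to the
    rostro-caudal axis (area-based; robust to voxel aliasing of thin tubes)."""
    rc = frame.rostrocaudal_axis
    lat = [a for a in range(3) if a != rc]
    foot = {(int(i[lat[0]]), int(i[lat[1]])) for i in indices}
    area = len(foot) * frame.spacing_um[lat[0]] * frame.spacing_um[lat[1]]
    return 2.0 * np.sqrt(area / np.pi)


def find_intersection_windows(fascicle_mask: LabeledMask, slab: ReferenceCuboid,
                              spec: SlabSpec) -> list[IntersectionWindow]:
    """Connected components of the admitted mask clipped to the slab.

    The intensity admission is applied per voxel — only mask voxels at or
    above ``min_fascicle_intensity`` form windows, which strips the dim
    blur halo around each fascicle core (otherwise halos of adjacent
    fascicles merge windows and widen them artificially).  After clipping,
    26-connected windows whose in-plane footprint diameter falls below
    ``min_fascicle_diameter_um`` are dropped.  Windows are returned in
    label order (deterministic).
    """
    frame = fascicle_mask.frame
    sl = roi_slices(frame, slab)
    labels = fascicle_mask.labels[sl]
    admitted = labels > 0
    if spec.min_fascicle_intensity is not None:
        admitted &= np.asarray(frame.data[sl]) >= spec.min_fascicle_intensity

    structure = ndimage.generate_binary_structure(3, 3)
    win_labels, n = ndimage.label(admitted, structure=structure)
    offset = np.array([s.start for s in sl])
    windows = []
    for lab in range(1, n + 1):
        idx_local = np.argwhere(win_labels == lab)
        idx = idx_local + offset
        dia = _inplane_equiv_diameter(idx, frame)
        if dia < spec.min_fascicle_diameter_um:
            continue
        intens = np.asarray(frame.data)[tuple(idx.T)]
        windows.append(IntersectionWindow(
            indices=idx,
            voxel_count=len(idx),
            mean_intensity=float(np.mean(intens)),
            centroid_um=frame.index_to_um(idx).mean(axis=0),
            inplane_diameter_um=dia,
        ))
    return windows


def count_pathway_units(windows: list[IntersectionWindow], spec: SlabSpec,
                        frame: Volume3D | None = None,
                        slab: ReferenceCuboid | None = None) -> PathwayUnitsResult:
    """Greedy sphere packing per window; every nonempty window counts >= 1.

    The packing rule is the one used for perikarya, with the fit fraction
    evaluated over the sphere voxels that fall inside the slab (the slab
    is thinner than the sphere by construction, so an unclipped
    denominator could never be met and every window would degenerate to a
    single unit — whereas a massive bundle should spawn several spheres).
    If the packing accepts no sphere in a nonempty window, the window
    still contributes exactly one unit: a thin fascicle is one pathway
    unit.
    """
    if frame is not None and slab is not None:
        sl = roi_slices(frame, slab)
        lo_block = np.array([s.start for s in sl])
        block_shape = tuple(s.stop - s.start for s in sl)
        spacing = frame.spacing_um
    else:
        lo_block = block_shape = None
        spacing = frame.spacing_um if frame is not None else (1.0, 1.0, 1.0)

    units = []
    for w in windows:
        if w.voxel_count == 0:
            units.append(0)
            continue
        if lo_block is None:
            lo = w.indices.min(axis=0)
            shape = tuple(w.indices.max(axis=0) + 1 - lo)
        else:
            lo, shape = lo_block, block_shape
        block = np.zeros(shape, dtype=bool)
        local = w.indices - lo
        block[tuple(local.T)] = True
        if frame is not None:
            hi = lo + np.asarray(shape)
            sub = np.asarray(frame.data)[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        else:
            sub = block.astype(float)
        centers = greedy_pack(block, sub, spacing, spec.sphere_params,
                              clip_denominator=True)
        units.append(max(len(centers), 1))
    slab_cuboid = slab if slab is not None else ReferenceCuboid(
        "measuring_slab", (0.0, 0.0, 0.0), (1.0, 1.0, 1.0))
    return PathwayUnitsResult(window_units=units, total_units=int(sum(units)),
                              slab=slab_cuboid, spec=spec)


def defasciculation_metrics(windows: list[IntersectionWindow],
                            slab: ReferenceCuboid,
                            admitted_voxels_in_slab: int | None = None,
                            mediolateral_axis: int = 2) -> DefasciculationMetrics:
    """Tract width and bundled fraction over the slab.

    Width is the robust (5th–95th percentile) range of window centroids
    along the mediolateral axis; the bundled fraction is the share of
    admitted TH+ voxels in the slab that belong to the retained
    (above-diameter-cut) windows.  With no windows the width is 0 and the
    bundled fraction undefined (``None``) unless an admitted-voxel total
    of 0 makes it undefined anyway.
    """
    if not windows:
        return DefasciculationMetrics(tract_width_um=0.0, bundled_fraction=None)
    pos = np.array([w.centroid_um[mediolateral_axis] for w in windows])
    width = float(np.percentile(pos, 95) - np.percentile(pos, 5))
    kept = sum(w.voxel_count for w in windows)
    total = admitted_voxels_in_slab if admitted_voxels_in_slab is not None else kept
    frac = kept / total if total > 0 else None
    return DefasciculationMetrics(tract_width_um=width, bundled_fraction=frac)


def measure_pathway_units(fascicle_mask: LabeledMask, spec: SlabSpec,
                          a1113_mask: LabeledMask | None = None) -> PathwayUnitsResult:
    """End-to-end slab measurement on a segmented volume.

    Locates the rostral limit (from the A11–13 mask unless the spec fixes
    a coordinate), places the slab, finds intersection windows, packs
    spheres and computes the defasciculation summary.
    """
    frame = fascicle_mask.frame
    limit = spec.rostral_limit_um
    if limit is None:
        if a1113_mask is None:
            raise ValueError("need an A11-13 mask or an explicit rostral limit")
        limit = locate_rostral_limit(a1113_mask)
    slab = place_slab(frame, spec, rostral_limit_um=limit)
    windows = find_intersection_windows(fascicle_mask, slab, spec)
    result = count_pathway_units(windows, spec, frame=frame, slab=slab)
    sl = roi_slices(frame, slab)
    labels = fascicle_mask.labels[sl]
    admitted = labels > 0
    if spec.min_fascicle_intensity is not None:
        admitted &= np.asarray(frame.data[sl]) >= spec.min_fascicle_intensity
    ml_axis = [a for a in range(3) if a != frame.rostrocaudal_axis]
    ml = frame.midline_axis if frame.midline_axis != frame.rostrocaudal_axis else ml_axis[-1]
    result.defasciculation = defasciculation_metrics(
        windows, slab, admitted_voxels_in_slab=int(admitted.sum()), mediolateral_axis=ml)
    return result
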