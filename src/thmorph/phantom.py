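"""Synthetic light-sheet phantoms of TH-immunostained whole-mount brains.

Real cleared-brain stacks of this kind are rarely shareable, so every
downstream stage of the pipeline is validated on phantoms: volumes that
emulate the structural classes the morphometry quantifies — nucleus-shaped
clusters of bright spherical somata (substantia nigra left/right, VTA,
A11–13, optionally the periventricular A12/A14 group), a rostro-caudally
running tract of bright tubular fascicles with dispersed thin fibers,
occasional long vessel-like tubes traversing the nuclei, anisotropic
optical blur, and background plus shot/read noise — while recording the
exact ground truth (every soma center, fascicle centerline, vessel
segment) keyed to a seed.

Geometry is specified in physical micrometres; the default sampling
follows the imaging protocol the pipeline targets: 7 µm z-step between
horizontal-section planes and 5 µm in-plane spacing, with the
rostro-caudal axis mapped to the array y-axis (rostral at the low index).

Determinism contract: ``generate_phantom(spec)`` called twice with the
same spec (including its seed) returns bit-identical volumes and ground
truth.  Each structure class draws from its own child of the master seed
sequence, so e.g. removing vessels from a spec does not reshuffle the
soma placement stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import Volume3D

__all__ = [
    "NucleusSpec",
    "TractSpec",
    "VesselSpec",
    "OpticsSpec",
    "NoiseSpec",
    "PhantomSpec",
    "GroundTruth",
    "PlacementError",
    "generate_phantom",
    "rasterize_tube",
    "apply_optics_and_noise",
    "default_study_spec",
    "recovery_study_spec",
    "rois_for_spec",
]

MAX_PLACEMENT_ATTEMPTS = 10_000  # rejection-sampling cap per nucleus


class PlacementError(RuntimeError):
    """Soma placement infeasible within the rejection-sampling budget."""


@dataclass
class NucleusSpec:
    """Ellipsoidal envelope filled with bright spherical somata."""

    name: str
    center_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    n_somata: int
    soma_diameter_um: float = 12.0
    soma_diameter_jitter_um: float = 1.0
    soma_intensity: float = 200.0
    soma_intensity_jitter: float = 20.0
    min_separation_um: float = 14.0

    def __post_init__(self) -> None:
        if self.n_somata < 0:
            raise ValueError("n_somata must be >= 0")
        if any(a <= 0 for a in self.semi_axes_um):
            raise ValueError("semi-axes must be positive")


@dataclass
class TractSpec:
    """A bundle of fascicle centerlines running rostro-caudally.

    Centerlines are monotone in the rostro-caudal coordinate by
    construction, so each crosses every interior coronal plane exactly
    once.  ``spread_um`` controls the mediolateral scatter of the
    centerlines; increasing it emulates defasciculation (the tract widens
    while the fascicle count stays fixed).  When
    ``min_fascicle_separation_um`` is set, base offsets are laid on evenly
    spaced lanes and the pointwise wobble is bounded so fascicle surfaces
    stay pairwise disjoint — the regime used for exactness checks.
    """

    n_fascicles: int = 12
    fascicle_diameter_um: tuple[float, float] = (10.0, 14.0)
    n_dispersed_fibers: int = 40
    fiber_diameter_um: float = 4.0
    fiber_length_um: float = 90.0
    rc_caudal_um: float = 440.0
    rc_rostral_um: float = 40.0
    center_um: tuple[float, float, float] = (60.0, 0.0, 180.0)  # RC component ignored
    spread_um: float = 25.0
    min_fascicle_separation_um: float | None = 12.0
    fascicle_intensity: float = 170.0
    fiber_intensity: float = 90.0
    n_control_points: int = 9
    centerlines_um: list | None = None  # explicit override, list of (k,3) point lists

    def __post_init__(self) -> None:
        if self.n_fascicles < 0 or self.n_dispersed_fibers < 0:
            raise ValueError("structure counts must be >= 0")


@dataclass
class VesselSpec:
    """Long straight bright tubes that may traverse nucleus envelopes.

    The length/diameter ratio is kept >= 5 so that the elongation-based
    artifact filter is well-posed on ground truth.  ``soma_clearance_um``
    is the margin kept between vessel surfaces and soma surfaces during
    placement, chosen so the two shape regimes stay separable after
    optical blur (halos must not bridge).  With ``render=False`` the
    vessels are placed (and constrain soma placement identically) but not
    painted into the volume — the matched vessel-free counterfactual of
    the same phantom.
    """

    n_vessels: int = 0
    diameter_um: float = 10.0
    length_um: float = 220.0
    intensity: float = 180.0
    soma_clearance_um: float = 10.0
    render: bool = True

    def __post_init__(self) -> None:
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be >= 0")
        if self.n_vessels > 0 and self.length_um < 5 * self.diameter_um:
            raise ValueError("vessel length must be >= 5 x diameter")


@dataclass
class OpticsSpec:
    """Anisotropic Gaussian blur, sigma per (z, y, x) axis in µm."""

    blur_sigma_um: tuple[float, float, float] = (3.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.blur_sigma_um):
            raise ValueError("blur sigmas must be >= 0")


@dataclass
class NoiseSpec:
    """Background autofluorescence plus shot/read noise.

    ``poisson_scale`` is photons per intensity unit (0 disables shot
    noise); ``gaussian_sd`` is the additive read-noise sd.
    """

    background: float = 20.0
    gaussian_sd: float = 4.0
    poisson_scale: float = 0.5


@dataclass
class PhantomSpec:
    """Full description of one phantom: geometry, optics, noise, seed."""

    volume_shape_voxels: tuple[int, int, int] = (44, 96, 72)
    voxel_spacing_um: tuple[float, float, float] = (7.0, 5.0, 5.0)
    rostrocaudal_axis: int = 1
    rostral_sign: int = -1
    nuclei: list[NucleusSpec] = field(default_factory=list)
    tract: TractSpec | None = None
    vessels: VesselSpec = field(default_factory=VesselSpec)
    optics: OpticsSpec = field(default_factory=OpticsSpec)
    noise: NoiseSpec | None = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing_um):
            raise ValueError("voxel spacing must be positive")
        if self.rostrocaudal_axis not in (0, 1, 2):
            raise ValueError("rostrocaudal_axis must be one of 0 (z), 1 (y), 2 (x)")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.volume_shape_voxels, self.voxel_spacing_um))

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["nuclei"] = [NucleusSpec(**n) if not isinstance(n, NucleusSpec) else n
                       for n in d.get("nuclei", [])]
        for key, typ in (("tract", TractSpec), ("vessels", VesselSpec),
                         ("optics", OpticsSpec), ("noise", NoiseSpec)):
            v = d.get(key)
            if isinstance(v, dict):
                d[key] = typ(**v)
        for key in ("volume_shape_voxels", "voxel_spacing_um"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Generator record of every structure, keyed to the master seed."""

    seed: int
    somata: dict  # nucleus name -> {"centers_um": [[z,y,x],...], "diameters_um": [...]}
    fascicles: list  # [{"centerline_um": [[z,y,x],...], "diameter_um": d}, ...]
    fibers: list
    vessels: list  # [{"p0_um": .., "p1_um": .., "diameter_um": d}, ...]
    a1113_envelope_rostral_um: float | None = None
    a1113_mask_rostral_um: float | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GroundTruth":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# rasterization


def _paint_tube(data: np.ndarray, spacing: np.ndarray, pts: np.ndarray,
                radius_um: float, intensity: float) -> None:
    """Set voxels within ``radius_um`` of the polyline to >= intensity (in place).

    Distances are physical (µm, voxel centers at ``(i + 0.5) * spacing``).
    A zero-length polyline paints a ball.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    segments = [(pts[0], pts[0])] if len(pts) == 1 else list(zip(pts[:-1], pts[1:]))
    shape = np.array(data.shape)
    for p0, p1 in segments:
        lo_um = np.minimum(p0, p1) - radius_um
        hi_um = np.maximum(p0, p1) + radius_um
        lo = np.maximum(np.floor(lo_um / spacing - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil(hi_um / spacing - 0.5).astype(int) + 1, shape)
        if np.any(hi <= lo):
            continue
        zz, yy, xx = np.meshgrid(
            *[(np.arange(lo[a], hi[a]) + 0.5) * spacing[a] for a in range(3)],
            indexing="ij",
        )
        centers = np.stack([zz, yy, xx], axis=-1)
        d = p1 - p0
        seg_len2 = float(d @ d)
        if seg_len2 == 0.0:
            dist = np.linalg.norm(centers - p0, axis=-1)
        else:
            t = np.clip(((centers - p0) @ d) / seg_len2, 0.0, 1.0)
            nearest = p0 + t[..., None] * d
            dist = np.linalg.norm(centers - nearest, axis=-1)
        inside = dist <= radius_um
        block = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        block[inside] = np.maximum(block[inside], intensity)


def rasterize_tube(centerline, diameter_um: float, volume: Volume3D,
                   intensity: float) -> Volume3D:
    """Paint a tube of the given physical diameter along a polyline.

    Every voxel whose center lies within ``diameter_um / 2`` of the
    polyline is raised to at least ``intensity``; the input volume is not
    modified.  The diameter must exceed the largest voxel spacing so the
    tube cannot alias away between sample planes.
    """
    if diameter_um <= max(volume.spacing_um):
        raise ValueError(
            f"tube diameter {diameter_um} um must exceed the largest voxel "
            f"spacing {max(volume.spacing_um)} um"
        )
    pts = np.atleast_2d(np.asarray(centerline, dtype=float)) - np.asarray(volume.origin_um)
    data = np.array(volume.data, dtype=np.float32, copy=True)
    _paint_tube(data, np.asarray(volume.spacing_um), pts, diameter_um / 2.0, intensity)
    out = Volume3D(
        data=data,
        spacing_um=volume.spacing_um,
        rostrocaudal_axis=volume.rostrocaudal_axis,
        rostral_sign=volume.rostral_sign,
        midline_axis=volume.midline_axis,
        midline_um=volume.midline_um,
        origin_um=volume.origin_um,
        provenance=volume.provenance,
    )
    return out


# ---------------------------------------------------------------------------
# structure placement


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    d = b - a
    l2 = float(d @ d)
    if l2 == 0.0:
        return float(np.linalg.norm(p - a))
    t = np.clip(float((p - a) @ d) / l2, 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * d)))


def _place_somata(nuc: NucleusSpec, vessels: list, clearance_um: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rejection-sample soma centers in the (radius-shrunk) ellipsoid.

    Enforces pairwise center separation and a clearance margin from every
    vessel surface.  Raises :class:`PlacementError` after the per-nucleus
    attempt budget.
    """
    r = nuc.soma_diameter_um / 2.0
    semi = np.maximum(np.asarray(nuc.semi_axes_um, dtype=float) - r, 1e-6)
    center = np.asarray(nuc.center_um, dtype=float)
    placed: list[np.ndarray] = []
    attempts = 0
    min_sep = nuc.min_separation_um
    while len(placed) < nuc.n_somata:
        if attempts >= MAX_PLACEMENT_ATTEMPTS:
            raise PlacementError(
                f"nucleus {nuc.name!r}: placed {len(placed)}/{nuc.n_somata} somata "
                f"in {attempts} attempts (envelope too crowded)"
            )
        attempts += 1
        # uniform point in the unit ball, scaled to the shrunk ellipsoid
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        p = center + semi * u * rng.uniform() ** (1.0 / 3.0)
        if any(np.linalg.norm(p - q) < min_sep for q in placed):
            continue
        ok = True
        for v in vessels:
            gap = v["diameter_um"] / 2.0 + r + clearance_um
            if _point_segment_distance(p, np.asarray(v["p0_um"]), np.asarray(v["p1_um"])) < gap:
                ok = False
                break
        if ok:
            placed.append(p)
    centers = np.array(placed) if placed else np.zeros((0, 3))
    diameters = nuc.soma_diameter_um + rng.uniform(-1, 1, len(placed)) * nuc.soma_diameter_jitter_um
    intensities = nuc.soma_intensity + rng.uniform(-1, 1, len(placed)) * nuc.soma_intensity_jitter
    return centers, diameters, intensities


def _lateral_axes(rc_axis: int) -> tuple[int, int]:
    """(mediolateral-like, other) axes given the rostro-caudal axis."""
    others = [a for a in range(3) if a != rc_axis]
    # by convention x (axis 2) is mediolateral when available
    others.sort(key=lambda a: -a)
    return others[0], others[1]


def _build_centerlines(tract: TractSpec, rc_axis: int, extent_um, rng) -> list[np.ndarray]:
    if tract.centerlines_um is not None:
        return [np.asarray(c, dtype=float) for c in tract.centerlines_um]
    ml_axis, other_axis = _lateral_axes(rc_axis)
    k = tract.n_control_points
    rc = np.linspace(tract.rc_caudal_um, tract.rc_rostral_um, k)
    n = tract.n_fascicles
    center = np.asarray(tract.center_um, dtype=float)
    d_max = tract.fascicle_diameter_um[1]
    lines = []
    if tract.min_fascicle_separation_um is not None and n > 0:
        lane = tract.min_fascicle_separation_um + d_max
        offsets = (np.arange(n) - (n - 1) / 2.0) * lane
        wobble_amp = tract.min_fascicle_separation_um / 4.0
    else:
        offsets = rng.normal(0.0, tract.spread_um, n)
        wobble_amp = tract.spread_um / 3.0
    for i in range(n):
        pts = np.zeros((k, 3))
        pts[:, rc_axis] = rc
        phase = rng.uniform(0, 2 * np.pi, 2)
        freq = rng.uniform(0.5, 1.5, 2)
        t = np.linspace(0, 2 * np.pi, k)
        pts[:, ml_axis] = center[ml_axis] + offsets[i] + wobble_amp * np.sin(freq[0] * t + phase[0])
        pts[:, other_axis] = center[other_axis] + wobble_amp * np.sin(freq[1] * t + phase[1])
        margin = d_max / 2.0 + 5.0
        for a in (ml_axis, other_axis):
            pts[:, a] = np.clip(pts[:, a], margin, extent_um[a] - margin)
        lines.append(pts)
    return lines


def _build_fibers(tract: TractSpec, rc_axis: int, extent_um, rng) -> list[dict]:
    ml_axis, other_axis = _lateral_axes(rc_axis)
    center = np.asarray(tract.center_um, dtype=float)
    rc_lo, rc_hi = sorted((tract.rc_caudal_um, tract.rc_rostral_um))
    fibers = []
    for _ in range(tract.n_dispersed_fibers):
        p = np.zeros(3)
        p[rc_axis] = rng.uniform(rc_lo, rc_hi)
        p[ml_axis] = center[ml_axis] + rng.normal(0, 2.0 * tract.spread_um)
        p[other_axis] = center[other_axis] + rng.normal(0, 15.0)
        direction = np.zeros(3)
        direction[rc_axis] = 1.0
        direction += rng.normal(0, 0.3, 3)
        direction /= np.linalg.norm(direction)
        half = direction * tract.fiber_length_um / 2.0
        p0, p1 = p - half, p + half
        margin = tract.fiber_diameter_um / 2.0 + 2.0
        p0 = np.clip(p0, margin, np.asarray(extent_um) - margin)
        p1 = np.clip(p1, margin, np.asarray(extent_um) - margin)
        fibers.append({"p0_um": p0.tolist(), "p1_um": p1.tolist(),
                       "diameter_um": tract.fiber_diameter_um})
    return fibers


def _build_vessels(spec: PhantomSpec, rng) -> list[dict]:
    v = spec.vessels
    if v.n_vessels == 0:
        return []
    extent = np.asarray(spec.extent_um)
    vessels = []
    nuclei = spec.nuclei or [None]
    for i in range(v.n_vessels):
        target = nuclei[i % len(nuclei)]
        anchor = (np.asarray(target.center_um, dtype=float) + rng.normal(0, 10.0, 3)
                  if target is not None else extent * rng.uniform(0.3, 0.7, 3))
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        half = direction * v.length_um / 2.0
        margin = v.diameter_um / 2.0 + 2.0
        p0 = np.clip(anchor - half, margin, extent - margin)
        p1 = np.clip(anchor + half, margin, extent - margin)
        vessels.append({"p0_um": p0.tolist(), "p1_um": p1.tolist(),
                        "diameter_um": v.diameter_um})
    return vessels


# ---------------------------------------------------------------------------
# optics and noise


def apply_optics_and_noise(volume: Volume3D, spec: PhantomSpec) -> Volume3D:
    """Blur with the physical-unit PSF model, then add background and noise.

    Blur sigmas are given in µm and divided by the per-axis spacing, so
    the point-spread anisotropy is expressed in physical space regardless
    of sampling.  Noise (background offset, optional Poisson shot noise,
    additive Gaussian read noise) is drawn from a child of the spec seed,
    so repeated calls are bit-identical.
    """
    data = np.asarray(volume.data, dtype=np.float32)
    sigma_vox = [s / sp for s, sp in zip(spec.optics.blur_sigma_um, volume.spacing_um)]
    if any(s > 0 for s in sigma_vox):
        data = ndimage.gaussian_filter(data, sigma=sigma_vox, mode="constant")
    if spec.noise is not None:
        data = data + spec.noise.background
        if spec.noise.poisson_scale > 0:
            # Gaussian approximation to photon shot noise (valid for the
            # >= 10-photon regime of these phantoms): sd = sqrt(signal/scale).
            # The per-voxel noise field is drawn independently of the signal,
            # so a local change to one structure perturbs only local voxels.
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
            shot = rng.standard_normal(data.shape).astype(np.float32)
            data = data + np.sqrt(np.maximum(data, 0) / spec.noise.poisson_scale) * shot
        if spec.noise.gaussian_sd > 0:
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 8]))
            read = rng.standard_normal(data.shape).astype(np.float32)
            data = data + spec.noise.gaussian_sd * read
        data = np.maximum(data, 0.0)
    return Volume3D(
        data=data.astype(np.float32),
        spacing_um=volume.spacing_um,
        rostrocaudal_axis=volume.rostrocaudal_axis,
        rostral_sign=volume.rostral_sign,
        midline_axis=volume.midline_axis,
        midline_um=volume.midline_um,
        origin_um=volume.origin_um,
        provenance=volume.provenance + " | optics+noise",
    )


# ---------------------------------------------------------------------------
# top-level generation


def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, GroundTruth]:
    """Render a phantom volume and its ground-truth record.

    Stages: vessels are laid first; somata are rejection-sampled inside
    their (radius-shrunk) envelopes with pairwise separation and vessel
    clearance; fascicle centerlines and dispersed fibers are built; all
    structures are painted at their intensities; finally the optical blur
    and noise model is applied.
    """
    ss = np.random.SeedSequence([spec.seed, 1])
    rng_vessels, rng_tract, rng_fibers = (np.random.default_rng(c)
                                          for c in ss.spawn(3))
    vessels = _build_vessels(spec, rng_vessels)

    somata: dict[str, dict] = {}
    nucleus_rngs = np.random.SeedSequence([spec.seed, 2]).spawn(max(len(spec.nuclei), 1))
    for nuc, child in zip(spec.nuclei, nucleus_rngs):
        centers, diameters, intensities = _place_somata(
            nuc, vessels, spec.vessels.soma_clearance_um, np.random.default_rng(child))
        somata[nuc.name] = {
            "centers_um": centers.tolist(),
            "diameters_um": diameters.tolist(),
            "intensities": intensities.tolist(),
        }

    fascicles: list[dict] = []
    fibers: list[dict] = []
    if spec.tract is not None:
        lines = _build_centerlines(spec.tract, spec.rostrocaudal_axis, spec.extent_um, rng_tract)
        d_lo, d_hi = spec.tract.fascicle_diameter_um
        for line in lines:
            fascicles.append({
                "centerline_um": line.tolist(),
                "diameter_um": float(rng_tract.uniform(d_lo, d_hi)),
            })
        fibers = _build_fibers(spec.tract, spec.rostrocaudal_axis, spec.extent_um, rng_fibers)

    data = np.zeros(spec.volume_shape_voxels, dtype=np.float32)
    spacing = np.asarray(spec.voxel_spacing_um)
    for nuc in spec.nuclei:
        rec = somata[nuc.name]
        for c, d, inten in zip(rec["centers_um"], rec["diameters_um"], rec["intensities"]):
            _paint_tube(data, spacing, np.asarray([c]), d / 2.0, inten)
    if spec.tract is not None:
        for f in fascicles:
            _paint_tube(data, spacing, np.asarray(f["centerline_um"]),
                        f["diameter_um"] / 2.0, spec.tract.fascicle_intensity)
        for f in fibers:
            _paint_tube(data, spacing, np.asarray([f["p0_um"], f["p1_um"]]),
                        f["diameter_um"] / 2.0, spec.tract.fiber_intensity)
    if spec.vessels.render:
        for v in vessels:
            _paint_tube(data, spacing, np.asarray([v["p0_um"], v["p1_um"]]),
                        v["diameter_um"] / 2.0, spec.vessels.intensity)

    volume = Volume3D(
        data=data,
        spacing_um=spec.voxel_spacing_um,
        rostrocaudal_axis=spec.rostrocaudal_axis,
        rostral_sign=spec.rostral_sign,
        provenance=f"phantom seed={spec.seed}",
    )
    volume = apply_optics_and_noise(volume, spec)

    rc = spec.rostrocaudal_axis
    env_rostral = mask_rostral = None
    a1113 = next((n for n in spec.nuclei if n.name.upper().startswith("A11")), None)
    if a1113 is not None:
        rec = somata[a1113.name]
        if spec.rostral_sign < 0:
            env_rostral = a1113.center_um[rc] - a1113.semi_axes_um[rc]
            if rec["centers_um"]:
                mask_rostral = min(c[rc] - d / 2.0 for c, d in
                                   zip(rec["centers_um"], rec["diameters_um"]))
        else:
            env_rostral = a1113.center_um[rc] + a1113.semi_axes_um[rc]
            if rec["centers_um"]:
                mask_rostral = max(c[rc] + d / 2.0 for c, d in
                                   zip(rec["centers_um"], rec["diameters_um"]))

    truth = GroundTruth(
        seed=spec.seed,
        somata=somata,
        fascicles=fascicles,
        fibers=fibers,
        vessels=vessels,
        a1113_envelope_rostral_um=env_rostral,
        a1113_mask_rostral_um=mask_rostral,
    )
    return volume, truth


# ---------------------------------------------------------------------------
# the standard study phantom

# Control-condition structure abundances for the simulated group studies:
# substantia nigra 32 somata per side, VTA 40, A11-13 42, 12 tract fascicles.
STUDY_N_SOMATA = {"SN_left": 32, "SN_right": 32, "VTA": 40, "A11_13": 42}
STUDY_N_FASCICLES = 12


def default_study_spec(seed: int = 0, *, n_somata: dict[str, int] | None = None,
                       n_fascicles: int | None = None, n_vessels: int = 0,
                       include_a1214: bool = False) -> PhantomSpec:
    """The standard phantom layout used by the simulated group studies.

    A 44x96x72-voxel volume at (7, 5, 5) µm spacing (308 x 480 x 360 µm),
    rostral at low y.  Substantia nigra envelopes sit left and right of
    the midline (x = 180 µm) in the caudal half, the VTA straddles the
    midline between them, and the A11-13 envelope lies rostral to both;
    the fascicle tract runs ventrally (low z) past the A11-13 group along
    the full rostro-caudal extent.  ``n_somata``/``n_fascicles`` override
    the control-condition abundances (used to inject group effects).
    """
    n = dict(STUDY_N_SOMATA)
    if include_a1214:
        n["A12_14"] = 40
    if n_somata:
        n.update(n_somata)
    nuclei = [
        NucleusSpec("SN_left", center_um=(160.0, 370.0, 90.0),
                    semi_axes_um=(42.0, 58.0, 40.0), n_somata=n["SN_left"]),
        NucleusSpec("SN_right", center_um=(160.0, 370.0, 270.0),
                    semi_axes_um=(42.0, 58.0, 40.0), n_somata=n["SN_right"]),
        NucleusSpec("VTA", center_um=(160.0, 370.0, 180.0),
                    semi_axes_um=(45.0, 55.0, 36.0), n_somata=n["VTA"]),
        NucleusSpec("A11_13", center_um=(170.0, 205.0, 180.0),
                    semi_axes_um=(45.0, 50.0, 55.0), n_somata=n["A11_13"]),
    ]
    if include_a1214:
        nuclei.append(NucleusSpec("A12_14", center_um=(265.0, 240.0, 180.0),
                                  semi_axes_um=(32.0, 48.0, 52.0), n_somata=n["A12_14"]))
    tract = TractSpec(
        n_fascicles=STUDY_N_FASCICLES if n_fascicles is None else n_fascicles,
        center_um=(60.0, 0.0, 180.0),
    )
    return PhantomSpec(
        nuclei=nuclei,
        tract=tract,
        vessels=VesselSpec(n_vessels=n_vessels),
        seed=seed,
    )


def recovery_study_spec(seed: int, n_somata: dict[str, int],
                        n_vessels: int = 0, render_vessels: bool = True,
                        noise: bool = True) -> PhantomSpec:
    """Four-nucleus phantom sized for soma-count recovery experiments.

    Uses slightly larger envelopes than the standard study layout so that
    up to 60 somata per nucleus can be placed even when vessel clearance
    corridors cut through the envelopes (random sequential placement jams
    near 38% volume fill).  ``render_vessels=False`` gives the matched
    vessel-free counterfactual with an identical soma layout.
    """
    nuclei = [
        NucleusSpec("SN_left", (160.0, 370.0, 86.0), (46.0, 62.0, 44.0),
                    n_somata["SN_left"]),
        NucleusSpec("SN_right", (160.0, 370.0, 274.0), (46.0, 62.0, 44.0),
                    n_somata["SN_right"]),
        NucleusSpec("VTA", (160.0, 370.0, 180.0), (50.0, 62.0, 40.0),
                    n_somata["VTA"]),
        NucleusSpec("A11_13", (170.0, 205.0, 180.0), (45.0, 56.0, 58.0),
                    n_somata["A11_13"]),
    ]
    return PhantomSpec(nuclei=nuclei, tract=None,
                       vessels=VesselSpec(n_vessels=n_vessels, render=render_vessels),
                       noise=NoiseSpec() if noise else None, seed=seed)


def rois_for_spec(spec: PhantomSpec, pad_um: float = 12.0):
    """Reference cuboids enclosing each nucleus envelope of a phantom spec.

    Substantia nigra envelopes get per-side cuboids; all other nuclei get
    midline-straddling bilateral cuboids, mirroring the counting
    conventions of the morphometry.
    """
    from .volume import ReferenceCuboid

    rois = []
    extent = spec.extent_um
    for nuc in spec.nuclei:
        lo = tuple(max(c - s - pad_um, 0.0)
                   for c, s in zip(nuc.center_um, nuc.semi_axes_um))
        hi = tuple(min(c + s + pad_um, e)
                   for c, s, e in zip(nuc.center_um, nuc.semi_axes_um, extent))
        if nuc.name.endswith("_left"):
            lat = "left"
        elif nuc.name.endswith("_right"):
            lat = "right"
        else:
            lat = "bilateral_midline"
        rois.append(ReferenceCuboid(name=nuc.name, min_um=lo, max_um=hi, laterality=lat))
    return rois
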