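"""Shared fixtures and independent oracles.

The oracles here deliberately re-implement the package's geometric
operations with plain Python loops and sets (flood-fill labeling,
exhaustive greedy sphere packing, principal-extent computation), so that
tests compare two independent code paths.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from thmorph.phantom import PhantomSpec, NucleusSpec, VesselSpec, NoiseSpec
from thmorph.volume import Volume3D

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# oracle: flood-fill connected-component labeling

_NEIGHBORS = {
    6: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if abs(dz) + abs(dy) + abs(dx) == 1],
    18: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
         if 0 < abs(dz) + abs(dy) + abs(dx) <= 2],
    26: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
         if (dz, dy, dx) != (0, 0, 0)],
}


def flood_fill_components(binary: np.ndarray, connectivity: int = 26) -> list[set]:
    """BFS connected components of a boolean grid; list of voxel-index sets."""
    binary = np.asarray(binary, dtype=bool)
    remaining = {tuple(v) for v in np.argwhere(binary)}
    comps = []
    while remaining:
        seed = min(remaining)
        queue = [seed]
        remaining.discard(seed)
        comp = {seed}
        while queue:
            z, y, x = queue.pop()
            for dz, dy, dx in _NEIGHBORS[connectivity]:
                nb = (z + dz, y + dy, x + dx)
                if nb in remaining:
                    remaining.discard(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# oracle: exhaustive greedy sphere packing

def brute_force_pack(mask: np.ndarray, intensity: np.ndarray, spacing,
                     diameter_um: float, fit_fraction: float,
                     clip_denominator: bool = True) -> list[tuple]:
    """Reference greedy packing: re-scan every candidate each iteration.

    Same rule as the production packer — candidates are mask voxels,
    visited by descending intensity with (z, y, x) tie-break; a sphere is
    accepted iff >= fit_fraction of its voxels lie on uncovered mask and
    its center is >= diameter from every accepted center; accepted sphere
    voxels on the mask become covered; a rejected candidate is never
    revisited — but implemented with per-iteration exhaustive re-sorting
    over plain Python sets.
    """
    spacing = np.asarray(spacing, dtype=float)
    r = diameter_um / 2.0
    offs = []
    ranges = [range(-int(np.floor(r / s)), int(np.floor(r / s)) + 1) for s in spacing]
    for dz in ranges[0]:
        for dy in ranges[1]:
            for dx in ranges[2]:
                if np.linalg.norm(np.array([dz, dy, dx]) * spacing) <= r:
                    offs.append((dz, dy, dx))
    shape = mask.shape
    mask_set = {tuple(v) for v in np.argwhere(mask)}
    covered: set = set()
    rejected: set = set()
    accepted: list[tuple] = []

    def key(v):
        return (-float(intensity[v]), v)

    while True:
        candidates = [v for v in mask_set if v not in covered and v not in rejected]
        if not candidates:
            break
        c = min(candidates, key=key)
        ball = [(c[0] + o[0], c[1] + o[1], c[2] + o[2]) for o in offs]
        inside = [v for v in ball
                  if 0 <= v[0] < shape[0] and 0 <= v[1] < shape[1] and 0 <= v[2] < shape[2]]
        hits = [v for v in inside if v in mask_set and v not in covered]
        # the packer's denominator is the sphere clipped to the imaged frame;
        # for these single-block fixtures the block IS the frame
        denom = len(inside) if clip_denominator else len(ball)
        c_um = (np.array(c) + 0.5) * spacing
        ok = denom > 0 and len(hits) / denom >= fit_fraction
        if ok and all(np.linalg.norm(c_um - np.array(a)) >= diameter_um
                      for a in accepted):
            accepted.append(tuple(c_um))
            covered.update(hits)
            covered.add(c)
        else:
            rejected.add(c)
    return accepted


# ---------------------------------------------------------------------------
# oracle: principal extents from second moments, straight from coordinates

def principal_extents(coords_um: np.ndarray, spacing) -> list[float]:
    coords = np.asarray(coords_um, dtype=float)
    centered = coords - coords.mean(axis=0)
    spacing = np.asarray(spacing, dtype=float)
    if len(coords) > 1:
        cov = centered.T @ centered / len(coords)
        _, vecs = np.linalg.eigh(cov)
        vecs = vecs.T[::-1]
    else:
        vecs = np.eye(3)
    out = []
    for v in vecs:
        proj = centered @ v
        out.append(float(proj.max() - proj.min()) + float(np.abs(v) @ spacing))
    return sorted(out, reverse=True)


# ---------------------------------------------------------------------------
# phantom builders

def unit_volume(data, **kw) -> Volume3D:
    return Volume3D(data=np.asarray(data, dtype=np.float32),
                    spacing_um=kw.pop("spacing_um", (1.0, 1.0, 1.0)), **kw)


def recovery_spec(seed: int, n: dict, n_vessels: int = 0, render: bool = True,
                  noise: bool = True) -> PhantomSpec:
    """Four-nucleus phantom with capacity for up to 60 somata per nucleus."""
    from thmorph.phantom import recovery_study_spec

    return recovery_study_spec(seed, n, n_vessels=n_vessels,
                               render_vessels=render, noise=noise)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
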