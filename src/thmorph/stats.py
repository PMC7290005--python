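"""Group-difference statistics and the simulated replication study.

Group effects on counts and pathway units are summarized as signed percent
changes on the control scale with a batch-stratified permutation test:
group labels are permuted only within preparation-day batches, which
absorbs day-to-day staining/imaging offsets the same way a day random
effect would, while making no distributional assumptions.  When the number
of admissible stratified label assignments is small the test enumerates
them exhaustively (exact p); otherwise it samples with the add-one
correction ``p = (1 + hits) / (1 + n_permutations)``.

The replication study generates phantom cohorts whose structure abundances
are scaled by injected treated/control ratios, pushes every phantom through
the full pipeline (background subtraction, segmentation, vessel exclusion,
sphere counting, slab measurement), and reports estimated against injected
percent changes — a parameter-recovery check of the whole morphometry.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation as ndi_binary_dilation

from . import fascicles as fq
from . import phantom as ph
from . import segmentation as seg
from .counting import SphereParams, count_perikarya
from .volume import crop

__all__ = [
    "AnimalRecord",
    "GroupComparison",
    "PipelineConfig",
    "percent_change",
    "permutation_test",
    "measure_phantom",
    "run_replication_study",
    "simulate_null_pvalues",
    "FIG_EFFECT_RATIOS",
]

# Injected treated/control ratios replicating the reported whole-mount
# effect structure: fascicle units -73.3%, SN +83.1%, VTA -43.0%,
# A11-13 -38.3%.
FIG_EFFECT_RATIOS = {
    "pathway_units": 0.267,
    "SN": 1.831,
    "VTA": 0.570,
    "A11_13": 0.617,
}


@dataclass
class AnimalRecord:
    """Per-animal measurements with group and preparation-batch labels."""

    animal_id: str
    group: str  # "control" | "treated"
    batch: str
    counts: dict = field(default_factory=dict)  # endpoint name -> value
    pathway_units: float | None = None
    sex: str | None = None

    def value(self, endpoint: str) -> float:
        if endpoint == "pathway_units":
            if self.pathway_units is None:
                raise KeyError(f"{self.animal_id}: no pathway units recorded")
            return float(self.pathway_units)
        return float(self.counts[endpoint])


@dataclass
class GroupComparison:
    """One endpoint's group contrast: means, percent change, permutation p."""

    name: str
    control_mean: float
    control_se: float
    treated_mean: float
    treated_se: float
    percent_change: float
    p_value: float
    n_control: int
    n_treated: int
    seed: int


def percent_change(control_mean: float, treated_mean: float) -> float:
    """Signed percent change of the treated mean on the control scale."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive for a percent change")
    if treated_mean < 0:
        raise ValueError("treated mean must be non-negative")
    return 100.0 * (treated_mean - control_mean) / control_mean


def _se(values: np.ndarray) -> float:
    if len(values) < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def _stratify(records: list[AnimalRecord]) -> dict[str, list[int]]:
    """Batch strata; batches containing a single group are pooled together."""
    batches: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        batches.setdefault(r.batch, []).append(i)
    strata: dict[str, list[int]] = {}
    pooled: list[int] = []
    for b, idx in batches.items():
        groups = {records[i].group for i in idx}
        if len(groups) < 2:
            pooled.extend(idx)
        else:
            strata[b] = idx
    if pooled:
        warnings.warn(
            "batch(es) with a single group pooled into one common stratum",
            stacklevel=3)
        strata["__pooled__"] = pooled
    return strata


def permutation_test(records: list[AnimalRecord], statistic,
                     n_permutations: int = 10_000, seed: int = 0,
                     exhaustive_limit: int = 20_000) -> float:
    """Two-sided batch-stratified permutation p for a group-mean difference.

    ``statistic`` is an endpoint name (or a callable mapping a record to a
    float); the test statistic is ``|mean(treated) - mean(control)|``.
    Within each stratum the treated-label positions are permuted; the
    exhaustive enumeration is used whenever the admissible assignment
    count is at most ``exhaustive_limit``, otherwise ``n_permutations``
    Monte Carlo draws with the add-one correction.
    """
    extract = statistic if callable(statistic) else (lambda r: r.value(statistic))
    values = np.array([extract(r) for r in records], dtype=float)
    groups = np.array([r.group for r in records])
    group_names = sorted(set(groups))
    if len(group_names) != 2:
        raise ValueError(f"need exactly two groups, got {group_names}")
    g_treat = "treated" if "treated" in group_names else group_names[1]
    is_treated = groups == g_treat
    if is_treated.sum() < 2 or (~is_treated).sum() < 2:
        raise ValueError("need at least 2 animals per group")

    strata = _stratify(records)

    def stat_for(treated_mask: np.ndarray) -> float:
        return abs(values[treated_mask].mean() - values[~treated_mask].mean())

    observed = stat_for(is_treated)
    eps = 1e-12

    per_stratum = []
    total = 1
    for idx in strata.values():
        idx = np.asarray(idx)
        k = int(is_treated[idx].sum())
        per_stratum.append((idx, k))
        total *= math.comb(len(idx), k)

    if total <= exhaustive_limit:
        hits = 0
        pools = [list(itertools.combinations(range(len(idx)), k)) for idx, k in per_stratum]
        for choice in itertools.product(*pools):
            mask = np.zeros(len(records), dtype=bool)
            for (idx, _), local in zip(per_stratum, choice):
                mask[idx[list(local)]] = True
            if stat_for(mask) >= observed - eps:
                hits += 1
        return hits / total

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        mask = np.zeros(len(records), dtype=bool)
        for idx, k in per_stratum:
            chosen = rng.choice(len(idx), size=k, replace=False)
            mask[idx[chosen]] = True
        if stat_for(mask) >= observed - eps:
            hits += 1
    return (1 + hits) / (1 + n_permutations)


# ---------------------------------------------------------------------------
# the phantom measurement pipeline


@dataclass
class PipelineConfig:
    """Analysis settings for measuring one phantom volume.

    The absolute intensity threshold (applied after background
    subtraction) sits between the blurred background and the blurred
    structure peaks of the phantom's intensity regime; vessel exclusion
    thresholds sit between the soma and vessel shape regimes.
    """

    background_sigma_um: float = 80.0
    threshold: float = 40.0
    min_component_voxels: int | None = None
    connectivity: int = 26
    vessel_max_extent_um: float = 100.0
    vessel_max_elongation: float = 5.0
    vessel_detect_threshold: float | None = 60.0
    vessel_purge_radius_um: float = 8.0
    sphere_params: SphereParams = field(
        default_factory=lambda: SphereParams(sphere_diameter_um=12.0, fit_fraction=0.4))
    slab_thickness_um: float = 12.0
    min_fascicle_diameter_um: float = 8.0
    min_fascicle_intensity: float | None = 110.0
    measure_fascicles: bool = True

    def segmentation_params(self) -> seg.SegmentationParams:
        return seg.SegmentationParams(
            background_sigma_um=self.background_sigma_um,
            threshold=self.threshold,
            threshold_percentile=None,
            min_component_voxels=self.min_component_voxels,
            connectivity=self.connectivity,
        )

    def slab_spec(self) -> fq.SlabSpec:
        return fq.SlabSpec(
            thickness_um=self.slab_thickness_um,
            sphere_params=self.sphere_params,
            min_fascicle_diameter_um=self.min_fascicle_diameter_um,
            min_fascicle_intensity=self.min_fascicle_intensity,
        )


def purge_vessel_signal(bg, config: PipelineConfig):
    """Delete vessel-like structures from an intensity volume.

    Vessels are detected at a raised threshold where their halos cannot
    bridge to somata, identified by the joint extent + elongation rule,
    and removed with a dilation margin so their low-threshold halo cannot
    chain nearby structures into one component.  Returns a copy when
    anything is removed, the input otherwise.
    """
    if config.vessel_detect_threshold is None:
        return bg
    pre = seg.segment(bg, seg.SegmentationParams(
        background_sigma_um=0.0, threshold=config.vessel_detect_threshold,
        threshold_percentile=None, min_component_voxels=1,
        connectivity=config.connectivity))
    t = pre.table
    if not len(t):
        return bg
    vessel_like = t.loc[(t["max_extent_um"] > config.vessel_max_extent_um)
                        & (t["elongation"] > config.vessel_max_elongation), "label"]
    if not len(vessel_like):
        return bg
    from .counting import ball_offsets

    vmask = np.isin(pre.labels, vessel_like.to_numpy())
    offs = ball_offsets(2.0 * config.vessel_purge_radius_um, bg.spacing_um)
    r = np.abs(offs).max(axis=0)
    structure = np.zeros(2 * r + 1, dtype=bool)
    structure[tuple((offs + r).T)] = True
    vmask = ndi_binary_dilation(vmask, structure=structure)
    from dataclasses import replace as _replace

    data = bg.data.copy()
    data[vmask] = 0.0
    return _replace(bg, data=data, provenance=bg.provenance + " | vessel-purge")


def measure_phantom(volume, rois, config: PipelineConfig) -> dict:
    """Run the full morphometry on one volume; returns endpoint values.

    Background subtraction, two-stage vessel purging (high-threshold
    detection, then component-level exclusion as a safety net),
    segmentation, sphere counting per cuboid, and the slab measurement.
    Returns per-cuboid sphere counts (left/right substantia nigra
    separately plus their sum under ``"SN"``) and, when requested, the
    pathway-unit total and defasciculation metrics.
    """
    bg_raw = seg.subtract_background(volume, config.background_sigma_um)
    bg = purge_vessel_signal(bg_raw, config)
    mask = seg.segment(bg, config.segmentation_params())
    clean = seg.exclude_vessels(mask, config.vessel_max_extent_um,
                                config.vessel_max_elongation)
    report = count_perikarya(clean, rois, config.sphere_params)
    out: dict = {}
    for _, row in report.table.iterrows():
        out[row["roi"]] = int(row["count"])
    if "SN_left" in out and "SN_right" in out:
        out["SN"] = out["SN_left"] + out["SN_right"]
    if config.measure_fascicles:
        # fascicles are themselves tubular: the slab measurement runs on the
        # un-purged mask; only the A11-13 anchor mask is vessel-purged
        a1113_roi = next((r for r in rois if r.name.upper().startswith("A11")), None)
        if a1113_roi is None:
            raise ValueError("fascicle measurement needs an A11-13 cuboid")
        fasc_mask = seg.segment(bg_raw, config.segmentation_params())
        a1113_volume = crop(bg, a1113_roi)
        a1113_mask = seg.exclude_vessels(
            seg.segment(a1113_volume, config.segmentation_params()),
            config.vessel_max_extent_um, config.vessel_max_elongation)
        result = fq.measure_pathway_units(fasc_mask, config.slab_spec(), a1113_mask=a1113_mask)
        out["pathway_units"] = result.total_units
        out["tract_width_um"] = result.defasciculation.tract_width_um
        out["bundled_fraction"] = result.defasciculation.bundled_fraction
    return out


def _child_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def _scaled_spec(base_n: dict, base_fascicles: int, ratios: dict, seed: int,
                 include_a1214: bool, n_vessels: int) -> ph.PhantomSpec:
    n = dict(base_n)
    if "SN" in ratios:
        n["SN_left"] = int(round(base_n["SN_left"] * ratios["SN"]))
        n["SN_right"] = int(round(base_n["SN_right"] * ratios["SN"]))
    for key in ("VTA", "A11_13", "A12_14"):
        if key in ratios and key in n:
            n[key] = int(round(base_n[key] * ratios[key]))
    n_fasc = base_fascicles
    if "pathway_units" in ratios:
        n_fasc = int(round(base_fascicles * ratios["pathway_units"]))
    return ph.default_study_spec(seed=seed, n_somata=n, n_fascicles=n_fasc,
                                 n_vessels=n_vessels, include_a1214=include_a1214)


def run_replication_study(n_per_group: int = 6,
                          effect_sizes: dict | None = None,
                          seed: int = 0,
                          pipeline_config: PipelineConfig | None = None,
                          include_a1214: bool = False,
                          n_vessels: int = 0,
                          animals_per_batch_arm: int = 2,
                          endpoints: list[str] | None = None) -> list[GroupComparison]:
    """Simulated two-arm study with injected treated/control ratios.

    Generates ``n_per_group`` phantoms per arm (control ratios 1.0;
    treated abundances scaled by ``effect_sizes``), measures each with the
    full pipeline, and compares the groups endpoint by endpoint.  Animals
    are grouped into preparation-day batches of ``animals_per_batch_arm``
    per arm, and the permutation test is stratified on those batches.
    Fully deterministic given ``seed``.
    """
    effect_sizes = dict(effect_sizes or FIG_EFFECT_RATIOS)
    config = pipeline_config or PipelineConfig(
        measure_fascicles="pathway_units" in effect_sizes)
    base_n = dict(ph.STUDY_N_SOMATA)
    if include_a1214:
        base_n["A12_14"] = 40

    records: list[AnimalRecord] = []
    for arm, ratios in (("control", {}), ("treated", effect_sizes)):
        for i in range(n_per_group):
            child = _child_seed(seed, 0 if arm == "control" else 1, i)
            spec = _scaled_spec(base_n, ph.STUDY_N_FASCICLES, ratios, child,
                                include_a1214, n_vessels)
            volume, _ = ph.generate_phantom(spec)
            rois = ph.rois_for_spec(spec)
            values = measure_phantom(volume, rois, config)
            records.append(AnimalRecord(
                animal_id=f"{arm}_{i}", group=arm,
                batch=f"day{i // animals_per_batch_arm}",
                counts={k: v for k, v in values.items() if k != "pathway_units"},
                pathway_units=values.get("pathway_units"),
            ))

    if endpoints is None:
        endpoints = []
        if records[0].pathway_units is not None:
            endpoints.append("pathway_units")
        endpoints += [e for e in ("SN", "VTA", "A11_13", "A12_14")
                      if e in records[0].counts]

    comparisons = []
    for name in endpoints:
        ctrl = np.array([r.value(name) for r in records if r.group == "control"])
        trt = np.array([r.value(name) for r in records if r.group == "treated"])
        p = permutation_test(records, name, seed=_child_seed(seed, 2))
        comparisons.append(GroupComparison(
            name=name,
            control_mean=float(ctrl.mean()), control_se=_se(ctrl),
            treated_mean=float(trt.mean()), treated_se=_se(trt),
            percent_change=percent_change(float(ctrl.mean()), float(trt.mean())),
            p_value=p, n_control=len(ctrl), n_treated=len(trt), seed=seed,
        ))
    return comparisons


def simulate_null_pvalues(n_sim: int = 200, n_per_group: int = 6,
                          animals_per_batch_arm: int = 2, mean_count: float = 40.0,
                          batch_sd: float = 0.2, seed: int = 0) -> np.ndarray:
    """Permutation p-values under the null on simulated count data.

    Each simulation draws Poisson counts with a shared log-normal batch
    effect (day-to-day staining variation) and no group effect, then runs
    the stratified test.  Used to check type-I validity.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    pvals = np.empty(n_sim)
    for s in range(n_sim):
        n_batches = int(np.ceil(n_per_group / animals_per_batch_arm))
        effects = np.exp(rng.normal(0.0, batch_sd, n_batches))
        records = []
        for arm in ("control", "treated"):
            for i in range(n_per_group):
                b = i // animals_per_batch_arm
                lam = mean_count * effects[b]
                records.append(AnimalRecord(
                    animal_id=f"{arm}{i}", group=arm, batch=f"b{b}",
                    counts={"y": rng.poisson(lam)}))
        pvals[s] = permutation_test(records, "y", seed=s)
    return pvals
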