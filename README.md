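# thmorph

3D morphometry of tyrosine-hydroxylase-positive (TH+) structures in cleared
whole-mount mouse brains imaged by light-sheet microscopy.

Whole-mount immunostaining with solvent clearing (iDISCO-style) makes the
entire catecholaminergic system of a neonatal mouse brain visible in one
volume: the midbrain dopaminergic cell groups (substantia nigra, SN; ventral
tegmental area, VTA), the hypothalamic groups (A11–A14), and the
mesotelencephalic (MT) axon tract running from the midbrain toward the
forebrain. At this scale individual neurites cannot be resolved — only
somata and tightly fasciculated axon bundles — so quantification needs
statistics built for exactly that regime. `thmorph` implements them as a
tested, deterministic pipeline for researchers quantifying group differences
(e.g., control vs. prenatally drug-exposed litters) in such volumes:

- **Segmentation** by intensity and voxel size after background
  subtraction, with artifact purging of vessel-like structures (long,
  strongly elongated components occasionally traversing the nuclei).
- **Perikaryon counting** per reference cuboid by a deterministic greedy
  packing of fixed-diameter *measuring spheres* into the segmented mask:
  one accepted sphere = one counted perikaryon. Candidate centers are
  visited by descending intensity (lexicographic tie-break); a sphere is
  accepted if at least a configurable fraction of its voxels lies on
  still-uncovered mask and it overlaps no accepted sphere. SN is counted
  separately per side; the other cell groups use one midline-straddling
  cuboid.
- **Pathway units** for the MT tract: a thin coronal slab (thickness not
  exceeding one measuring-sphere diameter) is laid orthogonally to the
  rostro-caudal axis at the rostral limit of the segmented A11–13 cell
  group, spanning the full tract width. Each connected fascicle–slab
  intersection window spawns one or more measuring spheres depending on how
  massive the bundle is; the sphere total is the abundance index. A
  defasciculation summary (tract width, bundled fraction) quantifies tract
  widening.
- **Group statistics**: signed percent change on the control scale with a
  preparation-day-stratified permutation test (exhaustive when the
  admissible relabeling count is small, Monte Carlo with add-one correction
  otherwise).
- **Synthetic phantoms**: because volumes of this kind are rarely
  deposited, the package ships a light-sheet phantom generator with exact
  ground truth (soma centers, fascicle centerlines, vessels, seed-keyed),
  used to validate every stage end to end.

All geometry is computed in physical micrometres — the default sampling is
anisotropic (7 µm z-step, 5 µm in-plane) and no resampling is ever applied.

## Worked example

```python
from thmorph import (default_study_spec, generate_phantom, rois_for_spec,
                     subtract_background, segment, exclude_vessels,
                     count_perikarya, SegmentationParams, SphereParams)

spec = default_study_spec(seed=42)      # SN 32/side, VTA 40, A11-13 42 somata
volume, truth = generate_phantom(spec)  # (44, 96, 72) voxels at (7, 5, 5) um

bg = subtract_background(volume, background_sigma_um=80.0)
mask = segment(bg, SegmentationParams(threshold=40.0, threshold_percentile=None))
mask = exclude_vessels(mask, max_extent_um=100.0, max_elongation=5.0)
report = count_perikarya(mask, rois_for_spec(spec),
                         SphereParams(sphere_diameter_um=12.0, fit_fraction=0.4))
print(report.table)
```

prints

```
     roi        laterality  count
 SN_left              left     32
SN_right             right     32
     VTA bilateral_midline     39
  A11_13 bilateral_midline     42
```

against ground-truth abundances of 32 / 32 / 40 / 42 — the measuring-sphere
counts recover the generated somata to within ±1 despite blur, noise and
touching cells. The scripts in `examples/` walk through each capability
(phantom generation, cell counting, pathway units, the full group study) and
print what every number means; `examples/04_replication_study.py` runs a
6-vs-6 two-arm study with injected treated/control abundance ratios and
reports

```
pathway_units  control   11.83 +- 0.17   treated    3.00 +- 0.00   change  -74.6%   p = 0.0093
SN             control   63.17 +- 0.54   treated  117.67 +- 0.33   change  +86.3%   p = 0.0093
VTA            control   39.83 +- 0.17   treated   23.00 +- 0.00   change  -42.3%   p = 0.0093
A11_13         control   41.67 +- 0.42   treated   26.00 +- 0.00   change  -37.6%   p = 0.0093
```

i.e., the pipeline recovers the injected effect structure (a ~73% fascicle
deficit, an SN surplus, VTA and A11–13 deficits) with the minimum attainable
exhaustive two-sided p of 2/216 within-day relabelings.

## Command line

A thin CLI wraps the same library calls, one subcommand per stage:

```bash
thmorph simulate --seed 1 --out run/           # phantom + ground truth
thmorph segment --in run/phantom.tif --out run/mask.tif --report run/components.csv
thmorph count-cells --in run/phantom.tif --rois rois.json --out counts.csv
thmorph count-fascicles --in run/phantom.tif --rois rois.json --out units.csv
thmorph stats --counts design.csv --out comparisons.csv
thmorph replicate --seed 1 --out study.csv     # full simulated study
```

Every stage is bit-identical across repeated runs with the same seed and
configuration.

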