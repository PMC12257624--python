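# Methods

## Coordinate conventions

All geometry lives in the DICOM LPS patient frame: +x toward the patient's
left, +y posterior, +z superior; "cranial" always means the +z extreme.
A `VolumeGeometry` maps voxel indices to patient millimeters via

```
p(i, j, k) = origin + i*s0*d0 + j*s1*d1 + k*s2*d2
```

where `d0, d1, d2` are the columns of the 3×3 direction matrix (unit-norm,
mutually orthogonal, validated at construction) and `s` the per-axis spacing.
Voxel axis 0 follows the DICOM row direction cosines; for DICOM input the
pixel array is transposed accordingly, and the axis-0 step uses
`PixelSpacing[1]` (column spacing) per the DICOM attribute ordering. NIfTI
affines are RAS; the loader negates the first two affine rows to convert to
LPS.

## Series discovery and loading

`scan_directory` groups files into series and studies for two dialects:
DICOM (one file per slice) and NIfTI-with-JSON-sidecar. Unreadable files,
multiframe DICOMs, and NIfTIs without sidecars are recorded in a skip log
rather than silently dropped, so series found + skips equals candidate
inputs. DICOM slices are sorted by their projection onto the slice normal;
inconsistent pixel spacing, orientation, or rescale parameters within a
series raise `CorruptSeriesError`, which the pipeline charges to the first
cascade step. Slice spacing is the median adjacent gap; spacing is uniform
iff every gap is within 10% of that median.

## Filter cascade

Each series is evaluated against five ordered steps with short-circuit
semantics (a series is attributed to the *first* step it fails; later
metrics are not computed for it):

| step | criterion | default parameters |
|---|---|---|
| axial3d | axial orientation, volumetric, uniform spacing | 10° tolerance; ≥ 20 slices; CT modality |
| labels | aorta, lungs, brachiocephalic trunk all present | ≥ 10 voxels each on the working grid |
| contrast | median aortic HU strictly above threshold | 150.0 HU (150.0 fails) |
| complete_aorta | no cranial or lateral edge touch of the aorta | buffer 0 voxels |
| thickness | effective slice thickness at most maximum | 3.0 mm (3.0 passes) |

Orientation is classified from the cross product of the row and column
cosines: the class is the patient axis whose angle to the slice normal is
within tolerance (axial/coronal/sagittal), `oblique` otherwise, and
`unknown` for non-unit or non-finite cosines.

The 150 HU threshold separates arterial-phase enhancement from non-contrast
and venous-phase blood pool; the *median* (not mean or max) makes the
decision robust to calcification and, deliberately, lets a dissection with a
minority-thrombosed lumen pass while a majority-thrombosed one fails. The
3 mm bound is inclusive because 3 mm reconstructions are the customary
thin-cut boundary; the HU bound is strict so the threshold itself is not
arterial.

Per study, the step attributed is the maximum step index reached by any of
its series (the study got as far as its best series). `select_best_series`
takes the surviving series with maximal median aortic HU, breaking ties by
higher slice count, then lexicographically smallest series UID — fully
deterministic. The attrition report enforces the conservation identity
`initial = selected + Σ per-step exclusions` and errors otherwise.

## Metrics

The thoracic slice range is the inclusive span of slices occupied by the
lungs mask (optionally padded by a margin). The contrast metric is
`numpy.median` over aorta voxels within that range; an even count yields the
mid-pair mean. If the aorta is empty in range, the metric is undefined and
the series fails with `metric_unavailable`, never with a fabricated value.

Edge-touch flags inspect the aorta mask on the native grid: the cranial face
is the slice with maximal patient z (respecting the sign of the slice-axis
direction cosine), and the lateral faces are the in-plane axis most aligned
with patient x. Caudal and anterior/posterior touches are ignored — the
descending aorta is expected to exit the field of view caudally. Both the
median and the edge flags are tested for exact agreement against brute-force
reference implementations on 1000+ random volumes.

## Segmentation backends and mask resampling

Backends implement `segment(volume) -> SegmentationResult` on a 3 mm
isotropic working grid. The oracle backend returns stored ground-truth
masks (resampled from the native grid); an external-adapter backend shells
out to a segmentation executable and raises `SegmentationFailure` if it is
unavailable — failures are charged to step 1, not dropped.

Mask resampling is nearest-neighbor in patient coordinates: each target
voxel center is mapped to continuous source indices; it is "inside" if it
falls within the source's physical voxel extent `[-0.5, size - 0.5]` (not
merely within the center lattice), with rounded indices clipped to the
array. Keeping that half-voxel boundary shell prevents erosion of
edge-touching masks on the native → working → native round trip, which
would silently defeat the edge-touch filter. The resampler is cross-checked
against SimpleITK's nearest-neighbor resampling on strictly interior,
non-tied points (numpy rounds half to even, ITK half up).

## Phantom cohort

`generate_phantom` renders a schematic chest on a configurable grid
(default 64×64×60 at 1.5 mm): an elliptical soft-tissue body (40 HU), two
ellipsoidal lungs (−800 HU), a candy-cane aorta (7 mm radius: ascending and
descending cylinders joined by a half-torus arch at z = 52 mm; the
descending limb runs to the caudal edge by design), and a brachiocephalic
trunk (6 mm radius, matching a real innominate artery's 12–15 mm diameter so
it survives the 3 mm working grid) rising above the arch. Aortic blood is
320 HU (arterial) or 45 HU (non-contrast); a mural thrombus (60 HU) occupies
a contiguous angular wedge containing an exact `round(f·N)` share of aortic
voxels, so the median flips exactly at fraction 0.5. Gaussian noise
(default σ = 5 HU) is seeded per series; ground-truth masks are noise-free.

Degraded variants: coronal and scout (single-slice) acquisitions, missing
lungs or brachiocephalic trunk, non-contrast fill, thick slices, and
cranial/lateral truncation implemented by shifting the anatomy so the
relevant structure crosses the stated image edge; a post-generation
geometric consistency check raises if a truncation flag and the actual mask
extent disagree. Each series carries its expected pipeline outcome (the
first failing step, or `selected_candidate`), derived from the spec by
construction, not by running the pipeline. Cohorts are written
deterministically (content-derived UIDs, no timestamps) in either dialect;
repeated generation is byte-identical.

What the phantoms do **not** emulate: real anatomy (no heart, vertebrae, or
branch vessels beyond one trunk), contrast-timing gradients, beam-hardening
or motion artifacts, and gantry-tilted or non-orthogonal acquisitions. They
are designed to make each filter's decision boundary unambiguous, not to be
radiologically realistic.

## Accuracy reporting

Exclusion accuracy per step is `appropriate / excluded` among reviewed
exclusions; the pooled figure is the ratio of summed numerators to summed
denominators (the exclusion-weighted mean). Inclusion accuracy is
`confirmed / selected`. Ratios with zero denominators are reported as
absent, never as 0% or 100%. `score_against_ground_truth` plays the
reviewer on phantom cohorts, comparing each series' terminal outcome
(exclusion step or selected-candidate) with the generator's expectation and
itemizing any disagreements.

## Limitations

- The oracle backend requires ground-truth masks; on real data an external
  segmentation model must be supplied, and its quality bounds steps 2–4.
- The contrast threshold is a single global HU cut; no per-scanner
  calibration is attempted.
- Edge-touch detection checks mask-to-boundary contact only; a field of
  view that crops the aorta *and* the segmentation equally would not be
  flagged by any image-intrinsic test.
- Phantom-derived accuracy (100% agreement) reflects the unambiguous
  construction of the phantoms, not expected performance on clinical data.
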