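# Methods

Conventions, models, parameters, and the rationale behind every
package-level choice. Units are micrometres (µm) and cubic micrometres
(µm³) throughout; arrays are ordered `(z, y, x)` with 0-based voxel-centre
coordinates.

## 1. Acquisition geometry

| Parameter | Mito time-lapse | Vesicle stack | Rationale |
|---|---|---|---|
| z slices | 10 | 12 (≥ 12 supported) | typical confocal live-cell stack depths |
| z step | 0.25 µm | 0.35 µm | modality-specific axial sampling |
| lateral voxel | 0.1 µm | 0.1 µm | package choice; high-NA 100× confocal sampling (not specified by any acquisition default, so it is an explicit `AcquisitionGeometry` field) |
| frames | 9 | 1 | short time-lapse; cells are the replication unit |
| field | 128×128 default | 128×128 (192×192 in experiments) | desk-scale |

Volumes are always `voxel_count × voxel_z_um × voxel_xy_um²`.
Connectivity is 26-neighbourhood in 3D everywhere (stated once in
`core.CONNECTIVITY`, used by every module).

## 2. Synthetic data model

### 2.1 Mitochondrial time-lapse

Structures are tubules: random-walk centerlines (length 2–4 µm, radius
0.25 µm) dilated with a physical-unit ellipsoid, placed with ≥ 2 voxel
clearance. Scripted events modify the label volume between frames:

- **Fission** cuts a one-voxel plane perpendicular to the coordinate axis
  most aligned with the structure's principal axis, scanning candidate
  planes from the middle outward until the cut yields exactly two
  components. Axis-aligned cuts are required because an oblique one-voxel
  plane does not sever 26-connectivity (diagonal neighbours bridge it).
- **Fusion** connects the nearest voxel pair of two structures with a
  rasterised bridge of the tubule radius; a bridge that would touch a third
  structure is rejected and the next-nearest candidate pair is tried.

Rendering: binary support × amplitude (default 100), blurred with a
Gaussian PSF (σ_xy = 0.04 µm, σ_z = 0.08 µm), then
`Poisson(img·s)/s + N(0, σ)` noise with defaults `s = 1.0`, `σ = 4.0`.
The PSF defaults are deliberately small so that Otsu on a *noise-free*
render recovers the ground-truth support exactly — a calibration property
the generator is required to satisfy, verified in the test suite.

**Event observability.** A fission and a fusion scheduled in the same frame
can compose to an identity transition (the fusion's auto-selected partner
is the nearest pair — typically the fission's two children). Such composed
events are unobservable by any detector that compares consecutive frames,
so scripted accuracy scenarios place at most one event per inter-frame
transition. This is a property of the measurement design, not of the
detector.

### 2.2 Vesicle stacks

Each punctum is an ellipsoid ball in physical units (radius 0.3–0.45 µm;
mitochondria-only 0.4–0.55 µm). Multi-channel classes place one ball per
involved channel, offset so that the pairwise overlap equals
`overlap_fraction` (default 0.5) of a single ball's volume; the offset is
solved from the equal-sphere lens formula
`V_lens = (π/12)(4r + d)(2r − d)²` with `scipy.optimize.brentq`. Puncta are
kept pairwise separated by the sum of their extents plus a 0.4 µm margin,
with larger classes placed first.

### 2.3 Experiments

A design maps group names to `GroupProfile`s (expected fission/fusion
counts and per-class punctum means). Per-cell realisations are Poisson
draws, giving genuine between-cell variability; every cell gets a sub-seed
drawn from the experiment seed (all seeds < 2³¹). One TIFF per cell per
modality plus a `manifest.json` with full ground truth.

Problem sizes are desk-scale by design: live-cell fields contain on the
order of 100 mitochondria and 50–140 vesicles per cell, which is too heavy
for a CI-friendly package. The demo design keeps the *direction* and
*relative size* of group effects while scaling counts down roughly 10×.

## 3. Preprocessing

`binarize` = denoise (Gaussian, default σ = 0.5 voxel for mito, 0.7 for
vesicles; `"none"` and Richardson–Lucy-free by design — no deconvolution) →
percentile contrast rescale (0.1/99.9 defaults; deterministic and
order-preserving) → threshold (Otsu default; `fixed` available) → boolean
mask, followed by `apply_size_filter` (vesicle default `min_voxels = 8`,
which removes hot-pixel debris smaller than any modelled punctum).
A constant image makes Otsu ill-posed and raises
`ValueError("degenerate histogram")` rather than guessing. The realised
threshold is recorded in the mask's provenance.

Exactness statements (noise-free mask = ground truth) are made with
`denoise="none"`: any smoothing moves the Otsu boundary by ~1 voxel, so
"exact" is only well-posed without it. The default config is held to a
separate contract, F1 ≥ 0.99 at default noise.

## 4. Event detection

Consecutive binarised frames are labelled (26-connected, deterministic
order: component size descending, then first-voxel scan order) and joined
by an overlap graph (voxel-count table of label co-occurrences,
`min_overlap_voxels = 1` default). A frame-t label overlapping *n* ≥ 2
frame-t+1 labels contributes *n − 1* **fission** events; **fusion** is the
same rule on the transposed graph, so time-reversal symmetry holds by
construction. Event location is the midpoint of the two largest overlap
regions' centroids, snapped to the nearest voxel of the participating
structures' union footprint. Labels with no counterpart are reported as
appeared/disappeared, never as events (structure loss has other causes —
degradation, focus drift — and is probed experimentally).

Per-cell summaries average per-frame-pair event counts and per-frame
morphometrics, because cells (not frames) are the unit of replication in
the downstream statistics.

## 5. Vesicle classification

Default is an **exclusive partition**: every LC3 punctum is exactly one of
AP / AL / AM / AML depending on which other channels it overlaps
(≥ `min_shared_voxels`, default 1); non-LC3 lysosome puncta are ML or LYS;
mitochondria puncta overlapping no vesicle channel are MITO. This makes
class counts additive (`AP + AL + AM + AML = #LC3 puncta` — the partition
property) and suits count-based statistics. An inclusive mode
(`classes_exclusive=False`) counts pairwise overlaps irrespective of the
third channel, matching the convention of pairwise colocalisation reports.
Volumes are attributed via the defining channel's punctum.

An all-background channel yields an empty punctum set (the degenerate-
histogram error is caught in `detect_puncta` only for this case), because
"no puncta" is a legitimate biological outcome.

## 6. RACC (regression-adjusted colocalisation)

Both channels are min–max normalised over the foreground (whole field by
default, or a supplied mask). A total-least-squares (orthogonal) line is
fit to the joint scatter via the 2×2 covariance eigendecomposition; TLS is
used because both channels carry noise, making OLS's asymmetric error model
inappropriate (it would also break channel symmetry). Each voxel's value is

```
w = max(0, 1 − d / D(θ)),   D(θ) = (√2/2)·(θ/90°),   value = w·(a + b)/2
```

with `d` the perpendicular distance to the line and θ ∈ (0°, 90°] the
penalisation angle (default 45°, the package's standard setting). `D(90°)`
equals the largest possible distance in the unit square, so θ = 90°
disables the penalty. Guaranteed contracts (all tested): channel symmetry,
monotonicity in θ, invariance to affine intensity rescaling, values in
[0, 1], zero outside the mask. A constant channel has no defined regression
and raises. RACC is computed in full 3D (no per-slice fitting): the
penalised quantity is an intensity relationship, not a spatial one, so
pooling all voxels uses the data fully and keeps the map independent of
slice order.

## 7. Statistics

Cells are the replication unit. `summarise_groups` reports mean ± SEM
(SEM undefined for n = 1). One-way ANOVA uses hand-computed sums of squares
with `scipy.stats.f`; the balanced two-way ANOVA requires a complete, 
equally replicated crossing (anything else raises with the offending cell
named) and decomposes SS into main effects + interaction + residual.
Fisher's LSD uses the pooled residual mean square with no multiplicity
correction — by construction, it is the classical LSD procedure; users
needing family-wise control should apply it downstream. `statsmodels` is
used in the test suite as an independent oracle (agreement to ~1e-10), not
at runtime.

The pipeline's two-way analysis crosses group × event type
(fission/fusion) on the per-cell event-count metric — a plain crossed
design; no repeated-measures structure is modelled, since per-cell means
enter once.

## 8. Determinism and numerics

- All randomness flows from user-supplied integer seeds through
  `numpy.random.default_rng`; derived sub-seeds are drawn below 2³¹.
- Identical inputs give bit-identical outputs (tested: per-cell metric CSVs
  byte-identical across reruns).
- TLS eigenvector sign is fixed (positive x-component) to make slopes
  reproducible.
- Morphometric identities (mean volume × count = total volume) hold to
  machine precision; tolerances in tests are 1e-9 relative or tighter.
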