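# Methods

This note documents the models, numerical choices and limitations behind
`dissolvis`.  It is written for users who want to know what the package
assumes, what its synthetic data do and do not emulate, and why the
defaults are what they are.

## The measurement being modelled

An inert (non-swelling, non-eroding) polymer matrix tablet containing a
soluble drug sits in a flow-through cell filled with dissolution medium.
The medium carries a dissolved high-atomic-number contrast agent (CsCl
brine), so wherever it penetrates the matrix the local X-ray attenuation —
and hence the reconstructed gray value — rises.  Repeated μCT scans during
dissolution therefore encode the wetting front; in parallel, 5 mL samples
withdrawn from the 900 mL circulating medium are assayed by UV
spectrophotometry to give the cumulative drug-release profile.  The
package's purpose is the image-analysis chain from those scans to a
water-penetration profile, plus the dissolution-profile arithmetic needed
to compare it with release.

## Synthetic phantom

### Geometry and attenuation

The tablet is a cylinder (defaults: Ø 10 mm × 2.8 mm, 20.18 μm voxels)
containing spherical air pores placed by rejection sampling until the
voxel-counted porosity reaches the 23.24% target within ±0.2 points.
Pores are non-overlapping (overlap is permitted, with a warning, only when
the target is otherwise unreachable — which happens in strongly
scaled-down tablets where the pore size distribution is large relative to
the tablet) and keep a 2.5-voxel matrix wall to the tablet surface so that
segmentation sees closed, internal porosity; surface-connected open pores
are not modelled.  Gray levels are arbitrary units: air 0, dry polymer
matrix 100, brine 200.

### Wetting model

Water ingress follows a shrinking-core geometry: the front advances
radially inward from the lateral surface at constant speed v (default
R/8 h, i.e. full wetting at 8 h), so the dry core radius is
r(t) = R − v·t, floored at zero.  Wetting is binary at the voxel level.
Wetted matrix voxels take gray 100 + u·(200 − 100) with uplift u = 0.5 by
default: the brine fills pore space and microporosity within a voxel but
does not displace polymer, so the wetted matrix forms a distinct
intermediate histogram peak rather than reaching pure-brine attenuation.
The uplift is a config parameter because no measured value exists for it;
0.5 places the wetted peak midway, which reproduces the qualitative
two-peak histogram of a partially wetted tablet.  Background outside the
tablet is air in the dry pre-scan and brine in every dissolution-series
scan (flooded cell).

### Imaging model and its calibration

Each scan is blurred with an isotropic Gaussian point-spread function
(σ = 0.8 voxel) and degraded with additive white Gaussian noise
(σ = 2 gray units), both seeded.  These two constants place the phantom in
the *partial-volume-dominated* regime that the emulated experiment
describes: the classification difficulty comes from intermediate gray
values at tablet surfaces, pore walls and the wetting front — voxels whose
blurred gray lies between the dry and wet modes — while the per-voxel
gray-noise tails are negligible against the 50-unit dry/wet contrast.
Under these conditions naive intersection thresholding of a completely dry
tablet already misclassifies ~8% of VOI voxels as wet (all of them
surface voxels brightened by the surrounding brine), which is the failure
mode the KNN classifier exists to fix.  Raising the noise instead would
shift errors into both classifiers' gray tails, where no feature can
separate them and the comparison between methods degenerates.

### Matched release data

The release curve is tied to the same shrinking-core kinetics: with a lag
(default 0.25 h, the time for dissolved drug to diffuse out after the
front passes), release(t) = 100·(1 − (r(t−lag)/R)²) percent of dose.
Released mass is converted to per-sample medium concentrations by
inverting the withdrawal-corrected accounting (closed loop, medium volume
shrinks by 5 mL per sample, no replacement), then to absorbances through
the linear calibration forward map, optionally with measurement noise.
This makes the quantification path exactly invertible in the noise-free
case, which the tests exploit.

### What the phantom does not emulate

Beam hardening, ring artifacts, scatter, reconstruction streaks, swelling
or erosion of the matrix, anisotropic printing microstructure
(layer/strand voids), axial wetting through the top/bottom faces,
saturation gradients behind the front, and contrast-agent crystallization.
Passing tests on the phantom therefore demonstrate that the analysis chain
recovers a known shrinking-core ground truth under realistic blur and
noise — not that it is robust to every artifact of real scanner data.

## Structural analysis

* **Bilateral filter**: direct 3-D implementation (shifted-window
  accumulation), window truncated at 2σ_spatial.  Defaults σ_spatial = 1.5
  voxels, σ_range = 15 gray units (several times the noise, well below the
  100-unit air/matrix contrast).  Implemented in-package because available
  library bilateral filters are 2-D only.
* **Segmentation**: explicit threshold from config (an automatic Otsu
  fallback exists but is always logged, to keep runs reproducible),
  followed by largest 26-connected component (removes the surround) and
  optional hole-filling to turn the matrix mask into the tablet mask; the
  pore mask is the sub-threshold tablet interior.
* **Porosity**: exact integer voxel counts; porosity · tablet_voxels =
  pore_voxels by construction.
* **Registration**: translation-only (the sample is clamped in the cell;
  source and detector rotate, not the sample).  Integer shift from
  cross-correlation, then subvoxel refinement by maximizing normalized
  cross-correlation over a continuous 3-DoF shift (Powell) on a
  boundary-trimmed core, then one trilinear resampling pass onto the
  reference grid.  Near-integer results are snapped (tolerance 0.01 voxel)
  so that already-aligned volumes pass through untouched.  A Pearson
  correlation below the configurable floor (default 0.2) raises an error.
* **VOI shrinking**: iterated 6-connected erosion; k iterations keep
  exactly the voxels with city-block distance to background > k.  Default
  2 iterations at fast-scan resolution — enough to remove the ~2-voxel
  partial-volume shell at the chosen PSF.

## Wetting classification

* **Histograms**: 256 equal-width bins over the global VOI min/max across
  the whole series, so bins are comparable over time.
* **Gaussian fits**: weighted-Gaussian least squares on bin counts
  (weight = voxel count); a fit window can isolate one mode; at least five
  nonzero bins are required.
* **Intersection threshold**: closed-form root of the quadratic obtained
  by equating the two weighted log-densities, taking the root strictly
  between the means; the equal-variance case degenerates to a line.  The
  rule is gray ≥ threshold ⇒ wet (`wet_is_bright` — CsCl raises
  attenuation).  The threshold is recomputed per experiment from the
  first/last scans.
* **KNN**: features (x, y, z, gray, EDT) are z-scored with the training
  statistics — without scaling, coordinates in the hundreds would swamp
  gray values.  k = 10; a 10% seeded holdout gives the reported validation
  error; the model keeps the remaining 90%.  Neighbour search uses a
  library KD-tree; voting is in-package, and an exact 5–5 tie falls back
  to the label of the single nearest neighbour (deterministic and local).
  Full volumes are classified in chunks of 200k voxels; chunking does not
  affect results.
* **Why KNN beats thresholding here**: the training set contains every VOI
  location in both a dry and a wet state, so the classifier learns a
  *locally adaptive* decision boundary — e.g. that surface voxels are
  bright even when dry.  Global thresholding cannot express that and
  systematically overcounts wet voxels while any dry surface remains.

## Release arithmetic

* Calibration is ordinary least squares; its validity range is the span of
  the standards, and conversions outside it warn but proceed.
* Withdrawal correction defaults to the closed-loop, no-replacement mass
  balance (the medium shrinks by one aliquot per sample); a `replaced`
  option switches to the constant-volume replacement formula.
* f2 uses shared timepoints only and refuses interpolation; an `fda_rule`
  option truncates one point beyond 85% reference release.  Alignment by
  linear interpolation happens only in the penetration-vs-release
  comparison, whose divergence time is the first time the absolute
  difference exceeds a configurable band (default 5 points).

## Problem sizes and determinism

Tests and the acceptance script run geometrically scaled-down tablets at
the full 20.18 μm voxel size: porosity recovery on a Ø 2.4 mm tablet
(129² × 43 grid, pores 150 ± 20 μm), penetration recovery on a
96-voxel-wide tablet over 8 timesteps, and the end-to-end demo on a
64-voxel-wide tablet over 6 timesteps.  Scan times are spaced so the front
advances several voxels — more than the PSF width — between scans;
timesteps finer than the blur cannot be resolved by any per-voxel
classifier.  In scaled-down tablets the pore size is reduced less than the
geometry (unresolvably small pores would bias porosity), which confines
pore centers to a thinner axial band than in the full-size tablet.  Every
stochastic stage takes an explicit seed; identical configs give
bit-identical outputs (stage wall-times go to a separate log file, not
into the compared CSV/JSON artifacts).

## Known limitations

* Rotation is not estimated during registration; a rotated acquisition
  would need an external tool first.
* The Gaussian-intersection threshold assumes both histogram modes are
  approximately Gaussian; strongly skewed modes (e.g. heavy partial-volume
  tails when the VOI is not shrunk) bias the fit — that is precisely why
  the VOI is shrunk before fitting.
* The KNN classifier is only as good as its label assumption: the first
  scan must be essentially dry and the last essentially wet.  With the
  radial front model these hold by construction; for real data a visibly
  pre-wetted first scan would poison the dry class.
* Porosity from voxel counting underestimates pores near the resolution
  limit (blur-filled); pore radii below ~3 voxels are not reliably
  recovered.
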