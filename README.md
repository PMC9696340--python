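# dissolvis

Analysis toolkit for **in-situ dissolution imaging** of solid dosage forms:
quantify how water penetrates an inert-matrix tablet from time-resolved
X-ray micro-CT (μCT) scans, and compare that penetration against the drug
release measured by standard dissolution testing.

## Who this is for

Pharmaceutical imaging groups running flow-through-cell dissolution
experiments inside a μCT scanner: a tablet sits in circulating dissolution
medium spiked with a contrast agent (e.g. 8% w/v CsCl brine), and 3-D scans
are acquired repeatedly while the medium soaks in.  Because the dissolved
high-Z salt raises X-ray attenuation, wetted regions of the polymer matrix
brighten, and the wetting front can be followed voxel by voxel.  No public
dataset of such scans exists, so the package ships a first-class synthetic
phantom generator with exact ground truth, used by the tests and usable for
method development.

## What it computes

**Structure.** The dry pre-scan is denoised with an edge-preserving 3-D
bilateral filter, the tablet is segmented by thresholding plus
largest-connected-component cleanup, and total porosity is the exact voxel
count ratio φ = V_pores / V_tablet.  A translation-only rigid registration
resamples the dry high-resolution scan onto the fast-scan grid.

**Wetting.** Inside the tablet-matrix volume of interest (VOI), the
gray-value histogram evolves from one low-attenuation peak (dry polymer) to
one high peak (wetted polymer).  Fitting Gaussians N(μ_d, σ_d) and
N(μ_w, σ_w) to the first and last timestep histograms (on a
morphologically shrunk VOI, which removes partially wetted surface voxels),
the wet/dry threshold is the gray value where the two weighted densities
intersect.  Because simple thresholding mislabels partial-volume voxels
with intermediate gray values, a k-nearest-neighbour classifier (k = 10,
Euclidean metric on z-scored features x, y, z, gray value, and Euclidean
distance to the nearest background voxel) is trained on the first scan (all
voxels labelled dry) and last scan (all wet), with 10% held out for a
validation error.  The **penetration profile** is the fraction of VOI
voxels classified wet at each time.

**Release.** A linear UV calibration A = a·C + b converts sampled
absorbances to concentrations; cumulative release applies the withdrawal
correction for sequential 5 mL aliquots from 900 mL of medium

    m_i = C_i (V − i·V_s) + Σ_{j<i} C_j V_s,

and two dissolution profiles are compared with the regulatory similarity
factor

    f2 = 50 · log10( 100 / sqrt(1 + (1/n) Σ_t (R_t − T_t)²) ),

which is 100 for identical profiles and ≥ 50 for conventionally "similar"
ones.  Penetration and release profiles are aligned in time and their
divergence time reported.

## Worked example

`examples/02_wetting_classification.py` builds a 96-voxel-wide tablet
phantom (20.18 μm voxels, 23.24% target porosity), simulates eight scans
over 8 h of brine ingress, and classifies every VOI voxel both ways:

```
dry mode 99.7+-2.1, wet mode 150.2+-2.0
intersection threshold: 125.57 gray units

KNN validation error: 0.015%

time_h  truth   threshold  knn
 0.00  0.0000     0.0798  0.0005
 1.14  0.3270     0.3610  0.3155
 2.29  0.5180     0.5430  0.5143
 3.43  0.6956     0.7113  0.6928
 4.57  0.8238     0.8340  0.8231
 5.71  0.9240     0.9289  0.9235
 6.86  0.9811     0.9821  0.9806
 8.00  1.0000     1.0000  1.0000
```

At the first timestep the tablet is completely dry, yet thresholding calls
8.0% of voxels wet — these are partial-volume voxels at the tablet surface,
brightened by the surrounding brine.  The KNN classifier, whose spatial and
distance-to-background features let it learn that surface voxels are bright
even when dry, stays within 0.05% of the truth there and within 1.2
points everywhere.  The other examples cover the phantom/porosity chain
(`01`), UV quantification and f2 (`03`), and the full pipeline from a single
config (`04`).

## Command line

A thin CLI wraps the library:

```bash
dissolvis phantom --out scratch/p --seed 1           # synthetic scan series
dissolvis porosity scan.tif --voxel-size-um 20.18 --threshold 50
dissolvis wet --manifest scratch/p/scans/manifest.json \
              --mask scratch/p/truth/matrix_mask.tif --seed 1 --out scratch/w
dissolvis release --standards std.csv --samples samples.csv --dose-mg 65.6 \
                  --out release.csv
dissolvis f2 reference.csv test.csv
dissolvis run --config examples/demo_config.yaml --out scratch/run
```

Exit codes: 0 success, 2 validation error, 3 stage failure.

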