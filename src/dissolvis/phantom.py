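"""Synthetic 4D tablet phantom with known ground truth.

No public time-resolved uCT dissolution scans of inert-matrix tablets exist,
so this module emulates them: a porous cylindrical tablet (polymer matrix
with spherical air-filled pores), immersed in a contrast-agent brine whose
dissolved high-Z salt raises the attenuation of wetted regions, imaged with
a Gaussian point-spread function and additive Gaussian noise.  Water ingress
follows an idealized shrinking-core geometry: the wetting front advances
radially inward from the lateral surface at constant speed, so the dry core
radius at time t is r(t) = R - v*t (floored at zero).  Wetted matrix voxels
take an intermediate gray level between dry matrix and pure brine (the
brine only fills the pore space and surface roughness, it does not replace
the polymer), producing the characteristic two-peak gray-value histogram of
a partially wetted tablet.

Defaults correspond to the emulated experiment: a 10 mm diameter x 2.8 mm
tablet, ~23.24% porosity, 20.18 um voxels, full wetting at 8 h.  Everything
is reproducible bit-exactly from (spec, seed).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import PhantomError, ValidationError
from .release import CalibrationCurve, ReleaseProfile, SamplingScheme, cumulative_release
from .volio import BinaryMask, ScanSeries, VoxelVolume

log = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "build_tablet",
    "simulate_ingress",
    "beer_lambert",
    "radiograph",
    "add_noise",
    "simulate_release",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of the synthetic tablet and its imaging.

    Lengths in mm unless suffixed ``_um``; attenuation levels in arbitrary
    gray units with ``mu_brine > mu_matrix > mu_background`` (the dissolved
    contrast agent raises attenuation).  ``wet_uplift`` places the wetted-
    matrix gray level between dry matrix (0) and pure brine (1).
    """

    tablet_radius_mm: float = 5.0
    tablet_height_mm: float = 2.8
    voxel_size_um: float = 20.18
    target_porosity: float = 0.2324
    pore_radius_mean_um: float = 100.0
    pore_radius_sd_um: float = 20.0
    mu_matrix: float = 100.0
    mu_brine: float = 200.0
    mu_background: float = 0.0
    wet_uplift: float = 0.5
    front_speed_mm_h: float = 0.625  # R/8h: full wetting at 8 h
    psf_sigma_vox: float = 0.8
    noise_sd: float = 2.0
    margin_vox: int = 4
    porosity_tol: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.target_porosity < 1):
            raise ValidationError(f"target_porosity must be in [0,1), got {self.target_porosity}")
        for name in ("tablet_radius_mm", "tablet_height_mm", "voxel_size_um",
                     "pore_radius_mean_um"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if not self.mu_brine > self.mu_matrix > self.mu_background:
            raise ValidationError("require mu_brine > mu_matrix > mu_background")
        if self.noise_sd < 0 or self.pore_radius_sd_um < 0:
            raise ValidationError("standard deviations must be >= 0")
        if not (0 <= self.wet_uplift <= 1):
            raise ValidationError(f"wet_uplift must be in [0,1], got {self.wet_uplift}")
        if self.front_speed_mm_h < 0:
            raise ValidationError("front_speed_mm_h must be >= 0")

    @property
    def wet_matrix_gray(self) -> float:
        return self.mu_matrix + self.wet_uplift * (self.mu_brine - self.mu_matrix)

    def scaled(self, factor: float, **overrides) -> "PhantomSpec":
        """A geometrically scaled copy (same voxel size, smaller tablet).

        Used for desk-scale grids; attenuation, noise and porosity are kept,
        the front speed is scaled so full wetting still occurs at R/v hours.
        """
        return replace(
            self,
            tablet_radius_mm=self.tablet_radius_mm * factor,
            tablet_height_mm=self.tablet_height_mm * factor,
            front_speed_mm_h=self.front_speed_mm_h * factor,
            **overrides,
        )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        r_vox = self.tablet_radius_mm * 1000.0 / self.voxel_size_um
        h_vox = self.tablet_height_mm * 1000.0 / self.voxel_size_um
        nxy = 2 * math.ceil(r_vox) + 2 * self.margin_vox + 1
        nz = math.ceil(h_vox) + 2 * self.margin_vox + 1
        return (nz, nxy, nxy)

    @property
    def full_wetting_time_h(self) -> float:
        if self.front_speed_mm_h == 0:
            return math.inf
        return self.tablet_radius_mm / self.front_speed_mm_h


@dataclass
class GroundTruth:
    """Known masks and wetting history of a generated phantom."""

    tablet_mask: BinaryMask
    pore_mask: BinaryMask
    matrix_mask: BinaryMask
    pore_centers_vox: np.ndarray  # (n, 3) float, (z, y, x) voxel coords
    pore_radii_vox: np.ndarray  # (n,) float
    realized_porosity: float
    times_h: np.ndarray = field(default_factory=lambda: np.empty(0))
    wet_fraction_per_time: np.ndarray = field(default_factory=lambda: np.empty(0))
    front_radius_per_time_mm: np.ndarray = field(default_factory=lambda: np.empty(0))


def _cylinder_geometry(spec: PhantomSpec):
    nz, ny, nx = spec.grid_shape
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    r_vox = spec.tablet_radius_mm * 1000.0 / spec.voxel_size_um
    h_vox = spec.tablet_height_mm * 1000.0 / spec.voxel_size_um
    zz = np.arange(nz)[:, None, None] - cz
    yy = np.arange(ny)[None, :, None] - cy
    xx = np.arange(nx)[None, None, :] - cx
    rad2 = yy**2 + xx**2  # (1, ny, nx) broadcastable cylindrical radius^2
    cylinder = (rad2 <= r_vox**2) & (np.abs(zz) <= h_vox / 2.0)
    return cylinder, rad2, np.broadcast_to(np.abs(zz), (nz, ny, nx)), (cz, cy, cx), r_vox, h_vox


def _sphere_voxel_count(radius_vox: float) -> int:
    r = int(math.ceil(radius_vox))
    ax = np.arange(-r, r + 1, dtype=float)
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    return int((d2 <= radius_vox**2).sum())


def build_tablet(spec: PhantomSpec) -> tuple[VoxelVolume, GroundTruth]:
    """Generate the clean (noise-free, unblurred) dry tablet volume.

    A cylindrical polymer matrix at ``mu_matrix`` in an air background, with
    spherical air pores carved by rejection sampling until the realized
    voxel-counted porosity is within ``porosity_tol`` of the target.  Pores
    are non-overlapping and lie fully inside the cylinder; overlap is only
    permitted (with a warning) if the target would otherwise be unreachable.
    """
    cylinder, rad2, absz, center, r_vox, h_vox = _cylinder_geometry(spec)
    nz, ny, nx = spec.grid_shape
    tablet_count = int(cylinder.sum())
    if tablet_count == 0:
        raise PhantomError("tablet cylinder does not fit on the grid")

    pore = np.zeros_like(cylinder)
    centers: list[tuple[float, float, float]] = []
    radii: list[float] = []
    rng = np.random.default_rng(spec.seed)
    vs = spec.voxel_size_um
    min_r_vox = 1.1
    mean_r_vox = spec.pore_radius_mean_um / vs
    sd_r_vox = spec.pore_radius_sd_um / vs
    cz, cy, cx = center

    target = spec.target_porosity
    tol = spec.porosity_tol
    pore_count = 0
    allow_overlap = False
    # cell list for O(1) overlap queries; cell edge >= 2 * max plausible radius
    cell = max(2.0 * (mean_r_vox + 4 * sd_r_vox), 2.0)
    occupied: dict[tuple[int, int, int], list[int]] = {}

    def overlaps(c, r) -> bool:
        key = tuple(int(q // cell) for q in c)
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for idx in occupied.get((key[0] + dz, key[1] + dy, key[2] + dx), ()):
                        oc, orad = centers[idx], radii[idx]
                        d2 = sum((a - b) ** 2 for a, b in zip(c, oc))
                        if d2 < (r + orad) ** 2:
                            return True
        return False

    max_attempts = 200_000 + 400 * tablet_count // max(_sphere_voxel_count(mean_r_vox), 1)
    attempts = 0
    while pore_count / tablet_count < target:
        attempts += 1
        if attempts > max_attempts:
            if not allow_overlap:
                allow_overlap = True
                attempts = 0
                warnings.warn(
                    "target porosity unreachable with non-overlapping pores; "
                    "allowing overlaps"
                )
                continue
            raise PhantomError(
                f"could not reach target porosity {target} "
                f"(realized {pore_count / tablet_count:.4f} after bounded attempts)"
            )
        r = rng.normal(mean_r_vox, sd_r_vox)
        if r < min_r_vox:
            continue
        r = min(r, mean_r_vox + 4 * sd_r_vox)  # keep within the cell-list reach
        # shrink the final pore so the target is hit within tolerance
        remaining = (target - pore_count / tablet_count) * tablet_count
        if _sphere_voxel_count(r) > remaining:
            r = max(min_r_vox, (3.0 * remaining / (4.0 * math.pi)) ** (1.0 / 3.0))
        # uniform center with the sphere fully inside the cylinder, keeping a
        # resolvable matrix wall to the surface (closed/internal porosity)
        wall = 2.5
        r_cap = min(r_vox, h_vox / 2.0) - wall - 0.5
        if r_cap < min_r_vox:
            raise PhantomError(
                f"tablet too small for any pore (max radius {r_cap * vs:.1f} um)"
            )
        r = min(r, r_cap)  # geometric truncation of the size distribution
        max_rad = r_vox - r - wall
        max_z = h_vox / 2.0 - r - wall
        u = rng.random()
        theta = rng.random() * 2 * math.pi
        rho = max_rad * math.sqrt(u)
        c = (
            cz + rng.uniform(-max_z, max_z),
            cy + rho * math.sin(theta),
            cx + rho * math.cos(theta),
        )
        if not allow_overlap and overlaps(c, r):
            continue
        # rasterize: voxel centers within r of the sphere center
        zlo, zhi = int(math.floor(c[0] - r)), int(math.ceil(c[0] + r)) + 1
        ylo, yhi = int(math.floor(c[1] - r)), int(math.ceil(c[1] + r)) + 1
        xlo, xhi = int(math.floor(c[2] - r)), int(math.ceil(c[2] + r)) + 1
        lz = np.arange(zlo, zhi, dtype=float)[:, None, None] - c[0]
        ly = np.arange(ylo, yhi, dtype=float)[None, :, None] - c[1]
        lx = np.arange(xlo, xhi, dtype=float)[None, None, :] - c[2]
        ball = lz**2 + ly**2 + lx**2 <= r**2
        sub = pore[zlo:zhi, ylo:yhi, xlo:xhi]
        new = int(ball.sum() - (ball & sub).sum())
        sub |= ball
        pore_count += new
        idx = len(centers)
        centers.append(c)
        radii.append(r)
        key = tuple(int(q // cell) for q in c)
        occupied.setdefault(key, []).append(idx)

    matrix = cylinder & ~pore
    values = np.full((nz, ny, nx), spec.mu_background, dtype=np.float32)
    values[matrix] = spec.mu_matrix
    realized = pore_count / tablet_count
    log.info(
        "phantom: %d pores, realized porosity %.4f (target %.4f)",
        len(centers), realized, target,
    )
    truth = GroundTruth(
        tablet_mask=BinaryMask(cylinder),
        pore_mask=BinaryMask(pore),
        matrix_mask=BinaryMask(matrix),
        pore_centers_vox=np.asarray(centers, dtype=float).reshape(-1, 3),
        pore_radii_vox=np.asarray(radii, dtype=float),
        realized_porosity=realized,
    )
    return VoxelVolume(values, spec.voxel_size_um), truth


def add_noise(vol: VoxelVolume, noise_sd: float, seed: int) -> VoxelVolume:
    """Additive zero-mean Gaussian gray-value noise, deterministic per seed."""
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    values = vol.values.astype(np.float32, copy=True)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values += rng.normal(0.0, noise_sd, size=values.shape).astype(np.float32)
    return VoxelVolume(values, vol.voxel_size_um)


def _step_seed(seed: int, step: int) -> int:
    """A stable per-timestep child seed below 2**31."""
    return int(np.random.SeedSequence([seed, step]).generate_state(1)[0] % (2**31))


def render_scan(clean: VoxelVolume, spec: PhantomSpec, seed: int) -> VoxelVolume:
    """Apply the imaging model: Gaussian PSF blur, then additive noise."""
    blurred = clean.values
    if spec.psf_sigma_vox > 0:
        blurred = ndi.gaussian_filter(clean.values.astype(np.float32), spec.psf_sigma_vox)
    return add_noise(VoxelVolume(blurred, clean.voxel_size_um), spec.noise_sd, seed)


def simulate_ingress(
    dry: VoxelVolume,
    truth: GroundTruth,
    spec: PhantomSpec,
    times_h,
) -> ScanSeries:
    """Simulate the flooded-cell dissolution scan series.

    At each timestep the dry core radius is r(t) = R - v*t (floored at 0);
    matrix voxels outside r(t) take the wetted-matrix gray level, pore
    voxels outside r(t) fill with brine, and the background (outside the
    tablet) is brine, mirroring a flooded flow cell.  Each step is imaged
    with the PSF + noise model under a per-step child seed, and the ground
    truth wet fraction and front radius are recorded on ``truth``.
    """
    times = np.asarray(times_h, dtype=float)
    if times.size == 0:
        raise ValidationError("times must be non-empty")
    if times[0] != 0 or (times.size > 1 and not np.all(np.diff(times) > 0)):
        raise ValidationError("times must start at 0 and increase strictly")
    cylinder = truth.tablet_mask.values
    matrix = truth.matrix_mask.values
    pore = truth.pore_mask.values
    _, rad2, _, _, r_vox, _ = _cylinder_geometry(spec)
    vs = spec.voxel_size_um
    matrix_count = int(matrix.sum())

    volumes = []
    wet_fracs = []
    front_radii = []
    for i, t in enumerate(times):
        r_mm = max(spec.tablet_radius_mm - spec.front_speed_mm_h * t, 0.0)
        r_front_vox = r_mm * 1000.0 / vs
        if r_front_vox > 1e-9:
            outside_front = rad2 > r_front_vox**2  # broadcasts over z
        else:  # fully penetrated: axis voxels (radius 0) wet too
            outside_front = np.ones_like(rad2, dtype=bool)
        values = np.full(dry.shape, spec.mu_brine, dtype=np.float32)
        values[matrix] = spec.mu_matrix
        values[pore] = spec.mu_background
        wet_matrix = matrix & outside_front
        values[wet_matrix] = spec.wet_matrix_gray
        values[pore & outside_front] = spec.mu_brine
        volumes.append(
            render_scan(VoxelVolume(values, vs), spec, _step_seed(spec.seed, i))
        )
        wet_fracs.append(int(wet_matrix.sum()) / matrix_count)
        front_radii.append(r_mm)

    truth.times_h = times
    truth.wet_fraction_per_time = np.asarray(wet_fracs)
    truth.front_radius_per_time_mm = np.asarray(front_radii)
    if np.any(np.diff(truth.wet_fraction_per_time) < 0):
        raise PhantomError("wet fraction must be non-decreasing in time")
    return ScanSeries(volumes, times)


def beer_lambert(i_in, mu, thickness):
    """Transmitted intensity I_out = I_in * exp(-mu * T).

    ``mu`` is the linear attenuation coefficient (1/length) and ``T`` the
    path thickness in matching length units.
    """
    i_in = np.asarray(i_in, dtype=float)
    mu = np.asarray(mu, dtype=float)
    thickness = np.asarray(thickness, dtype=float)
    if np.any(i_in <= 0):
        raise ValidationError("incident intensity must be > 0")
    if np.any(mu < 0) or np.any(thickness < 0):
        raise ValidationError("attenuation coefficient and thickness must be >= 0")
    out = i_in * np.exp(-mu * thickness)
    return float(out) if out.ndim == 0 else out


def radiograph(vol: VoxelVolume, i_in: float = 1.0e4, axis: int = 2,
               mu_per_gray_mm: float = 1.0e-3) -> np.ndarray:
    """Parallel-beam radiograph of a volume along one axis (demonstration).

    Gray values are mapped to linear attenuation coefficients via
    ``mu = gray * mu_per_gray_mm`` (1/mm) and the Beer-Lambert line integral
    is discretized per voxel: I = I_in * exp(-sum_k mu_k * dx).
    """
    mu_line = vol.values.astype(np.float64) * mu_per_gray_mm
    dx_mm = vol.voxel_size_um / 1000.0
    return beer_lambert(i_in, 1.0, mu_line.sum(axis=axis) * dx_mm)


def simulate_release(
    spec: PhantomSpec,
    times_h,
    dose_mg: float,
    calib: CalibrationCurve,
    seed: int,
    scheme: SamplingScheme | None = None,
    lag_h: float = 0.25,
    absorbance_noise_sd: float = 0.0,
):
    """Generate a matched sustained-release curve and its absorbance table.

    Release is proportional to the analytically wetted volume fraction of
    the shrinking-core model, delayed by ``lag_h`` (drug must dissolve and
    diffuse out after the front passes): with r(t) = R - v*max(t - lag, 0),
    release(t) = 100 * (1 - (r/R)^2).  The released masses are converted to
    medium concentrations under the sampling scheme (inverse of the
    withdrawal-corrected accounting in :func:`dissolvis.release.cumulative_release`),
    then to absorbances via the calibration forward map, optionally with
    measurement noise.  Returns ``(ReleaseProfile, absorbance DataFrame)``.
    """
    if not dose_mg > 0:
        raise ValidationError(f"dose must be > 0 mg, got {dose_mg}")
    times = np.asarray(times_h, dtype=float)
    if times.size == 0 or np.any(times < 0):
        raise ValidationError("times must be non-empty and non-negative")
    if scheme is None:
        scheme = SamplingScheme(timepoints_h=tuple(times))
    if not np.allclose(np.asarray(scheme.timepoints_h, dtype=float), times):
        raise ValidationError("scheme timepoints must match the requested times")

    r_rel = spec.tablet_radius_mm
    eff_t = np.maximum(times - lag_h, 0.0)
    r_core = np.maximum(r_rel - spec.front_speed_mm_h * eff_t, 0.0)
    release_pct = 100.0 * (1.0 - (r_core / r_rel) ** 2)
    profile = ReleaseProfile(times, release_pct)

    # invert the withdrawal-corrected accounting to per-sample concentrations
    mass_ug = release_pct / 100.0 * dose_mg * 1000.0
    v0, vs = scheme.medium_volume_ml, scheme.sample_volume_ml
    conc = np.empty_like(mass_ug)
    withdrawn = 0.0
    for i, m in enumerate(mass_ug):
        volume = v0 if scheme.replaced else v0 - i * vs
        conc[i] = (m - withdrawn) / volume
        withdrawn += conc[i] * vs
    absorb = calib.absorbance(conc)
    if absorbance_noise_sd > 0:
        rng = np.random.default_rng(seed)
        absorb = absorb + rng.normal(0.0, absorbance_noise_sd, size=absorb.shape)
    table = pd.DataFrame({"time_h": times, "absorbance": absorb})
    return profile, table
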