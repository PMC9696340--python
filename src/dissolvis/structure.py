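"""Static structural analysis of the dry scan and VOI preparation.

The dry, high-quality scan is denoised with an edge-preserving bilateral
filter, thresholded to segment the polymer matrix (keeping the largest
connected component to drop the sample holder and debris), and voxel
counting on the segmented masks yields the total porosity.  The dry scan is
rigidly registered (translation only -- in the emulated acquisition the
sample is fixed and only source/detector rotate) and resampled onto the
fast-scan grid, and the resulting volume-of-interest mask can be shrunk by
morphological erosion to discard partially wetted surface voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

from .errors import RegistrationError, SegmentationError, ValidationError
from .volio import BinaryMask, VoxelVolume

log = logging.getLogger(__name__)

__all__ = [
    "PorosityResult",
    "bilateral_filter",
    "segment_matrix",
    "segment_tablet",
    "compute_porosity",
    "register_resample",
    "shrink_voi",
    "otsu_threshold",
]

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class PorosityResult:
    """Voxel-counted total porosity: pore volume over total tablet volume."""

    porosity: float
    pore_voxels: int
    tablet_voxels: int  # total tablet voxels, pores included


def bilateral_filter(
    vol: VoxelVolume, sigma_spatial: float, sigma_range: float
) -> VoxelVolume:
    """Edge-preserving 3-D bilateral smoothing.

    Each voxel is replaced by a weighted mean of its neighbours, the weight
    being the product of a spatial Gaussian (``sigma_spatial``, voxels) and
    a gray-value Gaussian (``sigma_range``, gray units), so voxels across a
    strong edge contribute little and plateau levels are preserved.  The
    window is truncated at 2 * sigma_spatial.
    """
    if not (sigma_spatial > 0 and sigma_range > 0):
        raise ValidationError("bilateral filter sigmas must be > 0")
    values = vol.values.astype(np.float32)
    radius = max(1, int(np.ceil(2.0 * sigma_spatial)))
    pad = np.pad(values, radius, mode="reflect")
    num = np.zeros_like(values)
    den = np.zeros_like(values)
    nz, ny, nx = values.shape
    inv2ss = 1.0 / (2.0 * sigma_spatial**2)
    inv2sr = 1.0 / (2.0 * sigma_range**2)
    for dz in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            for dx in range(-radius, radius + 1):
                w_spatial = np.exp(-(dz * dz + dy * dy + dx * dx) * inv2ss)
                shifted = pad[
                    radius + dz : radius + dz + nz,
                    radius + dy : radius + dy + ny,
                    radius + dx : radius + dx + nx,
                ]
                diff = shifted - values
                w = w_spatial * np.exp(-(diff * diff) * inv2sr)
                num += w * shifted
                den += w
    return VoxelVolume(num / den, vol.voxel_size_um)


def otsu_threshold(vol: VoxelVolume) -> float:
    """Automatic two-class threshold (fallback when none is configured)."""
    from skimage.filters import threshold_otsu

    thr = float(threshold_otsu(vol.values))
    log.warning("no explicit threshold configured; Otsu fallback = %.3f", thr)
    return thr


def segment_matrix(
    vol: VoxelVolume, threshold: float, fill_pores: bool = False
) -> BinaryMask:
    """Threshold segmentation of the tablet matrix.

    Voxels with gray >= ``threshold`` are kept, then only the largest
    26-connected component survives (removing the surround and detached
    debris).  With ``fill_pores`` enclosed cavities are filled, turning the
    matrix mask into the full tablet mask (matrix + pore space).
    """
    lo, hi = float(vol.values.min()), float(vol.values.max())
    if not lo <= threshold <= hi:
        raise ValidationError(
            f"threshold {threshold} outside the volume gray range [{lo}, {hi}]"
        )
    fg = vol.values >= threshold
    if not fg.any():
        raise SegmentationError("no voxels above the threshold")
    labels, n = ndi.label(fg, structure=_CONNECTIVITY_26)
    if n == 0:
        raise SegmentationError("no connected component found")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    if fill_pores:
        mask = ndi.binary_fill_holes(mask)
    return BinaryMask(mask)


def segment_tablet(vol: VoxelVolume, threshold: float) -> tuple[BinaryMask, BinaryMask]:
    """Segment the full tablet and its pore space from a dry scan.

    Returns ``(tablet_mask, pore_mask)`` where the tablet mask is the
    largest bright component with enclosed pores filled and the pore mask
    is its sub-threshold interior.
    """
    tablet = segment_matrix(vol, threshold, fill_pores=True)
    pores = BinaryMask(tablet.values & (vol.values < threshold))
    return tablet, pores


def compute_porosity(tablet_mask: BinaryMask, pore_mask: BinaryMask) -> PorosityResult:
    """Exact voxel-count porosity: pore voxels / total tablet voxels."""
    if tablet_mask.shape != pore_mask.shape:
        raise ValidationError("tablet and pore masks must share one grid")
    if tablet_mask.count == 0:
        raise ValidationError("tablet mask is empty")
    if np.any(pore_mask.values & ~tablet_mask.values):
        raise ValidationError("pore mask must be a subset of the tablet mask")
    pore = pore_mask.count
    total = tablet_mask.count
    return PorosityResult(porosity=pore / total, pore_voxels=pore, tablet_voxels=total)


def register_resample(
    moving: VoxelVolume,
    reference: VoxelVolume,
    min_correlation: float = 0.2,
    upsample_factor: int = 20,
    full_output: bool = False,
):
    """Rigidly align ``moving`` to ``reference`` and resample onto its grid.

    Three-DoF translation only: the shift is found by cross-correlation
    maximization (with subvoxel refinement via Fourier upsampling) after an
    initial center-aligned rescale to the reference voxel size, and the
    final volume is produced by a single trilinear interpolation pass.
    Voxel sizes may differ (e.g. a 10.09 um dry scan onto a 20.18 um fast
    grid).  Raises :class:`RegistrationError` if the Pearson correlation of
    the aligned volumes falls below ``min_correlation``.
    """
    factor = reference.voxel_size_um / moving.voxel_size_um
    c_ref = (np.asarray(reference.shape, dtype=float) - 1.0) / 2.0
    c_mov = (np.asarray(moving.shape, dtype=float) - 1.0) / 2.0
    mov_values = moving.values.astype(np.float32)
    cval = float(moving.values.min())

    def sample(shift, box=None):
        axes = [
            np.arange(n, dtype=float)[sl]
            for n, sl in zip(reference.shape, box or (slice(None),) * 3)
        ]
        grids = np.meshgrid(*axes, indexing="ij")
        coords = [
            c_mov[a] + (grids[a] - shift[a] - c_ref[a]) * factor for a in range(3)
        ]
        return ndi.map_coordinates(
            mov_values, coords, order=1, mode="constant", cval=cval
        )

    def pearson(a, b):
        a, b = a.ravel(), b.ravel()
        denom = a.std() * b.std()
        if denom == 0:
            return 0.0
        return float(((a - a.mean()) * (b - b.mean())).mean() / denom)

    # integer-voxel estimate by cross-correlation maximization
    initial = sample(np.zeros(3))
    shift0, _, _ = phase_cross_correlation(
        reference.values.astype(np.float32), initial, upsample_factor=1,
        normalization=None,
    )
    # subvoxel refinement: maximize normalized cross-correlation over a
    # continuous translation, evaluated on a boundary-trimmed core region
    trim = int(np.ceil(np.abs(shift0).max())) + 2
    box = tuple(
        slice(min(trim, n // 4), max(n - trim, n - n // 4)) for n in reference.shape
    )
    ref_core = reference.values[box].astype(np.float32)

    from scipy.optimize import minimize

    res = minimize(
        lambda s: -pearson(sample(s, box), ref_core),
        np.asarray(shift0, dtype=float),
        method="Powell",
        options={"xtol": 1e-3, "ftol": 1e-8, "maxiter": 50},
    )
    shift = res.x
    # snap to whole voxels when the refinement is within optimizer tolerance
    # of an integer shift, avoiding a needless interpolation pass
    near = np.abs(shift - np.round(shift)) < 1e-2
    shift[near] = np.round(shift[near])
    aligned = sample(shift)
    corr = pearson(sample(shift, box), ref_core)
    if corr < min_correlation:
        raise RegistrationError(
            f"registration correlation {corr:.3f} below floor {min_correlation} "
            f"(estimated shift {np.round(shift, 3).tolist()} reference voxels)"
        )
    log.info("registration shift %s ref-voxels, correlation %.4f", shift, corr)
    out = VoxelVolume(aligned, reference.voxel_size_um)
    if full_output:
        return out, np.asarray(shift, dtype=float), corr
    return out


def shrink_voi(mask: BinaryMask, iterations: int) -> BinaryMask:
    """Erode the VOI with a 6-connected element, ``iterations`` times.

    Anti-extensive (result is a subset of the input); erosion to an empty
    mask raises with the iteration index at which it happened.
    """
    if iterations < 0:
        raise ValidationError("iterations must be >= 0")
    structure = ndi.generate_binary_structure(3, 1)  # 6-connected
    current = mask.values.copy()
    for i in range(iterations):
        current = ndi.binary_erosion(current, structure=structure)
        if not current.any():
            raise SegmentationError(f"VOI eroded to empty at iteration {i + 1}")
    return BinaryMask(current)
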