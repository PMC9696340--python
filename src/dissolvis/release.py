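"""Dissolution-profile quantification and comparison.

Covers the wet-chemistry side of an in-situ dissolution experiment: a linear
UV calibration (Beer-Lambert in the spectrophotometer regime), conversion of
sampled absorbances to cumulative percent of dose released with a withdrawal
correction for the sequentially removed aliquots, and the regulatory f2
similarity factor

    f2 = 50 * log10( 100 / sqrt(1 + (1/n) * sum_t (R_t - T_t)^2) )

over n shared timepoints; f2 = 100 for identical profiles and f2 >= 50 is
the conventional similarity criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "CalibrationCurve",
    "ReleaseProfile",
    "SamplingScheme",
    "fit_calibration",
    "to_concentration",
    "cumulative_release",
    "similarity_f2",
    "compare_penetration_release",
]


@dataclass
class CalibrationCurve:
    """Linear absorbance-vs-concentration calibration at a fixed wavelength."""

    slope: float  # absorbance per (ug/mL)
    intercept: float  # absorbance
    r_squared: float
    lambda_max_nm: float
    valid_range: tuple[float, float]  # ug/mL

    def __post_init__(self):
        if not self.slope > 0:
            raise ValidationError(f"calibration slope must be > 0, got {self.slope}")
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValidationError(f"invalid calibration range {self.valid_range}")

    def absorbance(self, concentration_ug_ml):
        """Forward map: concentration -> absorbance."""
        return self.slope * np.asarray(concentration_ug_ml, dtype=float) + self.intercept


@dataclass
class ReleaseProfile:
    """Cumulative percent of dose released at strictly increasing times (h)."""

    times_h: np.ndarray
    release_pct: np.ndarray

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.release_pct = np.asarray(self.release_pct, dtype=float)
        if self.times_h.shape != self.release_pct.shape or self.times_h.ndim != 1:
            raise ValidationError("times and release values must be equal-length vectors")
        if len(self.times_h) > 1 and not np.all(np.diff(self.times_h) > 0):
            raise ValidationError("release profile times must be strictly increasing")
        if np.any(self.release_pct < 0) or np.any(self.release_pct > 105):
            raise ValidationError("release_pct outside [0, 105] (assay-noise tolerance)")


# Timepoints (h) of the standard sampling schedule used throughout.
STANDARD_TIMEPOINTS_H = (
    0.25, 0.5, 0.75, 1, 1.5, 2, 2.5, 3, 3.5, 4, 5, 6, 7, 8, 10,
)


@dataclass
class SamplingScheme:
    """Medium volume and aliquot withdrawal plan for a dissolution run.

    ``replaced=False`` models a closed loop where each withdrawn aliquot
    shrinks the circulating medium; ``replaced=True`` assumes fresh medium
    tops the vessel back up after each sample.
    """

    medium_volume_ml: float = 900.0
    sample_volume_ml: float = 5.0
    timepoints_h: tuple = STANDARD_TIMEPOINTS_H
    replaced: bool = False

    def __post_init__(self):
        if self.sample_volume_ml * len(self.timepoints_h) >= self.medium_volume_ml:
            raise ValidationError("withdrawals would exhaust the dissolution medium")


def fit_calibration(concentrations_ug_ml, absorbances, lambda_max_nm: float) -> CalibrationCurve:
    """Ordinary least-squares line through absorbance standards.

    Requires at least three standards with nonzero concentration spread;
    the valid range is the span of the standards.
    """
    c = np.asarray(concentrations_ug_ml, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.shape != a.shape or c.ndim != 1:
        raise ValidationError("standards must be paired 1-D vectors")
    if len(c) < 3:
        raise ValidationError(f"need >= 3 calibration standards, got {len(c)}")
    if np.ptp(c) == 0:
        raise ValidationError("calibration standards have zero concentration spread")
    res = stats.linregress(c, a)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        lambda_max_nm=lambda_max_nm,
        valid_range=(float(c.min()), float(c.max())),
    )


def to_concentration(absorbance, calib: CalibrationCurve):
    """Invert the calibration: (A - intercept) / slope, in ug/mL.

    Emits a warning (never an error) when the result falls outside the
    calibrated concentration range.
    """
    a = np.asarray(absorbance, dtype=float)
    c = (a - calib.intercept) / calib.slope
    lo, hi = calib.valid_range
    if np.any(c < lo) or np.any(c > hi):
        warnings.warn(
            f"concentration outside calibrated range [{lo}, {hi}] ug/mL; extrapolating",
            stacklevel=2,
        )
    return float(c) if np.isscalar(absorbance) else c


def cumulative_release(concentrations_ug_ml, scheme: SamplingScheme, dose_mg: float) -> ReleaseProfile:
    """Cumulative percent released with withdrawal correction.

    With sequential aliquots of volume ``Vs`` taken from a medium of initial
    volume ``V`` (closed loop, not replaced), the total mass released by
    sample ``i`` is

        m_i = C_i * (V - i*Vs) + sum_{j<i} C_j * Vs

    i.e. what is still dissolved in the (shrunken) medium plus everything
    carried away by earlier aliquots.  With ``scheme.replaced`` the medium
    volume stays at ``V`` and the first term is ``C_i * V``.
    """
    if not dose_mg > 0:
        raise ValidationError(f"dose must be > 0 mg, got {dose_mg}")
    conc = np.asarray(concentrations_ug_ml, dtype=float)
    times = np.asarray(scheme.timepoints_h, dtype=float)
    if conc.shape != times.shape:
        raise ValidationError(
            f"{len(conc)} concentrations for {len(times)} scheduled timepoints"
        )
    v0, vs = scheme.medium_volume_ml, scheme.sample_volume_ml
    withdrawn_ug = 0.0
    mass_ug = np.empty_like(conc)
    for i, c in enumerate(conc):
        volume = v0 if scheme.replaced else v0 - i * vs
        mass_ug[i] = c * volume + withdrawn_ug
        withdrawn_ug += c * vs
    return ReleaseProfile(times, mass_ug / (dose_mg * 1000.0) * 100.0)


def _shared_points(reference: ReleaseProfile, test: ReleaseProfile, atol: float = 1e-9):
    idx_r, idx_t = [], []
    for i, t in enumerate(reference.times_h):
        j = np.flatnonzero(np.isclose(test.times_h, t, atol=atol, rtol=0.0))
        if j.size:
            idx_r.append(i)
            idx_t.append(int(j[0]))
    return np.asarray(idx_r, dtype=int), np.asarray(idx_t, dtype=int)


def similarity_f2(reference: ReleaseProfile, test: ReleaseProfile, fda_rule: bool = False) -> float:
    """f2 similarity factor over the profiles' shared timepoints.

    No interpolation is performed: timepoints must match (to 1e-9 h) and at
    least three shared points are required.  With ``fda_rule`` the point set
    is truncated one timepoint beyond 85% release of the reference, the
    common regulatory convention for nearly complete profiles.
    """
    idx_r, idx_t = _shared_points(reference, test)
    r = reference.release_pct[idx_r]
    t = test.release_pct[idx_t]
    if fda_rule:
        above = np.flatnonzero(r >= 85.0)
        if above.size:
            keep = min(above[0] + 1, len(r) - 1)
            r, t = r[: keep + 1], t[: keep + 1]
    if len(r) < 3:
        raise ValidationError(
            f"f2 requires >= 3 shared timepoints, found {len(r)}"
        )
    msd = float(np.mean((r - t) ** 2))
    return float(50.0 * np.log10(100.0 / np.sqrt(1.0 + msd)))


def compare_penetration_release(
    pen_times_h,
    pen_fraction,
    rel: ReleaseProfile,
    band_pct: float = 5.0,
):
    """Align a water-penetration profile with a release profile over time.

    The penetration profile (fraction of matrix voxels classified wet) is
    expressed in percent and both curves are linearly interpolated onto the
    union of their timepoints within the overlapping time range.  Returns a
    ``(table, divergence_time_h)`` pair where the table holds per-time values
    and differences, and the divergence time is the first time the absolute
    difference exceeds ``band_pct`` (None if it never does).
    """
    pt = np.asarray(pen_times_h, dtype=float)
    pv = np.asarray(pen_fraction, dtype=float) * 100.0
    if pt.ndim != 1 or pt.shape != pv.shape or len(pt) == 0:
        raise ValidationError("penetration profile must be paired non-empty vectors")
    lo = max(pt.min(), rel.times_h.min())
    hi = min(pt.max(), rel.times_h.max())
    if not lo <= hi:
        raise ValidationError("penetration and release profiles do not overlap in time")
    grid = np.union1d(pt, rel.times_h)
    grid = grid[(grid >= lo) & (grid <= hi)]
    pen_i = np.interp(grid, pt, pv)
    rel_i = np.interp(grid, rel.times_h, rel.release_pct)
    diff = pen_i - rel_i
    table = pd.DataFrame(
        {
            "time_h": grid,
            "penetration_pct": pen_i,
            "release_pct": rel_i,
            "difference_pct": diff,
        }
    )
    exceed = np.flatnonzero(np.abs(diff) > band_pct)
    divergence = float(grid[exceed[0]]) if exceed.size else None
    return table, divergence
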