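"""Time-resolved wet/dry discrimination inside the tablet matrix VOI.

As contrast-agent brine penetrates the matrix, the VOI gray-value histogram
develops a second, higher-attenuation peak; fitting one Gaussian to the dry
mode of the first timestep and one to the wetted mode of the last, the gray
value where the two weighted densities intersect is the natural single
threshold separating dry from wet.  Simple thresholding mislabels voxels
with intermediate gray values (partial-volume voxels at surfaces and pore
walls), so a K-nearest-neighbour classifier is trained on the first scan
(all voxels labelled dry) and the last scan (all wet), using per-voxel
coordinates, gray value, and Euclidean distance to the nearest background
voxel as features; the penetration profile is the fraction of VOI voxels
classified wet at each timestep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import curve_fit
from sklearn.neighbors import NearestNeighbors

from .errors import FitError, ValidationError
from .volio import BinaryMask, ScanSeries, VoxelVolume

log = logging.getLogger(__name__)

__all__ = [
    "HistogramModel",
    "GaussianComponent",
    "VoxelFeatures",
    "WettingClassifier",
    "PenetrationProfile",
    "voi_histogram",
    "series_gray_range",
    "count_histogram_modes",
    "fit_gaussian",
    "gaussian_intersection",
    "threshold_classify",
    "extract_features",
    "train_knn",
    "classify_series",
    "penetration_profile",
]


@dataclass
class HistogramModel:
    """Gray-value histogram of the masked VOI voxels."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValidationError("need len(edges) == len(counts) + 1")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass(frozen=True)
class GaussianComponent:
    """One weighted Gaussian mode of a histogram (weight = voxel count)."""

    mean: float
    sd: float
    weight: float

    def __post_init__(self):
        if not self.sd > 0:
            raise ValidationError(f"sd must be > 0, got {self.sd}")
        if not self.weight > 0:
            raise ValidationError(f"weight must be > 0, got {self.weight}")

    def density(self, x):
        x = np.asarray(x, dtype=float)
        return (
            self.weight
            / (self.sd * np.sqrt(2.0 * np.pi))
            * np.exp(-0.5 * ((x - self.mean) / self.sd) ** 2)
        )


@dataclass
class VoxelFeatures:
    """Per-voxel classifier features for the VOI foreground.

    ``coords`` are 0-based (x, y, z) voxel indices, ``gray`` the gray value,
    ``edt`` the exact Euclidean distance (voxels) to the nearest background
    (non-VOI) voxel.
    """

    coords: np.ndarray  # (n, 3) int, columns x, y, z
    gray: np.ndarray  # (n,)
    edt: np.ndarray  # (n,)

    def matrix(self) -> np.ndarray:
        """Stacked (n, 5) feature matrix: x, y, z, gray, edt."""
        return np.column_stack(
            [self.coords.astype(np.float64), self.gray, self.edt]
        )

    def __len__(self) -> int:
        return len(self.gray)


def voi_histogram(
    vol: VoxelVolume,
    mask: BinaryMask,
    n_bins: int = 256,
    gray_range: tuple[float, float] | None = None,
) -> HistogramModel:
    """Histogram of masked voxels over a shared gray range.

    Passing the global series gray range keeps bins comparable over time.
    Values outside the range are clipped into the edge bins so counts always
    sum to the VOI voxel count.
    """
    mask.check_matches(vol)
    if mask.count == 0:
        raise ValidationError("VOI mask is empty")
    data = vol.values[mask.values]
    if gray_range is None:
        gray_range = (float(data.min()), float(data.max()))
    lo, hi = gray_range
    if not lo < hi:
        hi = lo + 1.0
    counts, edges = np.histogram(np.clip(data, lo, hi), bins=n_bins, range=(lo, hi))
    return HistogramModel(edges, counts)


def series_gray_range(series: ScanSeries, mask: BinaryMask) -> tuple[float, float]:
    """Global (min, max) gray value over the VOI across the whole series."""
    lo = min(float(v.values[mask.values].min()) for v in series.volumes)
    hi = max(float(v.values[mask.values].max()) for v in series.volumes)
    return lo, hi


def count_histogram_modes(
    hist: HistogramModel,
    smooth_bins: float = 3.0,
    min_height_frac: float = 0.10,
    min_separation_bins: int = 3,
) -> int:
    """Number of distinct local maxima of a (smoothed) histogram.

    Used to follow the unimodal -> bimodal -> unimodal transition of the
    VOI histogram over a dissolution series.  Peaks lower than
    ``min_height_frac`` of the tallest or closer than
    ``min_separation_bins`` to a taller peak are not counted.
    """
    smooth = ndi.gaussian_filter1d(hist.counts.astype(float), smooth_bins)
    peaks = [
        i
        for i in range(1, len(smooth) - 1)
        if smooth[i] >= smooth[i - 1] and smooth[i] > smooth[i + 1]
    ]
    if not peaks:
        return 0
    floor = min_height_frac * smooth.max()
    peaks = [i for i in peaks if smooth[i] >= floor]
    peaks.sort(key=lambda i: -smooth[i])
    kept: list[int] = []
    for i in peaks:
        if all(abs(i - j) >= min_separation_bins for j in kept):
            kept.append(i)
    return len(kept)


def fit_gaussian(
    hist: HistogramModel, window: tuple[float, float] | None = None
) -> GaussianComponent:
    """Nonlinear least-squares fit of one weighted Gaussian to bin counts.

    ``window`` restricts the fit to a gray range (used to isolate one mode
    of a bimodal histogram); it must contain at least five nonzero bins.
    The fitted weight is the implied voxel count of the mode.
    """
    x = hist.centers
    y = hist.counts.astype(float)
    if window is not None:
        lo, hi = window
        keep = (x >= lo) & (x <= hi)
        x, y = x[keep], y[keep]
    if int((y > 0).sum()) < 5:
        raise FitError("fit window contains fewer than 5 nonzero bins")
    total = y.sum()
    mean0 = float((x * y).sum() / total)
    sd0 = float(np.sqrt(((x - mean0) ** 2 * y).sum() / total)) or hist.bin_width

    def model(x, weight, mean, sd):
        return (
            weight
            * hist.bin_width
            / (np.abs(sd) * np.sqrt(2 * np.pi))
            * np.exp(-0.5 * ((x - mean) / sd) ** 2)
        )

    try:
        popt, _ = curve_fit(
            model, x, y, p0=[total, mean0, sd0], maxfev=10_000
        )
    except RuntimeError as exc:
        resid = float(np.abs(y - model(x, total, mean0, sd0)).sum())
        raise FitError(
            f"Gaussian fit did not converge (initial residual {resid:.3g})"
        ) from exc
    weight, mean, sd = float(popt[0]), float(popt[1]), float(abs(popt[2]))
    return GaussianComponent(mean=mean, sd=sd, weight=weight)


def gaussian_intersection(a: GaussianComponent, b: GaussianComponent) -> float:
    """Gray value between the means where the weighted densities are equal.

    Closed-form: equating the two weighted normal densities and taking logs
    gives a quadratic in x; the root strictly between the means is the
    classification threshold (gray >= threshold => wet, since the contrast
    agent raises attenuation).
    """
    if not a.mean < b.mean:
        raise ValidationError(
            f"components must be ordered by mean, got {a.mean} >= {b.mean}"
        )
    log_ratio = np.log((a.weight * b.sd) / (b.weight * a.sd))
    if np.isclose(a.sd, b.sd, rtol=1e-12, atol=0.0):
        # equal variances: the quadratic degenerates to a line
        s2 = a.sd * b.sd
        x = 0.5 * (a.mean + b.mean) + s2 * log_ratio / (b.mean - a.mean)
        if not a.mean < x < b.mean:
            raise ValidationError(
                "no intersection strictly between the means (weights too unequal)"
            )
        return float(x)
    # (x-mu_a)^2/sa^2 - (x-mu_b)^2/sb^2 = 2*log_ratio
    c2 = 1.0 / a.sd**2 - 1.0 / b.sd**2
    c1 = -2.0 * (a.mean / a.sd**2 - b.mean / b.sd**2)
    c0 = a.mean**2 / a.sd**2 - b.mean**2 / b.sd**2 - 2.0 * log_ratio
    roots = np.roots([c2, c1, c0])
    roots = roots[np.isreal(roots)].real
    inside = roots[(roots > a.mean) & (roots < b.mean)]
    if inside.size == 0:
        raise ValidationError("no density intersection strictly between the means")
    return float(inside[0])


def threshold_classify(
    vol: VoxelVolume, mask: BinaryMask, threshold: float
) -> BinaryMask:
    """Wet mask: VOI voxels with gray >= threshold."""
    mask.check_matches(vol)
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    return BinaryMask(mask.values & (vol.values >= threshold))


def extract_features(vol: VoxelVolume, mask: BinaryMask) -> VoxelFeatures:
    """Per-voxel (x, y, z, gray, EDT) features of the VOI foreground.

    The EDT is the exact Euclidean distance transform of the mask in voxel
    units (distance to the nearest voxel outside the VOI).
    """
    mask.check_matches(vol)
    if mask.count == 0:
        raise ValidationError("VOI mask is empty")
    edt = ndi.distance_transform_edt(mask.values)
    zz, yy, xx = np.nonzero(mask.values)
    coords = np.column_stack([xx, yy, zz])
    return VoxelFeatures(
        coords=coords,
        gray=vol.values[zz, yy, xx].astype(np.float64),
        edt=edt[zz, yy, xx],
    )


@dataclass
class WettingClassifier:
    """KNN wet/dry voxel classifier in standardized feature space.

    Features are z-scored with the training mean/sd; votes use the
    Euclidean metric.  On an exact vote tie (possible for even k) the label
    of the single nearest neighbour decides -- a deterministic, local rule.
    """

    k: int
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    train_features: np.ndarray  # standardized (n, 5)
    train_labels: np.ndarray  # (n,) bool, True = wet
    validation_error: float
    _nn: NearestNeighbors = field(repr=False, default=None)

    def _index(self) -> NearestNeighbors:
        if self._nn is None:
            self._nn = NearestNeighbors(n_neighbors=self.k).fit(self.train_features)
        return self._nn

    def standardize(self, features: np.ndarray) -> np.ndarray:
        return (features - self.feature_mean) / self.feature_sd

    def predict(self, features: np.ndarray, chunk: int = 200_000) -> np.ndarray:
        """Wet/dry prediction for raw (n, 5) feature rows (True = wet)."""
        x = self.standardize(np.asarray(features, dtype=np.float64))
        out = np.empty(len(x), dtype=bool)
        index = self._index()
        for start in range(0, len(x), chunk):
            sl = slice(start, start + chunk)
            _, ind = index.kneighbors(x[sl])
            votes = self.train_labels[ind].sum(axis=1)
            wet = votes * 2 > self.k
            tie = votes * 2 == self.k
            if tie.any():
                wet[tie] = self.train_labels[ind[tie, 0]]
            out[sl] = wet
        return out


def train_knn(
    first: VoxelFeatures,
    last: VoxelFeatures,
    k: int = 10,
    validation_fraction: float = 0.10,
    seed: int = 0,
) -> WettingClassifier:
    """Train the wet/dry KNN from the first (dry) and last (wet) scans.

    All first-scan voxels are labelled dry and all last-scan voxels wet; a
    random ``validation_fraction`` is held out (seeded) to report the
    validation error, and the classifier keeps the remaining samples.
    """
    if len(first) == 0 or len(last) == 0:
        raise ValidationError("training feature sets must be non-empty")
    if k < 1:
        raise ValidationError("k must be >= 1")
    x = np.vstack([first.matrix(), last.matrix()])
    y = np.concatenate(
        [np.zeros(len(first), dtype=bool), np.ones(len(last), dtype=bool)]
    )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(x))
    n_val = int(round(validation_fraction * len(x)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if k > len(train_idx):
        raise ValidationError(f"k={k} exceeds training size {len(train_idx)}")
    mean = x[train_idx].mean(axis=0)
    sd = x[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    clf = WettingClassifier(
        k=k,
        feature_mean=mean,
        feature_sd=sd,
        train_features=(x[train_idx] - mean) / sd,
        train_labels=y[train_idx],
        validation_error=0.0,
    )
    if n_val > 0:
        pred = clf.predict(x[val_idx])
        clf.validation_error = float((pred != y[val_idx]).mean())
    log.info(
        "KNN trained on %d voxels (k=%d), validation error %.4f",
        len(train_idx), k, clf.validation_error,
    )
    return clf


def classify_series(
    clf: WettingClassifier, series: ScanSeries, mask: BinaryMask
) -> list[BinaryMask]:
    """Wet mask for every timestep of the series over a fixed VOI."""
    mask.check_matches(series.volumes[0])
    masks = []
    for vol in series.volumes:
        feats = extract_features(vol, mask)
        wet = clf.predict(feats.matrix())
        grid = np.zeros(mask.shape, dtype=bool)
        grid[feats.coords[:, 2], feats.coords[:, 1], feats.coords[:, 0]] = wet
        masks.append(BinaryMask(grid))
    return masks


def penetration_profile(
    wet_masks: list[BinaryMask], mask: BinaryMask, times_h
) -> "PenetrationProfile":
    """Fraction of VOI voxels classified wet at each timestep."""
    if len(wet_masks) == 0:
        raise ValidationError("need at least one timestep")
    total = mask.count
    if total == 0:
        raise ValidationError("VOI mask is empty")
    fracs = np.array(
        [int((w.values & mask.values).sum()) / total for w in wet_masks]
    )
    return PenetrationProfile(np.asarray(times_h, dtype=float), fracs)


@dataclass
class PenetrationProfile:
    """Wet VOI fraction over time (the water-penetration profile)."""

    times_h: np.ndarray
    wet_fraction: np.ndarray

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.wet_fraction = np.asarray(self.wet_fraction, dtype=float)
        if self.times_h.shape != self.wet_fraction.shape:
            raise ValidationError("times and fractions must have equal length")
        if np.any((self.wet_fraction < 0) | (self.wet_fraction > 1)):
            raise ValidationError("wet fractions must lie in [0, 1]")
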