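"""End-to-end orchestration: phantom -> structure -> wetting -> release.

A single :class:`RunConfig` (loadable from YAML) drives the whole analysis:
generate or load a dissolution scan series, segment the dry scan into the
matrix VOI and measure porosity, determine the wetting threshold from the
Gaussian intersection of the first/last shrunk-VOI histograms, classify
every timestep by thresholding and by KNN, quantify the matched release
curve from absorbances, and compare penetration against release (f2 and
divergence time).  Every artifact is written to the run directory; outputs
are bit-reproducible for a fixed config (wall times go to a separate log).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, phantom, release, structure, volio, wetting
from .errors import DissolvisError, StageError, ValidationError

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "default_demo_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run.

    Every stochastic stage derives its randomness from the explicit seeds
    here; the config is serialized into the run report for provenance.
    """

    seed: int
    phantom_spec: phantom.PhantomSpec
    times_h: tuple = (0.0, 1.6, 3.2, 4.8, 6.4, 8.0)
    matrix_threshold: float | None = 50.0  # explicit; None -> logged Otsu fallback
    sigma_spatial: float = 1.5
    sigma_range: float = 15.0
    shrink_iterations: int = 2
    n_bins: int = 256
    k: int = 10
    validation_fraction: float = 0.10
    dose_mg: float = 65.6
    calib_slope: float = 0.02  # absorbance per ug/mL
    calib_intercept: float = 0.001
    lambda_max_nm: float = 223.0
    standards_ug_ml: tuple = (5.0, 10.0, 20.0, 30.0, 40.0, 60.0, 80.0)
    standards_noise_sd: float = 0.002
    release_lag_h: float = 0.25
    absorbance_noise_sd: float = 0.001
    band_pct: float = 5.0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "seed" not in raw:
            raise ValidationError("config must set an explicit 'seed'")
        spec_raw = raw.pop("phantom", {})
        if "seed" not in spec_raw:
            spec_raw["seed"] = raw["seed"]
        try:
            spec = phantom.PhantomSpec(**spec_raw)
        except TypeError as exc:
            raise ValidationError(f"bad phantom spec: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)} - {"phantom_spec"}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "times_h" in raw:
            raw["times_h"] = tuple(raw["times_h"])
        if "standards_ug_ml" in raw:
            raw["standards_ug_ml"] = tuple(raw["standards_ug_ml"])
        return cls(phantom_spec=spec, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} is not a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom_spec"] = dataclasses.asdict(self.phantom_spec)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_demo_config(seed: int = 1) -> RunConfig:
    """Desk-scale demo: a 64^3 phantom over six timesteps up to 8 h."""
    spec = phantom.PhantomSpec(seed=seed).scaled(
        0.112, pore_radius_mean_um=80.0, pore_radius_sd_um=10.0, margin_vox=3
    )
    return RunConfig(seed=seed, phantom_spec=spec)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full analysis; returns the report dict.

    Any stage failure is re-raised as :class:`StageError` carrying the
    stage name; artifacts written before the failure are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
    }
    timings: list[str] = []

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except DissolvisError as exc:
            _json_dump(report, outdir / "report.json")
            raise StageError(name, exc) from exc
        timings.append(f"{name}: {time.perf_counter() - t0:.2f} s")
        log.info("stage %s done", name)
        return out

    spec = config.phantom_spec

    def _phantom():
        dry_clean, truth = phantom.build_tablet(spec)
        series = phantom.simulate_ingress(dry_clean, truth, spec, config.times_h)
        # large fixed tag keeps the dry-scan noise stream apart from timesteps
        dry_scan = phantom.render_scan(dry_clean, spec, phantom._step_seed(spec.seed, 999_983))
        volio.write_series(series, outdir / "scans")
        volio.write_mask(truth.matrix_mask, outdir / "truth" / "matrix_mask.tif")
        volio.write_mask(truth.pore_mask, outdir / "truth" / "pore_mask.tif")
        volio.write_profile_csv(
            truth.times_h, truth.wet_fraction_per_time,
            outdir / "truth" / "wet_fraction.csv", value_column="wet_fraction",
        )
        return dry_scan, truth, series

    dry_scan, truth, series = stage("phantom", _phantom)

    def _structure():
        filtered = structure.bilateral_filter(
            dry_scan, config.sigma_spatial, config.sigma_range
        )
        thr = config.matrix_threshold
        if thr is None:
            thr = structure.otsu_threshold(filtered)
        tablet_mask, pore_mask = structure.segment_tablet(filtered, thr)
        matrix_mask = volio.BinaryMask(tablet_mask.values & ~pore_mask.values)
        por = structure.compute_porosity(tablet_mask, pore_mask)
        _json_dump(
            {
                "threshold": thr,
                "porosity": por.porosity,
                "pore_voxels": por.pore_voxels,
                "tablet_voxels": por.tablet_voxels,
            },
            outdir / "porosity.json",
        )
        volio.write_mask(matrix_mask, outdir / "matrix_mask.tif")
        return matrix_mask, por, thr

    matrix_mask, porosity_result, matrix_threshold = stage("structure", _structure)

    def _wetting():
        voi = matrix_mask
        shrunk = structure.shrink_voi(voi, config.shrink_iterations)
        gray_range = wetting.series_gray_range(series, voi)
        hist_first = wetting.voi_histogram(
            series.volumes[0], shrunk, config.n_bins, gray_range
        )
        hist_last = wetting.voi_histogram(
            series.volumes[-1], shrunk, config.n_bins, gray_range
        )
        g_dry = wetting.fit_gaussian(hist_first)
        g_wet = wetting.fit_gaussian(hist_last)
        threshold = wetting.gaussian_intersection(g_dry, g_wet)

        thr_masks = [
            wetting.threshold_classify(v, voi, threshold) for v in series.volumes
        ]
        pen_thr = wetting.penetration_profile(thr_masks, voi, series.times_h)

        first = wetting.extract_features(series.volumes[0], voi)
        last = wetting.extract_features(series.volumes[-1], voi)
        clf = wetting.train_knn(
            first, last, k=config.k,
            validation_fraction=config.validation_fraction, seed=config.seed,
        )
        knn_masks = wetting.classify_series(clf, series, voi)
        pen_knn = wetting.penetration_profile(knn_masks, voi, series.times_h)

        for i, m in enumerate(knn_masks):
            volio.write_mask(m, outdir / "wet_masks" / f"knn_{i:03d}.tif")
        volio.write_profile_csv(
            pen_thr.times_h, pen_thr.wet_fraction,
            outdir / "penetration_threshold.csv", value_column="wet_fraction",
        )
        volio.write_profile_csv(
            pen_knn.times_h, pen_knn.wet_fraction,
            outdir / "penetration_knn.csv", value_column="wet_fraction",
        )
        _json_dump(
            {
                "threshold": threshold,
                "gaussian_dry": dataclasses.asdict(g_dry),
                "gaussian_wet": dataclasses.asdict(g_wet),
                "knn_k": config.k,
                "knn_validation_error": clf.validation_error,
            },
            outdir / "wetting_report.json",
        )
        return pen_thr, pen_knn, threshold, clf

    pen_thr, pen_knn, wet_threshold, clf = stage("wetting", _wetting)

    def _release():
        rng = np.random.default_rng(config.seed)
        conc = np.asarray(config.standards_ug_ml, dtype=float)
        absorb = (
            config.calib_slope * conc
            + config.calib_intercept
            + rng.normal(0.0, config.standards_noise_sd, size=conc.shape)
        )
        calib = release.fit_calibration(conc, absorb, config.lambda_max_nm)
        gen_calib = release.CalibrationCurve(
            config.calib_slope, config.calib_intercept, 1.0,
            config.lambda_max_nm, (float(conc.min()), float(conc.max())),
        )
        times = np.asarray(release.STANDARD_TIMEPOINTS_H, dtype=float)
        scheme = release.SamplingScheme(timepoints_h=tuple(times))
        true_profile, absorb_table = phantom.simulate_release(
            spec, times, config.dose_mg, gen_calib, seed=config.seed,
            scheme=scheme, lag_h=config.release_lag_h,
            absorbance_noise_sd=config.absorbance_noise_sd,
        )
        measured_conc = release.to_concentration(
            absorb_table["absorbance"].to_numpy(), calib
        )
        measured = release.cumulative_release(
            np.clip(measured_conc, 0.0, None), scheme, config.dose_mg
        )
        f2 = release.similarity_f2(true_profile, measured)
        table, divergence = release.compare_penetration_release(
            pen_knn.times_h, pen_knn.wet_fraction, measured, band_pct=config.band_pct
        )
        volio.write_profile_csv(
            measured.times_h, measured.release_pct, outdir / "release_measured.csv"
        )
        absorb_table.to_csv(outdir / "absorbances.csv", index=False)
        table.to_csv(outdir / "penetration_vs_release.csv", index=False)
        _json_dump(
            {
                "calibration": dataclasses.asdict(calib),
                "f2_measured_vs_generating": f2,
                "divergence_time_h": divergence,
            },
            outdir / "release_report.json",
        )
        _plot_comparison(pen_knn, measured, outdir / "penetration_vs_release.png")
        return measured, f2, divergence

    measured, f2, divergence = stage("release", _release)

    report.update(
        {
            "porosity": porosity_result.porosity,
            "matrix_threshold": matrix_threshold,
            "wetting_threshold": wet_threshold,
            "knn_validation_error": clf.validation_error,
            "penetration_knn": {
                "times_h": pen_knn.times_h.tolist(),
                "wet_fraction": pen_knn.wet_fraction.tolist(),
            },
            "penetration_threshold": {
                "times_h": pen_thr.times_h.tolist(),
                "wet_fraction": pen_thr.wet_fraction.tolist(),
            },
            "truth_wet_fraction": truth.wet_fraction_per_time.tolist(),
            "f2_measured_vs_generating": f2,
            "divergence_time_h": divergence,
        }
    )
    _json_dump(report, outdir / "report.json")
    (outdir / "timings.log").write_text("\n".join(timings) + "\n")
    return report


def _plot_comparison(pen, rel, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(rel.times_h, rel.release_pct, "o-", label="API release (UV)")
    ax.plot(pen.times_h, pen.wet_fraction * 100, "s--", label="water penetration (KNN)")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("% of dose / % of VOI wetted")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
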