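"""Run the complete pipeline from one config and summarize the report.

Phantom generation, dry-scan structural analysis, wetting classification by
both methods, release quantification, and the penetration-vs-release
comparison, with every artifact written to the output directory.
"""

import numpy as np

import dissolvis as dv

config = dv.default_demo_config(seed=1)
report = dv.run_pipeline(config, "scratch/demo_run")

print(f"porosity: {report['porosity'] * 100:.2f}%")
print(f"wetting threshold: {report['wetting_threshold']:.2f} gray units")
print(f"KNN validation error: {report['knn_validation_error'] * 100:.3f}%")
truth = np.asarray(report["truth_wet_fraction"])
knn = np.asarray(report["penetration_knn"]["wet_fraction"])
print(f"max |KNN - truth| wet fraction: {np.abs(knn - truth).max():.4f}")
print(f"f2 (measured vs generating release): "
      f"{report['f2_measured_vs_generating']:.2f}")
print(f"penetration/release divergence time: {report['divergence_time_h']} h")
print("\nArtifacts (scans, masks, CSV profiles, report.json, figure) are in")
print("scratch/demo_run/; rerunning with the same config reproduces them")
print("bit-identically.")
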