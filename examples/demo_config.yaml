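# Demo pipeline configuration: 64-voxel-wide tablet phantom, six scans to 8 h.
# Run with:  dissolvis run --config examples/demo_config.yaml --out scratch/run
seed: 1
times_h: [0.0, 1.6, 3.2, 4.8, 6.4, 8.0]
phantom:
  tablet_radius_mm: 0.56
  tablet_height_mm: 0.3136
  voxel_size_um: 20.18
  target_porosity: 0.2324
  pore_radius_mean_um: 80.0
  pore_radius_sd_um: 10.0
  front_speed_mm_h: 0.07    # full wetting at 8 h
  margin_vox: 3
  seed: 1
matrix_threshold: 50.0
sigma_spatial: 1.5
sigma_range: 15.0
shrink_iterations: 2
n_bins: 256
k: 10
dose_mg: 65.6
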