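# Desk-scale default paired experiment: 128 x 128 in-plane matrix, 6 slices,
# 40 dynamics at RR = 1 s, free breathing with one deep-breath event.
seed: 1
rr_s: 1.0
noise_sigma: 0.0005
navigator_noise: 0.02
com_reference: first

phantom:
  grid_shape: [128, 128, 96]
  voxel_size: [1.9, 1.9, 2.0]
  seed: 0

protocol:
  n_read: 128
  n_pe: 128
  n_dynamics: 40
  n_slices: 6
  multiband: 2
  inplane_accel: 3.5
  sr_blocks_per_beat: 3
  ts_ms: 100.0

motion:
  amplitude_mm: 7.0
  period_s: 4.0
  drift_mm_per_s: 0.05
  heart_scale: 0.42
  inplane_scale: 0.15
  events:
    - {onset_s: 24.0, duration_s: 8.0, extra_mm: 15.0}

bolus:
  t0_s: 5.0
  alpha: 2.5
  beta_s: 1.5
  peak_amplitude_mmol: 4.0
  tissue_delay_s: 4.0
  tissue_dispersion_s: 2.0
  tissue_fraction: 0.25
  r1_per_mmol_s: 4.5

tracking:
  tracking_factor: 0.42
  accept_threshold: 0.4
  search_window_mm: 20.0

recon:
  kernel_pe: 4
  kernel_ro: 5
  reg: 1.0e-4
  fit_stride: 2

moco:
  levels: 3
  iterations_per_level: 30
  field_sigma_mm: 2.0
  reference: peak
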