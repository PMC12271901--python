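# Reduced demo: coarse 64 x 64 matrix, 16 dynamics, compressed bolus timing
# so peak myocardial enhancement falls inside the short series.
seed: 7
rr_s: 1.0
noise_sigma: 0.0005
navigator_noise: 0.02

phantom:
  grid_shape: [64, 64, 64]
  voxel_size: [3.8, 3.8, 3.0]
  seed: 0

protocol:
  n_read: 64
  n_pe: 64
  n_dynamics: 16
  n_slices: 6
  multiband: 2
  inplane_accel: 3.5
  sr_blocks_per_beat: 3

motion:
  amplitude_mm: 7.0
  period_s: 4.0
  drift_mm_per_s: 0.0
  heart_scale: 0.42
  inplane_scale: 0.15
  events:
    - {onset_s: 10.0, duration_s: 4.0, extra_mm: 15.0}

bolus:
  t0_s: 2.0
  alpha: 2.0
  beta_s: 1.0
  tissue_delay_s: 2.0
  tissue_dispersion_s: 1.0

moco:
  levels: 2
  iterations_per_level: 15
  field_sigma_mm: 3.0
  reference: peak
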