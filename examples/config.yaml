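# Full configuration reference for the vesseg CLI.
# Every block is optional; omitted keys fall back to the defaults shown.

phantom:
  shape: [64, 64, 32]          # voxels per axis
  spacing: [1.0, 1.0, 2.0]     # native mm spacing (anisotropic, CT-like)
  n_branch_levels: 4
  root_radius: 2.5             # mm
  radius_taper: 0.7            # child radius = parent * taper
  vessel_contrast: 120.0       # HU above parenchyma
  background_mean: 80.0        # HU
  noise_sigma: 20.0            # HU
  target_foreground_fraction: 0.01

preprocess:
  hu_window: [0, 400]          # liver intensity window (HU)
  target_spacing: [1.0, 1.0, 1.0]
  mask_margin_mm: 20.0         # liver-ROI dilation per axis
  augmentation_axes: [0, 1, 2]

network:
  in_channels: 1
  n_classes: 2
  base_channels: 16            # channel schedule = base * (1, 2, 4, 8)
  dilation_rates: [3, 4, 5]
  pyramid_kernels: [3, 5, 7]
  dropout_p: 0.5
  dilated_arrangement: series  # or: parallel
  pyramid_blocks: true         # false = ablate skip blocks

supervision:
  enabled: true
  merge: add

loss:
  name: tversky                # tversky | dice | gdl | bce | focal
  alpha: 0.3                   # false-positive weight
  beta: 0.7                    # false-negative weight

train:
  learning_rate: 1.0e-4
  batch_size: 1
  dropout: 0.5
  max_steps: 300
  patch_size: [48, 48, 48]     # must be divisible by 8
  rng_seed: 0
  k_folds: 10
  val_volumes: 1
  eval_every: 50

postprocess:
  min_volume_mm3: 180.0
  connectivity: 26
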