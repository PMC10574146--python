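# Default desk-scale study conditions for the MTPI pipeline.
#
# The simulator runs at 64 px (min_size relaxed below the 224-px network
# contract; documented deviation for desk-scale nets). Vegetation classes
# are separated by colour and texture under heavy pixel noise (color_sd),
# so the segmentation task is noise-limited and decision margins are small.
# The season shift below is the calibrated default: strong enough that the
# pre-trained net drops below the 0.6 transfer threshold on the target
# season while staying above the 0.8 skip threshold on the source season.

scene:
  height: 64
  width: 64
  min_size: 64
  blob_scale: 12.0
  class_mix: [0.30, 0.25, 0.25, 0.20]
  texture_freq: [0.30, 0.07, 0.17, 0.03]
  texture_amp: [30.0, 30.0, 20.0, 10.0]
  base_color: [[30, 80, 42], [48, 102, 56], [128, 142, 64], [132, 122, 110]]
  color_sd: 30.0

# Calibrated season shift (identity = 0, 1, 1, 1). Shrubs and grasses dry
# out between seasons (hue toward brown, brighter, desaturated, flatter
# texture); deep-rooted trees and bare ground keep their appearance, so
# only classes 2 and 3 are flagged.
shift:
  hue_shift: -35.0
  brightness_gain: 1.3
  saturation_gain: 0.65
  texture_contrast_gain: 0.6
  per_class_flags: [false, true, true, false]

survey:
  n_scenes: 240
  source_seed: 100
  target_seed: 5000

split:
  seed: 1

augment:
  expansion_factor: 6
  seed: 7

net:
  depth: 2
  base_channels: 8
  residual: false
  decoder_channels: [32, 32]
  input_size: 64
  seed: 0

pretrain:
  max_iterations: 1500
  batch_size: 4
  learning_rate: 0.02
  momentum: 0.9
  validation_cadence: 100
  convergence_tol: 0.001
  convergence_window: 200
  seed: 0

transfer:
  max_iterations: 800
  batch_size: 4
  learning_rate: 0.01
  momentum: 0.9
  validation_cadence: 100
  convergence_tol: 0.005
  convergence_window: 100
  seed: 3

probe:
  calibration_n: 24
  eval_n: 60
  rule: standardized
  seed: 0

nlevel: 10
tpi_tp_form: fraction

# sweep grids: TP offsets are relative to TP0 ("full" = 0, "head" = -1);
# the TDS grid is the standard 0.2x..4x ladder around TDS0 scaled to the
# toy transfer pool
sweep:
  tp_offsets: [0, -1, 1, full, head]
  tds_grid: [1, 2, 5, 10, 20]
  seeds: [0, 1, 2]
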