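# Desk-scale pipeline configuration: small synthetic slides, a
# quarter-width network, and a coarse working resolution so every stage
# runs in seconds on one CPU.  The production-scale values are the
# package defaults (see mucomap.config.DEFAULTS).
seed: 3

tiling:
  tile_size: 64
  stride: 64

network:
  input_size: 64
  base_width: 16
  se_reduction: 4

train:
  epochs: 2
  rotation_range: [0, 359]
  shift_range: [0, 10]

synthetic:
  slide_size: [64, 360]
  n_cancer_lesions: 2
  n_metaplasia_lesions: 2
  lesion_radius_range: [14, 24]
  microns_per_pixel: 40.0
  photo_scale: 0.5
  n_sections: 4

mapping:
  refine: true
  search_window: 15
  rotation_search_deg: 4.0
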