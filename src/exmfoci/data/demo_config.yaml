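# Demo pipeline configuration: one small synthetic mid-S-phase nucleus,
# simulated pre/post ~4x expansion, then segmented, registered, spot-
# detected, classified and profiled end to end.
#
# Class-5 satellite rings are planted near the focal plane here so the
# average-structure stage has in-plane contributors even in a small scene.
seed: 11
simulate:
  taxonomy: two_channel
  s_phase: mid
  n_structures_per_class: {1: 3, 2: 3, 3: 2, 4: 2, 5: 5}
  class_geometry:
    tilt_range_deg: [0.0, 12.0]
detect:
  expected_radius_nm: [520.0, 180.0, 180.0]
  quality_threshold: 25.0
  link_radius_nm: 1500.0
  search_radius_nm: 2000.0
register:
  n_control_points: 21
  train_fraction: 0.8
average:
  max_tilt_deg: 20.0
  band_width_nm: 100.0
  crop_edge_um: 5.0
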