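# Demo study configuration: the default two-group calibration with a
# light sampling design.  Run with:
#   stereocap all --config examples/demo.yaml --seed 1 --out runs/demo
cohort:
  n_per_group: 7
sampling:
  t_mm: 1.0
  a_p_mm2: 0.59
  block_edge_mm: 0.3
  sections_per_animal: 4
  fields_per_section: 20
probes:
  field_um: 80.0
  frame_um: 50.0
  frame_rule: gundersen_full
  grid_spacing_um: 4.0
  line_spacing_um: 20.0
phantom:
  segment_length_mm: 0.05
  orientation: isotropic
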