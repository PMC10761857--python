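# Wild-type-like colonization scenario (scaled-down synthetic scene).
# Biomass enriches in the dead-end pores up to a 2.5-fold concentration
# ratio over two hours; a QS reporter front sits 0.1 mm into each DEP.
scenario: wt_like
seed: 1
geometry:
  domain_size_px: [256, 320]
  pixel_size: 4.0
  target_porosity: 0.35
  target_dep_fraction: 0.08
  mean_pore_size: 0.04
  mean_dep_depth: 0.1
  cavity_aspect: 3.0
flow:
  Q: 0.1
  h: 0.05
  target_u_m: 20.0
biomass:
  tp_mean: 3000.0
  noise_sigma: 300.0
reporter:
  front_depth_mm: 0.06
  steepness_um: 8.0
  biomass_floor: 10.0
model:
  c_B: 0.03
  t_end: 600.0
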