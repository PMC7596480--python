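seed: 0
geometry:
  mode: straight_channel
  tube_length: 1.5
  tube_radius: 0.2
  cavity_side: 1.0
medium:
  name: air
  temperature: 310.0
  dynamic_viscosity: 1.86e-05
  mean_free_path: 6.8e-08
particles:
  diameter: 200.0
  density: 2000.0
  charge: 0.0
  count: 200
force:
  mode: none
  direction: +x
  magnitude_model: gravity
  magnitude: 0.0
  scale: 1.0
interaction:
  enabled: false
  strength: 1.0e-24
  cutoff: 0.2
  softening: 0.005
source:
  region: source_slab
  slab_depth: 0.05
run:
  dt: null
  t_end: 600.0
  record_every: 60.0
  slip: true
  d_scale: 20.0
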