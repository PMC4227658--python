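# Shear test of a calibrated 2 mg/ml random collagen network.
# Any omitted field falls back to the calibrated defaults shown here.
collagen_density: 2.0
geometry: random
seeds: [1, 2, 3, 4, 5]
output_dir: fibernet_out

fiber:
  length: 100.0            # µm
  diameter: 0.3            # µm
  youngs_modulus: 32.0e+6   # Pa
  beads_per_fiber: 5
  fibril_molecular_weight: 8.05e+5   # g/mol
  fibril_length: 300.0     # nm
  fibril_diameter: 1.5     # nm

crosslinker:
  strength: 634.38e+3       # Pa (best fit)
  density_multiplier: 11.18  # xN, crosslinkers per fiber count (best fit)
  min_binding_distance: 0.45 # µm
  max_binding_distance: 50.0 # µm
  max_per_bead: 10

box:
  length_x: 200.0          # µm
  width_y: 200.0           # µm
  height_z: 300.0          # µm
  anchor_depth: 50.0       # µm (top and bottom grips)

protocol:
  mode: shear_y
  strain_step: 0.01        # 2 µm per step at the default free height
  n_steps: 10

criterion:
  relative_force_tolerance: 1.0e-5
  absolute_force_floor: 1.0e-9     # nN
  max_iterations: 100000
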