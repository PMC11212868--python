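# Wild-type mechanics scenario: calibrated defaults written out explicitly.
geometry:
  cell_radius: 9.0
  cell_half_length: 16.0
  nucleus_initial_radius: 3.5
  cage_semi_axes: [4.2, 6.8]
  lamina_thickness: 0.15
  mesh_target_edge: 0.25
materials:
  moduli: {cytoplasm: 7.0, nucleoplasm: 0.3, cage: 8.0, lamina: 40.0}
  poisson: {cytoplasm: 0.3, nucleoplasm: 0.48, cage: 0.4, lamina: 0.3}
active:
  rho0: 2.2
  sigma_mt: 3.8
  n_steps: 20
  polarization: single
  polarization_lambda: 0.5
# scenario modifiers
mutant_lamina_modulus: 10.0   # NE+lamina stiffness for mutant-lamin scenarios
linc_cage_fraction: 0.3       # cage stress+stiffness left after LINC disruption
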