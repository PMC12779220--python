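# Two-layer measurement: 3.5 mm hydrogel under 1.5 mm culture medium.
# The gel diffusivity here is a placeholder for exercising the two-layer
# pipeline, not a measured material value; the medium uses the
# diffusivity of water at 37 °C.
geometry:
  preset: gel
  D_gel_cm2_s: 1.5e-5
  D_medium_cm2_s: 3.1e-5
  gel_height_mm: 3.5
  medium_height_mm: 1.5
  probe_height_mm: 1.8
driver:
  mode: fopdt
  C_final_mol_m3: 0.0
  theta_s: 3.0
  tau_s: 23.0
solver:
  dz_mm: 0.02
  dt_s: 0.5
fit:
  target_layer: 0
  D_bounds_cm2_s: [1.0e-6, 1.0e-4]
synth:
  fixture: gel_2pct
  noise_sd: 0.01
  seed: 102
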