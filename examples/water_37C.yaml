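# Single-layer liquid measurement: 4 mm water column at 37 °C,
# probe 1.8 mm above the dish bottom, nitrogen purge at the surface.
geometry:
  preset: water
  D_cm2_s: 3.1e-5
  height_mm: 4.0
  probe_height_mm: 1.8
driver:
  mode: fopdt
  C_final_mol_m3: 0.0
  theta_s: 3.0
  tau_s: 23.0
solver:
  dz_mm: 0.02
  dt_s: 0.5
synth:
  fixture: water_37C
  noise_sd: 0.01
  seed: 101
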