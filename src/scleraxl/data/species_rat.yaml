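# Rat eye anatomy and composition preset.
# Lengths in micrometres, concentrations in molar, densities in g/cm^3,
# tissue volume (peripapillary hollow spherical frustum) in cm^3.
species_id: rat
lengths_um:
  X_RPE: 10.0
  X_Chor: 45.0
  X_Scl: 104.0
  X_Ten: 26.0
  X_Inj: 3100.0
  X_Retro: 45.0
amino_acids_scleral_M:
  His: 1.335e-2
  Met: 2.225e-2
  Trp: 8.90e-3
  Cys: 2.670e-2
  Tyr: 2.076e-2
amino_acids_choroidal_M:
  His: 6.46e-3
  Met: 1.076e-2
  Trp: 4.30e-3
  Cys: 1.29e-2
  Tyr: 1.004e-2
melanin_M:
  RPE: 8.50e-2
  choroid: 3.05e-1
  sclera: 6.46e-2
oxygen_21pct_M:
  choroid: 4.81e-5
  reservoir: 2.18e-5
density_g_cm3:
  sclera: 1.077
  choroid: 1.063
tissue_volume_cm3: 1.03e-4
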