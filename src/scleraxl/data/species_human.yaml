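# Human eye anatomy and composition preset (units as in species_rat.yaml).
species_id: human
lengths_um:
  X_RPE: 26.0
  X_Chor: 327.0
  X_Scl: 811.0
  X_Ten: 113.0
  X_Inj: 214.0
  X_Retro: 327.0
amino_acids_scleral_M:
  His: 1.375e-2
  Met: 3.667e-2
  Trp: 4.58e-3
  Cys: 4.584e-2
  Tyr: 1.375e-2
amino_acids_choroidal_M:
  His: 6.44e-3
  Met: 1.716e-2
  Trp: 2.14e-3
  Cys: 2.15e-2
  Tyr: 6.44e-3
melanin_M:
  RPE: 7.35e-2
  choroid: 6.00e-2
  sclera: 7.84e-2
oxygen_21pct_M:
  choroid: 7.02e-5
  reservoir: 3.09e-5
density_g_cm3:
  sclera: 1.049
  choroid: 1.002
tissue_volume_cm3: 1.36e-2
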