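# Minipig eye anatomy and composition preset (units as in species_rat.yaml).
species_id: minipig
lengths_um:
  X_RPE: 9.0
  X_Chor: 181.0
  X_Scl: 589.0
  X_Ten: 147.0
  X_Inj: 308.0
  X_Retro: 181.0
amino_acids_scleral_M:
  His: 1.342e-2
  Met: 1.939e-2
  Trp: 8.95e-3
  Cys: 2.685e-2
  Tyr: 2.237e-2
amino_acids_choroidal_M:
  His: 6.49e-3
  Met: 9.38e-3
  Trp: 4.33e-3
  Cys: 1.30e-2
  Tyr: 1.082e-2
melanin_M:
  RPE: 8.50e-2
  choroid: 3.05e-1
  sclera: 1.51e-2
oxygen_21pct_M:
  choroid: 6.07e-5
  reservoir: 2.18e-5
density_g_cm3:
  sclera: 1.077
  choroid: 1.063
tissue_volume_cm3: 6.53e-3
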