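# Photochemical and transport constants shared by all species.
# Rate constants follow the numbering of the published reaction scheme;
# k2 (dimer dissociation) is derived as k1 / K_D and is not listed here.
t_default_s: 1800.0
I_default_mW_cm2: 424.0
C0_MB_default_mM: 3.0
wavelength_nm: 660.0
Phi_Lumen: 5.1e-1
Phi_Fundus: 9.6e-2
Phi_MBT: 5.2e-1
eps_MBM_M_cm: 7.33e4
eps_MBD_M_cm: 3.53e4
eps_Mel_M_cm: 646.0
D_MB_Res_cm2_s: 4.60e-6
D_MB_Tis_cm2_s: 3.16e-7
D_O2_Tis_cm2_s: 6.00e-6
K_D_per_M: 1.0665e4
k1: 3.02e8          # MB dimer formation (M^-1 s^-1)
k3: 1.3e4           # MB triplet physical quenching by solvent (s^-1)
k4:                 # MB triplet physical quenching by quencher (M^-1 s^-1)
  MB: 4.1e7
  Met: 1.0e8
  Cys: 1.92e9
k5:                 # MB triplet chemical quenching by amino acids (M^-1 s^-1)
  His: 2.0e6
  Trp: 6.0e8
  Tyr: 2.96e7
k7: 89.0            # leuco MB formation from oxidation of reduced MB by 3O2
k8: 4.0e6           # crosslink formation from amino acid radical (type I)
k9: 2.6e9           # 1O2 generation from MB triplet
k10: 2.56e5         # 1O2 quenching by solvent (s^-1)
k11:                # 1O2 physical quenching by amino acids (M^-1 s^-1)
  Trp: 2.1e7
  Tyr: 2.7e7
  Cys: 4.2e7
k13:                # oxidized AA generation, 1O2 chemical quenching (M^-1 s^-1)
  Met: 1.6e7
  Cys: 8.9e6
k14:                # crosslink formation from 1O2 chemical quenching (type II)
  His: 1.0e8
  Trp: 3.0e7
  Tyr: 8.0e6
k_deg: 0.0          # optional MB photodegradation by 1O2 (M^-1 s^-1)
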