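# Potent mechanism-based inactivator; CYP3A4 substrate.
name: clarithromycin
molar_mass_g_mol: 747.95
CL_H_L_h: 26.52
CL_R_L_h: 6.00
fu_p: 0.1800
fu_b: 0.2813
R_BP: 0.64
fu_h: 0.0122
fu_gw: 0.0984
Kp: {RBC: 0.252, RB: 1.51, Kidney: 1.02, Lungs: 0.43, Liver: 1.24, Gut: 1.83}
Km_uM: 50.00
fm_3A4: 0.80
Fa: 0.55
ka_per_h: 1.08
Qg_L_h: 4.77
P_um_h: 7807.8
interaction:
  Ki_uM: 50.00
  kinact_per_h: 3.18
  KI_uM: 18.90
reported:
  CL_int_L_h: 112.47
  CL_int_star_L_h: 131.30
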