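# Weak mechanism-based inactivator; CYP3A4 substrate.
name: azithromycin
molar_mass_g_mol: 748.98
CL_H_L_h: 33.60
CL_R_L_h: 9.29
fu_p: 0.7000
fu_b: 0.1200
R_BP: 5.83
fu_h: 0.0031
fu_gw: 0.0055
Kp: {RBC: 12.424, RB: 77.34, Kidney: 110.75, Lungs: 23.16, Liver: 226.15, Gut: 126.72}
Km_uM: 150.00
fm_3A4: 1.00
Fa: 0.86
ka_per_h: 0.11
Qg_L_h: 20.51
P_um_h: 36000.0
interaction:
  Ki_uM: 150.00        # equals Km; a substrate competes through its Km
  kinact_per_h: 0.30
  KI_uM: 19.00
reported:
  CL_int_L_h: 353.81
  CL_int_star_L_h: 392.18
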