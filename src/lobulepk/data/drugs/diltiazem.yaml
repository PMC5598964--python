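# Mechanism-based inactivator; CYP3A4 substrate.
name: diltiazem
molar_mass_g_mol: 414.52
CL_H_L_h: 50.20
CL_R_L_h: 2.88
fu_p: 0.2028
fu_b: 0.2200
R_BP: 0.92
fu_h: 0.0173
fu_gw: 0.0251
Kp: {RBC: 0.816, RB: 5.39, Kidney: 6.26, Lungs: 1.49, Liver: 11.76, Gut: 8.10}
Km_uM: 30.00
fm_3A4: 1.00
Fa: 1.00
ka_per_h: 1.60
Qg_L_h: 18.41
P_um_h: 36000.0
interaction:
  Ki_uM: 30.00
  kinact_per_h: 1.68
  KI_uM: 1.15
reported:
  CL_int_L_h: 340.21
  CL_int_star_L_h: 375.54
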