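# Strong CYP3A4 inducer; not an inhibitor.
name: pleconaril
molar_mass_g_mol: 381.31
CL_H_L_h: 24.29
CL_R_L_h: 0.00
fu_p: 0.0100
fu_b: 0.0146
R_BP: 0.69
fu_h: 0.0041
fu_gw: 0.0019
Kp: {RBC: 0.258, RB: 4.65, Kidney: 2.58, Lungs: 0.69, Liver: 3.22, Gut: 5.34}
Km_uM: 10.00
fm_3A4: 0.00
Fa: 0.70
ka_per_h: 1.00
Qg_L_h: 23.31
P_um_h: 36000.0
interaction:
  FImax: 34.00
  EC50_uM: 16.40
  fu_inc: 0.507
reported:
  CL_int_L_h: 1953.50
  CL_int_star_L_h: 4248.41
  EC50_star_uM: 3.83
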