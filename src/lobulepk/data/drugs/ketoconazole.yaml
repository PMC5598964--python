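# Very potent reversible CYP3A4 inhibitor; not metabolised by CYP3A4.
name: ketoconazole
molar_mass_g_mol: 531.43
CL_H_L_h: 0.69
CL_R_L_h: 0.00
fu_p: 0.0095
fu_b: 0.0136
R_BP: 0.70
fu_h: 0.0075
fu_gw: 0.0048
Kp: {RBC: 0.096, RB: 1.75, Kidney: 1.01, Lungs: 0.39, Liver: 1.20, Gut: 2.00}
Km_uM: 1.52
fm_3A4: 0.00
Fa: 1.00
ka_per_h: 1.00
Qg_L_h: 23.34
P_um_h: 36000.0
interaction:
  Ki_uM: 0.006
reported:
  CL_int_L_h: 50.74
  CL_int_star_L_h: 51.46
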