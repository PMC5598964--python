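# Reversible CYP3A4 inhibitor; not metabolised by CYP3A4.
name: cimetidine
molar_mass_g_mol: 252.34
CL_H_L_h: 13.44
CL_R_L_h: 17.22
fu_p: 0.8730
fu_b: 0.9000
R_BP: 0.97
fu_h: 0.9880
fu_gw: 1.0000
Kp: {RBC: 0.657, RB: 0.74, Kidney: 0.88, Lungs: 0.89, Liver: 0.88, Gut: 0.83}
Km_uM: 10.00
fm_3A4: 0.00
Fa: 1.00
ka_per_h: 1.00
Qg_L_h: 2.57
P_um_h: 4468.6
interaction:
  Ki_uM: 115.00
reported:
  CL_int_L_h: 16.22
  CL_int_star_L_h: 16.83
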