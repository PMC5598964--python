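# Prototypical strong CYP3A4 inducer; weak reversible inhibitor.
name: rifampin
molar_mass_g_mol: 822.94
CL_H_L_h: 8.66
CL_R_L_h: 1.68
fu_p: 0.1100
fu_b: 0.1809
R_BP: 0.61
fu_h: 0.3513
fu_gw: 0.2234
Kp: {RBC: 0.074, RB: 0.46, Kidney: 0.32, Lungs: 0.29, Liver: 0.31, Gut: 0.49}
Km_uM: 10.00
fm_3A4: 0.00
Fa: 1.00
ka_per_h: 1.00
Qg_L_h: 19.18
P_um_h: 36000.0
interaction:
  Ki_uM: 100.00
  FImax: 34.00
  EC50_uM: 0.57
  fu_inc: 0.960
reported:
  CL_int_L_h: 50.45
  CL_int_star_L_h: 51.17
  EC50_star_uM: 0.54
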