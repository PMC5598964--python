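# Mixed perpetrator: reversible inhibition, MBI and mild induction.
name: fluoxetine
molar_mass_g_mol: 309.33
CL_H_L_h: 40.32
CL_R_L_h: 0.00
fu_p: 0.0500
fu_b: 0.0500
R_BP: 1.00
fu_h: 0.0057
fu_gw: 0.0049
Kp: {RBC: 1.000, RB: 6.31, Kidney: 8.96, Lungs: 1.87, Liver: 18.28, Gut: 10.30}
Km_uM: 10.00
fm_3A4: 0.00
Fa: 1.00
ka_per_h: 1.00
Qg_L_h: 22.29
P_um_h: 36000.0
interaction:
  Ki_uM: 8.00
  kinact_per_h: 1.32   # value missing in the source table; 0.022/min taken
                       # from the cited MBI compilation
  KI_uM: 0.61
  FImax: 3.10
  EC50_uM: 0.54
  fu_inc: 0.476
reported:
  CL_int_L_h: 1083.31
  CL_int_star_L_h: 1546.61
  EC50_star_uM: 0.18
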