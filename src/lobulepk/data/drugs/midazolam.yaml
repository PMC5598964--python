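# Victim probe substrate of CYP3A4.
name: midazolam
molar_mass_g_mol: 325.77   # external annotation (not from the source tables)
CL_H_L_h: 34.42
CL_R_L_h: 0.09
fu_p: 0.0264
fu_b: 0.0400
R_BP: 0.66
fu_h: 0.0202
fu_gw: 0.0189
Kp: {RBC: 0.005, RB: 0.84, Kidney: 1.41, Lungs: 1.61, Liver: 1.31, Gut: 1.40}
Km_uM: 2.30
fm_3A4: 0.96
Fa: 1.00
ka_per_h: 1.16
Qg_L_h: 15.44
P_um_h: 24228.0
reported:
  CL_int_L_h: 1095.19
  CL_int_star_L_h: 1991.20
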