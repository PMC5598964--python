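# Reversible CYP3A4 inhibitor; not metabolised by CYP3A4.
name: fluconazole
molar_mass_g_mol: 306.27
CL_H_L_h: 0.71
CL_R_L_h: 1.03
fu_p: 0.6893
fu_b: 0.8900
R_BP: 0.77
fu_h: 0.1051
fu_gw: 1.0000
Kp: {RBC: 0.467, RB: 0.54, Kidney: 0.65, Lungs: 0.63, Liver: 0.66, Gut: 0.68}
Km_uM: 10.00
fm_3A4: 0.00
Fa: 0.86
ka_per_h: 0.88
Qg_L_h: 6.23
P_um_h: 13646.5
interaction:
  Ki_uM: 3.40
reported:
  CL_int_L_h: 0.80
  CL_int_star_L_h: 0.80
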