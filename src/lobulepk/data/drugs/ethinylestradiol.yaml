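# Mixed perpetrator: MBI and inducer; partial CYP3A4 substrate.
name: ethinylestradiol
molar_mass_g_mol: 296.40
CL_H_L_h: 42.52
CL_R_L_h: 0.00
fu_p: 0.0300
fu_b: 0.0355
R_BP: 0.84
fu_h: 0.0039
fu_gw: 0.0023
Kp: {RBC: 0.632, RB: 10.93, Kidney: 6.11, Lungs: 1.38, Liver: 7.73, Gut: 12.79}
Km_uM: 18.00
fm_3A4: 0.60
Fa: 1.00
ka_per_h: 1.00
Qg_L_h: 15.13
P_um_h: 23635.9
interaction:
  Ki_uM: 18.00
  kinact_per_h: 2.40
  KI_uM: 18.00
  FImax: 70.00
  EC50_uM: 20.00
  fu_inc: 0.541      # incubation unbound fraction; consistent with the
                     # reported corrected potency below
reported:
  CL_int_L_h: 1643.00
  CL_int_star_L_h: 5334.34
  EC50_star_uM: 3.33
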