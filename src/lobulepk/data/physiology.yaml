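# Reference physiology of an average 70-kg man.
#
# The hepatic blood flow is the value consistent with the drug library's
# reported intrinsic-clearance column under the parallel-tube inversion;
# the remaining volumes and flows are standard reference-man values.
body:
  V_AB_L: 1.70        # arterial blood
  V_VB_L: 3.40        # venous blood
  V_Lungs_L: 0.50
  V_K_L: 0.31         # kidneys
  V_RB_L: 62.0        # rest of body (lumped)
  V_GW_L: 0.30        # gut wall (metabolically active mucosa/enterocytes)
  V_PV_L: 0.07        # portal vein
  Q_T_L_h: 336.0      # cardiac output (5.6 L/min)
  Q_Liver_L_h: 87.0   # total hepatic blood flow (1.45 L/min)
  Q_K_L_h: 66.0       # renal blood flow
  Q_RB_L_h: 183.0     # rest of body (closure: Q_T - Q_Liver - Q_K)
  portal_fraction: 0.75   # share of liver flow arriving via the portal vein
  hematocrit: 0.45

lobule:
  R_Lobule_um: 790.57
  R_sin_um: 3.65
  e_Lobule_um: 25.0
  R_H_um: 8.49
  V_Liver_L: 1.69
  V_cell_uL_per_1e6: 4.0
  liver_mass_g: 1800.0

enzymes:
  - name: CYP3A4
    amount_liver_umol: 9.228
    amount_gut_umol: 0.070
    kdeg_liver_per_h: 0.0192
    kdeg_gut_per_h: 0.0288

# Total CYP pools used to scale the unspecified (non-3A4) gut-wall pathway:
# CYP3A4 is ~30% of hepatic and ~80% of intestinal CYP content.
cyp_pool:
  A_CYP_liver_umol: 30.76
  A_CYP_gut_umol: 0.0875
  f_3A4_liver: 0.30
  f_3A4_gut: 0.80

reference:
  # Blood-hepatocyte exchange surface of the reference lobule construction,
  # used by the clearance-derivation chain (the freshly built geometry
  # reproduces it to within 1%).
  S_ex_dm2: 10046.0
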