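# single dose; probe 2 h later.
name: fluconazole_midazolam
perpetrator:
  drug: fluconazole
  dose_mg: 400
  times_h: [0.0]
victim:
  drug: midazolam
  dose_mg: 7.5
  times_h: [2.0]
observed:
  auc_ratio: 3.5
  cmax_ratio: 2.5
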