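# 4 once-daily doses; probe 1 h after the last.
name: ketoconazole_midazolam
perpetrator:
  drug: ketoconazole
  dose_mg: 400
  times_h: [0.0, 24.0, 48.0, 72.0]
victim:
  drug: midazolam
  dose_mg: 7.5
  times_h: [73.0]
observed:
  auc_ratio: 15.9
  cmax_ratio: 4.09
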