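# 3 once-daily doses; probe 1.5 h after the last.
name: azithromycin_midazolam
perpetrator:
  drug: azithromycin
  dose_mg: 500
  times_h: [0.0, 24.0, 48.0]
victim:
  drug: midazolam
  dose_mg: 15
  times_h: [49.5]
observed:
  auc_ratio: 1.27
  cmax_ratio: 1.29
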