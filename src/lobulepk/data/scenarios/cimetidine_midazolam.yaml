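# irregular intakes at 0, 12 and 24.5 h; probe 0.5 h after the last.
name: cimetidine_midazolam
perpetrator:
  drug: cimetidine
  dose_mg: 400
  times_h: [0.0, 12.0, 24.5]
victim:
  drug: midazolam
  dose_mg: 15
  times_h: [25.0]
observed:
  auc_ratio: 1.35
  cmax_ratio: 1.26
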