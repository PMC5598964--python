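# 5 doses three times daily; probe mid-treatment at 25 h.
name: diltiazem_midazolam
perpetrator:
  drug: diltiazem
  dose_mg: 60
  times_h: [0.0, 8.0, 16.0, 24.0, 32.0]
victim:
  drug: midazolam
  dose_mg: 15
  times_h: [25.0]
observed:
  auc_ratio: 3.75
  cmax_ratio: 2.05
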