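# 15 doses three times daily; probe with the last dose.
name: pleconaril_midazolam
perpetrator:
  drug: pleconaril
  dose_mg: 400
  times_h: [0.0, 8.0, 16.0, 24.0, 32.0, 40.0, 48.0, 56.0, 64.0, 72.0, 80.0, 88.0, 96.0, 104.0, 112.0]
victim:
  drug: midazolam
  dose_mg: 5
  times_h: [112.0]
observed:
  auc_ratio: 0.65
  cmax_ratio: 0.76
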