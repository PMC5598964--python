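# 10 once-daily doses; probe on day 5 (first reported intake).
name: rifampin_midazolam
perpetrator:
  drug: rifampin
  dose_mg: 600
  times_h: [0.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0, 168.0, 192.0, 216.0]
victim:
  drug: midazolam
  dose_mg: 5.5
  times_h: [118.0]
observed:
  auc_ratio: 0.12
  cmax_ratio: 0.17
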