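# 60 mg x 5 then 20 mg x 7, once daily; probe 1 h after the last.
name: fluoxetine_midazolam
perpetrator:
  drug: fluoxetine
  dose_mg: 20
  times_h: [0.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0, 168.0, 192.0, 216.0, 240.0, 264.0]
  # the first five intakes are 60 mg (see dose_mg_list)
  dose_mg_list: [60, 60, 60, 60, 60, 20, 20, 20, 20, 20, 20, 20]
victim:
  drug: midazolam
  dose_mg: 10
  times_h: [265.0]
observed:
  auc_ratio: 0.84
  cmax_ratio: 1.11
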