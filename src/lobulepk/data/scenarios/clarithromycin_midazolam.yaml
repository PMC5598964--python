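# 13 twice-daily doses; probe with the last dose.
name: clarithromycin_midazolam
perpetrator:
  drug: clarithromycin
  dose_mg: 500
  times_h: [0.0, 12.0, 24.0, 36.0, 48.0, 60.0, 72.0, 84.0, 96.0, 108.0, 120.0, 132.0, 144.0]
victim:
  drug: midazolam
  dose_mg: 8
  times_h: [144.0]
observed:
  auc_ratio: 8.39
  cmax_ratio: 3.8
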