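# 10 once-daily doses; probe 1 h after the last.
name: ethinylestradiol_midazolam
perpetrator:
  drug: ethinylestradiol
  dose_mg: 0.03
  times_h: [0.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0, 168.0, 192.0, 216.0]
victim:
  drug: midazolam
  dose_mg: 7.5
  times_h: [217.0]
observed:
  auc_ratio: 1.2
  cmax_ratio: 1.16
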