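name: OVAL-100W-120s
shape_label: OVAL
intervals:
- power_w: 100
  duration_s: 120
  distance_mm: 0
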