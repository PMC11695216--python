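name: TEAR-60W-600s
shape_label: TEAR
intervals:
- power_w: 60
  duration_s: 360
  distance_mm: 0
- power_w: 60
  duration_s: 210
  distance_mm: 30
- power_w: 60
  duration_s: 30
  distance_mm: 15
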