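name: HOUR-60W-600s
shape_label: HOUR
intervals:
- power_w: 60
  duration_s: 260
  distance_mm: 0
- power_w: 60
  duration_s: 80
  distance_mm: 40
- power_w: 60
  duration_s: 260
  distance_mm: 0
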