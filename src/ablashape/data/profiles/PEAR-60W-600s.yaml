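name: PEAR-60W-600s
shape_label: PEAR
intervals:
- power_w: 60
  duration_s: 100
  distance_mm: 25
- power_w: 60
  duration_s: 200
  distance_mm: 12.5
- power_w: 60
  duration_s: 300
  distance_mm: 12.5
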