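name: LONG-60W-600s
shape_label: LONG
intervals:
- power_w: 60
  duration_s: 600
  distance_mm: 50
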