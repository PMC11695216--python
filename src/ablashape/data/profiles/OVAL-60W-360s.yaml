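name: OVAL-60W-360s
shape_label: OVAL
intervals:
- power_w: 60
  duration_s: 360
  distance_mm: 0
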