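name: OVAL-60W-240s
shape_label: OVAL
intervals:
- power_w: 60
  duration_s: 240
  distance_mm: 0
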