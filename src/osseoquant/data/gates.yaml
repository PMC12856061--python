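# Default HSV color gates (8-bit convention: hue 0-179, sat/val 0-255).
scaffold:
  lower: [0, 0, 0]
  upper: [70, 67, 90]
bone:
  lower: [155, 57, 67]
  upper: [179, 202, 187]
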