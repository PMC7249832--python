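seed: 1
scene:
  preset: blood-smear
  extent: [300um, 300um]
optics:
  preset: 0.65NA-dry
camera:
  sensor_px: [400, 300]
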