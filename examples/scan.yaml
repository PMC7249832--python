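seed: 3
scene:
  preset: blood-smear
  extent: [300um, 300um]
camera:
  sensor_px: [200, 150]
stage:
  step_size: [100nm, 100nm, 50nm]
scan:
  grid: [2, 2]
  zstack: 3
  dz: 500nm
  overlap: 0.2
  autofocus: laplacian
  af_range: [-5um, 5um]
  af_points: 15
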