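# Reference configuration: neutral 100-cell population, 500-frame video.
analysis:
  gamma: 30.0             # half-cone width, degrees
  option: 1
  theta: 0.0              # gradient along +x
  max_displacement: 10.0  # linking search radius, µm (µ = 1 µm/px here)
  min_track_length: 10
simulation:
  n_cells: 100
  n_frames: 500
  arena_w: 800
  arena_h: 800
  D_rot: 0.1
  v0: 3.0
  beta: 0.0
  responsiveness: 0.0
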