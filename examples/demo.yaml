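# Demo sequence: a drifting soft-edged spot over a sine grating, followed by
# a binary white-noise checkerboard that is DoG-filtered, renormed into the
# dynamic range and gamma compensated.
label: demo
seed: 7
geometry:
  width_px: 48
  height_px: 48
  frame_rate_hz: 60
  um_per_px: 1.0

stimuli:
  - label: drifting_spot_on_grating
    duration_frames: 24
    components:
      - type: primer
        name: sine_grating
        params: {spatial_frequency: 0.08, orientation: 0.6, mean: 0.5, amplitude: 0.3}
      - type: primer
        name: disc
        params: {center: [12, 24], radius: 8, edge_width: 2, fill_color: 1.0}
      - type: motion
        name: linear
        params: {velocity: [60, 0]}
      - type: modulation
        name: sine
        params: {offset: 0.6, amplitude_start: 0.4, frequency_start: 2.0}

  - label: filtered_checkerboard
    duration_frames: 12
    components:
      - type: primer
        name: checkerboard
        params: {cell_px: 4, mode: binary, seed: 1234}
      - type: spatial_filter
        name: convolve
        params: {kind: dog, sigma_center: 1.0, sigma_surround: 2.5}
      - type: tonemap
        name: renorm
      - type: gamma
        name: compensate
        params: {exponent: 2.2}
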