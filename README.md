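# stimsynth

Offline, deterministic synthesis of visual stimuli for retina physiology,
optogenetics and psychophysics. Experiments in these fields need light
patterns with precise spatial and temporal structure — drifting bars and
gratings, soft-edged spots, white-noise checkerboards for receptive-field
mapping, filtered natural images — plus an exact record of *when* every
stimulus element appeared, so voltage traces can be aligned to frames.

`stimsynth` builds such stimuli from small, parameterized **stimulus
building components (SBCs)** instead of code: *primer* components produce
pixel colors (shapes defined by implicit equations or polygon vertices,
gratings, Campbell–Robson charts, images, random checkerboards); *motion*,
*modulation* and *warp* components decorate them; *composition* components
mix primers through a mask (`out = m·fg + (1−m)·bg`); *spatial filter*,
*temporal filter*, *tone map* and *gamma* components post-process the
frame. Everything is evaluated **pointwise** — every pixel center, every
frame, straight from the defining formulas — so set operations, soft
(fuzzy-membership) edges and nonlinear warps compose freely.

Key properties:

- **Reproducible randomness.** Flickering checkerboards draw from seeded
  xorshift128 streams arranged in 2D grids; shifting a grid spends fresh
  draws only on the vacated border. The identical number sequence arises on
  every run, and grids export to plain text for downstream analysis.
- **Dual-route filtering.** Spatial kernels (Gaussian, zero-integral
  difference-of-Gaussians, Gabor) convolve either directly or via padded
  FFT with identical results; kernels can also be specified straight in the
  frequency domain. Temporal filtering is causal, by tap convolution or by
  a recursive LTI state system whose impulse response is a sum of complex
  exponentials (fit by a Prony-type least squares).
- **Tone mapping & gamma.** Contrast stretch, sigmoid, histogram
  equalization and range renorming map filtered intensities back into
  [0, 1], per frame or with one global mapping measured over the stimulus;
  a compensation LUT built from measured (input, luminance) photometer
  samples linearizes the display.
- **Frame-accurate eventing.** Each run emits an event log (`stim`
  rise/fall per stimulus, one `stop` pulse) with times computed in exact
  rational arithmetic — the software stand-in for hardware TTL signaling.

## Worked example

Render the shipped demo — a drifting soft-edged spot over a sine grating,
then a DoG-filtered binary checkerboard, renormed and gamma compensated:

```sh
$ stimsynth render examples/demo.yaml -o out --seed 5
stimsynth 0.1.0 | seed 5 | 36 frames
wrote 36 file(s), events -> out/events.tsv
resolved config -> out/resolved_config.json
```

`out/` now holds `frame_000000.png … frame_000035.png` (16-bit linear-light
PNGs), the event log, and a resolved config with every parameter default
made explicit. The event log is frame-exact:

```
frame	time_s	channel	edge
0	0.000000	stim	rise
23	0.383333	stim	fall
24	0.400000	stim	rise
35	0.583333	stim	fall
35	0.583333	stop	pulse
```

Running the same command twice produces byte-identical files. The same
pipeline is scriptable from Python:

```python
import stimsynth as ss

spec = ss.parse_config("examples/demo.yaml")
ctx = ss.RenderContext(geometry=spec.geometry, seed=5)
frame = ss.render_frame(spec.stimuli[1], 0, ctx)   # checkerboard stimulus
print(ss.frame_stats(frame.values))
```

prints (values from this demo frame):

```
{'michelson': 1.0, 'rms_contrast': 0.1932851441287..., 'entropy_bits': 6.9711488776904...,
 'mean': 0.7233198626833..., 'variance': 0.0195459927499...}
```

— Michelson contrast 1.0 because the renormed DoG output spans the full
dynamic range; ~7 bits of entropy because DoG + renorm spread the binary
checkerboard over many gray levels; and a mean near 0.72 because the gamma
compensation (the inverse of a 2.2 power law) brightens mid-grays.

## Scope

The engine is deliberately offline: real-time display, vertical-sync and
frame-drop hardware handling, GPU shader generation, 3D/VR scenes and
USB/RS232 signaling are out of scope. Frame timing is deterministic by
construction (frame index ÷ frame rate), and a per-run budget report flags
frames whose render time exceeded the frame period, purely as information.
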