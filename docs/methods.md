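# Methods

This note records the model behind `stimsynth`, the conventions the
implementation fixes where several choices were defensible, and what the
test suite does and does not demonstrate.

## Rendering model

A stimulus is an ordered list of typed components evaluated over a field of
`width_px × height_px` pixels at `frame_rate_hz` frames per second. Every
frame is produced in three phases:

1. **Prerequisites** — stateful streams advance exactly once per frame
   (random grids for checkerboards are regenerated, shifted, or held).
2. **Core rendering** — each primer is evaluated pointwise at pixel-center
   coordinates and combined with the others.
3. **Post-processing** — spatial filters, the temporal filter, tone maps
   and gamma compensation are applied to the frame array, in listed order.

Conventions fixed by this implementation:

- **Pixel centers.** Pixel `(i, j)` samples the continuous point
  `((j+0.5)·um_per_px, (i+0.5)·um_per_px)`, origin at the top-left, y
  growing downward. One sample per pixel; anti-aliasing comes only from
  soft shape membership, never from supersampling.
- **Frame time.** Frame `k` is evaluated at its onset, `t = k / rate`.
- **Decoration order.** Within one primer's layer: warps transform the
  coordinates first, then the motion offset is subtracted, then the primer
  is evaluated, and the modulation scalar multiplies the resulting
  intensity. Modulation therefore **multiplies** intensity rather than
  interpolating toward a background color; fades toward a color are built
  explicitly with a mix composition.
- **Layer combination.** Without an explicit composition, primers
  composite in listed order over a black canvas using their coverage alpha
  (shape membership; full-field patterns have alpha 1). An explicit `mix`
  composition instead computes `m·fg + (1−m)·bg` from three referenced
  primers. The cross-fade template drives the mask with a linear ramp
  `m(k) = k/(D−1)` over `D` frames (`m ≡ 1` when `D = 1`), so the first
  frame is purely the old pattern and the last purely the new one.
- Intensities stay in float64 end to end; quantization (16-bit,
  round-half-away-from-zero) happens only at file write.

## Shapes, patterns, grids

Shapes are signed-distance functions (disc, annulus, rotated box, polygon,
piecewise-cubic Bezier region flattened at a 0.25 px chord tolerance).
Membership is a smoothstep of signed distance: 1 inside, 0 outside, 0.5 on
the contour, ramp width `edge_width`; `edge_width = 0` is a hard edge with
the contour counted inside. Polygon interiority uses the even-odd rule, so
self-intersecting outlines are legal. Set operations are the min/max/1−m
combinators, which satisfy the De Morgan identities exactly.

The Campbell–Robson chart interpolates frequency geometrically along x
(with continuous integrated carrier phase) and contrast geometrically
along y; a contrast endpoint of exactly 0 maps its edge row to flat
mid-gray. Square gratings assign the `sin = 0` tie to the high level.
Grid repetition (`grid_points`) places copies of a base primer on
rectangular, hexagonal (odd rows offset by s/2, vertical pitch s·√3/2),
random, or explicit vertex layouts, combined by pointwise maximum;
vertices may carry unique labels. Image assets map their integer range
linearly to [0, 1] with **no sRGB decoding** — files are assumed to encode
linear light.

## Motion and modulation

Linear motion takes either a velocity vector or a crossing time; the
derived speed is `(field extent along the motion direction + shape extent)
/ crossing_time`. Free-form paths are cubic Hermite interpolants through
`(time, position, velocity)` control points, clamped to the endpoint
positions outside the span. Random shaking adds per-frame jitter drawn
uniformly from `[−A, A]²` (the distribution is not dictated by anything
physical; uniform was chosen and is stated here), from a dedicated
xorshift128 stream keyed by (seed, frame) so it never perturbs the
checkerboard streams.

Sine/square modulation sweeps amplitude linearly and frequency linearly
**in integrated phase** (a continuous-phase chirp):
`φ(t) = 2π(f₀t + (f₁−f₀)t²/2T)`. A 1→3 Hz sweep over 1 s therefore
accumulates exactly 2 cycles. Multi-component modulation sums sinusoids,
normalizes by the total amplitude, and shifts into [0, 1]. All modulation
outputs clamp to [0, 1].

## Randomness

The generator is xorshift128 (four 32-bit words; taps 11, 8, 19). Seeding
puts the user seed in the first word (0 remaps to 1 to avoid the forbidden
all-zero state) and fills the rest with the reference constants, so the
stream can be checked word-for-word against an independent transliteration
of the published pseudocode. Grids fill row-major from a single stream —
an unambiguous contract chosen over per-cell hashing — and a grid shift
spends exactly `rows·|dx| + cols·|dy| − |dx·dy|` fresh draws on the
vacated border. Words map to [0, 1) as `w / 2³²`. Binary checkerboards
threshold at `u ≥ 0.5`; grayscale maps linearly; color uses three
independent streams derived from the base seed. This stream is
self-consistent and reproducible but makes no claim of matching any other
program's GPU-generated numbers.

## Filtering

- **Spatial, spatial-domain kernels**: per-channel linear convolution with
  zero padding outside the field, auto-sized supports (4σ truncation, odd).
  Difference-of-Gaussians kernels subtract two unit-sum Gaussians, so the
  discrete integral is exactly zero: homogeneous regions map to 0 and edge
  responses may leave [0, 1], which is why a renorm stage follows.
  The FFT route computes the *same* zero-padded linear convolution
  (`fftconvolve`); agreement with the direct route is ~1e−14 and is tested
  at 1e−10.
- **Frequency-specified kernels** (Gaussian-radial low/high/band-pass or a
  custom transfer) have no spatial support, so they multiply the frame
  spectrum directly with **cyclic** boundary semantics — a documented
  difference from the zero-padded spatial route.
- **Temporal**: kernels act on the per-pixel time series using only past
  frames; pre-stimulus history is zero (or the first frame, with
  `prestim='hold'`). Windows (rectangular, triangular, Hamming, Hann) and
  the exponential `a^k` are normalized to unit sum; the biphasic
  "cell" kernel (difference of two time Gaussians) is normalized to zero
  sum. A filter that would need future frames is realized by filtering
  causally and accepting a fixed delay.
- **LTI realization**: per pixel, `y = d·x + Σ Re(sⱼ)` then
  `sⱼ ← zⱼ(sⱼ + cⱼx)` — constant memory regardless of kernel length. With
  zero initial states the realized impulse response is `h₀ = d`,
  `h_k = Σ Re(cⱼ zⱼᵏ)` for k ≥ 1. `fit_exponentials` uses linear
  prediction for the poles and a complex Vandermonde least-squares for the
  coefficients on taps 1…L−1, carrying tap 0 exactly in the direct term;
  it returns the max-abs residual and rejects any fit with |z| ≥ 1
  (notably, a truncated constant kernel fits only the marginal pole z = 1
  and is therefore rejected rather than silently accepted).

## Tone mapping, statistics, color, gamma

Histogram reports (256 bins by default, range widened to include [0, 1] so
out-of-range mass is visible) feed the tone maps. `stretch` maps [lo, hi]
(measured bounds by default) linearly with clamping; `sigmoid` is the
logistic with its midpoint at `center`; `equalize` pushes values through
the linearly interpolated CDF normalized as `(cdf − cdf_min)/(1 −
cdf_min)`, with a single occupied bin treated as identity to avoid 0/0;
`renorm` is the unique affine map sending the measured range onto [0, 1]
(so the zero response of a zero-integral filter lands at mid-gray, e.g.
0.375 for the range [−0.3, 0.5]). Every map is monotone. `dynamic=True`
re-measures per frame; `dynamic=False` uses one report measured by a full
pre-pass over the stimulus with an identically seeded context.

Frame statistics use luminance = unweighted channel mean (the pipeline is
linear RGB; Rec.709 weights are available by argument): Michelson
`(Lmax−Lmin)/(Lmax+Lmin)`, RMS contrast `std/mean`, entropy over 256
luminance bins. Statistics are reported per frame; their mean over a
stimulus is the caller's one-liner, since "average contrast" is ambiguous
between the two orders of averaging. Color conversions (CMYK, HSV, XYZ via
the fixed sRGB/D65 matrix) clamp into [0, 1]; receptor "stimulation
levels" are a user-supplied 3×3 RGB→activation matrix — no spectral model.

Gamma compensation inverts a measured device curve: samples are sorted,
required strictly monotone in both coordinates, normalized to [0, 1], the
device curve D is their piecewise-linear interpolant, and the compensation
C = D⁻¹ is tabulated on a uniform `n_entries` grid **plus the measured
luminance knots** (pure uniform tabulation loses precision where the
inverse of a steep gamma curve bends near zero). Accuracy is bounded by
the sample density: ~256 uniform samples reach 1e−3 for a square-law
device, ~1024 for a 2.2 power law.

## Sequences, events, outputs

Sequences are declarative YAML (schema-validated; unknown keys and
parameters rejected; all defaults echoed into a resolved-config JSON).
Each stimulus renders with a single fresh context seeded from (sequence
seed, stimulus index), so the resolved config plus seed determine every
output byte. The event log records `stim` rise on each stimulus's first
frame and fall on its last, and one `stop` pulse on the final frame (the
rise/fall and on-last-frame conventions are this package's; only "onset",
"offset" and "stop" are inherent). Event times are exact rationals
`frame / rate`, printed at 6 decimals — no cumulative drift at any frame
count. Frames write as 16-bit RGB PNGs from a built-in fixed-settings
encoder (byte-stable for checksum comparisons) or as a raw little-endian
float32 stack with JSON sidecar. Real-time frame-drop handling is reframed
offline as a per-run budget report (render wall time vs frame period,
flagged indices); it never alters output.

## Test scale and what passing shows

Default test problem sizes are chosen for fast, exact checks: fields of
8²–64² pixels, 50 random FFT-vs-direct pairs, 100-frame LTI equivalence
runs at 16², a 5,000-shape stress scene on a 256² field, and 10⁵
reference-exact PRNG draws. These verify the arithmetic contracts —
determinism, dual-route equivalence, closed-form statistics, exact event
timing — at full fidelity, since none of these properties depends on
scale. What they do not exercise: display hardware (gamma drift,
vsync/tearing), perceptual calibration, real-time throughput at
experiment resolutions, and natural-video decoding (directories of
numbered PNG/TIFF frames stand in for video containers).

## Known limitations

- Frequency-domain kernels are cyclic; halo artifacts near borders differ
  from the zero-padded spatial route.
- Histogram equalization with interpolated CDF slightly smooths hard
  binary inputs compared to a step-CDF variant.
- The Prony fit is exact for noise-free exponential sums but is not a
  robust estimator for noisy or non-smooth kernels; the residual is
  returned so callers can decide.
- Polygon membership costs O(vertices) per pixel; very large vertex counts
  on large fields are better pre-flattened to coarser outlines.
- Vector-graphics import is limited to explicit vertex/control-point
  lists; SVG dialects are not parsed.
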