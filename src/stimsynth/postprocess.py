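"""Histogram measurement, tone mapping, frame statistics, color and gamma.

Zero-integral filters routinely push intensities outside the displayable
unit interval, so the final stages of the pipeline measure the intensity
distribution and map it back into [0, 1] with a monotone transfer function:
linear contrast stretch, sigmoid, histogram equalization, or a plain
renorming of the measured range.  Each can operate *dynamically* (the
transfer function re-measured per frame) or *statically* (one global
mapping measured over the whole stimulus).  Gamma compensation, applied
last, pre-distorts software intensities by the inverse of the display's
measured input-to-luminance curve so emitted light is linear in the
commanded value.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import frame_values


# --------------------------------------------------------------------------
# histogram measurement

@dataclasses.dataclass
class HistogramReport:
    """Intensity distribution of one frame or a whole stimulus."""

    bin_edges: np.ndarray
    counts: np.ndarray
    vmin: float
    vmax: float
    mean: float
    variance: float
    scope: str = "per_frame"
    n_below_unit: int = 0  # mass outside [0, 1], flagged for display in red
    n_above_unit: int = 0

    @property
    def out_of_range_fraction(self) -> float:
        total = int(self.counts.sum())
        return (self.n_below_unit + self.n_above_unit) / total if total else 0.0


def measure_histogram(frames, n_bins: int = 256, scope: str = "global"):
    """Histogram + min/max/mean/variance over frame(s).

    ``scope='global'`` pools every channel value of every frame into one
    report (the in-silico measurement of the whole stimulus used by static
    tone mapping); ``scope='per_frame'`` returns one report per frame.  The
    bin range is auto-detected from the data and widened to include [0, 1]
    so out-of-range mass is visible.
    """
    if scope == "per_frame":
        return [measure_histogram([f], n_bins, "global") for f in frames]
    if scope != "global":
        raise ValueError("scope must be 'global' or 'per_frame'")
    arrs = [frame_values(f).ravel() for f in frames]
    if not arrs:
        raise ValueError("measure_histogram needs at least one frame")
    v = np.concatenate(arrs)
    vmin, vmax = float(v.min()), float(v.max())
    lo, hi = min(vmin, 0.0), max(vmax, 1.0)
    if hi <= lo:
        hi = lo + 1.0
    counts, edges = np.histogram(v, bins=int(n_bins), range=(lo, hi))
    return HistogramReport(
        bin_edges=edges,
        counts=counts,
        vmin=vmin,
        vmax=vmax,
        mean=float(v.mean()),
        variance=float(v.var()),
        scope="global",
        n_below_unit=int(np.count_nonzero(v < 0.0)),
        n_above_unit=int(np.count_nonzero(v > 1.0)),
    )


# --------------------------------------------------------------------------
# tone mapping

@dataclasses.dataclass
class ToneMapSpec:
    """Which monotone transfer function to apply and with what parameters.

    ``dynamic=True`` re-measures the needed bounds/CDF on each frame;
    ``dynamic=False`` requires a global report measured over the stimulus,
    so every frame shares one mapping.
    """

    kind: str  # stretch | sigmoid | equalize | renorm
    lo: float | None = None
    hi: float | None = None
    center: float = 0.5
    slope: float = 10.0
    n_bins: int = 256
    dynamic: bool = True

    def __post_init__(self):
        if self.kind not in ("stretch", "sigmoid", "equalize", "renorm"):
            raise ValueError(f"unknown tone map kind {self.kind!r}")
        if self.lo is not None and self.hi is not None and self.lo >= self.hi:
            raise ValueError("tone map requires lo < hi")
        if self.slope <= 0:
            raise ValueError("sigmoid slope must be positive")


def _equalize(v: np.ndarray, report: HistogramReport) -> np.ndarray:
    counts = report.counts.astype(np.float64)
    total = counts.sum()
    if np.count_nonzero(counts) <= 1:
        return v.copy()  # single occupied bin: identity, no contrast to spread
    cdf_edges = np.concatenate(([0.0], np.cumsum(counts) / total))
    u = np.interp(v, report.bin_edges, cdf_edges)
    occupied = np.nonzero(counts)[0][0]
    cdf_min = cdf_edges[occupied]  # CDF at the left edge of the first occupied bin
    return np.clip((u - cdf_min) / (1.0 - cdf_min), 0.0, 1.0)


def tone_map(frame, spec: ToneMapSpec, report: HistogramReport | None = None) -> np.ndarray:
    """Apply one monotone tone-mapping transfer function to a frame.

    ``stretch`` maps [lo, hi] linearly onto [0, 1] with clamping (lo/hi
    default to the measured min/max); ``sigmoid`` is the logistic
    ``1 / (1 + exp(-slope (v - center)))``; ``equalize`` pushes values
    through the (interpolated) intensity CDF; ``renorm`` is the affine map
    sending the measured [min, max] onto [0, 1], turning the zero response
    of a zero-integral filter into mid-gray.
    """
    v = frame_values(frame)
    needs_report = spec.kind in ("equalize", "renorm") or (
        spec.kind == "stretch" and (spec.lo is None or spec.hi is None))
    if needs_report:
        if report is None:
            if not spec.dynamic:
                raise ValueError("static tone mapping requires a measured global report")
            report = measure_histogram([v], n_bins=spec.n_bins)
        elif spec.dynamic and report.scope != "global":
            raise ValueError("malformed histogram report")
    if spec.kind == "stretch":
        lo = spec.lo if spec.lo is not None else report.vmin
        hi = spec.hi if spec.hi is not None else report.vmax
        if lo >= hi:
            return np.clip(v - lo, 0.0, 1.0)
        return np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    if spec.kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-spec.slope * (v - spec.center)))
    if spec.kind == "equalize":
        return _equalize(v, report)
    # renorm
    lo, hi = report.vmin, report.vmax
    if hi <= lo:
        return np.clip(v - lo, 0.0, 1.0)
    return np.clip((v - lo) / (hi - lo), 0.0, 1.0)


# --------------------------------------------------------------------------
# frame statistics

def luminance(frame, weights=None) -> np.ndarray:
    """Per-pixel luminance: unweighted channel mean by default.

    The pipeline works in linear RGB; pass Rec.709 weights
    ``(0.2126, 0.7152, 0.0722)`` for photometric luminance instead.
    """
    v = frame_values(frame)
    if weights is None:
        return v.mean(axis=2)
    w = np.asarray(weights, dtype=np.float64)
    return v @ (w / w.sum())


def frame_stats(frame, weights=None) -> dict:
    """Michelson contrast, RMS contrast, entropy, mean and variance.

    Michelson = (Lmax - Lmin) / (Lmax + Lmin) (zero for a black frame);
    RMS contrast = std(L) / mean(L); entropy in bits over 256 luminance
    bins spanning [0, 1] (widened if values exceed it).
    """
    L = luminance(frame, weights)
    lmin, lmax = float(L.min()), float(L.max())
    denom = lmax + lmin
    michelson = (lmax - lmin) / denom if denom > 0 else 0.0
    mean = float(L.mean())
    rms = float(L.std() / mean) if mean > 0 else 0.0
    lo, hi = min(lmin, 0.0), max(lmax, 1.0)
    counts, _ = np.histogram(L, bins=256, range=(lo, hi))
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p)).sum() + 0.0)  # +0.0 normalizes -0.0
    return {
        "michelson": michelson,
        "rms_contrast": rms,
        "entropy_bits": entropy,
        "mean": mean,
        "variance": float(L.var()),
    }


# --------------------------------------------------------------------------
# color conversion

_XYZ_TO_RGB = np.array([  # sRGB primaries, D65 white, linear-light
    [3.2406, -1.5372, -0.4986],
    [-0.9689, 1.8758, 0.0415],
    [0.0557, -0.2040, 1.0570],
])


def color_convert(value, from_space: str):
    """Convert a color tuple from CMYK, HSV or XYZ into linear RGB in [0, 1]."""
    space = from_space.upper()
    v = tuple(float(c) for c in value)
    if space == "CMYK":
        if len(v) != 4 or not all(0 <= c <= 1 for c in v):
            raise ValueError("CMYK components must be 4 values in [0, 1]")
        c, m, y, k = v
        rgb = ((1 - c) * (1 - k), (1 - m) * (1 - k), (1 - y) * (1 - k))
    elif space == "HSV":
        if len(v) != 3 or not (0 <= v[1] <= 1 and 0 <= v[2] <= 1):
            raise ValueError("HSV needs (hue degrees, s in [0,1], v in [0,1])")
        h, s, val = v
        h = (h % 360.0) / 60.0
        i = int(h) % 6
        f = h - int(h)
        p, q, t = val * (1 - s), val * (1 - s * f), val * (1 - s * (1 - f))
        rgb = [(val, t, p), (q, val, p), (p, val, t),
               (p, q, val), (t, p, val), (val, p, q)][i]
    elif space == "XYZ":
        if len(v) != 3 or any(c < 0 for c in v):
            raise ValueError("XYZ components must be 3 non-negative values")
        rgb = tuple(_XYZ_TO_RGB @ np.asarray(v))
    else:
        raise ValueError(f"unknown color space {from_space!r}")
    return tuple(float(np.clip(c, 0.0, 1.0)) for c in rgb)


def receptor_activation(frame, matrix) -> np.ndarray:
    """Map RGB to receptor activation levels through a user 3x3 matrix."""
    m = np.asarray(matrix, dtype=np.float64)
    if m.shape != (3, 3):
        raise ValueError("receptor matrix must be 3x3")
    return frame_values(frame) @ m.T


# --------------------------------------------------------------------------
# gamma compensation

@dataclasses.dataclass
class GammaLUT:
    """Measured device curve and its tabulated inverse (the compensation).

    ``inputs``/``lum`` hold the normalized photometer samples of the device
    response D; ``comp_x``/``comp_y`` tabulate C = D^-1 so that C(D(v)) is
    the identity.  By construction C(0) = 0 and C(1) = 1.
    """

    inputs: np.ndarray
    lum: np.ndarray
    comp_x: np.ndarray
    comp_y: np.ndarray

    def device(self, v):
        """Simulated device response D(v) by piecewise-linear interpolation."""
        return np.interp(v, self.inputs, self.lum)

    def compensate(self, v):
        """Compensation C(v) by lookup with linear interpolation."""
        return np.interp(v, self.comp_x, self.comp_y)


def gamma_build(samples, n_entries: int = 256) -> GammaLUT:
    """Build the compensation LUT from measured (input, luminance) pairs.

    Samples are sorted by input value and must then be strictly increasing
    in both coordinates (a non-monotone photometer reading is reported with
    the index of the violation).  Luminance is rescaled to [0, 1]; the
    inverse is tabulated at ``n_entries`` points and applied by linear
    interpolation.
    """
    pts = sorted((float(a), float(b)) for a, b in samples)
    if len(pts) < 2:
        raise ValueError("need at least 2 gamma samples")
    inputs = np.array([p[0] for p in pts])
    lum = np.array([p[1] for p in pts])
    for i in range(1, len(pts)):
        if inputs[i] <= inputs[i - 1]:
            raise ValueError(f"gamma samples not strictly increasing in input at index {i}")
        if lum[i] <= lum[i - 1]:
            raise ValueError(f"gamma samples not strictly increasing in luminance at index {i}")
    inputs = (inputs - inputs[0]) / (inputs[-1] - inputs[0])
    lum = (lum - lum[0]) / (lum[-1] - lum[0])
    # tabulate the inverse on a uniform grid plus the measured luminance
    # knots, where the inverse of a steep gamma curve bends the hardest
    comp_x = np.union1d(np.linspace(0.0, 1.0, int(n_entries)), lum)
    comp_y = np.interp(comp_x, lum, inputs)  # inverse: luminance -> input
    return GammaLUT(inputs, lum, comp_x, comp_y)


def gamma_apply(frame, lut: GammaLUT) -> np.ndarray:
    """Per-channel application of the compensation lookup.

    Frames are expected in [0, 1] (gamma is the last stage, after tone
    mapping); out-of-range values are clamped with a warning.
    """
    v = frame_values(frame)
    if v.min() < 0.0 or v.max() > 1.0:
        import warnings

        warnings.warn("gamma_apply: frame outside [0, 1]; clamping", stacklevel=2)
        v = np.clip(v, 0.0, 1.0)
    return lut.compensate(v)
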