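"""Spatial and causal temporal filtering of rendered frames.

Spatial filtering is per-channel linear convolution with zero padding
outside the field, computed either directly (small kernels) or through a
padded FFT (large kernels); both routes give the same mathematical result.
Kernels may instead be specified in the frequency domain (low/band/high-pass
transfer functions applied with cyclic semantics, since no spatial support
exists).  Zero-integral difference-of-Gaussians kernels map homogeneous
regions to zero and may drive values beyond [0, 1]; a renorming tone map is
expected downstream.

Temporal filtering treats each pixel's value sequence as a discrete-time
signal.  Only past frames enter the filter (causality); looking "into the
future" is equivalent to filtering causally and presenting the stimulus
with a delay.  Smooth kernels can be realized recursively as a linear
time-invariant (LTI) state system whose impulse response is a sum of
complex exponentials, with constant per-pixel memory independent of kernel
length; :func:`fit_exponentials` converts a tap kernel into such a system.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, signal

from .geometry import frame_values


# --------------------------------------------------------------------------
# spatial kernels

@dataclasses.dataclass
class SpatialKernel:
    """Either an explicit odd-sized tap array or a frequency-domain transfer."""

    domain: str  # "spatial" | "frequency"
    weights: np.ndarray | None = None
    transfer: object = None  # callable rho (cycles/px) -> gain, or 2D array (DC centered)
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.domain not in ("spatial", "frequency"):
            raise ValueError("domain must be 'spatial' or 'frequency'")
        if self.domain == "spatial":
            w = np.asarray(self.weights, dtype=np.float64)
            if w.ndim != 2 or w.shape[0] % 2 == 0 or w.shape[1] % 2 == 0:
                raise ValueError("spatial kernels must be 2D with odd dimensions")
            self.weights = w

    def transfer_grid(self, shape: tuple[int, int]) -> np.ndarray:
        """Materialize the transfer function on the FFT grid (DC at [0, 0])."""
        if self.domain != "frequency":
            raise ValueError("not a frequency-domain kernel")
        if callable(self.transfer):
            fy = np.fft.fftfreq(shape[0])[:, None]
            fx = np.fft.fftfreq(shape[1])[None, :]
            return np.asarray(self.transfer(np.hypot(fy, fx)), dtype=np.float64)
        arr = np.asarray(self.transfer, dtype=np.float64)
        if arr.shape != shape:
            raise ValueError("custom transfer grid shape must match the frame")
        return np.fft.ifftshift(arr)  # stored DC-centered


def _odd_support(sigma: float) -> int:
    """Auto support: 4-sigma truncation radius, odd total size."""
    return 2 * max(1, int(np.ceil(4.0 * sigma))) + 1


def _gauss2d(size: int, sigma: float) -> np.ndarray:
    r = np.arange(size) - size // 2
    g = np.exp(-0.5 * (r / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def make_spatial_kernel(kind: str, **params) -> SpatialKernel:
    """Build a named spatial or frequency-domain kernel.

    Spatial kinds: ``gaussian`` (sigma; unit sum), ``dog`` (sigma_center <
    sigma_surround, optional gain; discrete sum exactly zero), ``gabor``
    (sigma, frequency, orientation, phase: Gaussian envelope times cosine
    carrier).  Frequency kinds: ``freq_lowpass`` / ``freq_highpass``
    (cutoff, cycles/px, Gaussian-radial rolloff), ``freq_bandpass``
    (center, bandwidth), ``freq_custom`` (callable or DC-centered 2D grid).
    """
    if kind == "gaussian":
        sigma = params.get("sigma", 2.0)
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        size = params.get("size") or _odd_support(sigma)
        return SpatialKernel("spatial", _gauss2d(size, sigma), params={"kind": kind, **params})
    if kind == "dog":
        s1 = params.get("sigma_center", 1.0)
        s2 = params.get("sigma_surround", 2.0)
        gain = params.get("gain", 1.0)
        if s1 <= 0 or s2 <= 0:
            raise ValueError("sigmas must be positive")
        if s2 <= s1:
            raise ValueError("sigma_surround must exceed sigma_center")
        size = params.get("size") or _odd_support(s2)
        center = _gauss2d(size, s1)
        surround = _gauss2d(size, s2)
        # both lobes unit-sum, so the difference has exactly zero integral
        k = gain * (center - surround)
        return SpatialKernel("spatial", k, params={"kind": kind, **params})
    if kind == "gabor":
        sigma = params.get("sigma", 2.0)
        freq = params.get("frequency", 0.1)  # cycles per px
        theta = params.get("orientation", 0.0)
        phase = params.get("phase", 0.0)
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        size = params.get("size") or _odd_support(sigma)
        r = np.arange(size) - size // 2
        X, Y = np.meshgrid(r, r)
        env = np.exp(-(X ** 2 + Y ** 2) / (2 * sigma ** 2))
        carrier = np.cos(2 * np.pi * freq * (X * np.cos(theta) + Y * np.sin(theta)) + phase)
        return SpatialKernel("spatial", env * carrier, params={"kind": kind, **params})
    if kind in ("freq_lowpass", "freq_highpass", "freq_bandpass"):
        if kind == "freq_bandpass":
            f0 = params.get("center", 0.1)
            bw = params.get("bandwidth", 0.05)
            if bw <= 0:
                raise ValueError("bandwidth must be positive")
            fn = lambda rho: np.exp(-0.5 * ((rho - f0) / bw) ** 2)
        else:
            fc = params.get("cutoff", 0.1)
            if fc <= 0:
                raise ValueError("cutoff must be positive")
            low = lambda rho: np.exp(-0.5 * (rho / fc) ** 2)
            fn = low if kind == "freq_lowpass" else (lambda rho: 1.0 - low(rho))
        return SpatialKernel("frequency", transfer=fn, params={"kind": kind, **params})
    if kind == "freq_custom":
        tr = params.get("transfer")
        if tr is None:
            raise ValueError("freq_custom needs a 'transfer' callable or grid")
        return SpatialKernel("frequency", transfer=tr, params={"kind": kind})
    raise ValueError(f"unknown spatial kernel kind {kind!r}")


def convolve_direct(frame, kernel: SpatialKernel) -> np.ndarray:
    """Per-channel direct 2D linear convolution, zero-padded, same size."""
    if kernel.domain != "spatial":
        raise ValueError("direct convolution needs a spatial-domain kernel")
    v = frame_values(frame)
    out = np.empty_like(v)
    for ch in range(3):
        out[:, :, ch] = signal.convolve2d(v[:, :, ch], kernel.weights,
                                          mode="same", boundary="fill")
    return out


def convolve_fft(frame, kernel: SpatialKernel) -> np.ndarray:
    """FFT-domain filtering.

    Spatial kernels: zero-padded linear convolution computed by padded FFT,
    cropped to the field — mathematically identical to
    :func:`convolve_direct`.  Frequency-specified kernels multiply the frame
    spectrum directly (cyclic semantics).
    """
    v = frame_values(frame)
    out = np.empty_like(v)
    if kernel.domain == "spatial":
        for ch in range(3):
            out[:, :, ch] = signal.fftconvolve(v[:, :, ch], kernel.weights, mode="same")
        return out
    H = kernel.transfer_grid(v.shape[:2])
    for ch in range(3):
        out[:, :, ch] = np.real(np.fft.ifft2(np.fft.fft2(v[:, :, ch]) * H))
    return out


def median_filter(frame, window: int) -> np.ndarray:
    """Per-channel moving median de-noising, edge-replicated borders."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    v = frame_values(frame)
    if window == 1:
        return v.copy()
    out = np.empty_like(v)
    for ch in range(3):
        out[:, :, ch] = ndimage.median_filter(v[:, :, ch], size=window, mode="nearest")
    return out


# --------------------------------------------------------------------------
# temporal kernels

@dataclasses.dataclass
class TemporalKernel:
    """Causal tap kernel over past frames; tap 0 weights the current frame."""

    taps: np.ndarray
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.taps, dtype=np.float64).ravel()
        if t.size < 1:
            raise ValueError("kernel must have >= 1 tap")
        self.taps = t

    def __len__(self):
        return self.taps.size


def _time_gauss(k, mu, sigma):
    return np.exp(-0.5 * ((k - mu) / sigma) ** 2)


def make_temporal_kernel(kind: str, length: int, **params) -> TemporalKernel:
    """Build a named temporal kernel of ``length`` taps.

    Window kinds (``rectangular``, ``triangular``, ``hamming``, ``hann``)
    and ``exponential`` attenuation (``h_k ~ a**k``, 0 < a < 1) are
    normalized to unit sum, so constants pass through unchanged once the
    window is full.  ``cell_dog`` — a difference of two Gaussians in time
    (positive lobe then delayed negative lobe), a coarse model of a retinal
    cell's biphasic impulse response — is normalized to exactly zero sum.
    """
    L = int(length)
    if L < 1:
        raise ValueError("length must be >= 1")
    if kind == "rectangular":
        taps = np.ones(L)
    elif kind == "triangular":
        taps = signal.windows.triang(L, sym=True)
    elif kind == "hamming":
        taps = signal.windows.hamming(L, sym=True)
    elif kind == "hann":
        taps = signal.windows.hann(L, sym=True)
    elif kind == "exponential":
        a = params.get("a", 0.8)
        if not 0 < a < 1:
            raise ValueError("exponential attenuation needs 0 < a < 1")
        taps = a ** np.arange(L)
    elif kind == "cell_dog":
        k = np.arange(L, dtype=float)
        mu1 = params.get("mu1", L / 6.0)
        s1 = params.get("sigma1", max(L / 10.0, 0.5))
        w1 = params.get("w1", 1.0)
        mu2 = params.get("mu2", L / 2.0)
        s2 = params.get("sigma2", max(L / 6.0, 0.5))
        w2 = params.get("w2", 0.8)
        pos = w1 * _time_gauss(k, mu1, s1)
        neg = w2 * _time_gauss(k, mu2, s2)
        if neg.sum() == 0:
            raise ValueError("degenerate cell_dog: negative lobe vanishes on the support")
        taps = pos - neg * (pos.sum() / neg.sum())
        return TemporalKernel(taps, {"kind": kind, **params})
    else:
        raise ValueError(f"unknown temporal kernel kind {kind!r}")
    s = taps.sum()
    if s != 0:
        taps = taps / s
    return TemporalKernel(taps, {"kind": kind, **params})


class TemporalConvolver:
    """Ring buffer realizing causal convolution over a frame stream.

    ``y_t = sum_k h_k x_{t-k}`` with frames before the stimulus start
    treated as zero (or held at the first frame with ``prestim='hold'``).
    """

    def __init__(self, kernel: TemporalKernel, prestim: str = "zero"):
        if prestim not in ("zero", "hold"):
            raise ValueError("prestim must be 'zero' or 'hold'")
        self.kernel = kernel
        self.prestim = prestim
        self._buffer: list[np.ndarray] = []

    def step(self, new_frame) -> np.ndarray:
        x = frame_values(new_frame)
        if not self._buffer and self.prestim == "hold":
            self._buffer = [x] * (len(self.kernel) - 1)
        self._buffer.insert(0, x)
        del self._buffer[len(self.kernel):]
        out = np.zeros_like(x)
        for h_k, past in zip(self.kernel.taps, self._buffer):
            out += h_k * past
        return out


def temporal_convolve(convolver: TemporalConvolver, kernel: TemporalKernel, new_frame):
    """Advance the ring buffer by one frame and return the filtered frame."""
    if convolver.kernel is not kernel and len(convolver.kernel) != len(kernel):
        raise ValueError("kernel length does not match the ring buffer")
    return convolver.step(new_frame)


# --------------------------------------------------------------------------
# LTI state systems

class LTISystem:
    """Diagonal complex-exponential state system applied pointwise.

    Per frame: ``y = d*x + sum_j Re(s_j)`` then ``s_j <- z_j * (s_j + c_j x)``,
    with states initialized to zero at stimulus start.  The realized impulse
    response is therefore ``h_0 = d`` and ``h_k = sum_j Re(c_j z_j^k)`` for
    k >= 1.  Memory per pixel is constant, independent of the equivalent
    kernel length.
    """

    def __init__(self, poles, coefficients, direct: float = 0.0):
        self.poles = np.asarray(poles, dtype=np.complex128).ravel()
        self.coefficients = np.asarray(coefficients, dtype=np.complex128).ravel()
        if self.poles.shape != self.coefficients.shape:
            raise ValueError("poles and coefficients must pair up")
        if np.any(np.abs(self.poles) >= 1.0):
            bad = np.abs(self.poles).max()
            raise ValueError(f"unstable pole |z| = {bad:.6f} >= 1 rejected")
        self.direct = float(direct)
        self._states: np.ndarray | None = None

    def reset(self) -> None:
        self._states = None

    def impulse_response(self, length: int) -> np.ndarray:
        k = np.arange(length)
        h = np.sum(np.real(self.coefficients[:, None] * self.poles[:, None] ** k[None, :]), axis=0)
        h[0] = self.direct  # states are zero when the impulse arrives
        return h

    def step(self, new_frame) -> np.ndarray:
        x = frame_values(new_frame)
        if self._states is None:
            self._states = np.zeros((len(self.poles),) + x.shape, dtype=np.complex128)
        y = self.direct * x + np.sum(np.real(self._states), axis=0)
        for j, (z, c) in enumerate(zip(self.poles, self.coefficients)):
            self._states[j] = z * (self._states[j] + c * x)
        return y


def lti_step(system: LTISystem, new_frame) -> np.ndarray:
    """Advance the LTI system by one input frame; returns the output frame."""
    return system.step(new_frame)


def fit_exponentials(kernel: TemporalKernel, n_poles: int) -> tuple[LTISystem, float]:
    """Prony-type fit of a tap kernel by a sum of complex exponentials.

    Linear prediction (least squares) yields the pole polynomial; a second
    linear solve fits the complex output coefficients.  Returns the system
    together with the max-abs residual of the reconstructed impulse
    response — the caller decides whether the fit is acceptable.  Fitted
    systems with any |z| >= 1 are rejected with an error reporting the
    offending magnitude.
    """
    h = kernel.taps
    p = int(n_poles)
    L = h.size
    if p < 1:
        raise ValueError("n_poles must be >= 1")
    if L <= 2 * p:
        raise ValueError("kernel must be longer than 2 * n_poles")
    # linear prediction: h[k] = -sum_{i=1..p} a_i h[k-i]
    A = np.column_stack([h[p - i: L - i] for i in range(1, p + 1)])
    b = -h[p:L]
    a, *_ = np.linalg.lstsq(A, b, rcond=None)
    poles = np.roots(np.concatenate(([1.0], a)))
    # complex Vandermonde solve for the coefficients on taps 1..L-1; the
    # direct term carries tap 0 exactly (the recursion outputs d on impulse)
    k = np.arange(1, L)
    V = poles[None, :] ** k[:, None]
    c, *_ = np.linalg.lstsq(V, h[1:].astype(np.complex128), rcond=None)
    system = LTISystem(poles, c, direct=float(h[0]))  # raises on unstable poles
    residual = float(np.max(np.abs(h - system.impulse_response(L))))
    return system, residual
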