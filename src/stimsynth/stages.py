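"""Post-processing and composition SBCs wrapping the filtering/tone modules.

These components adapt the functional filtering and tone-mapping operations
to the per-frame pipeline: each holds its declarative parameters and applies
the operation to the frame array, keeping any cross-frame state (temporal
ring buffers, LTI states) in the render context so a fresh context restarts
the stimulus cleanly.
"""

from __future__ import annotations

import numpy as np

from .components import Component, register
from . import filtering, postprocess


@register("composition", "mix")
class MixComposition(Component):
    """Foreground/mask/background template; indices reference primers."""

    DEFAULTS = {"foreground": 1, "background": 0, "mask": 2}


@register("prng", "xorshift128")
class XorshiftPRNG(Component):
    """Declarative marker configuring the seed of grid random streams.

    Checkerboard primers default to seeds derived from the stimulus seed;
    listing this component pins the base seed explicitly for provenance.
    """

    DEFAULTS = {"seed": 0}

    def prepare(self, t_frame, ctx):
        ctx.seed = int(self.params["seed"])


class _SpatialFilter(Component):
    def apply(self, values, ctx):  # pragma: no cover - interface
        raise NotImplementedError


@register("spatial_filter", "convolve")
class ConvolveFilter(_SpatialFilter):
    """Linear spatial filtering with a named kernel.

    ``method='auto'`` picks direct convolution for small kernels and the
    FFT route for large ones or frequency-specified kernels; the two routes
    are mathematically identical for spatial kernels.
    """

    DEFAULTS = {"kind": "dog", "method": "auto", "sigma": 2.0,
                "sigma_center": 1.0, "sigma_surround": 2.0, "gain": 1.0,
                "frequency": 0.1, "orientation": 0.0, "phase": 0.0,
                "cutoff": 0.1, "center": 0.1, "bandwidth": 0.05,
                "size": None, "transfer": None}

    _KERNEL_KEYS = {
        "gaussian": ("sigma", "size"),
        "dog": ("sigma_center", "sigma_surround", "gain", "size"),
        "gabor": ("sigma", "frequency", "orientation", "phase", "size"),
        "freq_lowpass": ("cutoff",),
        "freq_highpass": ("cutoff",),
        "freq_bandpass": ("center", "bandwidth"),
        "freq_custom": ("transfer",),
    }

    def _validate(self):
        if self.params["kind"] not in self._KERNEL_KEYS:
            raise ValueError(f"unknown kernel kind {self.params['kind']!r}")
        if self.params["method"] not in ("auto", "direct", "fft"):
            raise ValueError("method must be auto, direct or fft")

    def kernel(self) -> filtering.SpatialKernel:
        kind = self.params["kind"]
        kw = {k: self.params[k] for k in self._KERNEL_KEYS[kind]
              if self.params[k] is not None}
        return filtering.make_spatial_kernel(kind, **kw)

    def apply(self, values, ctx):
        k = self.kernel()
        method = self.params["method"]
        if k.domain == "frequency":
            return filtering.convolve_fft(values, k)
        if method == "direct" or (method == "auto" and max(k.weights.shape) <= 15):
            return filtering.convolve_direct(values, k)
        return filtering.convolve_fft(values, k)


@register("spatial_filter", "median")
class MedianFilter(_SpatialFilter):
    DEFAULTS = {"window": 3}

    def apply(self, values, ctx):
        return filtering.median_filter(values, int(self.params["window"]))


@register("temporal_filter", "convolve")
class TemporalConvolveFilter(Component):
    """Causal temporal filtering with a named tap kernel.

    ``realization='direct'`` keeps a ring buffer of the last L frames;
    ``realization='lti'`` fits the kernel with ``n_poles`` complex
    exponentials once and runs the recursive state system instead (constant
    memory per pixel).  Pre-stimulus frames are zero, or the first frame is
    held with ``prestim='hold'``.
    """

    DEFAULTS = {"kind": "exponential", "length": 8, "a": 0.8,
                "mu1": None, "sigma1": None, "w1": None,
                "mu2": None, "sigma2": None, "w2": None,
                "prestim": "zero", "realization": "direct", "n_poles": 2}

    def _validate(self):
        if self.params["realization"] not in ("direct", "lti"):
            raise ValueError("realization must be 'direct' or 'lti'")

    def kernel(self) -> filtering.TemporalKernel:
        p = self.params
        extra = {}
        if p["kind"] == "exponential":
            extra["a"] = p["a"]
        if p["kind"] == "cell_dog":
            extra = {k: p[k] for k in ("mu1", "sigma1", "w1", "mu2", "sigma2", "w2")
                     if p[k] is not None}
        return filtering.make_temporal_kernel(p["kind"], int(p["length"]), **extra)

    def apply(self, values, ctx):
        slot = ctx.state_for(self)
        if "engine" not in slot:
            kernel = self.kernel()
            if self.params["realization"] == "lti":
                system, residual = filtering.fit_exponentials(kernel, int(self.params["n_poles"]))
                slot["fit_residual"] = residual
                slot["engine"] = system
            else:
                slot["engine"] = filtering.TemporalConvolver(kernel, self.params["prestim"])
        return slot["engine"].step(values)


@register("temporal_filter", "lti")
class LTIFilter(Component):
    """Directly specified LTI state system (poles, coefficients, direct term).

    Poles and coefficients are given as ``[re, im]`` pairs; useful when the
    differential equations of a theoretical system realization are known.
    """

    DEFAULTS = {"poles": ((0.5, 0.0),), "coefficients": ((1.0, 0.0),), "direct": 0.0}

    def system(self) -> filtering.LTISystem:
        poles = [complex(p[0], p[1]) for p in self.params["poles"]]
        coeff = [complex(c[0], c[1]) for c in self.params["coefficients"]]
        return filtering.LTISystem(poles, coeff, float(self.params["direct"]))

    def apply(self, values, ctx):
        slot = ctx.state_for(self)
        if "engine" not in slot:
            slot["engine"] = self.system()
        return slot["engine"].step(values)


class _ToneMap(Component):
    DEFAULTS = {"lo": None, "hi": None, "center": 0.5, "slope": 10.0,
                "n_bins": 256, "dynamic": True}


@register("tonemap", "stretch")
class StretchToneMap(_ToneMap):
    """Linear contrast stretch of [lo, hi] (measured bounds by default)."""


@register("tonemap", "sigmoid")
class SigmoidToneMap(_ToneMap):
    """Logistic transfer 1 / (1 + exp(-slope (v - center)))."""


@register("tonemap", "equalize")
class EqualizeToneMap(_ToneMap):
    """Histogram equalization through the measured intensity CDF."""


@register("tonemap", "renorm")
class RenormToneMap(_ToneMap):
    """Affine map of the measured intensity range onto [0, 1]."""


@register("gamma", "compensate")
class GammaCompensate(Component):
    """Gamma compensation from measured samples or a power-law exponent.

    Provide photometer ``samples`` as (input, luminance) pairs, or an
    ``exponent`` g to synthesize samples of the power-law device D(v) = v**g
    at ``n_samples`` points.
    """

    DEFAULTS = {"samples": None, "exponent": None, "n_samples": 33, "n_entries": 256}

    def _validate(self):
        if self.params["samples"] is None and self.params["exponent"] is None:
            raise ValueError("gamma needs 'samples' or an 'exponent'")

    def lut(self) -> postprocess.GammaLUT:
        if not hasattr(self, "_lut"):
            samples = self.params["samples"]
            if samples is None:
                g = float(self.params["exponent"])
                v = np.linspace(0.0, 1.0, int(self.params["n_samples"]))
                samples = list(zip(v, v ** g))
            self._lut = postprocess.gamma_build(samples, int(self.params["n_entries"]))
        return self._lut

    def apply(self, values, ctx):
        return postprocess.gamma_apply(values, self.lut())
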