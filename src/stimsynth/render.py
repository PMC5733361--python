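"""Per-frame rendering workflow: prerequisites, core rendering, post-processing.

One frame is produced in three phases.  *Prerequisites* advance stateful
streams (random grids for checkerboards).  *Core rendering* evaluates each
primer pointwise at warped, motion-shifted pixel-center coordinates, scales
it by its modulation, and combines primers — either through an explicit mix
composition (foreground/mask/background template) or by compositing each
primer over the canvas with its coverage alpha, in listed order.  *Post
processing* applies the frame's spatial filters, the temporal filter, tone
mapping and gamma compensation, in the order the components are listed.

Decoration binding: motion, modulation and warp components attach to the
most recently listed primer.  Rendering is deterministic — identical
stimulus, seed and geometry produce bit-identical frame stacks.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np

from .components import ComponentSpec, StimulusSpec
from .geometry import FieldGeometry, Frame, frame_values
from . import filtering, postprocess
from .postprocess import HistogramReport, ToneMapSpec


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclasses.dataclass
class RenderContext:
    """The only mutable carrier across the frames of one stimulus.

    Holds the geometry, the seed, per-component PRNG/grid state, temporal
    filter state, and the optional global histogram used by static tone
    mapping.  A fresh context restarts the stimulus from scratch.
    """

    geometry: FieldGeometry
    seed: int = 0
    global_stats: HistogramReport | None = None
    component_state: dict[int, dict] = dataclasses.field(default_factory=dict)
    temporal_state: Any = None
    last_grids: Any = None

    def state_for(self, component) -> dict:
        key = getattr(component, "_slot", id(component))
        return self.component_state.setdefault(key, {})

    def record_grids(self, grids) -> None:
        """Remember the most recent random grid(s) (for export alongside frames)."""
        self.last_grids = grids


def _build_components(stimulus: StimulusSpec, ctx: RenderContext):
    slot = ctx.component_state.setdefault("__built__", {})
    if "components" not in slot:
        comps = []
        for i, spec in enumerate(stimulus.components):
            c = spec.build()
            c._slot = i
            comps.append(c)
        slot["components"] = comps
    return slot["components"]


def _tonemap_spec(comp) -> ToneMapSpec:
    p = comp.params
    return ToneMapSpec(kind=comp.name, lo=p.get("lo"), hi=p.get("hi"),
                       center=p.get("center", 0.5), slope=p.get("slope", 10.0),
                       n_bins=p.get("n_bins", 256), dynamic=p.get("dynamic", True))


def _core_render(stimulus, comps, t_frame, t, ctx) -> np.ndarray:
    g = ctx.geometry
    X0, Y0 = g.pixel_centers()
    duration_s = stimulus.duration_frames / g.frame_rate_hz

    # group decorations with their primer, in listed order
    layers: list[dict] = []
    composition = None
    for comp in comps:
        if comp.sbc_type == "primer":
            layers.append({"index": comp._slot, "primer": comp,
                           "motions": [], "modulations": [], "warps": []})
        elif comp.sbc_type in ("motion", "modulation", "warp"):
            if not layers:
                raise ValueError(f"{comp.sbc_type}/{comp.name} listed before any primer")
            layers[-1][comp.sbc_type + "s"].append(comp)
        elif comp.sbc_type == "composition":
            composition = comp

    if not layers:
        raise ValueError("stimulus has no primer component")

    wanted = set()
    if composition is not None:
        wanted = {composition.params[k] for k in ("foreground", "background", "mask")}

    kept: dict[int, np.ndarray] = {}
    canvas = np.zeros(g.shape + (3,))
    for layer in layers:
        X, Y = X0, Y0
        for warp in layer["warps"]:
            X, Y = warp.map_coords(X, Y, ctx)
        for motion in layer["motions"]:
            ox, oy = motion.offset(t, g, t_frame=t_frame)
            X, Y = X - ox, Y - oy
        rgb, alpha = layer["primer"].evaluate(X, Y, t, ctx)
        rgb = np.asarray(rgb, dtype=np.float64)
        for mod in layer["modulations"]:
            rgb = rgb * mod.value(t, duration_s, g.frame_rate_hz)
        if composition is None:
            a = np.asarray(alpha)[:, :, None]
            canvas = a * rgb + (1.0 - a) * canvas
        elif layer["index"] in wanted:
            kept[layer["index"]] = rgb

    if composition is not None:
        p = composition.params
        return compose_mix(kept[p["foreground"]], kept[p["background"]],
                           kept[p["mask"]])
    return canvas


def render_frame(stimulus: StimulusSpec, t_frame: int, ctx: RenderContext) -> Frame:
    """Render frame ``t_frame`` of a stimulus, advancing the context once."""
    if not 0 <= t_frame < stimulus.duration_frames:
        raise ValueError(
            f"t_frame {t_frame} outside [0, {stimulus.duration_frames})")
    comps = _build_components(stimulus, ctx)
    t = ctx.geometry.time_of_frame(t_frame)

    try:
        for comp in comps:
            comp.prepare(t_frame, ctx)
    except Exception as e:  # noqa: BLE001 - stage name context
        raise StageError("prerequisites", e) from e

    try:
        values = _core_render(stimulus, comps, t_frame, t, ctx)
    except Exception as e:  # noqa: BLE001
        raise StageError("core_rendering", e) from e

    for comp in comps:
        stage = f"{comp.sbc_type}/{comp.name}"
        try:
            if comp.sbc_type == "spatial_filter":
                values = comp.apply(values, ctx)
            elif comp.sbc_type == "temporal_filter":
                values = comp.apply(values, ctx)
            elif comp.sbc_type == "tonemap":
                spec = _tonemap_spec(comp)
                report = None if spec.dynamic else ctx.global_stats
                values = postprocess.tone_map(values, spec, report)
            elif comp.sbc_type == "gamma":
                values = comp.apply(values, ctx)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

    return Frame(values, t_frame)


def compose_mix(foreground, background, mask) -> np.ndarray:
    """Per-pixel linear interpolation of two primers controlled by a third.

    ``out = mask * foreground + (1 - mask) * background`` — the foreground
    shows inside the masking shape, the background outside.
    """
    fg = frame_values(foreground)
    bg = frame_values(background)
    m = frame_values(mask)
    if fg.shape != bg.shape or fg.shape != m.shape:
        raise ValueError("mix inputs must share geometry")
    if m.min() < -1e-12 or m.max() > 1 + 1e-12:
        raise ValueError("mask values must lie in [0, 1]")
    return m * fg + (1.0 - m) * bg


def crossfade(primer_a: ComponentSpec, primer_b: ComponentSpec,
              duration_frames: int, label: str = "crossfade") -> StimulusSpec:
    """Smooth interchange between two primers over a duration.

    The mask is a fullfield primer under linear modulation rising 0 -> 1
    with mask(t_frame) = t_frame / (duration_frames - 1): frame 0 shows pure
    ``a``, the final frame pure ``b`` (a single-frame fade shows pure ``b``).
    """
    if int(duration_frames) < 1:
        raise ValueError("duration_frames must be >= 1")
    mask = ComponentSpec("primer", "fullfield", {"color": 1.0})
    ramp = ComponentSpec("modulation", "linear",
                         {"start": 0.0, "end": 1.0,
                          "ramp_frames": int(duration_frames) - 1})
    mix = ComponentSpec("composition", "mix",
                        {"foreground": 1, "background": 0, "mask": 2})
    return StimulusSpec(
        components=[primer_a, primer_b, mask, ramp, mix],
        duration_frames=int(duration_frames),
        label=label,
    )


def render_stimulus(stimulus: StimulusSpec, geometry: FieldGeometry,
                    seed: int = 0, ctx: RenderContext | None = None):
    """Yield every frame of a stimulus with one shared context.

    If the stimulus contains a static (non-dynamic) tone map, a measuring
    prepass renders the stimulus up to (not including) tone mapping with an
    identically seeded context to obtain the global histogram first.
    """
    if ctx is None:
        ctx = RenderContext(geometry=geometry, seed=seed)
    if ctx.global_stats is None and _needs_global_stats(stimulus):
        ctx.global_stats = measure_stimulus_stats(stimulus, geometry, seed)
    for k in range(stimulus.duration_frames):
        yield render_frame(stimulus, k, ctx)


def _needs_global_stats(stimulus: StimulusSpec) -> bool:
    return any(c.sbc_type == "tonemap" and c.params.get("dynamic") is False
               for c in stimulus.components)


def measure_stimulus_stats(stimulus: StimulusSpec, geometry: FieldGeometry,
                           seed: int = 0, n_bins: int = 256) -> HistogramReport:
    """Global intensity distribution of a stimulus before tone mapping.

    Runs a full prepass with a fresh, identically seeded context, rendering
    each frame with the tone-map and gamma stages stripped, and pools the
    resulting intensities into one report.
    """
    pre = StimulusSpec(
        components=[c for c in stimulus.components
                    if c.sbc_type not in ("tonemap", "gamma")],
        duration_frames=stimulus.duration_frames,
        label=stimulus.label,
    )
    ctx = RenderContext(geometry=geometry, seed=seed)
    frames = [render_frame(pre, k, ctx).values for k in range(pre.duration_frames)]
    return postprocess.measure_histogram(frames, n_bins=n_bins, scope="global")
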