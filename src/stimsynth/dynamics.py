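"""Motion, modulation and warp SBCs that decorate primers.

Inside core rendering the decoration order is fixed: warps transform pixel
coordinates first, then the motion offset is subtracted, then the primer is
evaluated at the resulting coordinates, and finally the modulation scalar
multiplies the primer's intensity.  Modulation therefore scales intensity
(it does not interpolate toward a background color); building a fade toward
a color is done explicitly with a mix composition.
"""

from __future__ import annotations

import math

import numpy as np

from .components import Component, register
from . import randoms as rnd


# --------------------------------------------------------------------------
# motion

class Motion(Component):
    """Produces a displacement vector (dx, dy) as a function of time."""

    def _base_offset(self, t, geometry):  # pragma: no cover - interface
        raise NotImplementedError

    def offset(self, t: float, geometry, t_frame: int | None = None):
        ox, oy = self._base_offset(t, geometry)
        amp = float(self.params.get("shake_amplitude", 0.0))
        if amp > 0.0:
            if t_frame is None and geometry is not None:
                t_frame = int(round(t * geometry.frame_rate_hz))
            seed = self.params.get("shake_seed") or 1
            ux, uy = rnd.uniform_pair(int(seed), int(t_frame or 0))
            ox += amp * (2.0 * ux - 1.0)
            oy += amp * (2.0 * uy - 1.0)
        return (ox, oy)


_SHAKE_DEFAULTS = {"shake_amplitude": 0.0, "shake_seed": 1}


@register("motion", "static")
class StaticMotion(Motion):
    DEFAULTS = {**_SHAKE_DEFAULTS}

    def _base_offset(self, t, geometry):
        return (0.0, 0.0)


@register("motion", "linear")
class LinearMotion(Motion):
    """Constant-velocity sweep.

    Exactly one of ``velocity`` (a length/second vector) or
    ``crossing_time`` must be given.  With ``crossing_time``, the speed is
    derived so the shape crosses the whole field along ``direction``:
    ``(field extent along direction + shape_extent) / crossing_time``.
    """

    DEFAULTS = {"velocity": None, "crossing_time": None, "direction": 0.0,
                "shape_extent": 0.0, **_SHAKE_DEFAULTS}

    def _validate(self):
        v, ct = self.params["velocity"], self.params["crossing_time"]
        if (v is None) == (ct is None):
            raise ValueError("linear motion needs exactly one of velocity / crossing_time")
        if ct is not None and ct <= 0:
            raise ValueError("crossing_time must be positive")

    def velocity_vector(self, geometry):
        v = self.params["velocity"]
        if v is not None:
            return (float(v[0]), float(v[1]))
        theta = float(self.params["direction"])
        extent = (abs(geometry.width_um * math.cos(theta))
                  + abs(geometry.height_um * math.sin(theta)))
        speed = (extent + float(self.params["shape_extent"])) / self.params["crossing_time"]
        return (speed * math.cos(theta), speed * math.sin(theta))

    def _base_offset(self, t, geometry):
        vx, vy = self.velocity_vector(geometry)
        return (vx * t, vy * t)


def _hermite(t, cps):
    """Cubic Hermite interpolation through (time, position, velocity) points."""
    times = [c[0] for c in cps]
    if t <= times[0]:
        return tuple(cps[0][1])
    if t >= times[-1]:
        return tuple(cps[-1][1])
    k = max(i for i, tk in enumerate(times) if tk <= t)
    t0, p0, v0 = cps[k]
    t1, p1, v1 = cps[k + 1]
    h = t1 - t0
    s = (t - t0) / h
    h00 = (1 + 2 * s) * (1 - s) ** 2
    h10 = s * (1 - s) ** 2
    h01 = s * s * (3 - 2 * s)
    h11 = s * s * (s - 1)
    return tuple(
        h00 * p0[d] + h10 * h * v0[d] + h01 * p1[d] + h11 * h * v1[d]
        for d in range(2)
    )


@register("motion", "path")
class PathMotion(Motion):
    """Free-form trajectory through control points with prescribed velocities.

    ``control_points`` is a list of ``[time, [x, y], [vx, vy]]`` entries with
    strictly increasing times; positions are interpolated by cubic Hermite
    splines, and times outside the span clamp to the endpoint positions.
    """

    DEFAULTS = {"control_points": None, **_SHAKE_DEFAULTS}

    def _validate(self):
        cps = self.params["control_points"]
        if not cps or len(cps) < 2:
            raise ValueError("path motion needs >= 2 control points")
        times = [c[0] for c in cps]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("control point times must be strictly increasing")

    def _base_offset(self, t, geometry):
        return _hermite(t, [(c[0], tuple(c[1]), tuple(c[2])) for c in self.params["control_points"]])


def motion_offset(motion: Motion, t: float, geometry=None, shape_extent: float | None = None,
                  t_frame: int | None = None):
    """Displacement of a motion component at time ``t`` (seconds)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if shape_extent is not None and "shape_extent" in motion.DEFAULTS:
        motion = type(motion)(**{**motion.params, "shape_extent": shape_extent})
    return motion.offset(t, geometry, t_frame=t_frame)


# --------------------------------------------------------------------------
# modulation

class Modulation(Component):
    """Produces a scalar intensity factor in [0, 1] as a function of time."""

    def _raw(self, t, duration_s):  # pragma: no cover - interface
        raise NotImplementedError

    def value(self, t: float, duration_s: float | None = None,
              frame_rate_hz: float | None = None) -> float:
        self._frame_rate = frame_rate_hz
        return float(np.clip(self._raw(t, duration_s), 0.0, 1.0))


@register("modulation", "constant")
class ConstantModulation(Modulation):
    DEFAULTS = {"value": 1.0}

    def _raw(self, t, duration_s):
        return self.params["value"]


@register("modulation", "linear")
class LinearModulation(Modulation):
    """Linear fade from ``start`` to ``end``.

    The ramp length is ``ramp_s`` seconds, or ``ramp_frames`` frame steps
    (so a ramp over D frames runs 0 -> 1 with mask(t_frame) =
    t_frame/(D-1)); when neither is given the ramp spans the whole stimulus
    duration.  A zero-length ramp yields ``end`` immediately.
    """

    DEFAULTS = {"start": 0.0, "end": 1.0, "ramp_s": None, "ramp_frames": None}

    def _raw(self, t, duration_s):
        ramp = self.params["ramp_s"]
        if ramp is None and self.params["ramp_frames"] is not None:
            rate = getattr(self, "_frame_rate", None)
            if rate is None:
                raise ValueError("ramp_frames requires a frame rate context")
            ramp = self.params["ramp_frames"] / rate
        if ramp is None:
            ramp = duration_s
        if ramp is None:
            raise ValueError("linear modulation needs ramp_s, ramp_frames or a stimulus duration")
        a, b = self.params["start"], self.params["end"]
        if ramp <= 0:
            return b
        s = min(max(t / ramp, 0.0), 1.0)
        return a + (b - a) * s


def _chirp_phase(t, f_start, f_end, sweep_s):
    """Integrated phase of a linear frequency sweep (continuous-phase chirp)."""
    if sweep_s is None or sweep_s <= 0 or f_start == f_end:
        return 2 * math.pi * f_start * t
    if t <= sweep_s:
        return 2 * math.pi * (f_start * t + (f_end - f_start) * t * t / (2 * sweep_s))
    phi_end = 2 * math.pi * (f_start * sweep_s + (f_end - f_start) * sweep_s / 2)
    return phi_end + 2 * math.pi * f_end * (t - sweep_s)


class _WaveModulation(Modulation):
    DEFAULTS = {"offset": 0.5, "amplitude_start": 0.5, "amplitude_end": None,
                "frequency_start": 1.0, "frequency_end": None, "phase": 0.0}

    def _validate(self):
        if self.params["frequency_start"] < 0:
            raise ValueError("frequencies must be >= 0")

    def _amp_phase(self, t, duration_s):
        p = self.params
        a0 = p["amplitude_start"]
        a1 = p["amplitude_end"] if p["amplitude_end"] is not None else a0
        f0 = p["frequency_start"]
        f1 = p["frequency_end"] if p["frequency_end"] is not None else f0
        if duration_s and duration_s > 0:
            s = min(max(t / duration_s, 0.0), 1.0)
        else:
            s = 0.0
        amp = a0 + (a1 - a0) * s
        phi = _chirp_phase(t, f0, f1, duration_s) + p["phase"]
        return amp, phi


@register("modulation", "sine")
class SineModulation(_WaveModulation):
    """Sinusoidal intensity modulation with linearly swept amplitude/frequency."""

    def _raw(self, t, duration_s):
        amp, phi = self._amp_phase(t, duration_s)
        return self.params["offset"] + amp * math.sin(phi)


@register("modulation", "square")
class SquareModulation(_WaveModulation):
    """Two-level modulation thresholding the same swept phase as the sine."""

    def _raw(self, t, duration_s):
        amp, phi = self._amp_phase(t, duration_s)
        return self.params["offset"] + (amp if math.sin(phi) >= 0 else -amp)


@register("modulation", "multi_component")
class MultiComponentModulation(Modulation):
    """Sum of sinusoids, normalized by total amplitude and shifted into [0, 1].

    ``components`` is a list of ``[frequency_hz, amplitude, phase]`` triples:
    m(t) = 0.5 + 0.5 * sum_i a_i sin(2 pi f_i t + phi_i) / sum_i a_i.
    """

    DEFAULTS = {"components": None}

    def _validate(self):
        comps = self.params["components"]
        if not comps:
            raise ValueError("multi_component modulation needs >= 1 component")
        if any(c[0] < 0 for c in comps):
            raise ValueError("frequencies must be >= 0")

    def _raw(self, t, duration_s):
        comps = self.params["components"]
        total = sum(abs(c[1]) for c in comps)
        if total == 0:
            return 0.5
        s = sum(c[1] * math.sin(2 * math.pi * c[0] * t + (c[2] if len(c) > 2 else 0.0))
                for c in comps)
        return 0.5 + 0.5 * s / total


def modulation_value(mod: Modulation, t: float, duration_s: float | None = None,
                     frame_rate_hz: float | None = None) -> float:
    """Modulation factor at time ``t`` (seconds), clamped to [0, 1]."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return mod.value(t, duration_s, frame_rate_hz)


# --------------------------------------------------------------------------
# warps

class Warp(Component):
    """Maps pixel-center coordinates before primer evaluation."""

    def map_coords(self, x, y, ctx=None):  # pragma: no cover - interface
        raise NotImplementedError


@register("warp", "identity")
class IdentityWarp(Warp):
    DEFAULTS = {}

    def map_coords(self, x, y, ctx=None):
        return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


@register("warp", "repeat")
class RepeatWarp(Warp):
    """Tiles the primer by taking coordinates modulo the stated periods."""

    DEFAULTS = {"period_x": 20.0, "period_y": 20.0}

    def _validate(self):
        if self.params["period_x"] == 0 or self.params["period_y"] == 0:
            raise ValueError("repeat periods must be nonzero")

    def map_coords(self, x, y, ctx=None):
        return (np.mod(x, self.params["period_x"]),
                np.mod(y, self.params["period_y"]))


@register("warp", "polar")
class PolarWarp(Warp):
    """Maps (x, y) to (radius, angle * angle_scale) about a center.

    Feeding a checkerboard or grating through this warp produces ring/sector
    patterns (checkerboards "in polar coordinates").
    """

    DEFAULTS = {"center": None, "angle_scale": 10.0}

    def map_coords(self, x, y, ctx=None):
        c = self.params["center"]
        if c is None:
            c = ctx.geometry.center if ctx is not None else (0.0, 0.0)
        dx = np.asarray(x, dtype=float) - c[0]
        dy = np.asarray(y, dtype=float) - c[1]
        return np.hypot(dx, dy), np.arctan2(dy, dx) * self.params["angle_scale"]


@register("warp", "pinch_twist")
class PinchTwistWarp(Warp):
    """Nonlinear pinch-twist distortion inside a disc of radius ``radius``.

    For r < R the coordinates are rotated by ``twist * (1 - r/R)**2`` and the
    radius is remapped to ``(r/R)**strength * R``; the mapping is the
    identity at the rim and outside, so the distortion blends continuously
    into the undistorted field.
    """

    DEFAULTS = {"center": None, "radius": 50.0, "strength": 1.0, "twist": math.pi / 2}

    def _validate(self):
        if self.params["radius"] <= 0:
            raise ValueError("radius must be positive")
        if self.params["strength"] <= 0:
            raise ValueError("strength must be positive")

    def map_coords(self, x, y, ctx=None):
        c = self.params["center"]
        if c is None:
            c = ctx.geometry.center if ctx is not None else (0.0, 0.0)
        R = self.params["radius"]
        dx = np.asarray(x, dtype=float) - c[0]
        dy = np.asarray(y, dtype=float) - c[1]
        r = np.hypot(dx, dy)
        inside = r < R
        with np.errstate(invalid="ignore", divide="ignore"):
            rr = np.where(r > 0, r, 1.0)
            angle = self.params["twist"] * (1.0 - r / R) ** 2
            new_r = np.power(r / R, self.params["strength"]) * R
            cos_a, sin_a = np.cos(angle), np.sin(angle)
            nx = (dx * cos_a - dy * sin_a) / rr * np.where(inside, new_r, r)
            ny = (dx * sin_a + dy * cos_a) / rr * np.where(inside, new_r, r)
        nx = np.where(r == 0, 0.0, nx)
        ny = np.where(r == 0, 0.0, ny)
        return (np.where(inside, nx, dx) + c[0], np.where(inside, ny, dy) + c[1])


@register("warp", "custom")
class CustomWarp(Warp):
    """User-supplied coordinate mapping.

    Either a callable ``mapping(x, y) -> (x', y')`` or a coarse lookup grid:
    ``grid_x`` / ``grid_y`` are 2D arrays of target coordinates laid over
    the field, bilinearly interpolated between grid nodes.  A plain-text
    two-column table (rows of ``x' y'``, one per node, row-major with
    ``grid_shape``) can be loaded with :func:`load_warp_table`.
    """

    DEFAULTS = {"mapping": None, "grid_x": None, "grid_y": None}

    def _validate(self):
        has_fn = callable(self.params["mapping"])
        has_grid = self.params["grid_x"] is not None and self.params["grid_y"] is not None
        if not (has_fn or has_grid):
            raise ValueError("custom warp needs a mapping callable or grid_x/grid_y tables")

    def map_coords(self, x, y, ctx=None):
        if callable(self.params["mapping"]):
            nx, ny = self.params["mapping"](np.asarray(x, float), np.asarray(y, float))
            return np.asarray(nx, float), np.asarray(ny, float)
        from scipy.ndimage import map_coordinates

        gx = np.asarray(self.params["grid_x"], dtype=float)
        gy = np.asarray(self.params["grid_y"], dtype=float)
        if ctx is None:
            raise ValueError("grid-based custom warp needs a render context")
        g = ctx.geometry
        # fractional indices of (x, y) into the coarse grid spanning the field
        ri = np.asarray(y, float) / g.height_um * (gx.shape[0] - 1)
        ci = np.asarray(x, float) / g.width_um * (gx.shape[1] - 1)
        nx = map_coordinates(gx, [ri, ci], order=1, mode="nearest")
        ny = map_coordinates(gy, [ri, ci], order=1, mode="nearest")
        return nx, ny


def load_warp_table(path, grid_shape):
    """Read a two-column ``x' y'`` text table into (grid_x, grid_y) arrays."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("warp table must have two columns")
    rows, cols = grid_shape
    if data.shape[0] != rows * cols:
        raise ValueError("warp table row count does not match grid_shape")
    return data[:, 0].reshape(rows, cols), data[:, 1].reshape(rows, cols)


def warp_coords(warp: Warp, x, y, ctx=None):
    """Apply a warp component to coordinates."""
    return warp.map_coords(x, y, ctx)
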