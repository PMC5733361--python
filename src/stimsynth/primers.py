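"""Primer SBCs: shapes, patterns, images, checkerboards and grid repetition.

Primers produce pixel colors directly.  Shapes are defined pointwise by
implicit equations (signed distance functions) or polygon vertex lists, not
by rasterizing polygons, so set operations, soft edges and nonlinear warps
come for free.  Membership is 1 strictly inside, 0 strictly outside, and a
smoothstep ramp of width ``edge_width`` across the boundary provides
anti-aliasing; the hard edge is the ``edge_width -> 0`` limit.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .components import Component, ComponentSpec, register
from . import randoms as rnd


# --------------------------------------------------------------------------
# colors

def as_rgb(value) -> np.ndarray:
    """Normalize a scalar intensity or an RGB triple to a float64 triple."""
    v = np.asarray(value, dtype=np.float64)
    if v.ndim == 0:
        return np.full(3, float(v))
    if v.shape == (3,):
        return v
    raise ValueError("color must be a scalar intensity or an RGB triple")


# --------------------------------------------------------------------------
# implicit shapes

@dataclasses.dataclass(frozen=True)
class Disc:
    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 10.0

    def signed_distance(self, x, y):
        if self.radius <= 0:
            raise ValueError("disc radius must be positive")
        cx, cy = self.center
        return np.hypot(np.asarray(x) - cx, np.asarray(y) - cy) - self.radius


@dataclasses.dataclass(frozen=True)
class Annulus:
    center: tuple[float, float] = (0.0, 0.0)
    inner_radius: float = 5.0
    outer_radius: float = 10.0

    def signed_distance(self, x, y):
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("annulus requires 0 < inner_radius < outer_radius")
        cx, cy = self.center
        r = np.hypot(np.asarray(x) - cx, np.asarray(y) - cy)
        return np.maximum(self.inner_radius - r, r - self.outer_radius)


@dataclasses.dataclass(frozen=True)
class Rectangle:
    center: tuple[float, float] = (0.0, 0.0)
    width: float = 10.0
    height: float = 10.0
    angle: float = 0.0  # radians, counter-clockwise

    def signed_distance(self, x, y):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("rectangle sides must be positive")
        cx, cy = self.center
        c, s = math.cos(self.angle), math.sin(self.angle)
        dx = np.asarray(x) - cx
        dy = np.asarray(y) - cy
        u = c * dx + s * dy
        v = -s * dx + c * dy
        qx = np.abs(u) - 0.5 * self.width
        qy = np.abs(v) - 0.5 * self.height
        outside = np.hypot(np.maximum(qx, 0.0), np.maximum(qy, 0.0))
        inside = np.minimum(np.maximum(qx, qy), 0.0)
        return outside + inside


@dataclasses.dataclass(frozen=True)
class Polygon:
    """Simple or self-intersecting polygon; interiority by the even-odd rule."""

    vertices: tuple[tuple[float, float], ...] = ((0.0, 0.0), (10.0, 0.0), (0.0, 10.0))

    def __post_init__(self):
        object.__setattr__(self, "vertices", tuple(map(tuple, self.vertices)))
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")

    def signed_distance(self, x, y):
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        vx = np.array([v[0] for v in self.vertices])
        vy = np.array([v[1] for v in self.vertices])
        n = len(vx)
        inside = np.zeros(np.broadcast(x, y).shape, dtype=bool)
        dist2 = np.full(inside.shape, np.inf)
        for i in range(n):
            j = (i + 1) % n
            x0, y0, x1, y1 = vx[i], vy[i], vx[j], vy[j]
            # even-odd ray crossing (horizontal ray towards +x)
            cond = (y0 > y) != (y1 > y)
            with np.errstate(divide="ignore", invalid="ignore"):
                xint = x0 + (y - y0) * (x1 - x0) / (y1 - y0)
            inside ^= cond & (x < xint)
            # squared distance to the segment
            ex, ey = x1 - x0, y1 - y0
            ee = ex * ex + ey * ey
            t = 0.0 if ee == 0 else np.clip(((x - x0) * ex + (y - y0) * ey) / ee, 0.0, 1.0)
            dist2 = np.minimum(dist2, (x - (x0 + t * ex)) ** 2 + (y - (y0 + t * ey)) ** 2)
        d = np.sqrt(dist2)
        return np.where(inside, -d, d)


def _flatten_cubic(p0, p1, p2, p3, tol, out):
    """Adaptive de Casteljau flattening of one cubic segment."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    chord = p3 - p0
    norm = np.hypot(*chord)
    if norm < 1e-12:
        dev = max(np.hypot(*(p1 - p0)), np.hypot(*(p2 - p0)))
    else:
        dev = max(
            abs(chord[0] * (p1 - p0)[1] - chord[1] * (p1 - p0)[0]) / norm,
            abs(chord[0] * (p2 - p0)[1] - chord[1] * (p2 - p0)[0]) / norm,
        )
    if dev <= tol:
        out.append(tuple(p3))
        return
    m01 = 0.5 * (p0 + p1)
    m12 = 0.5 * (p1 + p2)
    m23 = 0.5 * (p2 + p3)
    m012 = 0.5 * (m01 + m12)
    m123 = 0.5 * (m12 + m23)
    mid = 0.5 * (m012 + m123)
    _flatten_cubic(p0, m01, m012, mid, tol, out)
    _flatten_cubic(mid, m123, m23, p3, tol, out)


@dataclasses.dataclass(frozen=True)
class BezierRegion:
    """Closed region bounded by piecewise cubic Bezier curves.

    ``control_points`` holds ``3k + 1`` points; the curve is flattened to a
    polygon at a fixed chord tolerance before the even-odd test.
    """

    control_points: tuple[tuple[float, float], ...] = (
        (0.0, -10.0), (8.0, -10.0), (10.0, -6.0), (10.0, 0.0),
        (10.0, 6.0), (6.0, 10.0), (0.0, 10.0),
        (-6.0, 10.0), (-10.0, 6.0), (-10.0, 0.0),
        (-10.0, -6.0), (-8.0, -10.0), (0.0, -10.0),
    )
    chord_tol: float = 0.25

    def to_polygon(self) -> Polygon:
        cp = [tuple(p) for p in self.control_points]
        if len(cp) < 4 or (len(cp) - 1) % 3 != 0:
            raise ValueError("control_points must contain 3k + 1 points")
        pts: list[tuple[float, float]] = [cp[0]]
        for k in range(0, len(cp) - 3, 3):
            _flatten_cubic(cp[k], cp[k + 1], cp[k + 2], cp[k + 3], self.chord_tol, pts)
        if np.hypot(pts[-1][0] - pts[0][0], pts[-1][1] - pts[0][1]) > 1e-9:
            pts.append(pts[0])
        # drop duplicated closing vertex
        if pts[-1] == pts[0]:
            pts = pts[:-1]
        return Polygon(tuple(pts))

    def signed_distance(self, x, y):
        return self.to_polygon().signed_distance(x, y)


def shape_membership(shape, x, y, edge_width: float = 0.0) -> np.ndarray:
    """Fuzzy membership of point(s) in a shape.

    Returns 1 strictly inside, 0 strictly outside, with a smoothstep ramp of
    width ``edge_width`` centered on the contour (membership 0.5 on the
    contour itself); ``edge_width = 0`` gives a hard edge with the contour
    counted as inside.
    """
    if edge_width < 0:
        raise ValueError("edge_width must be >= 0")
    d = shape.signed_distance(x, y)
    if edge_width == 0:
        return (d <= 0).astype(np.float64)
    with np.errstate(over="ignore"):  # vanishing edge_width: clip saturates
        s = np.clip(0.5 - d / edge_width, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


# set operations on memberships — min/max/complement combinators
def membership_not(m):
    return 1.0 - np.asarray(m)


def membership_and(m1, m2):
    return np.minimum(m1, m2)


def membership_or(m1, m2):
    return np.maximum(m1, m2)


def membership_difference(m1, m2):
    return np.minimum(m1, 1.0 - np.asarray(m2))


# --------------------------------------------------------------------------
# patterns

def sine_grating(x, y, spatial_frequency=0.05, orientation=0.0, phase=0.0,
                 mean=0.5, amplitude=0.5):
    if spatial_frequency <= 0:
        raise ValueError("spatial_frequency must be positive")
    proj = np.asarray(x) * math.cos(orientation) + np.asarray(y) * math.sin(orientation)
    return mean + amplitude * np.sin(2 * np.pi * spatial_frequency * proj + phase)


def square_grating(x, y, spatial_frequency=0.05, orientation=0.0, phase=0.0,
                   mean=0.5, amplitude=0.5):
    """Two-level grating; the tie at sin = 0 takes the high level."""
    if spatial_frequency <= 0:
        raise ValueError("spatial_frequency must be positive")
    proj = np.asarray(x) * math.cos(orientation) + np.asarray(y) * math.sin(orientation)
    s = np.sin(2 * np.pi * spatial_frequency * proj + phase)
    return np.where(s >= 0, mean + amplitude, mean - amplitude)


def campbell_robson(x, y, width, height, freq_start=0.005, freq_end=0.2,
                    contrast_start=1.0, contrast_end=0.0):
    """Contrast-sensitivity chart: frequency sweeps along x, contrast along y.

    The carrier frequency is log-interpolated (geometric) between
    ``freq_start`` and ``freq_end`` across the field width, with continuous
    integrated phase; the contrast envelope is log-interpolated along y.  A
    contrast endpoint of exactly zero maps its edge row to flat mid-gray.
    """
    if freq_start <= 0 or freq_end <= 0:
        raise ValueError("frequencies must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx = np.clip(x / width, 0.0, 1.0)
    sy = np.clip(y / height, 0.0, 1.0)
    if abs(freq_end - freq_start) < 1e-15:
        phi = freq_start * x
    else:
        ratio = freq_end / freq_start
        # integral of f0 * ratio**(x/W) dx
        phi = freq_start * width / math.log(ratio) * (np.power(ratio, sx) - 1.0)
    tiny = 1e-12
    c0 = max(contrast_start, tiny)
    c1 = max(contrast_end, tiny)
    c = np.exp((1.0 - sy) * math.log(c0) + sy * math.log(c1))
    if contrast_start <= 0:
        c = np.where(sy == 0.0, 0.0, c)
    if contrast_end <= 0:
        c = np.where(sy == 1.0, 0.0, c)
    return 0.5 + 0.5 * c * np.sin(2 * np.pi * phi)


def eval_pattern(kind: str, x, y, t: float = 0.0, **params):
    """Evaluate a named pattern at coordinates; returns intensity value(s)."""
    funcs = {
        "sine_grating": sine_grating,
        "square_grating": square_grating,
        "campbell_robson": campbell_robson,
    }
    if kind not in funcs:
        raise ValueError(f"unknown pattern kind {kind!r}")
    return funcs[kind](x, y, **params)


# --------------------------------------------------------------------------
# grid layouts

def layout_rectangular(rows=3, cols=3, spacing_x=20.0, spacing_y=None, origin=(0.0, 0.0)):
    if spacing_y is None:
        spacing_y = spacing_x
    ox, oy = origin
    return [
        (ox + j * spacing_x, oy + i * spacing_y)
        for i in range(int(rows))
        for j in range(int(cols))
    ]


def layout_hexagonal(rows=3, cols=3, spacing=20.0, origin=(0.0, 0.0)):
    """Hexagonal lattice: odd rows offset by spacing/2, vertical pitch s*sqrt(3)/2."""
    ox, oy = origin
    verts = []
    for i in range(int(rows)):
        off = 0.5 * spacing if i % 2 == 1 else 0.0
        for j in range(int(cols)):
            verts.append((ox + j * spacing + off, oy + i * spacing * math.sqrt(3) / 2))
    return verts


def layout_random(n=10, width=100.0, height=100.0, seed=0, origin=(0.0, 0.0)):
    """n uniform vertices in an origin-anchored box, from a seeded stream."""
    state = rnd.seed_state(rnd.derive_seed(int(seed), 0x9E37))
    ox, oy = origin
    verts = []
    for _ in range(int(n)):
        ux, state = rnd.next_unit(state)
        uy, state = rnd.next_unit(state)
        verts.append((ox + ux * width, oy + uy * height))
    return verts


def make_layout(layout: str, **params) -> list[tuple[float, float]]:
    if layout == "rectangular":
        return layout_rectangular(**params)
    if layout == "hexagonal":
        return layout_hexagonal(**params)
    if layout == "random":
        return layout_random(**params)
    if layout == "explicit":
        verts = params.get("vertices")
        if not verts:
            raise ValueError("explicit layout requires a non-empty vertex list")
        return [tuple(v) for v in verts]
    raise ValueError(f"unknown layout {layout!r}")


def grid_points(primer: ComponentSpec, layout: str = "explicit",
                labels: Sequence[str] | None = None, **layout_params) -> ComponentSpec:
    """Repeat a primer at preset positions (grid vertices).

    Returns a new primer component whose value at (x, y) is the pointwise
    maximum over copies of the base primer translated to each vertex.
    Vertices may be labeled and retrieved by label for downstream use
    (e.g., aiming motion at a particular electrode site).
    """
    vertices = make_layout(layout, **layout_params)
    if labels is not None:
        labels = list(labels)
        if len(labels) != len(vertices):
            raise ValueError("labels must match the number of vertices")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate vertex labels")
    return ComponentSpec(
        "primer",
        "grid",
        {
            "base": {"type": primer.sbc_type, "name": primer.name, "params": dict(primer.params)},
            "vertices": [list(v) for v in vertices],
            "labels": labels,
        },
    )


def grid_vertices(spec: ComponentSpec) -> dict:
    """Label -> vertex mapping of a grid primer (indices when unlabeled)."""
    p = spec.resolved_params()
    labels = p["labels"] or list(range(len(p["vertices"])))
    return {lab: tuple(v) for lab, v in zip(labels, p["vertices"])}


# --------------------------------------------------------------------------
# primer components

class Primer(Component):
    """A component that produces pixel colors: (rgb, coverage alpha)."""

    def evaluate(self, X, Y, t, ctx):  # pragma: no cover - interface
        raise NotImplementedError


@register("primer", "fullfield")
class FullfieldPrimer(Primer):
    """Spatially uniform color over the whole field."""

    DEFAULTS = {"color": 1.0}

    def evaluate(self, X, Y, t, ctx):
        rgb = np.broadcast_to(as_rgb(self.params["color"]), X.shape + (3,)).copy()
        return rgb, np.ones(X.shape)


class _ShapePrimer(Primer):
    """Common behavior of implicit-shape primers.

    ``fill_color`` paints the interior; coverage alpha equals the fuzzy
    membership.  When ``background_color`` is given the primer covers the
    whole field (alpha 1) with the exterior painted in that color.
    """

    SHAPE_KEYS: tuple[str, ...] = ()

    def _shape(self, ctx):  # pragma: no cover - interface
        raise NotImplementedError

    def _resolve_center(self, ctx):
        c = self.params.get("center")
        if c is not None:
            return tuple(c)
        if ctx is not None:
            return ctx.geometry.center
        return (0.0, 0.0)

    def evaluate(self, X, Y, t, ctx):
        m = shape_membership(self._shape(ctx), X, Y, self.params["edge_width"])
        fill = as_rgb(self.params["fill_color"])
        bg = self.params["background_color"]
        if bg is None:
            rgb = m[:, :, None] * fill
            return rgb, m
        rgb = m[:, :, None] * fill + (1.0 - m)[:, :, None] * as_rgb(bg)
        return rgb, np.ones_like(m)


@register("primer", "disc")
class DiscPrimer(_ShapePrimer):
    DEFAULTS = {"center": None, "radius": 10.0, "edge_width": 0.0,
                "fill_color": 1.0, "background_color": None}

    def _shape(self, ctx):
        return Disc(self._resolve_center(ctx), self.params["radius"])


@register("primer", "annulus")
class AnnulusPrimer(_ShapePrimer):
    DEFAULTS = {"center": None, "inner_radius": 5.0, "outer_radius": 10.0,
                "edge_width": 0.0, "fill_color": 1.0, "background_color": None}

    def _shape(self, ctx):
        return Annulus(self._resolve_center(ctx), self.params["inner_radius"],
                       self.params["outer_radius"])


@register("primer", "rectangle")
class RectanglePrimer(_ShapePrimer):
    DEFAULTS = {"center": None, "width": 10.0, "height": 10.0, "angle": 0.0,
                "edge_width": 0.0, "fill_color": 1.0, "background_color": None}

    def _shape(self, ctx):
        return Rectangle(self._resolve_center(ctx), self.params["width"],
                         self.params["height"], self.params["angle"])


@register("primer", "polygon")
class PolygonPrimer(_ShapePrimer):
    DEFAULTS = {"vertices": ((0.0, 0.0), (10.0, 0.0), (0.0, 10.0)),
                "edge_width": 0.0, "fill_color": 1.0, "background_color": None}

    def _shape(self, ctx):
        return Polygon(tuple(map(tuple, self.params["vertices"])))


@register("primer", "bezier_region")
class BezierRegionPrimer(_ShapePrimer):
    DEFAULTS = {"control_points": BezierRegion.control_points,
                "chord_tol": 0.25, "edge_width": 0.0,
                "fill_color": 1.0, "background_color": None}

    def _shape(self, ctx):
        return BezierRegion(tuple(map(tuple, self.params["control_points"])),
                            self.params["chord_tol"])


class _PatternPrimer(Primer):
    def _value(self, X, Y, t, ctx):  # pragma: no cover - interface
        raise NotImplementedError

    def evaluate(self, X, Y, t, ctx):
        v = self._value(X, Y, t, ctx)
        return np.repeat(np.asarray(v)[:, :, None], 3, axis=2), np.ones(X.shape)


@register("primer", "sine_grating")
class SineGratingPrimer(_PatternPrimer):
    DEFAULTS = {"spatial_frequency": 0.05, "orientation": 0.0, "phase": 0.0,
                "mean": 0.5, "amplitude": 0.5}

    def _validate(self):
        p = self.params
        if p["amplitude"] > min(p["mean"], 1.0 - p["mean"]) + 1e-12:
            raise ValueError("amplitude must satisfy amplitude <= min(mean, 1-mean)")

    def _value(self, X, Y, t, ctx):
        p = self.params
        return sine_grating(X, Y, p["spatial_frequency"], p["orientation"],
                            p["phase"], p["mean"], p["amplitude"])


@register("primer", "square_grating")
class SquareGratingPrimer(_PatternPrimer):
    DEFAULTS = dict(SineGratingPrimer.DEFAULTS)
    _validate = SineGratingPrimer._validate

    def _value(self, X, Y, t, ctx):
        p = self.params
        return square_grating(X, Y, p["spatial_frequency"], p["orientation"],
                              p["phase"], p["mean"], p["amplitude"])


@register("primer", "campbell_robson")
class CampbellRobsonPrimer(_PatternPrimer):
    DEFAULTS = {"freq_start": 0.005, "freq_end": 0.2,
                "contrast_start": 1.0, "contrast_end": 0.0}

    def _value(self, X, Y, t, ctx):
        p = self.params
        g = ctx.geometry
        return campbell_robson(X, Y, g.width_um, g.height_um,
                               p["freq_start"], p["freq_end"],
                               p["contrast_start"], p["contrast_end"])


@register("primer", "image")
class ImagePrimer(Primer):
    """Samples a PNG/TIFF/JPEG asset with bilinear interpolation.

    Integer pixel values are mapped linearly from the container's full range
    to [0, 1]; no sRGB decoding is applied (linear-light assumption).  The
    image is stretched to cover the field.
    """

    DEFAULTS = {"path": None}

    def _validate(self):
        if self.params["path"] is None:
            raise ValueError("image primer requires a 'path' parameter")

    def _load(self):
        if not hasattr(self, "_asset"):
            import imageio.v3 as iio

            img = iio.imread(self.params["path"])
            arr = np.asarray(img)
            if np.issubdtype(arr.dtype, np.integer):
                arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
            else:
                arr = arr.astype(np.float64)
            if arr.ndim == 2:
                arr = np.repeat(arr[:, :, None], 3, axis=2)
            self._asset = arr[:, :, :3]
        return self._asset

    def evaluate(self, X, Y, t, ctx):
        from scipy.ndimage import map_coordinates

        img = self._load()
        g = ctx.geometry
        ih, iw = img.shape[:2]
        # stretch the asset over the field; sample at fractional pixel coords
        ci = Y / g.height_um * ih - 0.5
        cj = X / g.width_um * iw - 0.5
        rgb = np.stack(
            [map_coordinates(img[:, :, ch], [ci, cj], order=1, mode="nearest")
             for ch in range(3)],
            axis=2,
        )
        return rgb, np.ones(X.shape)


@register("primer", "checkerboard")
class CheckerboardPrimer(Primer):
    """Random flickering checkerboard driven by seeded xorshift128 grids.

    ``update`` selects the per-frame prerequisite: ``refresh`` regenerates
    the whole grid every frame (white noise), ``shift`` translates it by
    ``(shift_dx, shift_dy)`` cells drawing fresh numbers only for the
    vacated border, ``static`` fills once at the first frame.  Color mode
    keeps three independent streams, one per channel.
    """

    DEFAULTS = {
        "rows": None, "cols": None, "cell_px": 4, "mode": "binary",
        "low": 0.0, "high": 1.0, "seed": None,
        "update": "refresh", "shift_dx": 0, "shift_dy": 0,
    }

    def _validate(self):
        if self.params["mode"] not in ("binary", "grayscale", "color"):
            raise ValueError("mode must be binary, grayscale or color")
        if self.params["update"] not in ("refresh", "shift", "static"):
            raise ValueError("update must be refresh, shift or static")
        if int(self.params["cell_px"]) < 1:
            raise ValueError("cell_px must be positive")

    def _dims(self, ctx):
        g = ctx.geometry
        cell = int(self.params["cell_px"])
        rows = self.params["rows"] or -(-g.height_px // cell)
        cols = self.params["cols"] or -(-g.width_px // cell)
        return int(rows), int(cols)

    def _seeds(self, ctx):
        base = self.params["seed"]
        if base is None:
            base = rnd.derive_seed(ctx.seed, getattr(self, "_slot", 0))
        if self.params["mode"] == "color":
            return [rnd.derive_seed(int(base), ch + 1) for ch in range(3)]
        return [int(base)]

    def prepare(self, t_frame, ctx):
        slot = ctx.state_for(self)
        rows, cols = self._dims(ctx)
        if "states" not in slot:
            slot["states"] = [rnd.seed_state(s) for s in self._seeds(ctx)]
            slot["grids"] = [None] * len(slot["states"])
        update = self.params["update"]
        for i, state in enumerate(slot["states"]):
            if slot["grids"][i] is None:
                slot["grids"][i], slot["states"][i] = rnd.fill_grid(state, rows, cols, t_frame)
            elif update == "refresh":
                slot["grids"][i], slot["states"][i] = rnd.fill_grid(state, rows, cols, t_frame)
            elif update == "shift":
                g, slot["states"][i] = rnd.shift_grid(
                    slot["grids"][i], int(self.params["shift_dx"]),
                    int(self.params["shift_dy"]), state)
                g.frame_index = t_frame
                slot["grids"][i] = g
            # static: keep the first grid
        ctx.record_grids(slot["grids"] if self.params["mode"] == "color" else slot["grids"][0])

    def evaluate(self, X, Y, t, ctx):
        slot = ctx.state_for(self)
        grids = slot.get("grids")
        if grids is None:
            raise RuntimeError("checkerboard evaluated before prepare()")
        src = grids if self.params["mode"] == "color" else grids[0]
        frame = rnd.grid_to_checkerboard(
            src, self.params["mode"], self.params["low"], self.params["high"],
            int(self.params["cell_px"]), ctx.geometry.shape)
        return frame, np.ones(ctx.geometry.shape)


@register("primer", "grid")
class GridPrimer(Primer):
    """A base primer repeated at grid vertices, combined by pointwise maximum."""

    DEFAULTS = {"base": None, "vertices": None, "labels": None}

    def _validate(self):
        if self.params["base"] is None or not self.params["vertices"]:
            raise ValueError("grid primer requires a base primer and >= 1 vertex")
        labels = self.params["labels"]
        if labels is not None and len(set(labels)) != len(labels):
            raise ValueError("duplicate vertex labels")

    def _base(self):
        if not hasattr(self, "_base_comp"):
            b = self.params["base"]
            comp = ComponentSpec(b["type"], b["name"], dict(b.get("params", {}))).build()
            # grid vertices are absolute positions: anchor the base at the origin
            if "center" in comp.DEFAULTS and comp.params.get("center") is None:
                comp.params["center"] = (0.0, 0.0)
            self._base_comp = comp
        return self._base_comp

    def vertex(self, label):
        labels = self.params["labels"] or list(range(len(self.params["vertices"])))
        return tuple(self.params["vertices"][labels.index(label)])

    def evaluate(self, X, Y, t, ctx):
        base = self._base()
        rgb = np.zeros(X.shape + (3,))
        alpha = np.zeros(X.shape)
        for vx, vy in self.params["vertices"]:
            r, a = base.evaluate(X - vx, Y - vy, t, ctx)
            rgb = np.maximum(rgb, r)
            alpha = np.maximum(alpha, a)
        return rgb, alpha
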