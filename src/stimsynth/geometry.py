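"""Display-field geometry and the frame container.

A *field* is the rectangular pixel raster the stimulus is rendered on.  All
shape and pattern formulas are evaluated pointwise at pixel centers expressed
in physical units (micrometers by default): pixel ``(i, j)`` samples the
continuous point ``((j + 0.5) * um_per_px, (i + 0.5) * um_per_px)`` with the
origin at the field's top-left corner, x growing rightwards and y downwards.
Time is discretized in frames; frame ``k`` is rendered at its onset time
``k / frame_rate_hz`` seconds.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction

import numpy as np


@dataclasses.dataclass(frozen=True)
class FieldGeometry:
    """Size, physical scale and refresh rate of the display field.

    Parameters
    ----------
    width_px, height_px
        Raster size in pixels (each >= 1).
    frame_rate_hz
        Display refresh rate in frames per second (> 0).  One rendered frame
        covers ``1 / frame_rate_hz`` seconds.
    um_per_px
        Physical pixel pitch in micrometers per pixel.  Purely a coordinate
        scale; shape sizes, velocities and spatial frequencies are expressed
        in these physical units.
    """

    width_px: int
    height_px: int
    frame_rate_hz: float = 60.0
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        if int(self.width_px) < 1 or int(self.height_px) < 1:
            raise ValueError("field must be at least 1x1 pixels")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """(height_px, width_px) array shape of one channel plane."""
        return (self.height_px, self.width_px)

    @property
    def frame_duration_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def width_um(self) -> float:
        return self.width_px * self.um_per_px

    @property
    def height_um(self) -> float:
        return self.height_px * self.um_per_px

    @property
    def center(self) -> tuple[float, float]:
        """Physical coordinates of the field center."""
        return (0.5 * self.width_um, 0.5 * self.height_um)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, Y)`` physical coordinates of every pixel center.

        Both arrays have shape ``(height_px, width_px)``.
        """
        x = (np.arange(self.width_px) + 0.5) * self.um_per_px
        y = (np.arange(self.height_px) + 0.5) * self.um_per_px
        return np.meshgrid(x, y)

    def time_of_frame(self, t_frame: int) -> float:
        """Onset time of frame ``t_frame`` in seconds."""
        return t_frame / self.frame_rate_hz

    def exact_time_of_frame(self, t_frame: int) -> Fraction:
        """Onset time as an exact rational, for drift-free event timing."""
        return Fraction(t_frame) / Fraction(str(float(self.frame_rate_hz)))


@dataclasses.dataclass
class Frame:
    """One rendered frame: an ``H x W x 3`` array of linear-light intensities.

    Values are kept in floating point throughout the pipeline; intermediate
    stages (notably zero-integral filters) may leave the unit interval, and a
    tone-mapping stage is expected to bring the final image back into
    ``[0, 1]`` before quantization at file write.
    """

    values: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim == 2:
            v = np.repeat(v[:, :, None], 3, axis=2)
        if v.ndim != 3 or v.shape[2] != 3:
            raise ValueError("frame values must have shape (H, W, 3)")
        if not np.all(np.isfinite(v)):
            raise ValueError("frame values must be finite")
        if self.index < 0:
            raise ValueError("frame index must be >= 0")
        self.values = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def frame_values(frame) -> np.ndarray:
    """Accept a :class:`Frame` or a bare array and return the (H, W, 3) array."""
    if isinstance(frame, Frame):
        return frame.values
    v = np.asarray(frame, dtype=np.float64)
    if v.ndim == 2:
        v = np.repeat(v[:, :, None], 3, axis=2)
    if v.ndim != 3 or v.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) frame array")
    return v
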