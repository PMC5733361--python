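"""Grid pseudo-random number generation and random checkerboards.

The generator is Marsaglia's xorshift128: four 32-bit words of state, one
word of output per step.  Stimuli that flicker (white-noise checkerboards,
randomly shaken shapes) draw from seeded streams of this generator, so the
full stimulus is a pure function of the seed — the same sequence of
pseudo-random numbers arises on every run, can be re-created by analysis
software from the seed alone, and can be exported to plain text.

Grids of random words are filled in row-major order from a single stream;
shifting a grid translates the existing words and spends fresh draws only on
the vacated border region, which keeps the stream position accountable.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np

_M32 = 0xFFFFFFFF


class PRNGState(NamedTuple):
    """xorshift128 state: four 32-bit unsigned words, never all zero."""

    x: int
    y: int
    z: int
    w: int


def seed_state(seed: int) -> PRNGState:
    """Build the initial state for ``seed``.

    The seed replaces the first word (remapped to 1 when zero so the
    forbidden all-zero state cannot arise); the remaining words are the
    constants of the published reference generator, which makes the stream
    cross-checkable against a scalar transliteration of that pseudocode.
    """
    seed = int(seed)
    if seed < 0:
        raise ValueError("seed must be non-negative")
    return PRNGState(seed & _M32 if seed & _M32 else 1, 362436069, 521288629, 88675123)


def next_u32(state: PRNGState) -> tuple[int, PRNGState]:
    """Advance one step; return ``(word, new_state)``."""
    t = (state.x ^ ((state.x << 11) & _M32)) & _M32
    t ^= t >> 8
    w = ((state.w ^ (state.w >> 19)) ^ t) & _M32
    return w, PRNGState(state.y, state.z, state.w, w)


def next_unit(state: PRNGState) -> tuple[float, PRNGState]:
    """One draw mapped to the half-open unit interval, ``word / 2**32``."""
    w, state = next_u32(state)
    return w / 4294967296.0, state


@dataclasses.dataclass
class RandomGrid:
    """A ``rows x cols`` array of 32-bit random words for one frame."""

    words: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.words = np.asarray(self.words, dtype=np.uint32)
        if self.words.ndim != 2:
            raise ValueError("grid words must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.words.shape

    def unit(self) -> np.ndarray:
        """Words mapped to [0, 1) as float64."""
        return self.words.astype(np.float64) / 4294967296.0


def fill_grid(state: PRNGState, rows: int, cols: int, frame_index: int = 0) -> tuple[RandomGrid, PRNGState]:
    """Fill a fresh grid in row-major order with consecutive draws."""
    if rows < 1 or cols < 1:
        raise ValueError("grid must be at least 1x1")
    out = np.empty(rows * cols, dtype=np.uint32)
    for i in range(rows * cols):
        w, state = next_u32(state)
        out[i] = w
    return RandomGrid(out.reshape(rows, cols), frame_index), state


def shift_grid(grid: RandomGrid, dx: int, dy: int, state: PRNGState) -> tuple[RandomGrid, PRNGState]:
    """Translate the grid contents by ``(dx, dy)`` cells and refill the border.

    Positive ``dx`` moves contents towards higher column indices (rightwards),
    positive ``dy`` towards higher row indices (downwards).  Cells whose
    source falls outside the grid are vacated and refilled with fresh draws
    in row-major order over the vacated region only, so exactly
    ``rows*|dx| + cols*|dy| - |dx|*|dy|`` draws are consumed.
    """
    rows, cols = grid.shape
    if abs(dx) >= cols or abs(dy) >= rows:
        raise ValueError("shift magnitude must be smaller than the grid")
    if dx == 0 and dy == 0:
        return grid, state
    src_r = np.arange(rows)[:, None] - dy
    src_c = np.arange(cols)[None, :] - dx
    valid = (src_r >= 0) & (src_r < rows) & (src_c >= 0) & (src_c < cols)
    new = grid.words[np.clip(src_r, 0, rows - 1), np.clip(src_c, 0, cols - 1)].copy()
    # refill vacated cells row-major
    for i in range(rows):
        for j in range(cols):
            if not valid[i, j]:
                w, state = next_u32(state)
                new[i, j] = w
    return RandomGrid(new, grid.frame_index), state


def grid_to_checkerboard(
    grid,
    mode: str = "binary",
    low=(0.0, 0.0, 0.0),
    high=(1.0, 1.0, 1.0),
    cell_px: int = 1,
    field_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Map a random grid (or three, for color) onto a frame array.

    Each grid cell drives a ``cell_px`` x ``cell_px`` block of pixels.  In
    ``binary`` mode a cell takes the ``high`` color when its draw, spread
    within [0, 1), is >= 0.5 and the ``low`` color otherwise; ``grayscale``
    maps draws linearly between ``low`` and ``high``; ``color`` takes three
    independent grids, one per RGB channel.
    """
    if cell_px < 1:
        raise ValueError("cell_px must be positive")
    low = np.broadcast_to(np.asarray(low, dtype=np.float64), (3,)).astype(np.float64)
    high = np.broadcast_to(np.asarray(high, dtype=np.float64), (3,)).astype(np.float64)
    if mode == "color":
        grids = list(grid)
        if len(grids) != 3:
            raise ValueError("color mode requires three grids")
        u = np.stack([g.unit() for g in grids], axis=2)
        cells = low + u * (high - low)
    else:
        u = grid.unit()
        if mode == "binary":
            cells = np.where(u[:, :, None] >= 0.5, high, low)
        elif mode == "grayscale":
            cells = low + u[:, :, None] * (high - low)
        else:
            raise ValueError(f"unknown checkerboard mode {mode!r}")
    frame = np.repeat(np.repeat(cells, cell_px, axis=0), cell_px, axis=1)
    if field_shape is not None:
        h, w = field_shape
        if frame.shape[0] < h or frame.shape[1] < w:
            raise ValueError("grid does not cover the field")
        frame = frame[:h, :w]
    return frame


_EXPORT_VERSION = "v1"


def export_randoms(grids: Sequence[RandomGrid], path) -> None:
    """Write grids to a plain-text file, one block per frame.

    Each block is a versioned header line ``frame <k> rows <r> cols <c> v1``
    followed by ``r`` lines of ``c`` space-separated decimal 32-bit words
    (so one 2x2 grid occupies exactly 3 lines).  Round-trips losslessly
    through :func:`read_randoms`.
    """
    grids = list(grids)
    if not grids:
        raise ValueError("no grids to export")
    with open(path, "w") as fh:
        for g in grids:
            r, c = g.shape
            fh.write(f"frame {g.frame_index} rows {r} cols {c} {_EXPORT_VERSION}\n")
            for row in g.words:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_randoms(path) -> list[RandomGrid]:
    """Parse a file written by :func:`export_randoms`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    grids: list[RandomGrid] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        parts = lines[i].split()
        if parts[0] != "frame":
            raise ValueError(f"bad header at line {i + 1}")
        k, r, c = int(parts[1]), int(parts[3]), int(parts[5])
        words = np.array(
            [[int(v) for v in lines[i + 1 + j].split()] for j in range(r)],
            dtype=np.uint32,
        )
        if words.shape != (r, c):
            raise ValueError(f"bad block at line {i + 1}")
        grids.append(RandomGrid(words, k))
        i += 1 + r
    return grids


def derive_seed(base_seed: int, salt: int) -> int:
    """Mix a base seed with a salt into an independent 31-bit stream seed."""
    return ((base_seed * 2654435761 + salt * 40503 + 1) & 0x7FFFFFFF) or 1


def uniform_pair(seed: int, frame_index: int) -> tuple[float, float]:
    """Two reproducible uniforms in [0, 1) as a pure function of (seed, frame).

    Used for per-frame jitter: a fresh short stream is seeded from the pair
    and warmed up before drawing, so consecutive frames are decorrelated.
    """
    state = seed_state(derive_seed(seed, frame_index))
    for _ in range(4):
        _, state = next_u32(state)
    a, state = next_unit(state)
    b, _ = next_unit(state)
    return a, b
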