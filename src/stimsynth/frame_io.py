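"""Frame, event-log and report writers.

Frames leave the pipeline as 16-bit-per-channel PNGs (one file per frame)
or as a single raw little-endian float32 stack with a JSON sidecar.  The
PNG encoder is written here because the stack's imaging backends do not
handle 16-bit RGB PNG; it emits byte-identical files for identical input
(fixed filter and compression settings), which makes whole-run checksums a
meaningful determinism check.  Quantization to 16 bits uses
round-half-away-from-zero: ``q = floor(v * 65535 + 0.5)``.
"""

from __future__ import annotations

import json
import os
import struct
import zlib
from fractions import Fraction

import numpy as np

from .geometry import frame_values

_PNG_SIG = b"\x89PNG\r\n\x1a\n"


def _chunk(tag: bytes, payload: bytes) -> bytes:
    crc = zlib.crc32(tag + payload) & 0xFFFFFFFF
    return struct.pack(">I", len(payload)) + tag + payload + struct.pack(">I", crc)


def write_png16(path, values: np.ndarray) -> None:
    """Write an (H, W, 3) array in [0, 1] as a 16-bit RGB PNG."""
    v = frame_values(values)
    if v.min() < 0.0 or v.max() > 1.0:
        raise ValueError("frame values must lie in [0, 1]; tone-map first")
    q = np.floor(v * 65535.0 + 0.5).astype(np.uint16)
    q = np.minimum(q, 65535)
    h, w = q.shape[:2]
    ihdr = struct.pack(">IIBBBBB", w, h, 16, 2, 0, 0, 0)
    raw = bytearray()
    big = q.astype(">u2").tobytes()
    stride = w * 6
    for row in range(h):
        raw.append(0)  # filter type 0 on every scanline
        raw += big[row * stride:(row + 1) * stride]
    idat = zlib.compress(bytes(raw), 6)
    with open(path, "wb") as fh:
        fh.write(_PNG_SIG + _chunk(b"IHDR", ihdr) + _chunk(b"IDAT", idat) + _chunk(b"IEND", b""))


def read_png16(path) -> np.ndarray:
    """Read a PNG written by :func:`write_png16` back to a float array."""
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:8] != _PNG_SIG:
        raise ValueError("not a PNG file")
    pos = 8
    ihdr = None
    idat = b""
    while pos < len(data):
        (length,) = struct.unpack(">I", data[pos:pos + 4])
        tag = data[pos + 4:pos + 8]
        payload = data[pos + 8:pos + 8 + length]
        if tag == b"IHDR":
            ihdr = struct.unpack(">IIBBBBB", payload)
        elif tag == b"IDAT":
            idat += payload
        pos += 12 + length
    if ihdr is None:
        raise ValueError("missing IHDR")
    w, h, depth, ctype, _, _, interlace = ihdr
    if depth != 16 or ctype != 2 or interlace != 0:
        raise ValueError("only 16-bit RGB non-interlaced PNGs are supported")
    raw = zlib.decompress(idat)
    stride = w * 6
    out = np.empty((h, w, 3), dtype=np.uint16)
    for row in range(h):
        line = raw[row * (stride + 1):(row + 1) * (stride + 1)]
        if line[0] != 0:
            raise ValueError("unsupported PNG scanline filter")
        out[row] = np.frombuffer(line[1:], dtype=">u2").reshape(w, 3)
    return out.astype(np.float64) / 65535.0


def quantize16(v: float) -> int:
    """Scalar 16-bit quantization with round-half-away-from-zero."""
    return min(int(np.floor(v * 65535.0 + 0.5)), 65535)


def write_frames(frames, out_dir, fmt: str = "png16", geometry=None) -> list[str]:
    """Write a frame sequence; returns the written file paths.

    ``png16``: one PNG per frame named ``frame_%06d.png``.  ``raw_stack``: a
    single ``frames.raw`` of little-endian float32, frame-major, with a JSON
    sidecar recording dims, count and frame rate; lossless round trip.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    if fmt == "png16":
        for frame in frames:
            v = frame_values(frame)
            index = getattr(frame, "index", len(paths))
            path = os.path.join(out_dir, f"frame_{index:06d}.png")
            write_png16(path, v)
            paths.append(path)
        return paths
    if fmt == "raw_stack":
        arrs = [frame_values(f).astype("<f4") for f in frames]
        if not arrs:
            raise ValueError("no frames to write")
        path = os.path.join(out_dir, "frames.raw")
        with open(path, "wb") as fh:
            for a in arrs:
                fh.write(a.tobytes())
        sidecar = {
            "dtype": "<f4",
            "height": arrs[0].shape[0],
            "width": arrs[0].shape[1],
            "channels": 3,
            "count": len(arrs),
            "frame_rate_hz": geometry.frame_rate_hz if geometry else None,
        }
        with open(path + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)
        return [path, path + ".json"]
    raise ValueError(f"unknown frame format {fmt!r}")


def read_raw_stack(path) -> np.ndarray:
    """Read a raw float stack back as an (N, H, W, 3) array."""
    with open(path + ".json") as fh:
        meta = json.load(fh)
    data = np.fromfile(path, dtype="<f4")
    return data.reshape(meta["count"], meta["height"], meta["width"], meta["channels"])


# --------------------------------------------------------------------------
# event log

def format_event_time(frame_index: int, frame_rate_hz: float) -> str:
    """Exact rational frame time printed with 6 decimals (no cumulative drift)."""
    t = Fraction(int(frame_index)) / Fraction(str(float(frame_rate_hz)))
    scaled = t * 1_000_000
    micros = scaled.numerator // scaled.denominator
    # round half up on the remainder
    if 2 * (scaled.numerator % scaled.denominator) >= scaled.denominator:
        micros += 1
    return f"{micros // 1_000_000}.{micros % 1_000_000:06d}"


def write_event_log(log, path, frame_rate_hz: float | None = None) -> None:
    """Write an event log as TSV: frame, time_s (6 decimals), channel, edge."""
    rate = frame_rate_hz if frame_rate_hz is not None else log.frame_rate_hz
    with open(path, "w") as fh:
        fh.write("frame\ttime_s\tchannel\tedge\n")
        for rec in log.records:
            fh.write(f"{rec.frame_index}\t{format_event_time(rec.frame_index, rate)}"
                     f"\t{rec.channel}\t{rec.edge}\n")


def read_event_log(path):
    """Parse a TSV event log back into (frame, time_s, channel, edge) rows."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["frame", "time_s", "channel", "edge"]:
            raise ValueError("not an event log file")
        for line in fh:
            f, t, ch, e = line.rstrip("\n").split("\t")
            rows.append((int(f), t, ch, e))
    return rows


# --------------------------------------------------------------------------
# reports

def write_histogram_tsv(report, path) -> None:
    """Histogram as TSV (bin_left, bin_right, count) plus a summary line."""
    with open(path, "w") as fh:
        fh.write("bin_left\tbin_right\tcount\n")
        for left, right, count in zip(report.bin_edges[:-1], report.bin_edges[1:],
                                      report.counts):
            fh.write(f"{left:.9g}\t{right:.9g}\t{int(count)}\n")
        fh.write(f"# min={report.vmin:.9g} max={report.vmax:.9g} "
                 f"mean={report.mean:.9g} variance={report.variance:.9g} "
                 f"out_of_range={report.n_below_unit + report.n_above_unit}\n")


def write_stats_tsv(stats_rows, path) -> None:
    """Per-frame statistics table (frame, michelson, rms, entropy, mean, var)."""
    cols = ["michelson", "rms_contrast", "entropy_bits", "mean", "variance"]
    with open(path, "w") as fh:
        fh.write("frame\t" + "\t".join(cols) + "\n")
        for i, row in enumerate(stats_rows):
            fh.write(str(i) + "\t" + "\t".join(f"{row[c]:.9g}" for c in cols) + "\n")


def read_gamma_samples(path):
    """Two-column (input, luminance) text file of photometer readings."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("gamma sample file must have two columns")
    return [tuple(row) for row in data]
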