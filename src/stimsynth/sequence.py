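"""Sequence assembly, config parsing, event signaling and the run driver.

A *sequence* concatenates stimuli over one field geometry with a global
seed.  Instead of executable scripts, sequences are declared in a YAML
configuration; every component name and parameter is validated against the
registry and all defaults are resolved into a normalized "resolved config"
for provenance — the resolved config plus the seed fully determine every
output byte.

Timing markers that the original real-time system emitted as voltage edges
are recorded here as a frame-accurate event log: by convention the ``stim``
channel rises on each stimulus's first frame and falls on its last, and the
``stop`` channel pulses on the final frame of the sequence.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time

import yaml

from .components import ComponentSpec, StimulusSpec, SBC_TYPES
from .geometry import FieldGeometry
from .render import RenderContext, render_frame, measure_stimulus_stats, _needs_global_stats
from . import frame_io, postprocess


@dataclasses.dataclass(frozen=True)
class EventRecord:
    frame_index: int
    channel: str
    edge: str  # rise | fall | pulse


class EventLog:
    """Ordered (frame, channel, edge) records with exact frame times."""

    def __init__(self, frame_rate_hz: float):
        self.frame_rate_hz = float(frame_rate_hz)
        self.records: list[EventRecord] = []

    def add(self, frame_index: int, channel: str, edge: str) -> None:
        if edge not in ("rise", "fall", "pulse"):
            raise ValueError("edge must be rise, fall or pulse")
        self.records.append(EventRecord(int(frame_index), channel, edge))
        self.records.sort(key=lambda r: (r.frame_index, r.channel, r.edge))

    def channel(self, name: str) -> list[EventRecord]:
        return [r for r in self.records if r.channel == name]

    def validate(self) -> None:
        """Every rise must be matched by a later fall on the same channel."""
        open_by_channel: dict[str, int] = {}
        for rec in self.records:
            if rec.edge == "rise":
                open_by_channel[rec.channel] = open_by_channel.get(rec.channel, 0) + 1
            elif rec.edge == "fall":
                if open_by_channel.get(rec.channel, 0) < 1:
                    raise ValueError(f"fall without rise on channel {rec.channel!r}")
                open_by_channel[rec.channel] -= 1
        dangling = [ch for ch, n in open_by_channel.items() if n]
        if dangling:
            raise ValueError(f"unmatched rise on channel(s) {dangling}")


@dataclasses.dataclass
class SequenceSpec:
    geometry: FieldGeometry
    stimuli: list[StimulusSpec]
    seed: int = 0
    label: str = "sequence"

    def __post_init__(self):
        if not self.stimuli:
            raise ValueError("sequence needs at least one stimulus")

    @property
    def total_frames(self) -> int:
        return sum(s.duration_frames for s in self.stimuli)


class ConfigError(ValueError):
    """Configuration schema violation; parsing fails fast with no partial spec."""


def _require(mapping, key, context, typ=None):
    if key not in mapping:
        raise ConfigError(f"{context}: missing required key {key!r}")
    value = mapping[key]
    if typ is not None and not isinstance(value, typ):
        raise ConfigError(f"{context}: key {key!r} has wrong type "
                          f"({type(value).__name__})")
    return value


def parse_config(source) -> SequenceSpec:
    """Parse and fully validate a YAML sequence configuration.

    ``source`` is a path or a YAML string.  Unknown top-level keys, unknown
    component names and unknown component parameters are rejected with the
    offending location named; YAML syntax errors keep the loader's
    line/column report.
    """
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source) as fh:
            text = fh.read()
    else:
        text = str(source)
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ConfigError(f"YAML syntax error: {e}") from e
    if not isinstance(doc, dict):
        raise ConfigError("config must be a mapping")
    allowed = {"geometry", "stimuli", "seed", "label"}
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")

    gdoc = _require(doc, "geometry", "config", dict)
    gallowed = {"width_px", "height_px", "frame_rate_hz", "um_per_px"}
    gunknown = set(gdoc) - gallowed
    if gunknown:
        raise ConfigError(f"geometry: unknown key(s) {sorted(gunknown)}")
    try:
        geometry = FieldGeometry(
            width_px=int(_require(gdoc, "width_px", "geometry", int)),
            height_px=int(_require(gdoc, "height_px", "geometry", int)),
            frame_rate_hz=float(gdoc.get("frame_rate_hz", 60.0)),
            um_per_px=float(gdoc.get("um_per_px", 1.0)),
        )
    except ValueError as e:
        raise ConfigError(f"geometry: {e}") from e

    stimuli_doc = _require(doc, "stimuli", "config", list)
    if not stimuli_doc:
        raise ConfigError("config: 'stimuli' must be a non-empty list")
    stimuli = []
    for si, sdoc in enumerate(stimuli_doc):
        where = f"stimuli[{si}]"
        if not isinstance(sdoc, dict):
            raise ConfigError(f"{where}: each stimulus must be a mapping")
        sallowed = {"label", "duration_frames", "components"}
        sunknown = set(sdoc) - sallowed
        if sunknown:
            raise ConfigError(f"{where}: unknown key(s) {sorted(sunknown)}")
        comps_doc = _require(sdoc, "components", where, list)
        comps = []
        for ci, cdoc in enumerate(comps_doc):
            cwhere = f"{where}.components[{ci}]"
            if not isinstance(cdoc, dict):
                raise ConfigError(f"{cwhere}: component must be a mapping")
            cunknown = set(cdoc) - {"type", "name", "params"}
            if cunknown:
                raise ConfigError(f"{cwhere}: unknown key(s) {sorted(cunknown)}")
            ctype = _require(cdoc, "type", cwhere, str)
            cname = _require(cdoc, "name", cwhere, str)
            if ctype not in SBC_TYPES:
                raise ConfigError(f"{cwhere}: unknown component type {ctype!r}")
            params = cdoc.get("params") or {}
            if not isinstance(params, dict):
                raise ConfigError(f"{cwhere}: params must be a mapping")
            params = {k: (tuple(v) if isinstance(v, list) and k in ("center", "origin")
                          else v) for k, v in params.items()}
            try:
                spec = ComponentSpec(ctype, cname, params)
                spec.build()  # validates parameter names and values
            except (KeyError, ValueError) as e:
                raise ConfigError(f"{cwhere}: {e}") from e
            comps.append(spec)
        try:
            stimuli.append(StimulusSpec(
                components=comps,
                duration_frames=int(_require(sdoc, "duration_frames", where, int)),
                label=str(sdoc.get("label", f"stimulus_{si}")),
            ))
        except ValueError as e:
            raise ConfigError(f"{where}: {e}") from e

    return SequenceSpec(
        geometry=geometry,
        stimuli=stimuli,
        seed=int(doc.get("seed", 0)),
        label=str(doc.get("label", "sequence")),
    )


def resolved_config(spec: SequenceSpec) -> dict:
    """Normalized configuration with every component default filled in."""
    return {
        "label": spec.label,
        "seed": spec.seed,
        "geometry": {
            "width_px": spec.geometry.width_px,
            "height_px": spec.geometry.height_px,
            "frame_rate_hz": spec.geometry.frame_rate_hz,
            "um_per_px": spec.geometry.um_per_px,
        },
        "stimuli": [
            {
                "label": s.label,
                "duration_frames": s.duration_frames,
                "components": [
                    {"type": c.sbc_type, "name": c.name,
                     "params": _jsonable(c.resolved_params())}
                    for c in s.components
                ],
            }
            for s in spec.stimuli
        ],
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if callable(obj):
        return f"<callable {getattr(obj, '__name__', 'object')}>"
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


@dataclasses.dataclass
class RunResult:
    frame_paths: list[str]
    event_log: EventLog
    event_log_path: str | None
    resolved_config_path: str | None
    stats: list[dict]
    budget: dict


def build_event_log(spec: SequenceSpec) -> EventLog:
    """Stimulus onset/offset and stop markers for a sequence.

    ``stim`` rises on each stimulus's first frame and falls on its last;
    ``stop`` pulses on the final frame of the sequence.
    """
    log = EventLog(spec.geometry.frame_rate_hz)
    start = 0
    for stim in spec.stimuli:
        log.add(start, "stim", "rise")
        log.add(start + stim.duration_frames - 1, "stim", "fall")
        start += stim.duration_frames
    log.add(start - 1, "stop", "pulse")
    log.validate()
    return log


def iter_sequence_frames(spec: SequenceSpec, collect_stats: bool = False):
    """Yield ``(global_index, Frame, stats_or_None, render_seconds)``.

    Each stimulus runs with a single fresh render context seeded from the
    sequence seed and the stimulus position, so re-running any stimulus in
    isolation reproduces its frames.
    """
    offset = 0
    for si, stim in enumerate(spec.stimuli):
        ctx = RenderContext(geometry=spec.geometry, seed=_stimulus_seed(spec.seed, si))
        if _needs_global_stats(stim):
            ctx.global_stats = measure_stimulus_stats(stim, spec.geometry, ctx.seed)
        for k in range(stim.duration_frames):
            t0 = time.perf_counter()
            frame = render_frame(stim, k, ctx)
            elapsed = time.perf_counter() - t0
            frame.index = offset + k
            stats = postprocess.frame_stats(frame.values) if collect_stats else None
            yield offset + k, frame, stats, elapsed
        offset += stim.duration_frames


def _stimulus_seed(seed: int, index: int) -> int:
    from .randoms import derive_seed

    return derive_seed(seed, index * 7919)


def run_sequence(spec: SequenceSpec, out_dir, fmt: str = "png16",
                 write_stats: bool = False) -> RunResult:
    """Render a whole sequence to disk.

    Writes frames (``frame_%06d`` numbering, no gaps), the event log TSV,
    the resolved config JSON and optionally per-frame statistics.  The
    offline stand-in for real-time frame-drop detection is a budget report:
    per-frame render wall time is compared with the frame period and
    over-budget frame indices are flagged — purely informational, the
    output is unaffected.
    """
    os.makedirs(out_dir, exist_ok=True)
    frames = []
    stats = []
    budget_times = []
    for _, frame, st, elapsed in iter_sequence_frames(spec, collect_stats=write_stats):
        frames.append(frame)
        if st is not None:
            stats.append(st)
        budget_times.append(elapsed)

    frame_paths = frame_io.write_frames(frames, out_dir, fmt, spec.geometry)
    log = build_event_log(spec)
    log_path = os.path.join(out_dir, "events.tsv")
    frame_io.write_event_log(log, log_path)
    cfg_path = os.path.join(out_dir, "resolved_config.json")
    with open(cfg_path, "w") as fh:
        json.dump(resolved_config(spec), fh, indent=1, sort_keys=True)
    if write_stats:
        frame_io.write_stats_tsv(stats, os.path.join(out_dir, "frame_stats.tsv"))

    period = spec.geometry.frame_duration_s
    over = [i for i, dt in enumerate(budget_times) if dt > period]
    budget = {
        "frame_period_s": period,
        "max_render_s": max(budget_times),
        "mean_render_s": sum(budget_times) / len(budget_times),
        "over_budget_frames": over,
    }
    with open(os.path.join(out_dir, "budget.json"), "w") as fh:
        json.dump(budget, fh, indent=1, sort_keys=True)
    return RunResult(frame_paths, log, log_path, cfg_path, stats, budget)
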