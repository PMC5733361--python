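"""Config parsing, event timing, frame/event writers and the CLI."""

import hashlib
import os
from fractions import Fraction
from pathlib import Path

import numpy as np
import pytest

from stimsynth import (
    ComponentSpec,
    FieldGeometry,
    StimulusSpec,
    SequenceSpec,
    ConfigError,
    build_event_log,
    parse_config,
    read_randoms,
    resolved_config,
    run_sequence,
)
from stimsynth import frame_io
from stimsynth.cli import main as cli_main
from stimsynth.sequence import EventLog

REPO = Path(__file__).resolve().parent.parent
DEMO = REPO / "examples" / "demo.yaml"

MINIMAL = """
geometry: {width_px: 8, height_px: 8, frame_rate_hz: 60}
stimuli:
  - duration_frames: 60
    components:
      - {type: primer, name: fullfield, params: {color: 0.5}}
"""


def two_stimulus_spec(frames=(120, 60)):
    stimuli = [
        StimulusSpec([ComponentSpec("primer", "fullfield", {"color": 0.3})], f)
        for f in frames
    ]
    return SequenceSpec(FieldGeometry(8, 8, 60.0), stimuli, seed=1)


class TestParseConfig:
    def test_minimal_config(self):
        spec = parse_config(MINIMAL)
        assert spec.total_frames == 60
        assert spec.geometry.width_px == 8

    def test_unknown_component_named_in_error(self):
        bad = MINIMAL.replace("fullfield", "plaid")
        with pytest.raises(ConfigError, match="plaid"):
            parse_config(bad)

    def test_unknown_parameter_named_in_error(self):
        bad = MINIMAL.replace("color: 0.5", "colour: 0.5")
        with pytest.raises(ConfigError, match="colour"):
            parse_config(bad)

    def test_unknown_top_level_key_rejected(self):
        with pytest.raises(ConfigError, match="extras"):
            parse_config(MINIMAL + "\nextras: 1\n")

    def test_missing_duration_rejected(self):
        bad = MINIMAL.replace("  - duration_frames: 60\n    components:",
                              "  - components:")
        with pytest.raises(ConfigError, match="duration_frames"):
            parse_config(bad)

    def test_defaults_resolved_into_config(self):
        cfg = resolved_config(parse_config(MINIMAL))
        disc_free = cfg["stimuli"][0]["components"][0]
        assert disc_free["params"]["color"] == 0.5
        spec = parse_config(DEMO)
        cfg = resolved_config(spec)
        disc = next(c for c in cfg["stimuli"][0]["components"] if c["name"] == "disc")
        assert disc["params"]["edge_width"] == 2
        assert "background_color" in disc["params"]  # default echoed

    def test_yaml_syntax_error_keeps_location(self):
        with pytest.raises(ConfigError, match="line"):
            parse_config("geometry: {width_px: 8,\n  : bad")

    def test_shipped_demo_validates(self):
        spec = parse_config(DEMO)
        assert spec.total_frames == 36


class TestEventLog:
    def test_two_stimulus_timing(self):
        log = build_event_log(two_stimulus_spec())
        stim = [(r.frame_index, r.edge) for r in log.channel("stim")]
        assert stim == [(0, "rise"), (119, "fall"), (120, "rise"), (179, "fall")]
        stop = [(r.frame_index, r.edge) for r in log.channel("stop")]
        assert stop == [(179, "pulse")]

    def test_event_counts_match_stimuli(self):
        log = build_event_log(two_stimulus_spec((10, 20, 30)))
        rises = [r for r in log.channel("stim") if r.edge == "rise"]
        falls = [r for r in log.channel("stim") if r.edge == "fall"]
        assert len(rises) == len(falls) == 3
        assert len(log.channel("stop")) == 1

    def test_times_are_exact_frame_fractions(self):
        assert frame_io.format_event_time(0, 60.0) == "0.000000"
        assert frame_io.format_event_time(120, 60.0) == "2.000000"
        assert frame_io.format_event_time(1, 60.0) == "0.016667"

    def test_no_drift_over_a_million_frames(self):
        # exact rational arithmetic: frame 10^6 at 60 Hz is 10^6/60 s
        expected = Fraction(10 ** 6, 60)
        micros = expected * 1_000_000
        text = frame_io.format_event_time(10 ** 6, 60.0)
        whole, frac = text.split(".")
        got = Fraction(int(whole) * 1_000_000 + int(frac), 1_000_000)
        assert abs(got - expected) <= Fraction(1, 2_000_000)

    def test_round_trip(self, tmp_path):
        log = build_event_log(two_stimulus_spec())
        path = tmp_path / "events.tsv"
        frame_io.write_event_log(log, path)
        rows = frame_io.read_event_log(path)
        assert len(rows) == len(log.records)
        assert rows[0] == (0, "0.000000", "stim", "rise")

    def test_unmatched_rise_rejected(self):
        log = EventLog(60.0)
        log.add(0, "stim", "rise")
        with pytest.raises(ValueError, match="unmatched"):
            log.validate()


class TestWriters:
    def test_png16_quantization_rule(self):
        assert frame_io.quantize16(1.0) == 65535
        assert frame_io.quantize16(0.5) == 32768  # 32767.5 rounds half away
        assert frame_io.quantize16(0.0) == 0

    def test_png16_round_trip_within_quantization(self, tmp_path, rng):
        v = rng.random((8, 8, 3))
        path = tmp_path / "f.png"
        frame_io.write_png16(path, v)
        back = frame_io.read_png16(path)
        assert np.max(np.abs(back - v)) <= 0.5 / 65535

    def test_png16_rejects_out_of_range(self, tmp_path):
        with pytest.raises(ValueError):
            frame_io.write_png16(tmp_path / "f.png", np.full((2, 2, 3), 1.2))

    def test_raw_stack_is_lossless(self, tmp_path, rng):
        frames = [rng.random((4, 4, 3)).astype("<f4").astype(float) for _ in range(3)]
        geometry = FieldGeometry(4, 4, 60.0)
        frame_io.write_frames(frames, tmp_path, "raw_stack", geometry)
        back = frame_io.read_raw_stack(str(tmp_path / "frames.raw"))
        assert np.array_equal(back, np.stack(frames).astype("<f4"))

    def test_run_sequence_outputs_complete(self, tmp_path):
        result = run_sequence(two_stimulus_spec((3, 2)), tmp_path)
        names = sorted(os.path.basename(p) for p in result.frame_paths)
        assert names == [f"frame_{k:06d}.png" for k in range(5)]
        assert (tmp_path / "events.tsv").exists()
        assert (tmp_path / "resolved_config.json").exists()
        assert (tmp_path / "budget.json").exists()

    def test_histogram_tsv_has_bins_and_summary(self, tmp_path):
        from stimsynth import measure_histogram

        rep = measure_histogram([np.full((4, 4, 3), 0.5)], n_bins=16)
        path = tmp_path / "hist.tsv"
        frame_io.write_histogram_tsv(rep, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 + 16 + 1
        assert lines[-1].startswith("# min=")


def _checksums(root):
    sums = {}
    for path in sorted(Path(root).rglob("*")):
        if path.is_file() and path.name != "budget.json":  # wall times vary
            sums[str(path.relative_to(root))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    return sums


class TestCLI:
    def test_validate_shipped_config(self, capsys):
        assert cli_main(["validate", str(DEMO)]) == 0
        assert "OK" in capsys.readouterr().out

    def test_validate_bad_config_exit_1(self, tmp_path, capsys):
        bad = tmp_path / "bad.yaml"
        bad.write_text(MINIMAL.replace("fullfield", "plaid"))
        assert cli_main(["validate", str(bad)]) == 1

    def test_render_is_deterministic_across_runs(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        assert cli_main(["render", str(DEMO), "-o", str(a), "--seed", "5"]) == 0
        assert cli_main(["render", str(DEMO), "-o", str(b), "--seed", "5"]) == 0
        ca, cb = _checksums(a), _checksums(b)
        assert ca and ca == cb

    def test_randoms_export_parses_back(self, tmp_path):
        out = tmp_path / "randoms.txt"
        assert cli_main(["randoms", "--seed", "3", "--rows", "4", "--cols", "5",
                         "--frames", "2", "-o", str(out)]) == 0
        grids = read_randoms(out)
        assert len(grids) == 2 and grids[0].shape == (4, 5)

    def test_kernel_command_writes_zero_sum_dog(self, tmp_path):
        out = tmp_path / "dog.txt"
        assert cli_main(["kernel", "--kind", "dog", "--sigma1", "1.0",
                         "--sigma2", "2.0", "-o", str(out)]) == 0
        k = np.loadtxt(out)
        assert abs(k.sum()) < 1e-10

    def test_stats_command(self, tmp_path):
        out = tmp_path / "stats"
        assert cli_main(["stats", str(DEMO), "-o", str(out)]) == 0
        assert (out / "frame_stats.tsv").exists()
        assert (out / "histogram.tsv").exists()

    def test_version_and_seed_logged(self, tmp_path, capsys):
        cli_main(["render", str(DEMO), "-o", str(tmp_path / "r"), "--seed", "9"])
        out = capsys.readouterr().out
        assert "stimsynth" in out and "seed 9" in out
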