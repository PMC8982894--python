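"""Config round trips, group statistics, end-to-end report, CLI, IO."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

import pecowaco as pw
from pecowaco import io as pio
from pecowaco.cli import main as cli_main
from pecowaco.errors import InvalidSpecError
from pecowaco.reporting import report_to_json, report_to_rows


class TestAnalysisConfig:
    def test_defaults_are_published_constants(self):
        cfg = pw.AnalysisConfig()
        assert (cfg.piv_window_coarse, cfg.piv_window_fine) == (20.0, 10.0)
        assert cfg.band == (50.0, 200.0)
        assert cfg.threshold == 1.777
        assert cfg.strip_length == 10.0
        assert cfg.frame_interval == 5.0

    def test_yaml_round_trip_idempotent(self, tmp_path):
        cfg = pw.AnalysisConfig(seed=3, stages={"s1": "4-cell/early"})
        p1 = tmp_path / "a.yaml"
        cfg.to_yaml(p1)
        cfg2 = pw.AnalysisConfig.from_yaml(p1)
        assert cfg2 == cfg
        p2 = tmp_path / "b.yaml"
        cfg2.to_yaml(p2)
        assert p1.read_text() == p2.read_text()
        assert cfg.content_hash() == cfg2.content_hash()


class TestCompareGroups:
    def test_extreme_detection_table_significant(self):
        res = pw.compare_groups((10, 10), (0, 10), "proportions")
        assert res.p_value < 0.01
        assert res.significant

    def test_identical_proportions_p_one(self):
        res = pw.compare_groups((5, 10), (5, 10), "proportions")
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_t_test_matches_permutation_oracle(self):
        # small fixed data; oracle = permutation distribution of the
        # difference in means, one-tailed
        a = np.array([148.0, 153.0, 150.0, 155.0, 149.0, 151.0])
        b = np.array([80.0, 84.0, 78.0, 82.0, 86.0, 79.0])
        res = pw.compare_groups(a, b, "means", alternative="greater")
        pooled = np.concatenate([a, b])
        rng = np.random.default_rng(0)
        observed = a.mean() - b.mean()
        count = 0
        reps = 20000
        for _ in range(reps):
            perm = rng.permutation(pooled)
            if perm[:6].mean() - perm[6:].mean() >= observed - 1e-12:
                count += 1
        p_perm = count / reps
        assert res.p_value == pytest.approx(p_perm, abs=0.02)
        assert res.significant

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidSpecError):
            pw.compare_groups([], [1.0], "means")


@pytest.fixture(scope="module")
def pipeline_inputs(tmp_path_factory):
    root = tmp_path_factory.mktemp("inputs")
    spec = pw.WaveCellSpec(radius=12.0, amplitude=1.0, period=100.0,
                           wave_number=2, frame_interval=5.0, duration=405.0,
                           seed=5)
    contours, _ = pw.make_wave_cell(spec)
    movie = pw.render_movie(contours, pixel_size=0.5, seed=5)
    pio.write_movie(movie, root / "m.tif")
    pio.write_contours(contours, root / "c.csv")
    series = pw.make_aspiration_series(450.0, 10.0, 30.0, pressure_step=5.0)
    pio.write_aspiration(series, root / "a.csv", embryo_id="e1")
    return root


class TestRunPipeline:
    def test_end_to_end_report_and_determinism(self, pipeline_inputs):
        cfg = pw.AnalysisConfig()
        kwargs = dict(movies={"s1": pipeline_inputs / "m.tif"},
                      contour_files={"s1": pipeline_inputs / "c.csv"},
                      aspiration_files={"e1": pipeline_inputs / "a.csv"})
        r1 = pw.run_pipeline(cfg, **kwargs)
        r2 = pw.run_pipeline(cfg, **kwargs)
        assert report_to_json(r1) == report_to_json(r2)
        s1 = r1["samples"]["s1"]
        assert s1["oscillation_call"]["oscillating"]
        assert s1["oscillation_call"]["period"] == pytest.approx(100.0)
        assert s1["kymograph_call"]["oscillating"]
        assert r1["per_embryo_tension"]["e1"] == pytest.approx(450.0, abs=40)
        assert r1["provenance"]["config_hash"] == cfg.content_hash()
        rows = report_to_rows(r1)
        assert any(row["metric"] == "oscillation_call" for row in rows)

    def test_missing_sidecar_names_file(self, pipeline_inputs, tmp_path):
        import shutil

        bare = tmp_path / "bare.tif"
        shutil.copy(pipeline_inputs / "m.tif", bare)
        with pytest.raises(InvalidSpecError, match="bare.tif.json"):
            pw.run_pipeline(pw.AnalysisConfig(), movies={"x": bare})


class TestIoRoundTrips:
    def test_movie(self, tmp_path):
        frames = np.random.default_rng(0).normal(0, 1, (3, 16, 16)).astype(
            np.float32)
        movie = pw.TimeLapse(frames, pixel_size=0.5, frame_interval=5.0)
        pio.write_movie(movie, tmp_path / "m.tif")
        back = pio.read_movie(tmp_path / "m.tif")
        assert np.array_equal(back.frames, frames)
        assert back.pixel_size == 0.5

    def test_contours(self, tmp_path):
        contours, _ = pw.make_wave_cell(pw.WaveCellSpec(
            radius=10.0, amplitude=0.5, period=100.0, wave_number=2,
            duration=25.0, frame_interval=5.0))
        pio.write_contours(contours, tmp_path / "c.csv")
        back = pio.read_contours(tmp_path / "c.csv")
        assert back.n_frames == contours.n_frames
        assert np.allclose(back.contours[2], contours.contours[2])

    def test_aspiration(self, tmp_path):
        series = pw.make_aspiration_series(300.0, 8.0, 24.0)
        pio.write_aspiration(series, tmp_path / "a.csv", embryo_id="e9")
        back, meta = pio.read_aspiration(tmp_path / "a.csv")
        assert np.allclose(back.pressures, series.pressures)
        assert meta["embryo_id"] == "e9"

    def test_traces_and_kymograph(self, tmp_path):
        traces = pw.VelocityTraces(u=np.arange(6.0).reshape(2, 3),
                                   v=np.zeros((2, 3)),
                                   positions=np.zeros((2, 2)),
                                   frame_interval=5.0)
        pio.write_traces(traces, tmp_path / "t.csv")
        back = pio.read_traces(tmp_path / "t.csv")
        assert np.allclose(back.u, traces.u)
        contours, _ = pw.make_wave_cell(pw.WaveCellSpec(
            radius=10.0, amplitude=0.5, period=100.0, wave_number=2,
            duration=45.0, frame_interval=5.0))
        kymo = pw.build_kymograph(contours, n_bins=60)
        pio.write_kymograph(kymo, tmp_path / "k.csv")
        back = pio.read_kymograph(tmp_path / "k.csv")
        assert np.allclose(back.values, kymo.values)


class TestCli:
    def test_simulate_fit_round_trip(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "asp.csv"
        res = runner.invoke(cli_main, ["simulate", "aspiration",
                                       "--tension", "450", "--rp", "10",
                                       "--rc", "30", "--pressure-step", "5",
                                       "--out", str(out)])
        assert res.exit_code == 0, res.output
        res = runner.invoke(cli_main, ["tension", "fit", "--series",
                                       str(out), "--mode", "interpolate"])
        assert res.exit_code == 0, res.output
        assert "gamma=450.00" in res.output

    def test_compare_command(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["compare", "--kind", "proportions",
                                       "--a", "10,10", "--b", "0,10"])
        assert res.exit_code == 0, res.output
        assert "significant=True" in res.output

    def test_oscillation_detect_from_traces(self, tmp_path):
        t = np.cos(2 * np.pi * np.arange(120) * 5.0 / 100.0)
        traces = pw.VelocityTraces(u=t[None, :], v=np.zeros((1, 120)),
                                   positions=np.zeros((1, 2)),
                                   frame_interval=5.0)
        pio.write_traces(traces, tmp_path / "t.csv")
        runner = CliRunner()
        res = runner.invoke(cli_main, ["oscillation", "detect", "--traces",
                                       str(tmp_path / "t.csv")])
        assert res.exit_code == 0, res.output
        assert "period=100.0" in res.output
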