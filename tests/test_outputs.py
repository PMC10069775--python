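import json

import numpy as np
import pandas as pd
import pytest

from haircell import synthetic
from haircell.frequency import CellRecord
from haircell.outputs import (
    AnalysisConfig,
    AnalysisReport,
    combine_pieces,
    plot_cochleogram,
    read_cells_csv,
    render_overlay,
    report_to_frame,
    run_batch,
    write_csv,
)


def _records(n, label="OHC"):
    rng = np.random.default_rng(0)
    recs = []
    for i in range(1, n + 1):
        pct = float(rng.uniform(0, 100))
        recs.append(
            CellRecord(
                cell_id=i, label=label, centroid=(float(rng.uniform(0, 50)), float(rng.uniform(0, 50))),
                percent_from_apex=pct, distance_um_from_apex=pct * 50.0,
                frequency_khz=float(rng.uniform(3, 70)), score=float(rng.uniform(0.5, 1)),
                box=(0.0, 0.0, 4.0, 4.0), distance_to_path_um=float(rng.uniform(0, 20)),
            )
        )
    return recs


class TestWriteCsv:
    def test_empty_report_is_header_only(self, tmp_path):
        f = write_csv(AnalysisReport(cells=[], path=None, cochleogram=None), tmp_path / "c.csv")
        assert f.read_text().count("\n") == 1
        assert "cell_id" in f.read_text()

    def test_ten_cells_eleven_lines(self, tmp_path):
        rep = AnalysisReport(cells=_records(10), path=None, cochleogram=None)
        f = write_csv(rep, tmp_path / "c.csv")
        assert f.read_text().strip().count("\n") == 10

    def test_round_trip_field_for_field(self, tmp_path):
        recs = _records(5)
        rep = AnalysisReport(cells=recs, path=None, cochleogram=None)
        f = write_csv(rep, tmp_path / "c.csv")
        back = read_cells_csv(f)
        for rec, row in zip(recs, back.itertuples()):
            assert row.cell_id == rec.cell_id
            assert row.label == rec.label
            assert row.score == pytest.approx(rec.score, abs=1e-4)
            assert row.percent_from_apex == pytest.approx(rec.percent_from_apex, abs=1e-3)
            assert row.frequency_khz == pytest.approx(rec.frequency_khz, abs=0.01)
            assert row.centroid_row == pytest.approx(rec.centroid[0])


class TestOverlay:
    def test_empty_report_draws_no_glyphs(self, default_cochlea):
        import matplotlib.pyplot as plt

        fig = render_overlay(default_cochlea.image, AnalysisReport(cells=[], path=None, cochleogram=None))
        ax = fig.axes[0]
        assert len(ax.collections) == 0  # no scatter glyphs at all
        plt.close(fig)

    def test_glyph_count_equals_cell_count(self, default_cochlea):
        import matplotlib.pyplot as plt

        recs = _records(7, label="OHC") + _records(4, label="IHC")
        rep = AnalysisReport(cells=recs, path=None, cochleogram=None)
        fig = render_overlay(default_cochlea.image, rep, annotate=False)
        ax = fig.axes[0]
        n_glyphs = sum(len(coll.get_offsets()) for coll in ax.collections)
        assert n_glyphs == 11
        plt.close(fig)

    def test_apex_marker_at_path_apex(self, default_cochlea, analyzed_cochlea):
        import matplotlib.pyplot as plt

        fig = render_overlay(default_cochlea.image, analyzed_cochlea, annotate=False)
        ax = fig.axes[0]
        apex = analyzed_cochlea.path.apex_point
        # the apex scatter holds exactly one offset at (col, row)
        markers = [c for c in ax.collections if len(c.get_offsets()) == 1]
        dists = [
            np.hypot(m.get_offsets()[0][0] - apex[1], m.get_offsets()[0][1] - apex[0])
            for m in markers
        ]
        assert min(dists) <= 2.0
        plt.close(fig)


class TestCombinePieces:
    def test_split_vs_whole_equivalence(self, default_cochlea, analyzed_cochlea):
        """A coil analyzed whole vs as two manual-path pieces yields the
        same combined cochleogram totals."""
        from haircell.outputs import analyze_detections
        from haircell.path_estimation import CochlearPath, swap_apex

        whole = analyzed_cochlea
        center_pts = default_cochlea.centerline
        # split the analytic centerline at 50% arc length
        cut = int(np.searchsorted(center_pts.cumulative_um, center_pts.total_length_um / 2))
        piece1 = CochlearPath(points=center_pts.points[: cut + 1].copy(), pixel_size_nm=center_pts.pixel_size_nm)
        piece2 = CochlearPath(points=center_pts.points[cut:].copy(), pixel_size_nm=center_pts.pixel_size_nm)
        # assign each merged detection to the closer piece by percent
        from haircell.path_estimation import project_cells

        dets = whole.detections
        proj = project_cells(dets, center_pts)
        dets1 = [d for (d, pct, _) in proj if pct < 50.0]
        dets2 = [d for (d, pct, _) in proj if pct >= 50.0]
        cfg = AnalysisConfig(pixel_size_nm=default_cochlea.image.pixel_size_nm)
        rep1 = analyze_detections(dets1, piece1, cfg)
        rep2 = analyze_detections(dets2, piece2, cfg)
        cells, combined = combine_pieces([rep1, rep2], bin_size_percent=1.0)
        assert len(cells) == len(whole.cells)
        assert combined.counts_ihc.sum() == whole.cochleogram.counts_ihc.sum()
        assert combined.counts_ohc.sum() == whole.cochleogram.counts_ohc.sum()

    def test_piece_offsets_shift_percent(self):
        from haircell.path_estimation import CochlearPath

        pts = np.column_stack([np.zeros(11), np.linspace(0, 100, 11)])
        path = CochlearPath(points=pts, pixel_size_nm=1000.0)  # 100 um long
        rep1 = AnalysisReport(cells=[_records(1)[0]], path=path, cochleogram=None)
        rep1.cells[0].percent_from_apex = 50.0
        rep2 = AnalysisReport(cells=[_records(1)[0]], path=path, cochleogram=None)
        rep2.cells[0].percent_from_apex = 50.0
        cells, _ = combine_pieces([rep1, rep2])
        assert [c.percent_from_apex for c in cells] == [25.0, 75.0]
        assert [c.cell_id for c in cells] == [1, 2]


class TestRunBatch:
    @pytest.fixture(scope="class")
    def small_folder(self, tmp_path_factory):
        import tifffile

        folder = tmp_path_factory.mktemp("imgs")
        coch = synthetic.render(seed=3, turns=1.0, a=60, b=40)
        tifffile.imwrite(folder / "coil.tif", (coch.image.pixels * 65535).astype(np.uint16))
        return folder, coch

    def test_csv_rows_match_detections_and_outputs_exist(self, small_folder, tmp_path):
        folder, coch = small_folder
        cfg = AnalysisConfig(pixel_size_nm=coch.image.pixel_size_nm, seed=1)
        reports = run_batch(folder, cfg, tmp_path / "out", overlays=False)
        assert len(reports) == 1
        rep = next(iter(reports.values()))
        df = pd.read_csv(tmp_path / "out" / "coil_cells.csv")
        assert len(df) == len(rep.cells) == len(rep.detections)
        snap = json.loads((tmp_path / "out" / "coil_config.json").read_text())
        assert snap["seed"] == 1

    def test_rerun_is_byte_identical(self, small_folder, tmp_path):
        folder, coch = small_folder
        cfg = AnalysisConfig(pixel_size_nm=coch.image.pixel_size_nm, seed=1)
        run_batch(folder, cfg, tmp_path / "a", overlays=False)
        run_batch(folder, cfg, tmp_path / "b", overlays=False)
        assert (tmp_path / "a" / "coil_cells.csv").read_bytes() == (tmp_path / "b" / "coil_cells.csv").read_bytes()

    def test_empty_folder_is_input_error(self, tmp_path):
        from haircell.errors import InputError

        (tmp_path / "empty").mkdir()
        with pytest.raises(InputError):
            run_batch(tmp_path / "empty", AnalysisConfig(), tmp_path / "out")


class TestCli:
    def test_synth_detect_tune_round_trip(self, tmp_path):
        from click.testing import CliRunner

        from haircell.cli import main

        runner = CliRunner()
        res = runner.invoke(main, ["synth", "--seed", "2", "--turns", "1.0", "--out", str(tmp_path / "synth")])
        assert res.exit_code == 0, res.output
        tif = next((tmp_path / "synth").glob("*.tif"))
        res = runner.invoke(
            main,
            [
                "detect", str(tif), "--pixel-size-nm", "1152", "--no-path",
                "--seed", "2", "--out", str(tmp_path / "det"),
            ],
        )
        assert res.exit_code == 0, res.output
        csvs = list((tmp_path / "det").glob("*_cells.csv"))
        assert len(csvs) == 1
        assert len(pd.read_csv(csvs[0])) > 100

    def test_cochleogram_plot(self, analyzed_cochlea, tmp_path):
        import matplotlib.pyplot as plt

        fig = plot_cochleogram(analyzed_cochlea.cochleogram, tmp_path / "cg.png")
        assert (tmp_path / "cg.png").exists()
        plt.close(fig)
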