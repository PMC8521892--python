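"""File I/O contracts, the batch engine, and the CLI surface."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from hepaquant import PhantomSpec, generate_cohort, generate_phantom
from hepaquant.batch import (
    BatchConfig,
    load_config,
    load_roi,
    process_roi,
    read_mask,
    run_batch,
    slide_id_of,
    write_mask,
)
from hepaquant.cli import main as cli_main
from hepaquant.synthetic import write_cohort, write_phantom


@pytest.fixture(scope="module")
def cohort_dirs(tmp_path_factory):
    """A small written cohort: 4 animals x 2 ROIs at 121 px."""
    root = tmp_path_factory.mktemp("cohort")
    phantoms, truth = generate_cohort(n_animals=4, rois_per_slide=2, seed=5,
                                      side_px=121)
    write_cohort(phantoms, truth, root / "images", root / "masks")
    return root, truth


def _config(root, out_name="results.csv", **kw):
    return BatchConfig(input_dir=root / "images", mask_dir=root / "masks",
                       output_csv=root / out_name, lumen_mode="automated", **kw)


class TestMaskIO:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        mask = rng.random((33, 21)) < 0.4
        path = write_mask(mask, tmp_path / "m.png")
        np.testing.assert_array_equal(read_mask(path), mask)

    def test_phantom_writer_emits_sidecar(self, tmp_path):
        ph = generate_phantom(PhantomSpec(side_px=121, seed=3))
        paths = write_phantom(ph, tmp_path, "ph")
        assert paths["spec"].exists()
        np.testing.assert_array_equal(read_mask(paths["vein"]), ph.truth_vein)


class TestLoadRoi:
    def test_valid_rgb_png(self, tmp_path):
        import imageio.v3 as iio

        arr = np.random.default_rng(0).integers(0, 256, (50, 60, 3)).astype(np.uint8)
        iio.imwrite(tmp_path / "roi.png", arr)
        roi = load_roi(tmp_path / "roi.png")
        assert roi.shape == (50, 60)
        assert roi.scale_um_per_px == 4.55

    def test_grayscale_rejected(self, tmp_path):
        import imageio.v3 as iio

        iio.imwrite(tmp_path / "g.png", np.zeros((10, 10), dtype=np.uint8))
        with pytest.raises(ValueError, match="RGB"):
            load_roi(tmp_path / "g.png")

    def test_16bit_rejected(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "deep.tif",
                         np.zeros((10, 10, 3), dtype=np.uint16))
        with pytest.raises(ValueError, match="8-bit"):
            load_roi(tmp_path / "deep.tif")

    def test_wrong_mask_shape_rejected(self, tmp_path):
        import imageio.v3 as iio

        iio.imwrite(tmp_path / "roi.png",
                    np.zeros((10, 10, 3), dtype=np.uint8))
        write_mask(np.zeros((9, 10), dtype=bool), tmp_path / "v.png")
        with pytest.raises(ValueError, match="shape"):
            load_roi(tmp_path / "roi.png", vein_mask_path=tmp_path / "v.png")


class TestBatch:
    def test_row_and_summary_cardinality(self, cohort_dirs):
        root, truth = cohort_dirs
        results, summaries, n_fail = run_batch(_config(root))
        assert len(results) == len(truth) == 8
        assert len(summaries) == 4
        assert n_fail == 0
        assert (results["status"] == "ok").all()

    def test_rerun_is_byte_identical(self, cohort_dirs):
        root, _ = cohort_dirs
        run_batch(_config(root, out_name="a.csv"))
        run_batch(_config(root, out_name="b.csv"))
        assert (root / "a.csv").read_bytes() == (root / "b.csv").read_bytes()

    def test_batch_row_matches_single_image_pipeline(self, cohort_dirs):
        root, truth = cohort_dirs
        config = _config(root, out_name="c.csv")
        results, _, _ = run_batch(config)
        roi_id = truth["roi_id"].iloc[3]
        roi = load_roi(root / "images" / f"{roi_id}.png",
                       vein_mask_path=root / "masks" / f"{roi_id}_vein.png")
        m, _ = process_roi(roi, config)
        row = results.set_index("roi_id").loc[roi_id]
        assert row["cfr_percent"] == pytest.approx(m.cfr_percent)
        assert row["fibrosis_area_um2"] == pytest.approx(m.fibrosis_area_um2)

    def test_recovered_cfr_tracks_truth(self, cohort_dirs):
        root, truth = cohort_dirs
        results, _, _ = run_batch(_config(root, out_name="d.csv"))
        merged = results.merge(truth, on="roi_id")
        err = (merged["cfr_percent"] - merged["true_cfr_percent"]).abs()
        assert err.max() <= 1.0

    def test_failed_image_flagged_not_skipped(self, tmp_path):
        import imageio.v3 as iio

        ph = generate_phantom(PhantomSpec(side_px=121, seed=0))
        (tmp_path / "images").mkdir()
        iio.imwrite(tmp_path / "images" / "s1_roi1.png", ph.image)
        iio.imwrite(tmp_path / "images" / "s1_roi2.png",
                    np.zeros((10, 10), dtype=np.uint8))  # grayscale: must fail
        results, summaries, n_fail = run_batch(
            BatchConfig(input_dir=tmp_path / "images",
                        output_csv=tmp_path / "out.csv",
                        lumen_mode="automated"))
        assert len(results) == 2
        assert n_fail == 1
        assert results.set_index("roi_id")["status"].str.startswith("error").sum() == 1
        assert summaries["n_rois"].sum() == 1  # failed ROI excluded from means

    def test_empty_input_dir_rejected(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(ValueError, match="no TIFF/PNG"):
            run_batch(BatchConfig(input_dir=tmp_path / "empty",
                                  output_csv=tmp_path / "o.csv"))

    @pytest.mark.parametrize("roi_id, slide", [
        ("animal001_roi1", "animal001"),
        ("slideA_roi12", "slideA"),
        ("oddname", "oddname"),
    ])
    def test_slide_grouping_convention(self, roi_id, slide):
        assert slide_id_of(roi_id) == slide


class TestConfigFile:
    def test_parse_and_override(self, tmp_path):
        cfg = tmp_path / "run.cfg"
        cfg.write_text(
            "# macro settings\n"
            "input_dir = ./images\n"
            "output_csv = out.csv\n"
            "scale_um_per_px = 4.55\n"
            "fibrosis_band = 140 190 0 255 0 248\n"
            "lumen_band = 0,255,0,255,0,50\n"
            "smoothing = on\n"
            "lumen_mode = annotated\n"
            "random_seed = 7\n"
        )
        config = load_config(cfg, lumen_mode="automated")
        assert config.fibrosis_band.hue_lo == 140
        assert config.fibrosis_band.bri_hi == 248
        assert config.lumen_band.bri_hi == 50
        assert config.smoothing is True
        assert config.lumen_mode == "automated"  # override wins
        assert config.random_seed == 7

    def test_unknown_key_rejected(self, tmp_path):
        cfg = tmp_path / "bad.cfg"
        cfg.write_text("input_dir=x\noutput_csv=y\nmystery=1\n")
        with pytest.raises(ValueError, match="unknown config key"):
            load_config(cfg)


class TestCli:
    def test_phantom_segment_batch_stats_round_trip(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "fixtures"
        r = runner.invoke(cli_main, [
            "phantom", "--out-dir", str(out), "--cohort",
            "--n-animals", "3", "--rois-per-slide", "2",
            "--side-px", "121", "--seed", "2",
        ])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, [
            "batch", "--input-dir", str(out / "images"),
            "--mask-dir", str(out / "masks"),
            "--output-csv", str(tmp_path / "res.csv"),
            "--lumen-mode", "automated",
        ])
        assert r.exit_code == 0, r.output
        results = pd.read_csv(tmp_path / "res.csv", comment="#")
        assert len(results) == 6

        img = sorted((out / "images").glob("*_roi1.png"))[0]
        vein = out / "masks" / (img.stem + "_vein.png")
        r = runner.invoke(cli_main, [
            "segment", str(img), "--vein-mask", str(vein),
            "--lumen-mode", "automated",
        ])
        assert r.exit_code == 0, r.output
        assert "cfr_percent" in r.output

        cohort_csv = tmp_path / "cohort.csv"
        rng = np.random.default_rng(0)
        pd.DataFrame({
            "animal_id": [f"a{i}" for i in range(30)],
            "chfs": [0] * 15 + [1] * 15,
            "cfr_percent": np.concatenate([rng.normal(2, 1, 15),
                                           rng.normal(10, 2, 15)]),
        }).to_csv(cohort_csv, index=False)
        r = runner.invoke(cli_main, ["stats", str(cohort_csv)])
        assert r.exit_code == 0, r.output
        assert "ANOVA" in r.output
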