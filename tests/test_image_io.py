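import json

import numpy as np
import pytest
from PIL import Image

from normeval import (
    Box,
    DataError,
    DegenerateInputError,
    ImageSample,
    MetricReport,
    UsageError,
    load_annotations,
    load_image,
    preprocess,
    read_report,
    write_report,
)
from normeval.image_io import (
    FormatError,
    binarize_mask_array,
    flatten_report,
    load_boxes_json,
    load_mask,
    read_report_csv,
    resample_mask,
    save_boxes_json,
    save_image_png,
    save_mask_png,
    scale_box,
)


class TestLoadImage:
    def test_png_identity_read(self, tmp_path):
        p = tmp_path / "white.png"
        Image.fromarray(np.full((16, 16), 255, dtype=np.uint8)).save(p)
        img = load_image(p)
        assert img.id == "white"
        assert np.all(img.pixels == 255.0)

    def test_rgb_png_uses_unweighted_channel_mean(self, tmp_path):
        rgb = np.zeros((4, 4, 3), dtype=np.uint8)
        rgb[...] = (30, 60, 90)
        p = tmp_path / "rgb.png"
        Image.fromarray(rgb).save(p)
        assert np.all(load_image(p).pixels == 60.0)

    def test_2d_nifti_zeros(self, tmp_path):
        import nibabel as nib

        p = tmp_path / "zeros.nii"
        nib.save(nib.Nifti1Image(np.zeros((64, 64)), np.eye(4)), p)
        img = load_image(p)
        assert img.shape == (64, 64)
        assert np.all(img.pixels == 0.0)

    def test_3d_nifti_needs_slice_index(self, tmp_path):
        import nibabel as nib

        p = tmp_path / "vol.nii"
        vol = np.arange(4 * 4 * 3, dtype=float).reshape(4, 4, 3)
        nib.save(nib.Nifti1Image(vol, np.eye(4)), p)
        with pytest.raises(UsageError):
            load_image(p)
        img = load_image(p, slice_index=1)
        assert np.array_equal(img.pixels, vol[:, :, 1])

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(DataError, match="nowhere.png"):
            load_image(tmp_path / "nowhere.png")


class TestPreprocess:
    def test_normalization_divides_by_percentile(self):
        # 128x128 already canonical: no resampling interferes
        rng = np.random.default_rng(0)
        px = rng.uniform(0, 150, size=(128, 128))
        px[0, 0] = 100.0
        img = ImageSample("a", px)
        ref = np.percentile(px, 98)
        out = preprocess(img)
        assert out.pixels[0, 0] == pytest.approx(min(1.0, 100.0 / ref), abs=1e-12)

    def test_percentile_pixel_maps_to_one(self):
        px = np.linspace(0, 200, 128 * 128).reshape(128, 128)
        out = preprocess(ImageSample("a", px))
        ref = np.percentile(px, 98)
        # the pixel(s) at/above the reference intensity saturate at exactly 1
        assert out.pixels.max() == 1.0
        assert np.all(out.pixels[px >= ref] == 1.0)

    def test_values_above_percentile_clip_to_one(self):
        px = np.ones((128, 128))
        px[0, 0] = 1000.0
        out = preprocess(ImageSample("a", px))
        assert out.pixels[0, 0] == 1.0

    @pytest.mark.parametrize("shape", [(100, 60), (60, 100), (128, 128), (33, 201)])
    def test_output_always_canonical(self, shape, rng):
        img = ImageSample("a", rng.uniform(0, 255, size=shape))
        out = preprocess(img)
        assert out.shape == (128, 128)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_padding_centers_before_resize(self):
        # a single bright row in a wide image must stay centered vertically
        px = np.random.default_rng(0).uniform(0, 0.3, size=(60, 100))
        px[30, :] = 100.0
        out = preprocess(ImageSample("a", px))
        row_mass = out.pixels.sum(axis=1)
        center = np.argmax(row_mass)
        assert abs(int(center) - 64) <= 2

    def test_idempotent_on_canonical_images(self):
        # an image whose top >2% saturates: second pass is a no-op
        rng = np.random.default_rng(3)
        px = rng.uniform(0, 0.9, size=(128, 128))
        px[:8, :8] = 2.0  # ~0.4% ... make it >2%: 24x24 = 3.5%
        px[:24, :24] = 2.0
        once = preprocess(ImageSample("a", px))
        twice = preprocess(once)
        np.testing.assert_allclose(twice.pixels, once.pixels, atol=1e-6)

    def test_constant_zero_image_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            preprocess(ImageSample("a", np.zeros((32, 32))))

    def test_invalid_percentile(self):
        with pytest.raises(UsageError):
            preprocess(ImageSample("a", np.ones((8, 8))), percentile=0)


class TestAnnotations:
    def test_mask_png_binarizes(self, tmp_path):
        arr = np.zeros((16, 16), dtype=np.uint8)
        arr[2:5, 3:7] = 255
        p = tmp_path / "m.png"
        Image.fromarray(arr).save(p)
        mask = load_mask(p)
        assert set(np.unique(mask)) <= {0, 1}
        assert mask.sum() == 12

    def test_nonbinary_mask_rejected_with_strict_tolerance(self):
        arr = np.array([[0.0, 0.5, 1.0]])
        with pytest.raises(FormatError):
            binarize_mask_array(arr, "x", tolerance=0.1)
        # default tolerance thresholds instead of failing
        assert binarize_mask_array(arr, "x").tolist() == [[0, 1, 1]]

    def test_box_half_open_area(self):
        box = Box("lesion", 10, 10, 20, 20)
        assert box.area == 100
        box.validate_against((128, 128))

    def test_box_outside_grid_rejected(self):
        box = Box("lesion", 120, 120, 140, 140)
        with pytest.raises(DataError, match="img7"):
            box.validate_against((128, 128), "img7")

    def test_box_nonpositive_area_rejected(self):
        with pytest.raises(DataError):
            Box("lesion", 5, 5, 5, 9)

    def test_load_annotations_requires_a_source(self):
        with pytest.raises(UsageError):
            load_annotations()

    def test_annotation_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        masks = {f"p_{i}": (rng.uniform(size=(32, 32)) > 0.7).astype(np.uint8)
                 for i in range(3)}
        boxes = {"p_0": [Box("edema", 1, 2, 5, 9), Box("mass", 10, 10, 20, 20)]}
        mask_dir = tmp_path / "masks"
        mask_dir.mkdir()
        for k, m in masks.items():
            save_mask_png(m, mask_dir / f"{k}.png")
        save_boxes_json(boxes, tmp_path / "boxes.json")
        ann = load_annotations(mask_dir=mask_dir, box_file=tmp_path / "boxes.json")
        for k, m in masks.items():
            np.testing.assert_array_equal(ann.masks[k], m)
        assert ann.boxes == boxes

    def test_malformed_box_json(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(json.dumps({"p_0": [{"label": "x", "x_min": 0}]}))
        with pytest.raises(FormatError):
            load_boxes_json(p)

    def test_resample_mask_stays_binary(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[5:10, 5:10] = 1
        out = resample_mask(mask, (40, 40))
        assert out.shape == (40, 40)
        assert set(np.unique(out)) <= {0, 1}

    def test_scale_box_rounds_outward(self):
        box = Box("l", 3, 3, 7, 7)
        scaled = scale_box(box, (10, 10), (15, 15))
        assert scaled.x_min <= 4 and scaled.x_max >= 10  # 3*1.5=4.5, 7*1.5=10.5
        assert scaled.area >= box.area


class TestReports:
    @pytest.fixture()
    def report(self):
        return MetricReport(
            rqi=0.6,
            ahi=0.25,
            caci=0.5,
            fused=0.4,
            fid_components={"fid_rp_h": 1.5, "fid_uh_h": 0.5, "fid_p_h": 3.0},
            per_class_detection={"edema": {"n_detected": 2, "n_total": 3, "f1": 0.5}},
            overall_detection={"n_detected": 2, "n_total": 3, "f1": 0.5},
            ceiling_dice={"all": {"dice": 0.8, "threshold": 0.1, "n_cases": 3,
                                  "dice_mean_case": 0.75, "degenerate": False}},
            config_echo={"seed": 1},
        )

    def test_json_round_trip(self, tmp_path, report):
        p = tmp_path / "r.json"
        write_report(report, p, format="json")
        back = read_report(p)
        assert json.loads(p.read_text())["rqi"] == 0.6
        assert back.to_dict() == report.to_dict()
        assert abs(back.fused - report.fused) < 1e-9

    def test_csv_round_trip_numeric_fields(self, tmp_path, report):
        p = tmp_path / "r.csv"
        write_report(report, p, format="csv")
        rows = read_report_csv(p)
        flat = {(r["metric"], r["group"], r["field"]): r["value"]
                for r in flatten_report(report)}
        got = {(r["metric"], r["group"], r["field"]): r["value"] for r in rows}
        for key, value in flat.items():
            if isinstance(value, (int, float)):
                assert got[key] == pytest.approx(float(value), abs=1e-9)

    def test_empty_sections_are_valid(self, tmp_path):
        p = tmp_path / "r.json"
        write_report(MetricReport(rqi=1.0), p, format="json")
        back = read_report(p)
        assert back.rqi == 1.0
        assert back.per_class_detection == {}

    def test_unknown_format(self, tmp_path):
        with pytest.raises(UsageError):
            write_report(MetricReport(), tmp_path / "r.xml", format="xml")
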