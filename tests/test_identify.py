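import numpy as np
import pytest

from pigtag import identify, scene_synth as ss
from pigtag.annotations_io import BBox
from pigtag.identify import (
    AffineMap,
    IDProposal,
    Rejection,
    assemble_id,
    crop_and_square,
    dedup_proposals,
    preprocess_frame,
    run_pipeline,
    verify_glyphs,
    write_results_tsv,
)


class TestPreprocessFrame:
    def test_identity_for_640_gray(self):
        img = np.random.default_rng(0).uniform(0, 255, (640, 640))
        out, t = preprocess_frame(img)
        assert np.allclose(out, img)
        assert (t.scale, t.tx, t.ty) == (1.0, 0.0, 0.0)

    def test_equal_rgb_channels(self):
        rgb = np.full((640, 640, 3), 100.0)
        out, _ = preprocess_frame(rgb)
        assert np.allclose(out, 100.0)

    def test_letterbox_1080p(self):
        img = np.full((1080, 1920), 200.0)
        out, t = preprocess_frame(img)
        assert out.shape == (640, 640)
        # content region 640x360 centered; bands above/below filled with 114
        assert np.allclose(out[:140], 114.0)
        assert np.allclose(out[500:], 114.0)
        assert np.allclose(out[140:500], 200.0)
        # transform maps content corners back to source corners
        assert t.to_source(0.0, 140.0) == pytest.approx((0.0, 0.0))
        assert t.to_source(640.0, 500.0) == pytest.approx((1920.0, 1080.0))

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            preprocess_frame(np.zeros((0, 10)))


class TestCropAndSquare:
    def test_square_box_pure_resize(self):
        frame = np.random.default_rng(0).uniform(0, 255, (640, 640))
        box = BBox(0, 0.5, 0.5, 0.25, 0.25)
        crop, t = crop_and_square(frame, box, 64)
        assert crop.shape == (64, 64)
        assert not np.any(crop == 114.0)  # no padding for a square box

    def test_wide_box_pads_top_bottom(self):
        frame = np.full((640, 640), 200.0)
        box = BBox(0, 0.5, 0.5, 100 / 640, 50 / 640)
        crop, _ = crop_and_square(frame, box, 64)
        # 25% pad bands top and bottom (one boundary row blurs under
        # bilinear resampling)
        assert np.allclose(crop[:15], 114.0)
        assert np.allclose(crop[-15:], 114.0)
        assert np.allclose(crop[18:46], 200.0)

    def test_round_trip_within_one_pixel(self):
        frame = np.zeros((640, 640))
        box = BBox(0, 0.4, 0.3, 0.2, 0.1)
        _, t = crop_and_square(frame, box, 128)
        from pigtag.annotations_io import to_pixels
        x0, y0, x1, y1 = to_pixels(box, 640, 640)
        # crop corner (pixel origin of the content area) maps back to (x0, y0)
        bx, by = t.from_source(x0, y0)
        rx, ry = t.to_source(bx, by)
        assert abs(rx - x0) <= 1.0 and abs(ry - y0) <= 1.0

    def test_degenerate_edge_box_padded(self):
        frame = np.zeros((64, 64))
        edge = BBox(0, 1.0, 1.0, 1e-6, 1e-6)
        crop, _ = crop_and_square(frame, edge, 8)
        assert crop.shape == (8, 8)


class TestAffineMap:
    def test_compose(self):
        inner = AffineMap(scale=2.0, tx=10.0, ty=20.0)
        outer = AffineMap(scale=0.5, tx=100.0, ty=200.0)
        chained = inner.then(outer)
        x, y = 8.0, 6.0
        manual = outer.to_source(*inner.to_source(x, y))
        assert chained.to_source(x, y) == pytest.approx(manual)

    def test_inverse(self):
        t = AffineMap(scale=0.3, tx=-12.0, ty=7.5)
        x, y = t.from_source(123.0, 45.0)
        assert t.to_source(x, y) == pytest.approx((123.0, 45.0))


class TestAssembleID:
    def test_fig3_example(self):
        boxes = [
            BBox(7, 0.72, 0.5, 0.1, 0.3, conf=0.9),
            BBox(5, 0.30, 0.5, 0.1, 0.3, conf=0.95),
        ]
        out = assemble_id(boxes)
        assert isinstance(out, IDProposal)
        assert out.id_str == "57"
        assert out.value == 57
        assert out.conf == pytest.approx(0.9)
        assert out.digit_confs == (0.95, 0.9)

    def test_single_digit_rejected(self):
        out = assemble_id([BBox(4, 0.5, 0.5, 0.1, 0.3, conf=0.9)])
        assert isinstance(out, Rejection)
        assert out.reason == "wrong_digit_count"

    def test_out_of_range(self):
        boxes = [
            BBox(0, 0.2, 0.5, 0.1, 0.3, conf=0.9),
            BBox(8, 0.6, 0.5, 0.1, 0.3, conf=0.9),
        ]
        out = assemble_id(boxes)
        assert isinstance(out, Rejection)
        assert out.reason == "out_of_range"

    def test_no_digits(self):
        out = assemble_id([])
        assert isinstance(out, Rejection)
        assert out.reason == "no_digits"


class TestDedup:
    def _prop(self, id_str, conf, area=0.01):
        side = float(np.sqrt(area))
        return IDProposal(id_str, int(id_str), conf, 0,
                          BBox(0, 0.5, 0.5, side, side, conf), (conf, conf))

    def test_keeps_highest_confidence(self):
        props = [self._prop("41", 0.9), self._prop("41", 0.8), self._prop("47", 0.7)]
        out = dedup_proposals(props)
        assert [(p.id_str, p.conf) for p in out] == [("41", 0.9), ("47", 0.7)]

    def test_empty(self):
        assert dedup_proposals([]) == []

    def test_distinct_sorted(self):
        props = [self._prop("93", 0.5), self._prop("12", 0.6)]
        assert [p.id_str for p in dedup_proposals(props)] == ["12", "93"]

    def test_idempotent(self):
        props = [self._prop("41", 0.9), self._prop("41", 0.8), self._prop("47", 0.7)]
        once = dedup_proposals(props)
        assert dedup_proposals(once) == once

    def test_tie_breaks_to_larger_tag(self):
        small = self._prop("41", 0.9, area=0.01)
        large = self._prop("41", 0.9, area=0.04)
        assert dedup_proposals([small, large])[0].tag_box.w == large.tag_box.w


class TestVerifyGlyphs:
    def _clean_rect_crop(self, backends):
        spec = ss.SceneSpec(n_pigs=1, seed=8)
        img, _ = ss.render_scene(spec)
        proc, _ = identify.preprocess_frame(img)
        pig = backends["pig"].detect(proc)[0]
        crop, _ = identify.crop_and_square(proc, pig, 640)
        tag = backends["tag"].detect(crop)[0]
        tag_crop, _ = identify.crop_and_square(crop, tag, 320)
        from pigtag.rectify import rectify_tag
        rect, _ = rectify_tag(tag_crop, backends["pin"].detect(tag_crop))
        digits = backends["digit"].detect(rect)
        return rect, digits

    def test_clean_read_passes(self, backends):
        rect, digits = self._clean_rect_crop(backends)
        assert len(digits) == 2
        ok, detail = verify_glyphs(rect, digits)
        assert ok, detail

    def test_extra_ink_rejected(self, backends):
        rect, digits = self._clean_rect_crop(backends)
        rect = rect.copy()
        rect[5:25, 85:105] = 30.0  # unexplained ink blob
        ok, detail = verify_glyphs(rect, digits)
        assert not ok

    def test_blank_crop_rejected(self):
        blank = np.full((120, 120), 230.0)
        ok, _ = verify_glyphs(blank, [BBox(5, 0.5, 0.5, 0.2, 0.3, 0.9)])
        assert not ok


class TestRunPipeline:
    def test_no_pigs(self, backends):
        img, _ = ss.render_scene(ss.SceneSpec(n_pigs=0, seed=1))
        res = run_pipeline([img], backends)
        assert len(res) == 1
        assert res[0].proposals == [] and res[0].error is None

    def test_adjacent_pigs_both_ids_once(self, backends):
        spec = ss.SceneSpec(n_pigs=2, id_pool=(39, 41), seed=6)
        img, truth = ss.render_scene(spec)
        res = run_pipeline([img], backends)[0]
        assert sorted(p.id_str for p in res.proposals) == sorted(truth.tag_ids)
        assert len({p.id_str for p in res.proposals}) == len(res.proposals)

    def test_frame_independence(self, backends):
        imgs = [ss.render_scene(ss.SceneSpec(n_pigs=2, seed=s))[0] for s in (4, 5)]
        joint = run_pipeline(imgs, backends)
        solo = [run_pipeline([im], backends)[0] for im in imgs]
        for j, s in zip(joint, solo):
            assert [p.id_str for p in j.proposals] == [p.id_str for p in s.proposals]

    def test_missing_backend(self, backends):
        partial = {k: v for k, v in backends.items() if k != "pin"}
        with pytest.raises(ValueError, match="pin"):
            run_pipeline([], partial)

    def test_proposal_invariants(self, backends, clean_scene):
        _, img, _ = clean_scene
        res = run_pipeline([img], backends)[0]
        for p in res.proposals:
            assert p.id_str == str(p.value).zfill(2)
            assert 10 <= p.value <= 99
            assert p.conf == pytest.approx(min(p.digit_confs))

    def test_tag_box_matches_truth_in_frame_coords(self, backends, clean_scene):
        from pigtag.detect import iou
        _, img, truth = clean_scene
        res = run_pipeline([img], backends)[0]
        for p in res.proposals:
            assert max(iou(p.tag_box, tb) for tb in truth.tag_boxes) >= 0.5

    def test_write_results_tsv(self, backends, clean_scene, tmp_path):
        _, img, _ = clean_scene
        res = run_pipeline([img], backends)
        out = tmp_path / "results.tsv"
        write_results_tsv(res, out, frame_shapes=[img.shape])
        lines = out.read_text().strip().splitlines()
        assert len(lines) == len(res[0].proposals) > 0
        frame, id_str, conf, coords = lines[0].split("\t")
        assert frame == "0" and len(id_str) == 2
        assert 0.0 <= float(conf) <= 1.0
        assert len(coords.split(",")) == 4
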