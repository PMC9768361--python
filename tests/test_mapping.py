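"""Section placement, layout refinement, and recovery-map compositing."""

import numpy as np
import pytest
from dataclasses import replace

from mucomap.loss_metrics import dice
from mucomap.mapping import (
    SectionLayout,
    build_recovery_map,
    load_layouts,
    place_section,
    refine_layout,
    save_layouts,
)
from mucomap.masks import classmap_to_rgb


def lesion_cm(shape=(20, 40), box=(5, 15, 10, 30), klass=1):
    cm = np.zeros(shape, dtype=np.int8)
    r0, r1, c0, c1 = box
    cm[r0:r1, c0:c1] = klass
    return cm


class TestPlaceSection:
    def test_identity_layout_reproduces_mask_colors(self):
        cm = lesion_cm()
        layout = SectionLayout(0, anchor=(0.0, 0.0), rotation_deg=0.0, scale=1.0)
        placed, cov, overlay = place_section(cm, layout, cm.shape)
        assert (placed == cm).all()
        rgb = classmap_to_rgb(cm)
        lesion = cm > 0
        assert (overlay[lesion, :3] == rgb[lesion]).all()
        assert (overlay[lesion, 3] == 255).all()
        assert (overlay[~lesion, 3] == 0).all()

    def test_half_scale_shrinks_area_by_four(self):
        cm = lesion_cm((40, 80), (10, 30, 20, 60))
        layout = SectionLayout(0, anchor=(0.0, 0.0), scale=0.5)
        placed, _, _ = place_section(cm, layout, (40, 80))
        ratio = (cm == 1).sum() / max((placed == 1).sum(), 1)
        assert ratio == pytest.approx(4.0, rel=0.1)

    def test_double_180_rotation_is_identity(self):
        cm = lesion_cm((21, 41), (3, 9, 5, 25))
        h, w = cm.shape
        # rotate 180 about the strip by anchoring the opposite corner
        layout = SectionLayout(0, anchor=(float(w), float(h)), rotation_deg=180.0)
        once, _, _ = place_section(cm, layout, cm.shape)
        twice, _, _ = place_section(once, layout, cm.shape)
        inner = (slice(1, h - 1), slice(1, w - 1))
        assert (twice[inner] == cm[inner]).all()

    def test_out_of_canvas_strip_is_clipped(self, caplog):
        cm = lesion_cm()
        layout = SectionLayout(0, anchor=(30.0, 10.0))
        with caplog.at_level("WARNING"):
            placed, cov, _ = place_section(cm, layout, (20, 40))
        assert cov.sum() < cm.size
        assert any("clipping" in r.message for r in caplog.records)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            SectionLayout(0, anchor=(0, 0), scale=0.0)


class TestRefineLayout:
    def test_recovers_known_displacement(self, small_case):
        sec = small_case.sections[1]
        displaced = replace(
            sec.layout_true,
            anchor=(sec.layout_true.anchor[0] + 10, sec.layout_true.anchor[1] - 7),
        )
        res = refine_layout(
            sec.image, displaced, small_case.specimen_photo, search_window=15
        )
        assert not res.low_confidence
        err = np.hypot(
            res.layout.anchor[0] - sec.layout_true.anchor[0],
            res.layout.anchor[1] - sec.layout_true.anchor[1],
        )
        assert err <= 2.0

    def test_already_optimal_layout_keeps_score(self, small_case):
        sec = small_case.sections[0]
        res = refine_layout(sec.image, sec.layout_true, small_case.specimen_photo)
        err = np.hypot(
            res.layout.anchor[0] - sec.layout_true.anchor[0],
            res.layout.anchor[1] - sec.layout_true.anchor[1],
        )
        assert err <= 2.0 and res.score > 0.5

    def test_featureless_strip_low_confidence(self, small_case):
        flat = np.full_like(small_case.sections[0].image, 128)
        layout = small_case.sections[0].layout_nominal
        res = refine_layout(flat, layout, small_case.specimen_photo)
        assert res.low_confidence
        assert res.layout == layout


class TestBuildRecoveryMap:
    def test_single_section_identity_matches_place_section(self):
        cm = lesion_cm()
        layout = SectionLayout(0, anchor=(0.0, 0.0))
        photo = np.full(cm.shape + (3,), 200, dtype=np.uint8)
        rec = build_recovery_map([(cm, layout)], photo)
        placed, _, overlay = place_section(cm, layout, cm.shape)
        assert (rec.class_canvas == placed).all()
        assert (rec.overlay == overlay).all()

    def test_duplicate_section_index_rejected(self):
        cm = lesion_cm()
        photo = np.zeros((64, 64, 3), dtype=np.uint8)
        layouts = [SectionLayout(1, anchor=(0, 0)), SectionLayout(1, anchor=(0, 30))]
        with pytest.raises(ValueError, match="duplicate"):
            build_recovery_map([(cm, l) for l in layouts], photo)

    def test_lower_section_index_wins_overlaps(self):
        a = lesion_cm((10, 10), (0, 10, 0, 10), klass=1)
        b = lesion_cm((10, 10), (0, 10, 0, 10), klass=2)
        photo = np.zeros((10, 16, 3), dtype=np.uint8)
        rec = build_recovery_map(
            [(b, SectionLayout(2, anchor=(6.0, 0.0))),
             (a, SectionLayout(1, anchor=(0.0, 0.0)))],
            photo,
        )
        assert (rec.class_canvas[:, :10] == 1).all()  # overlap kept section 1
        assert (rec.class_canvas[:, 10:] == 2).all()
        assert (rec.provenance[:, :10] == 1).all()
        assert rec.summary["overlap_pixels"] == 40

    def test_lesion_free_case_is_transparent(self):
        cm = np.zeros((10, 20), dtype=np.int8)
        photo = np.full((10, 20, 3), 180, dtype=np.uint8)
        rec = build_recovery_map([(cm, SectionLayout(0, anchor=(0, 0)))], photo)
        assert not rec.overlay[..., 3].any()
        assert rec.summary["per_class_area_px"] == {"1": 0, "2": 0}
        assert (rec.composite == photo).all()

    def test_area_conserved_through_mapping(self, small_case):
        """Lesion area maps as scale^2 within resampling tolerance."""
        photo = small_case.specimen_photo
        secs = [(s.class_map, s.layout_true) for s in small_case.sections]
        rec = build_recovery_map(secs, photo)
        for k in (1, 2):
            slide_px = sum((s.class_map == k).sum() for s in small_case.sections)
            scale = small_case.sections[0].layout_true.scale
            mapped = (rec.class_canvas == k).sum()
            if slide_px:
                assert mapped == pytest.approx(slide_px * scale**2, rel=0.1)

    def test_physical_area_uses_scale_and_resolution(self):
        cm = lesion_cm((20, 20), (0, 10, 0, 10))
        photo = np.zeros((20, 20, 3), dtype=np.uint8)
        rec = build_recovery_map(
            [(cm, SectionLayout(0, anchor=(0, 0), scale=1.0))],
            photo,
            microns_per_pixel=1000.0,  # 1 mm per slide pixel
        )
        assert rec.summary["per_class_area_mm2"]["1"] == pytest.approx(100.0)

    def test_layout_json_round_trip(self, tmp_path):
        layouts = [
            SectionLayout(i, anchor=(1.5 * i, 2.0), rotation_deg=-2.5, scale=0.5)
            for i in range(3)
        ]
        save_layouts(tmp_path / "l.json", layouts)
        assert load_layouts(tmp_path / "l.json") == layouts


def test_refinement_reduces_jitter_error(small_case, rng):
    """Across sections and random jitters, refinement shrinks the mean
    translation error of the initial layouts."""
    photo = small_case.specimen_photo
    errs_before, errs_after = [], []
    for sec in small_case.sections:
        for _ in range(3):
            jx, jy = rng.uniform(-8, 8, size=2)
            start = replace(
                sec.layout_true,
                anchor=(sec.layout_true.anchor[0] + jx,
                        sec.layout_true.anchor[1] + jy),
            )
            res = refine_layout(sec.image, start, photo, search_window=12)
            errs_before.append(np.hypot(jx, jy))
            errs_after.append(
                np.hypot(res.layout.anchor[0] - sec.layout_true.anchor[0],
                         res.layout.anchor[1] - sec.layout_true.anchor[1])
            )
    assert np.mean(errs_after) < np.mean(errs_before)


def test_end_to_end_recovery_dice(small_case):
    """Refined nominal layouts reproduce the ground-truth recovery map."""
    photo = small_case.specimen_photo
    sections = []
    for sec in small_case.sections:
        res = refine_layout(sec.image, sec.layout_nominal, photo, search_window=15)
        sections.append((sec.class_map, res.layout))
    rec = build_recovery_map(sections, photo)
    gt = small_case.gt_class_canvas
    assert dice(rec.class_canvas, gt, 3) >= 0.9
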