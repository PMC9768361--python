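"""Section-to-specimen mapping: the mucosal recovery map.

After segmentation, each histology section's slide-level class map is placed
back at its cut position on the macroscopic photograph of the sectioned ESD
specimen.  Placement is a rigid similarity transform per section (scale,
rotation, anchor translation) taken from a layout manifest; an optional
refinement step adjusts the translation (and coarsely the rotation) by
maximizing normalized cross-correlation between the transformed slide and
the photo.  Sections are composited in cut order; where adjacent strips
overlap, the lower section index wins and the overlap area is logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import match_template
from skimage.transform import SimilarityTransform, warp

from .masks import DEFAULT_SCHEME, ColorScheme

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SectionLayout:
    """Rigid placement of one section strip on the specimen photo.

    ``anchor`` is the photo-pixel position of the slide's (0, 0) corner;
    ``scale`` is specimen-photo pixels per slide pixel; ``strip_axis`` the
    unit direction of the cut (strips run along +x by default).
    """

    section_index: int
    anchor: tuple  # (x, y) photo pixels
    rotation_deg: float = 0.0
    scale: float = 1.0
    strip_axis: tuple = (1.0, 0.0)

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    def transform(self) -> SimilarityTransform:
        """Slide (x, y) -> photo (x, y)."""
        return SimilarityTransform(
            scale=self.scale,
            rotation=np.deg2rad(self.rotation_deg),
            translation=tuple(self.anchor),
        )

    def to_dict(self) -> dict:
        return {
            "section_index": self.section_index,
            "anchor": list(self.anchor),
            "rotation_deg": self.rotation_deg,
            "scale": self.scale,
            "strip_axis": list(self.strip_axis),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SectionLayout":
        return cls(
            section_index=int(d["section_index"]),
            anchor=tuple(d["anchor"]),
            rotation_deg=float(d.get("rotation_deg", 0.0)),
            scale=float(d.get("scale", 1.0)),
            strip_axis=tuple(d.get("strip_axis", (1.0, 0.0))),
        )


def save_layouts(path, layouts) -> None:
    with open(path, "w") as fh:
        json.dump([l.to_dict() for l in layouts], fh, indent=2)


def load_layouts(path) -> list:
    with open(path) as fh:
        return [SectionLayout.from_dict(d) for d in json.load(fh)]


@dataclass
class RecoveryMap:
    """Lesion overlay on the specimen photo plus provenance bookkeeping."""

    overlay: np.ndarray  # (H, W, 4) uint8 RGBA, transparent off-lesion
    class_canvas: np.ndarray  # (H, W) int class labels (0 where nothing placed)
    provenance: np.ndarray  # (H, W) int section index, -1 where none
    composite: np.ndarray  # (H, W, 3) uint8 photo with blended overlay
    summary: dict


def warp_section(
    arr: np.ndarray, layout: SectionLayout, canvas_shape, order: int, cval=0.0
):
    """Warp a slide-frame array into the photo frame (nearest/bilinear)."""
    tf = layout.transform()
    return warp(
        arr.astype(np.float64),
        inverse_map=tf.inverse,
        output_shape=tuple(canvas_shape),
        order=order,
        cval=cval,
        preserve_range=True,
    )


def place_section(
    cm: np.ndarray,
    layout: SectionLayout,
    canvas_shape,
    scheme: ColorScheme = DEFAULT_SCHEME,
):
    """Map one section's class map onto the photo canvas.

    Returns ``(class_canvas, coverage, overlay)``: integer classes (0 where
    the strip does not cover), a boolean strip-coverage mask, and an RGBA
    overlay with opaque scheme colors on lesion (non-normal) pixels.  Strips
    extending beyond the canvas are clipped with a warning.
    """
    cm = np.asarray(cm)
    H, W = canvas_shape
    tf = layout.transform()
    h, w = cm.shape
    corners = tf(np.array([[0, 0], [w, 0], [0, h], [w, h]], dtype=float))
    if (
        corners[:, 0].min() < -0.5
        or corners[:, 1].min() < -0.5
        or corners[:, 0].max() > W + 0.5
        or corners[:, 1].max() > H + 0.5
    ):
        logger.warning(
            "section %d: transformed strip exceeds the canvas; clipping",
            layout.section_index,
        )
    placed = warp_section(cm, layout, canvas_shape, order=0).astype(cm.dtype)
    coverage = warp_section(np.ones(cm.shape), layout, canvas_shape, order=0) > 0.5
    placed[~coverage] = 0

    overlay = np.zeros((H, W, 4), dtype=np.uint8)
    palette = scheme.as_array()
    lesion = coverage & (placed > 0)
    overlay[lesion, :3] = palette[placed[lesion]]
    overlay[lesion, 3] = 255
    return placed, coverage, overlay


@dataclass
class RefineResult:
    layout: SectionLayout
    score: float
    low_confidence: bool = False


def refine_layout(
    slide_image: np.ndarray,
    layout: SectionLayout,
    specimen_photo: np.ndarray,
    search_window: int = 15,
    rotation_search_deg: float = 4.0,
    rotation_step_deg: float = 1.0,
    min_score: float = 0.2,
) -> RefineResult:
    """Adjust a section's placement by normalized cross-correlation.

    The slide is rendered into photo scale under the candidate transform and
    matched against the photo within ``search_window`` pixels of the initial
    anchor, over a coarse grid of rotation offsets.  The best-scoring
    placement is returned; a flat or weak correlation surface (peak below
    ``min_score``) leaves the layout unchanged with ``low_confidence`` set.
    """
    photo_gray = rgb2gray(specimen_photo) if specimen_photo.ndim == 3 else specimen_photo
    slide_gray = rgb2gray(slide_image) if slide_image.ndim == 3 else slide_image
    if slide_gray.std() < 1e-6:
        return RefineResult(layout, 0.0, low_confidence=True)
    H, W = photo_gray.shape
    fill = float(np.median(photo_gray))

    n_steps = int(round(rotation_search_deg / rotation_step_deg))
    dthetas = [i * rotation_step_deg for i in range(-n_steps, n_steps + 1)]

    h, w = slide_gray.shape
    base_corners = np.array([[0, 0], [w, 0], [0, h], [w, h]], dtype=float)

    best = None
    init_score = None
    for dth in dthetas:
        rot = layout.rotation_deg + dth
        tf_lin = SimilarityTransform(
            scale=layout.scale, rotation=np.deg2rad(rot)
        )
        lin = tf_lin(base_corners)
        bbox_min = lin.min(axis=0)
        extent = np.ceil(lin.max(axis=0) - bbox_min).astype(int)
        tf_tpl = SimilarityTransform(
            scale=layout.scale,
            rotation=np.deg2rad(rot),
            translation=tuple(-bbox_min),
        )
        template = warp(
            slide_gray,
            inverse_map=tf_tpl.inverse,
            output_shape=(int(extent[1]), int(extent[0])),
            order=1,
            cval=fill,
            preserve_range=True,
        )
        # expected photo-pixel position of the template's top-left corner
        exp_x = layout.anchor[0] + bbox_min[0]
        exp_y = layout.anchor[1] + bbox_min[1]
        x0 = int(np.floor(exp_x)) - search_window
        y0 = int(np.floor(exp_y)) - search_window
        x1 = int(np.ceil(exp_x)) + template.shape[1] + search_window
        y1 = int(np.ceil(exp_y)) + template.shape[0] + search_window
        x0c, y0c = max(x0, 0), max(y0, 0)
        region = photo_gray[y0c : min(y1, H), x0c : min(x1, W)]
        if region.shape[0] < template.shape[0] or region.shape[1] < template.shape[1]:
            continue
        score_map = match_template(region, template)
        peak = np.unravel_index(np.argmax(score_map), score_map.shape)
        score = float(score_map[peak])
        dy = (y0c + peak[0]) - exp_y
        dx = (x0c + peak[1]) - exp_x
        if dth == 0.0:
            iy, ix = int(round(exp_y)) - y0c, int(round(exp_x)) - x0c
            if 0 <= iy < score_map.shape[0] and 0 <= ix < score_map.shape[1]:
                init_score = float(score_map[iy, ix])
        if best is None or score > best[0]:
            best = (score, dth, dx, dy)

    if best is None or best[0] < min_score:
        return RefineResult(layout, 0.0 if best is None else best[0], True)
    score, dth, dx, dy = best
    if init_score is not None and score < init_score:
        return RefineResult(layout, init_score, False)
    refined = replace(
        layout,
        anchor=(layout.anchor[0] + dx, layout.anchor[1] + dy),
        rotation_deg=layout.rotation_deg + dth,
    )
    return RefineResult(refined, score, False)


def build_recovery_map(
    sections,
    specimen_photo: np.ndarray,
    scheme: ColorScheme = DEFAULT_SCHEME,
    microns_per_pixel: float | None = None,
) -> RecoveryMap:
    """Composite per-section class maps into the mucosal recovery map.

    ``sections``: iterable of ``(class_map, SectionLayout)``.  Placement
    happens in ascending section index; overlapping strip pixels keep the
    lower index.  The summary reports per-class areas (mm^2 when
    ``microns_per_pixel`` is given, else photo pixels with a warning) and
    per-section class presence.
    """
    sections = sorted(sections, key=lambda s: s[1].section_index)
    indices = [layout.section_index for _, layout in sections]
    if len(set(indices)) != len(indices):
        raise ValueError(f"duplicate section_index in {indices}")

    H, W = specimen_photo.shape[:2]
    class_canvas = np.zeros((H, W), dtype=np.int16)
    provenance = np.full((H, W), -1, dtype=np.int32)
    overlap_px = 0
    per_section = {}
    scales = {}
    for cm, layout in sections:
        placed, coverage, _ = place_section(cm, layout, (H, W), scheme)
        new = coverage & (provenance == -1)
        overlap_px += int((coverage & (provenance != -1)).sum())
        class_canvas[new] = placed[new]
        provenance[new] = layout.section_index
        scales[layout.section_index] = layout.scale
        present = sorted(
            int(c) for c in np.unique(placed[new]) if c != 0
        )
        per_section[str(layout.section_index)] = {"classes_present": present}
    if overlap_px:
        logger.info("recovery map: %d overlapping strip pixels resolved", overlap_px)

    palette = scheme.as_array()
    overlay = np.zeros((H, W, 4), dtype=np.uint8)
    lesion = class_canvas > 0
    overlay[lesion, :3] = palette[class_canvas[lesion]]
    overlay[lesion, 3] = 255

    composite = specimen_photo[..., :3].astype(np.float32).copy()
    composite[lesion] = 0.5 * composite[lesion] + 0.5 * overlay[lesion, :3]
    composite = np.clip(np.rint(composite), 0, 255).astype(np.uint8)

    summary = {
        "per_section": per_section,
        "overlap_pixels": overlap_px,
        "per_class_area_px": {},
    }
    for k in range(1, scheme.num_classes):
        summary["per_class_area_px"][str(k)] = int((class_canvas == k).sum())
    if microns_per_pixel is not None:
        areas_mm2 = {}
        for k in range(1, scheme.num_classes):
            total = 0.0
            for idx, scale in scales.items():
                n = int(((class_canvas == k) & (provenance == int(idx))).sum())
                mm_per_px = microns_per_pixel / (1000.0 * scale)
                total += n * mm_per_px**2
            areas_mm2[str(k)] = total
        summary["per_class_area_mm2"] = areas_mm2
    else:
        logger.warning("no microns_per_pixel given; areas reported in pixels only")
    return RecoveryMap(overlay, class_canvas, provenance, composite, summary)
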