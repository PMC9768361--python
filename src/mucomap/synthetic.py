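"""Synthetic slides, masks, and specimen photographs for end-to-end testing.

No public dataset accompanies this pipeline, so every stage is exercised on
generated data with the statistical structure the real inputs have:

* a *slide* is a textured tissue field — a pink, lightly speckled normal
  mucosa background with smooth blob-shaped lesions of two non-normal
  classes stamped into it (cancerous: same hue family but a much higher
  density of dark nuclei spots; intestinal metaplasia: a distinct
  blue-purple hue shift) — with a pixel-exact paired class map;
* a *case* is a virtual 2-D specimen cut into parallel strips at
  2.0-3.0 mm intervals, each strip rendered both as its own slide and onto
  a macroscopic specimen photo at a known (slightly jittered) rigid
  placement, together with the ground-truth recovery map.

Everything is deterministic given ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import disk, polygon

from .mapping import SectionLayout, place_section

SPOT_COLOR = (100, 60, 130)  # dark hematoxylin-like nuclei


@dataclass(frozen=True)
class ClassTexture:
    """Texture recipe for one tissue class."""

    base_rgb: tuple
    spot_density: float  # nuclei per pixel^2
    spot_radius: float  # pixels
    spot_rgb: tuple = SPOT_COLOR


@dataclass
class SynthParams:
    """Generator settings.

    Class textures are pairwise distinguishable by construction: cancerous
    tissue has ~10x the normal nuclei density at the same hue family, and
    intestinal metaplasia a >=20-unit blue hue shift at intermediate
    density — margins a small network separates quickly, which is what
    desk-scale tests need.
    """

    slide_size: tuple = (512, 512)
    n_cancer_lesions: int = 2
    n_metaplasia_lesions: int = 2
    lesion_radius_range: tuple = (30, 80)
    textures: dict = field(
        default_factory=lambda: {
            # normal mucosa: pale pink, sparse light nuclei
            0: ClassTexture((235, 195, 205), 0.0015, 2.0, (150, 110, 160)),
            # cancerous: deeper pink with ~10x nuclei density
            1: ClassTexture((225, 150, 170), 0.022, 2.0, (90, 50, 110)),
            # intestinal metaplasia: strong blue-purple shift, goblet-like spots
            2: ClassTexture((140, 145, 235), 0.006, 2.5, (70, 80, 170)),
        }
    )
    noise_sd: float = 5.0
    microns_per_pixel: float = 1.0
    rng_seed: int = 0

    # case-level geometry
    photo_scale: float = 0.25  # specimen-photo px per slide px
    layout_jitter_px: float = 10.0
    layout_jitter_deg: float = 3.0
    photo_margin_px: int = 20
    strip_gap_px: int = 6

    def n_lesions(self, klass: int) -> int:
        return {1: self.n_cancer_lesions, 2: self.n_metaplasia_lesions}[klass]


@dataclass
class Section:
    """One cut strip: its slide rendering, labels, and placements."""

    image: np.ndarray  # (h, w, 3) uint8
    class_map: np.ndarray  # (h, w) int8
    layout_true: SectionLayout  # placement actually used to draw the photo
    layout_nominal: SectionLayout  # regular-grid initialization (no jitter)


@dataclass
class SyntheticCase:
    specimen_photo: np.ndarray  # (H, W, 3) uint8
    sections: list
    cut_interval_mm: float
    gt_class_canvas: np.ndarray  # ground-truth recovery map (photo frame)
    virtual_specimen: np.ndarray  # full-resolution specimen image
    virtual_class_map: np.ndarray


def _blob_mask(rng: np.random.Generator, shape, center, radius: float) -> np.ndarray:
    """Smooth perturbed-ellipse blob, area within ~[0.6, 1.25] * pi r^2."""
    theta = np.linspace(0.0, 2.0 * np.pi, 360, endpoint=False)
    aspect = rng.uniform(0.75, 1.0)
    tilt = rng.uniform(0.0, np.pi)
    k1, k2 = rng.integers(2, 5), rng.integers(5, 9)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    wobble = 1.0 + 0.07 * np.sin(k1 * theta + ph1) + 0.03 * np.sin(k2 * theta + ph2)
    rx = radius * wobble * np.cos(theta)
    ry = radius * aspect * wobble * np.sin(theta)
    xs = center[1] + rx * np.cos(tilt) - ry * np.sin(tilt)
    ys = center[0] + rx * np.sin(tilt) + ry * np.cos(tilt)
    rr, cc = polygon(ys, xs, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _render_texture(cm: np.ndarray, params: SynthParams, rng: np.random.Generator):
    """Paint class textures over a class map; pixel-exact alignment."""
    H, W = cm.shape
    img = np.zeros((H, W, 3), dtype=np.float32)
    for klass, tex in params.textures.items():
        region = cm == klass
        img[region] = tex.base_rgb
    for klass, tex in params.textures.items():
        region = cm == klass
        area = int(region.sum())
        if area == 0 or tex.spot_density <= 0:
            continue
        n_spots = rng.poisson(tex.spot_density * area)
        if n_spots == 0:
            continue
        ridx = np.flatnonzero(region.ravel())
        chosen = rng.choice(ridx, size=n_spots, replace=True)
        ys, xs = np.unravel_index(chosen, (H, W))
        for y, x in zip(ys, xs):
            rr, cc = disk((y, x), tex.spot_radius, shape=(H, W))
            img[rr, cc] = tex.spot_rgb
    img += rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_classmap(
    params: SynthParams, rng: np.random.Generator, shape=None, max_retries: int = 200
) -> np.ndarray:
    """Place non-overlapping lesion blobs of both classes on a normal field."""
    shape = tuple(shape or params.slide_size)
    cm = np.zeros(shape, dtype=np.int8)
    r_lo, r_hi = params.lesion_radius_range
    for klass in (1, 2):
        for _ in range(params.n_lesions(klass)):
            placed = False
            for _attempt in range(max_retries):
                radius = float(rng.uniform(r_lo, r_hi))
                margin = 1.2 * radius
                if 2 * margin >= min(shape):
                    continue
                cy = float(rng.uniform(margin, shape[0] - margin))
                cx = float(rng.uniform(margin, shape[1] - margin))
                blob = _blob_mask(rng, shape, (cy, cx), radius)
                if not (cm[blob] != 0).any():
                    cm[blob] = klass
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place a class-{klass} lesion without overlap "
                    f"after {max_retries} retries"
                )
    return cm


def generate_slide(params: SynthParams, rng=None, shape=None):
    """One synthetic annotated slide: (uint8 RGB image, class map)."""
    rng = rng if rng is not None else np.random.default_rng(params.rng_seed)
    cm = generate_classmap(params, rng, shape)
    img = _render_texture(cm, params, rng)
    return img, cm


def generate_case(params: SynthParams, n_sections: int = 6) -> SyntheticCase:
    """One synthetic specimen case cut into parallel strips.

    A single virtual specimen (one large slide) is cut into ``n_sections``
    horizontal strips whose height corresponds to a cut interval drawn from
    2.0-3.0 mm at ``microns_per_pixel``.  Each strip becomes a section with
    its own image and class map; the specimen photo renders every strip at
    ``photo_scale`` with per-section rotation (± ``layout_jitter_deg``) and
    translation (± ``layout_jitter_px``) jitter relative to the nominal grid
    layout, emulating how real strips never sit perfectly straight.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    rng = np.random.default_rng(params.rng_seed)
    interval_mm = float(rng.uniform(2.0, 3.0))
    strip_h = max(16, int(round(interval_mm * 1000.0 / params.microns_per_pixel)))
    W = params.slide_size[1]
    H = strip_h * n_sections

    specimen_img, specimen_cm = generate_slide(params, rng, shape=(H, W))

    s = params.photo_scale
    margin = params.photo_margin_px
    gap = params.strip_gap_px
    row_h = strip_h * s + gap
    photo_H = int(np.ceil(2 * margin + n_sections * row_h))
    photo_W = int(np.ceil(2 * margin + W * s))
    # cork-board background with mild mottling
    photo = np.clip(
        rng.normal(0.0, 4.0, size=(photo_H, photo_W, 3))
        + np.array([205.0, 185.0, 160.0]),
        0,
        255,
    ).astype(np.float32)

    sections = []
    for i in range(n_sections):
        img_i = specimen_img[i * strip_h : (i + 1) * strip_h]
        cm_i = specimen_cm[i * strip_h : (i + 1) * strip_h]
        nominal = SectionLayout(
            section_index=i,
            anchor=(float(margin), float(margin + i * row_h)),
            rotation_deg=0.0,
            scale=s,
        )
        true = replace(
            nominal,
            anchor=(
                nominal.anchor[0] + float(rng.uniform(-params.layout_jitter_px,
                                                      params.layout_jitter_px)),
                nominal.anchor[1] + float(rng.uniform(-params.layout_jitter_px,
                                                      params.layout_jitter_px)),
            ),
            rotation_deg=float(
                rng.uniform(-params.layout_jitter_deg, params.layout_jitter_deg)
            ),
        )
        # draw the strip into the photo under its true placement
        from .mapping import warp_section

        cov = warp_section(np.ones(cm_i.shape), true, (photo_H, photo_W), order=0) > 0.5
        for c in range(3):
            ch = warp_section(img_i[..., c], true, (photo_H, photo_W), order=1)
            photo[..., c][cov] = ch[cov]
        sections.append(
            Section(image=img_i, class_map=cm_i, layout_true=true,
                    layout_nominal=nominal)
        )

    photo = np.clip(np.rint(photo), 0, 255).astype(np.uint8)

    # ground-truth recovery map: each section's labels through its true layout
    gt = np.zeros((photo_H, photo_W), dtype=np.int16)
    prov = np.full((photo_H, photo_W), -1, dtype=np.int32)
    for sec in sections:
        placed, cov, _ = place_section(sec.class_map, sec.layout_true,
                                       (photo_H, photo_W))
        new = cov & (prov == -1)
        gt[new] = placed[new]
        prov[new] = sec.layout_true.section_index

    return SyntheticCase(
        specimen_photo=photo,
        sections=sections,
        cut_interval_mm=interval_mm,
        gt_class_canvas=gt,
        virtual_specimen=specimen_img,
        virtual_class_map=specimen_cm,
    )


def generate_patches(
    params: SynthParams,
    n_patches: int,
    patch_size: int = 128,
    rng=None,
):
    """Seeded set of (image, class map) training patches.

    Each patch is an independent small slide; lesion radii are drawn from
    ``lesion_radius_range`` (keep them well under ``patch_size``).  Roughly
    one third of patches are lesion-free so the class balance resembles
    tiled real slides.
    """
    rng = rng if rng is not None else np.random.default_rng(params.rng_seed)
    out = []
    for _ in range(n_patches):
        kind = rng.integers(0, 3)
        p = replace(
            params,
            n_cancer_lesions=(1 if kind == 1 else 0),
            n_metaplasia_lesions=(1 if kind == 2 else 0),
        )
        img, cm = generate_slide(p, rng, shape=(patch_size, patch_size))
        out.append((img, cm))
    return out
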