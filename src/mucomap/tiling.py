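"""Slide tiling, blank-tile filtering, stitching, and patch oversampling.

Whole-slide images are far too large for a segmentation network, so they are
split into fixed-size square patches (512 x 512 at ~1 micron/pixel in the
production configuration) on a regular grid, blank glass patches are dropped,
and per-patch predictions are later reassembled into a slide-level map using
each patch's recorded origin.

Coordinate convention: 0-based, (x, y) = (column, row), patch origins at the
top-left corner, half-open pixel intervals.  Slides whose size is not a
multiple of the stride are zero-padded on the right/bottom so every tile is
full-size; the padding is cropped again on stitching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv

logger = logging.getLogger(__name__)

#: tissue pixel = HSV saturation above this (H&E tissue is strongly colored,
#: glass background is near-achromatic white)
DEFAULT_SATURATION_THRESH = 0.07
#: tile is blank if the tissue-pixel fraction falls below this
DEFAULT_TISSUE_FRAC_THRESH = 0.05


@dataclass
class TileRecord:
    """One patch plus its bookkeeping: origin in slide coordinates."""

    pixels: np.ndarray  # (tile, tile[, 3])
    x: int
    y: int
    slide_id: str = ""
    is_blank: bool = False

    @property
    def origin(self) -> tuple[int, int]:
        return (self.x, self.y)


@dataclass
class TileManifest:
    """Ordered tile metadata for one slide (persisted as CSV)."""

    rows: pd.DataFrame  # columns: slide_id, x, y, is_blank, path
    slide_shape: tuple[int, int]  # (H, W)
    tile_size: int
    stride: int

    COLUMNS = ["slide_id", "x", "y", "is_blank", "path"]

    def __len__(self) -> int:
        return len(self.rows)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)
        meta = pd.DataFrame(
            [
                {
                    "height": self.slide_shape[0],
                    "width": self.slide_shape[1],
                    "tile_size": self.tile_size,
                    "stride": self.stride,
                }
            ]
        )
        meta.to_csv(Path(path).with_suffix(".meta.csv"), index=False)

    @classmethod
    def from_csv(cls, path) -> "TileManifest":
        rows = pd.read_csv(path, keep_default_na=False)
        meta = pd.read_csv(Path(path).with_suffix(".meta.csv")).iloc[0]
        return cls(
            rows=rows,
            slide_shape=(int(meta["height"]), int(meta["width"])),
            tile_size=int(meta["tile_size"]),
            stride=int(meta["stride"]),
        )


def grid_origins(height: int, width: int, tile_size: int, stride: int):
    """Row-major tile origins covering the (padded) slide.

    The last tile in each direction starts at the largest multiple of the
    stride that still contains un-tiled pixels, so the grid covers every
    pixel and every tile is full-size after right/bottom zero padding.
    """
    if height < 1 or width < 1:
        raise ValueError("empty image")
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    if not (1 <= stride <= tile_size):
        raise ValueError("stride must satisfy 1 <= stride <= tile_size")

    def starts(n: int) -> list[int]:
        if n <= tile_size:
            return [0]
        last = int(np.ceil((n - tile_size) / stride)) * stride
        return list(range(0, last + 1, stride))

    ys, xs = starts(height), starts(width)
    return [(x, y) for y in ys for x in xs]


def padded_shape(height: int, width: int, tile_size: int, stride: int):
    """(H, W) of the zero-padded canvas the tile grid covers exactly."""
    origins = grid_origins(height, width, tile_size, stride)
    max_x = max(x for x, _ in origins)
    max_y = max(y for _, y in origins)
    return (max_y + tile_size, max_x + tile_size)


def tile_slide(
    slide: np.ndarray,
    tile_size: int,
    stride: int | None = None,
    slide_id: str = "",
    mask: np.ndarray | None = None,
    blank_filter: bool = False,
    saturation_thresh: float = DEFAULT_SATURATION_THRESH,
    tissue_frac_thresh: float = DEFAULT_TISSUE_FRAC_THRESH,
):
    """Split a slide (and optionally its class map) into full-size tiles.

    Parameters
    ----------
    slide : (H, W[, 3]) array
    tile_size : int
    stride : int, default tile_size
        Must satisfy 1 <= stride <= tile_size (a larger stride would skip
        pixels).
    mask : optional class map of the same spatial shape; tiled identically.
    blank_filter : if True, tiles classified blank by :func:`is_blank` are
        flagged (``is_blank=True``) and excluded from the returned tile list
        but kept in the manifest rows.

    Returns
    -------
    (TileManifest, list[TileRecord]) or
    (TileManifest, list[TileRecord], list[mask tiles]) when ``mask`` given.
    """
    slide = np.asarray(slide)
    if stride is None:
        stride = tile_size
    H, W = slide.shape[:2]
    if mask is not None and mask.shape[:2] != (H, W):
        raise ValueError("mask shape does not match slide shape")

    origins = grid_origins(H, W, tile_size, stride)
    pH, pW = padded_shape(H, W, tile_size, stride)

    pad_spec = [(0, pH - H), (0, pW - W)] + [(0, 0)] * (slide.ndim - 2)
    padded = np.pad(slide, pad_spec)
    padded_mask = None
    if mask is not None:
        padded_mask = np.pad(mask, [(0, pH - H), (0, pW - W)])

    records, mask_tiles, rows = [], [], []
    for x, y in origins:
        patch = padded[y : y + tile_size, x : x + tile_size]
        blank = (
            is_blank(patch, saturation_thresh, tissue_frac_thresh)
            if blank_filter
            else False
        )
        rows.append(
            {"slide_id": slide_id, "x": x, "y": y, "is_blank": blank, "path": ""}
        )
        if blank_filter and blank:
            continue
        records.append(
            TileRecord(pixels=patch, x=x, y=y, slide_id=slide_id, is_blank=blank)
        )
        if padded_mask is not None:
            mask_tiles.append(padded_mask[y : y + tile_size, x : x + tile_size])

    manifest = TileManifest(
        rows=pd.DataFrame(rows, columns=TileManifest.COLUMNS),
        slide_shape=(H, W),
        tile_size=tile_size,
        stride=stride,
    )
    if mask is not None:
        return manifest, records, mask_tiles
    return manifest, records


def is_blank(
    tile: np.ndarray,
    saturation_thresh: float = DEFAULT_SATURATION_THRESH,
    tissue_frac_thresh: float = DEFAULT_TISSUE_FRAC_THRESH,
) -> bool:
    """True when a patch contains (almost) no stained tissue.

    Glass background scans as near-white and scanner dropouts as black; both
    are achromatic, i.e. have HSV saturation ~0, while H&E-stained tissue is
    strongly colored.  A tile is blank when the fraction of pixels with
    saturation above ``saturation_thresh`` is below ``tissue_frac_thresh``.
    """
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[-1] != 3:
        raise ValueError("is_blank expects an RGB patch")
    sat = rgb2hsv(tile)[..., 1]
    tissue_frac = float((sat > saturation_thresh).mean())
    return tissue_frac < tissue_frac_thresh


def stitch_classmaps(
    tiles,
    slide_shape: tuple[int, int],
    tile_size: int | None = None,
    stride: int | None = None,
) -> np.ndarray:
    """Reassemble class-map patches into a slide-level class map.

    ``tiles`` is an iterable of ``(patch, (x, y))`` pairs (or TileRecord-like
    objects with ``pixels`` and ``origin``).  Each patch is placed at its
    origin on the padded canvas; the padding is cropped at the end.  With
    stride == tile_size placement is disjoint; with overlapping tiles the
    last writer wins (use :func:`stitch_probmaps` for principled averaging).
    Pixels no tile covers stay class 0 (a warning is logged).
    """
    pairs = [_as_pair(t) for t in tiles]
    if not pairs:
        raise ValueError("no tiles to stitch")
    ts = tile_size or pairs[0][0].shape[0]
    H, W = slide_shape
    pH, pW = padded_shape(H, W, ts, stride or ts)

    canvas = np.zeros((pH, pW), dtype=np.asarray(pairs[0][0]).dtype)
    covered = np.zeros((pH, pW), dtype=bool)
    for patch, (x, y) in pairs:
        patch = np.asarray(patch)
        if x < 0 or y < 0 or y + patch.shape[0] > pH or x + patch.shape[1] > pW:
            raise ValueError(f"tile origin ({x}, {y}) outside padded canvas")
        canvas[y : y + patch.shape[0], x : x + patch.shape[1]] = patch
        covered[y : y + patch.shape[0], x : x + patch.shape[1]] = True
    if not covered[:H, :W].all():
        logger.warning(
            "stitch: %d slide pixels not covered by any tile; left as class 0",
            int((~covered[:H, :W]).sum()),
        )
    return canvas[:H, :W]


def stitch_probmaps(tiles, slide_shape: tuple[int, int]) -> np.ndarray:
    """Average overlapping per-tile probability maps onto the slide canvas.

    ``tiles``: iterable of ``(prob_patch (h, w, C), (x, y))``.  Overlapping
    pixels are resolved by averaging the class probabilities of every tile
    covering the pixel.  Returns an (H, W, C) probability map; uncovered
    pixels get a one-hot class-0 vector.
    """
    pairs = [_as_pair(t) for t in tiles]
    if not pairs:
        raise ValueError("no tiles to stitch")
    first = np.asarray(pairs[0][0])
    C = first.shape[-1]
    ts = first.shape[0]
    H, W = slide_shape
    max_x = max(x for _, (x, y) in pairs)
    max_y = max(y for _, (x, y) in pairs)
    pH, pW = max(H, max_y + ts), max(W, max_x + ts)

    acc = np.zeros((pH, pW, C), dtype=np.float64)
    count = np.zeros((pH, pW), dtype=np.int32)
    for patch, (x, y) in pairs:
        patch = np.asarray(patch)
        if x < 0 or y < 0:
            raise ValueError("negative tile origin")
        acc[y : y + patch.shape[0], x : x + patch.shape[1]] += patch
        count[y : y + patch.shape[0], x : x + patch.shape[1]] += 1
    uncovered = count == 0
    count = np.maximum(count, 1)
    out = acc / count[..., None]
    out[uncovered] = np.eye(C)[0]
    return out[:H, :W]


def probmap_argmax(prob: np.ndarray) -> np.ndarray:
    """Per-pixel argmax; exact ties resolved to the lowest class index."""
    return np.asarray(prob).argmax(axis=-1).astype(np.int8)


def _as_pair(t):
    if isinstance(t, TileRecord):
        return t.pixels, t.origin
    patch, origin = t
    return patch, tuple(int(v) for v in origin)


def class_presence_stratum(mask_tile: np.ndarray) -> str:
    """Stratum key for oversampling: which non-normal classes the tile holds.

    Returns e.g. ``"normal"``, ``"1"``, ``"2"`` or ``"1+2"``.
    """
    present = sorted(int(c) for c in np.unique(mask_tile) if c != 0)
    return "+".join(str(c) for c in present) if present else "normal"


def oversample(
    manifest: pd.DataFrame, rng_seed: int = 0, stratum_col: str = "stratum"
) -> pd.DataFrame:
    """Balance class-presence strata by duplicating minority-stratum tiles.

    Lesion pixels cover a small fraction of a slide, so patches containing
    cancerous or metaplastic tissue are heavily outnumbered by normal-only
    patches.  Each stratum is brought up to the size of the largest stratum
    by sampling rows with replacement (deterministic given ``rng_seed``).
    The input rows are always a sub-multiset of the output.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    if stratum_col not in manifest.columns:
        raise ValueError(f"manifest lacks a '{stratum_col}' column")
    rng = np.random.default_rng(rng_seed)
    counts = manifest[stratum_col].value_counts()
    target = int(counts.max())
    parts = [manifest]
    for stratum in sorted(counts.index.astype(str)):
        n = int(counts[stratum])
        deficit = target - n
        if deficit <= 0:
            continue
        pool = manifest.index[manifest[stratum_col] == stratum].to_numpy()
        extra = rng.choice(pool, size=deficit, replace=True)
        parts.append(manifest.loc[extra])
    return pd.concat(parts, ignore_index=True)
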