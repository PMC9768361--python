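"""RGB annotation masks <-> integer class maps.

Annotated slides carry a paired RGB mask in which cancerous mucosa is drawn
in red, intestinal metaplasia in blue, and normal mucosa in green.  Internally
the pipeline works on integer class maps with the fixed convention

    0 = normal mucosa (NR), 1 = cancerous (CR), 2 = intestinal metaplasia (IR),

so that class 0 is the background/majority class for oversampling logic.
Hand-drawn masks contain anti-aliased edge pixels; decoding assigns each pixel
the nearest scheme color within a tolerance and falls back to class 0 for
pixels that match nothing, keeping a tally of such pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

NUM_CLASSES = 3

CLASS_NORMAL = 0
CLASS_CANCER = 1
CLASS_METAPLASIA = 2


@dataclass(frozen=True)
class ColorScheme:
    """Bijective mapping between class indices and mask RGB colors."""

    colors: dict = field(
        default_factory=lambda: {
            CLASS_NORMAL: (0, 255, 0),
            CLASS_CANCER: (255, 0, 0),
            CLASS_METAPLASIA: (0, 0, 255),
        }
    )

    def __post_init__(self):
        triples = list(self.colors.values())
        if len(set(triples)) != len(triples):
            raise ValueError("color scheme must be a bijection: duplicate colors")
        if set(self.colors) != set(range(len(self.colors))):
            raise ValueError("class indices must be 0..K-1")

    @property
    def num_classes(self) -> int:
        return len(self.colors)

    def as_array(self) -> np.ndarray:
        """(K, 3) uint8 array, row k = color of class k."""
        return np.array(
            [self.colors[k] for k in range(self.num_classes)], dtype=np.uint8
        )


DEFAULT_SCHEME = ColorScheme()


def _check_classmap(cm: np.ndarray, num_classes: int = NUM_CLASSES) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.ndim != 2:
        raise ValueError(f"class map must be 2-D, got shape {cm.shape}")
    if cm.size and (cm.min() < 0 or cm.max() >= num_classes):
        raise ValueError(f"class labels must lie in [0, {num_classes})")
    return cm


def rgb_mask_to_classmap(
    rgb_image: np.ndarray,
    scheme: ColorScheme = DEFAULT_SCHEME,
    tolerance: float = 0.0,
) -> np.ndarray:
    """Decode an RGB annotation mask into an integer class map.

    Each pixel is assigned the class whose scheme color is nearest in
    Euclidean RGB distance, provided that distance is within ``tolerance``;
    otherwise the pixel falls back to class 0 (normal) and is counted in a
    logged tally.  ``tolerance`` is measured on the 0-255 scale.

    Parameters
    ----------
    rgb_image : (H, W, 3) array
    scheme : ColorScheme
    tolerance : float >= 0
        Maximum RGB distance for a match; 0 accepts exact colors only.

    Returns
    -------
    (H, W) int8 class map.
    """
    rgb_image = np.asarray(rgb_image)
    if rgb_image.ndim != 3 or rgb_image.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB mask, got shape {rgb_image.shape}")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")

    palette = scheme.as_array().astype(np.float32)  # (K, 3)
    px = rgb_image.reshape(-1, 3).astype(np.float32)
    # squared distance to each scheme color
    d2 = ((px[:, None, :] - palette[None, :, :]) ** 2).sum(axis=2)  # (N, K)
    nearest = d2.argmin(axis=1)
    within = d2[np.arange(px.shape[0]), nearest] <= float(tolerance) ** 2

    labels = np.where(within, nearest, CLASS_NORMAL).astype(np.int8)
    n_unmatched = int((~within).sum())
    if n_unmatched:
        logger.warning(
            "%d / %d mask pixels matched no scheme color within tolerance %g; "
            "assigned to class 0 (normal)",
            n_unmatched,
            px.shape[0],
            tolerance,
        )
    return labels.reshape(rgb_image.shape[:2])


def classmap_to_rgb(
    cm: np.ndarray, scheme: ColorScheme = DEFAULT_SCHEME
) -> np.ndarray:
    """Render a class map as an RGB mask with exact scheme colors."""
    cm = _check_classmap(cm, scheme.num_classes)
    return scheme.as_array()[cm]


def read_mask(path, scheme: ColorScheme = DEFAULT_SCHEME, tolerance: float = 0.0):
    """Read an 8-bit RGB PNG mask and decode it to a class map."""
    img = np.asarray(Image.open(path).convert("RGB"))
    return rgb_mask_to_classmap(img, scheme, tolerance)


def write_mask(path, cm: np.ndarray, scheme: ColorScheme = DEFAULT_SCHEME) -> None:
    """Write a class map as an 8-bit RGB PNG in scheme colors."""
    Image.fromarray(classmap_to_rgb(cm, scheme)).save(path)


def write_indexed(path, cm: np.ndarray, scheme: ColorScheme = DEFAULT_SCHEME) -> None:
    """Write a class map as a single-channel indexed PNG (palette = scheme)."""
    cm = _check_classmap(cm, scheme.num_classes)
    img = Image.fromarray(cm.astype(np.uint8), mode="P")
    img.putpalette(scheme.as_array().flatten().tolist())
    img.save(path)


def read_indexed(path) -> np.ndarray:
    """Read a single-channel indexed PNG back to a class map."""
    return np.asarray(Image.open(path)).astype(np.int8)
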