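"""Pipeline configuration: one YAML document covering every stage.

The document has one section per stage (``tiling``, ``network``, ``train``,
``synthetic``, ``mapping``) plus global ``seed`` and ``scheme`` entries.
Loading merges user values over the defaults; a loaded config re-serializes
to an equivalent document.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import yaml

from .masks import ColorScheme
from .model import NetworkConfig
from .training import TrainConfig

DEFAULTS: dict = {
    "seed": 0,
    "scheme": {"0": [0, 255, 0], "1": [255, 0, 0], "2": [0, 0, 255]},
    "tiling": {
        "tile_size": 512,
        "stride": 512,
        "blank_filter": True,
        "saturation_thresh": 0.07,
        "tissue_frac_thresh": 0.05,
    },
    "network": NetworkConfig().to_dict(),
    "train": TrainConfig().to_dict(),
    "synthetic": {
        "slide_size": [512, 512],
        "n_cancer_lesions": 2,
        "n_metaplasia_lesions": 2,
        "lesion_radius_range": [30, 80],
        "noise_sd": 6.0,
        "microns_per_pixel": 1.0,
        "photo_scale": 0.25,
        "n_sections": 6,
    },
    "mapping": {
        "refine": True,
        "search_window": 15,
        "rotation_search_deg": 4.0,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


@dataclass
class PipelineConfig:
    data: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @classmethod
    def load(cls, path=None, overrides: dict | None = None) -> "PipelineConfig":
        doc = {}
        if path is not None:
            with open(path) as fh:
                doc = yaml.safe_load(fh) or {}
        merged = _merge(DEFAULTS, doc)
        if overrides:
            merged = _merge(merged, overrides)
        return cls(merged)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=True)

    # typed views -----------------------------------------------------------

    def scheme(self) -> ColorScheme:
        return ColorScheme(
            {int(k): tuple(v) for k, v in self.data["scheme"].items()}
        )

    def network(self) -> NetworkConfig:
        return NetworkConfig.from_dict(self.data["network"])

    def train(self) -> TrainConfig:
        return TrainConfig.from_dict(self.data["train"])

    def __getitem__(self, key):
        return self.data[key]
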