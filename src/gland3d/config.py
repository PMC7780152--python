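"""Pipeline configuration (YAML/JSON).

A config file maps channels to markers, fixes the voxel spacing and all
analysis thresholds so that group comparisons run with identical
settings — thresholds are deliberately *not* re-estimated per sample
when comparing groups.

Example
-------
.. code-block:: yaml

    channels: {Emcn: 0, aSMA: 1, insulin: 2, nuclei: 3}
    spacing_um: [0.82, 0.69, 0.69]
    thresholds:
      vessel: auto          # or a number
      smooth_sigma_um: 1.5
      background_scale_um: 20.0
      noise_max_volume_um3: 500.0
      noise_min_sphericity: 0.8
    arteries:
      min_length_um: 50.0
      min_radius_um: 3.0
      min_elongation: 2.0
    interactome:
      max_distance_um: 18.0
      presence_min_fraction: 0.1
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .grid import DEFAULT_SPACING_UM


@dataclass
class PipelineConfig:
    channels: dict[str, int] = field(default_factory=dict)
    spacing_um: tuple[float, float, float] = DEFAULT_SPACING_UM
    vessel_channel: str = "Emcn"
    artery_channel: str = "aSMA"
    nuclei_channel: str = "nuclei"
    vessel_threshold: float | str = "auto"
    smooth_sigma_um: float = 1.5
    background_scale_um: float = 20.0
    noise_max_volume_um3: float = 500.0
    noise_min_sphericity: float = 0.8
    artery_min_length_um: float = 50.0
    artery_min_radius_um: float = 3.0
    artery_min_elongation: float = 2.0
    interactome_max_distance_um: float = 18.0
    presence_min_fraction: float = 0.1
    diameter_n_regions: int = 7
    diameter_region_size_um: float = 50.0
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        cfg.channels = dict(raw.get("channels", {}))
        if "spacing_um" in raw:
            cfg.spacing_um = tuple(float(s) for s in raw["spacing_um"])  # type: ignore[assignment]
        for key in ("vessel_channel", "artery_channel", "nuclei_channel", "seed"):
            if key in raw:
                setattr(cfg, key, raw[key])
        th = raw.get("thresholds", {})
        if "vessel" in th:
            cfg.vessel_threshold = th["vessel"]
        for key in ("smooth_sigma_um", "background_scale_um",
                    "noise_max_volume_um3", "noise_min_sphericity"):
            if key in th:
                setattr(cfg, key, float(th[key]))
        art = raw.get("arteries", {})
        for key in ("min_length_um", "min_radius_um", "min_elongation"):
            if key in art:
                setattr(cfg, "artery_" + key, float(art[key]))
        inter = raw.get("interactome", {})
        if "max_distance_um" in inter:
            cfg.interactome_max_distance_um = float(inter["max_distance_um"])
        if "presence_min_fraction" in inter:
            cfg.presence_min_fraction = float(inter["presence_min_fraction"])
        diam = raw.get("diameters", {})
        if "n_regions" in diam:
            cfg.diameter_n_regions = int(diam["n_regions"])
        if "region_size_um" in diam:
            cfg.diameter_region_size_um = float(diam["region_size_um"])
        return cfg

    def to_dict(self) -> dict[str, Any]:
        return {
            "channels": dict(self.channels),
            "spacing_um": list(self.spacing_um),
            "vessel_channel": self.vessel_channel,
            "artery_channel": self.artery_channel,
            "nuclei_channel": self.nuclei_channel,
            "thresholds": {
                "vessel": self.vessel_threshold,
                "smooth_sigma_um": self.smooth_sigma_um,
                "background_scale_um": self.background_scale_um,
                "noise_max_volume_um3": self.noise_max_volume_um3,
                "noise_min_sphericity": self.noise_min_sphericity,
            },
            "arteries": {
                "min_length_um": self.artery_min_length_um,
                "min_radius_um": self.artery_min_radius_um,
                "min_elongation": self.artery_min_elongation,
            },
            "interactome": {
                "max_distance_um": self.interactome_max_distance_um,
                "presence_min_fraction": self.presence_min_fraction,
            },
            "diameters": {
                "n_regions": self.diameter_n_regions,
                "region_size_um": self.diameter_region_size_um,
            },
            "seed": self.seed,
        }


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON pipeline config file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return PipelineConfig.from_dict(raw or {})


def save_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
    return path
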