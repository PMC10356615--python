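"""Run configuration.

Defaults follow the published analysis parameters: onion layers of n = 10 px
with k = 100 angular sectors; a 100 px (~39 um at the study's nominal scale)
close-interaction threshold; a 50 px perivascular band; presence of >=5 EVTs
per artery compartment; 100 bootstrap iterations for spatial enrichment;
1e5 randomizations and a 1.5 score cutoff for pathway coordination; 25-cell
neighbourhoods clustered with k-means (k = 20) and merged at centroid
distance 0.5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    onion_layer_px: int = 10
    onion_sectors: int = 100
    positivity_thresholds: dict[str, float] = field(default_factory=dict)
    segment_thresholds: dict[str, float] = field(default_factory=dict)
    sector_thresholds: dict[str, float] = field(default_factory=dict)
    interaction_threshold_px: float = 100.0
    perivascular_band_px: float = 50.0
    evt_presence_min: int = 5
    n_bootstrap: int = 100
    n_randomizations: int = 100_000
    coordination_cutoff: float = 1.5
    neighbourhood_size: int = 25
    kmeans_k: int = 20
    centroid_merge_threshold: float = 0.5
    um_per_px: float = 0.39
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "onion_layer_px", "onion_sectors", "evt_presence_min",
            "n_bootstrap", "n_randomizations", "neighbourhood_size", "kmeans_k",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for d in (
            self.positivity_thresholds,
            self.segment_thresholds,
            self.sector_thresholds,
        ):
            for marker, thr in d.items():
                if thr < 0:
                    raise ValueError(f"threshold for {marker!r} must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
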