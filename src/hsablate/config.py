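"""Run configuration shared by the pipeline stages.

All coordinates used in this package are 0-based ``(x=column, y=row)`` with a
pixel-center convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Pipeline-wide parameters.

    Attributes
    ----------
    patch_width : int
        Spatial width/height ``w`` of the spectral sub-volume fed to the CNNs.
    n_bands : int
        Number of spectral bands ``l`` expected in every hypercube.
    roi_diameter : float
        Diameter in pixels of the circular evaluation ROI centred on the
        ablation spot.
    damage_threshold : float
        Peak temperature (deg C) above which tissue is considered irreversibly
        damaged; used to extract ablation margins from predicted peak maps.
    lr, batch_size, epochs : training hyper-parameters (SGD).
    n_folds : int
        Number of leave-one-ablation-out cross-validation folds.
    specularity_tau : float
        Reflectance level counted as near-saturation by the specularity rule.
    specularity_min_bands : int
        Minimum number of bands >= tau for a pixel to be flagged specular.
    frames_per_average : int
        Number of consecutive IR frames averaged into each step's
        characteristic temperature map.
    """

    patch_width: int = 5
    n_bands: int = 100
    roi_diameter: float = 58.0
    damage_threshold: float = 50.6
    lr: float = 0.001
    batch_size: int = 1
    epochs: int = 5
    n_folds: int = 6
    seed: int = 0
    specularity_tau: float = 0.95
    specularity_min_bands: int = 50
    frames_per_average: int = 5

    def __post_init__(self) -> None:
        if self.patch_width < 1 or self.patch_width % 2 == 0:
            raise ValueError("patch_width must be a positive odd integer")
        if self.n_bands < 1:
            raise ValueError("n_bands must be positive")
        if self.batch_size != 1:
            raise ValueError("training uses strict single-sample SGD (batch_size=1)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
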