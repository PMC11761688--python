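"""Pipeline configuration with defaults traceable to the emulated protocol.

Every default mirrors the analysis settings of the emulated experiment:
50 ms exposure, <30 nm precision filter, 20 nm / 1 off-frame merge, DBSCAN
eps 0.3 (um) with 5 minimum localizations, 5x mean-NN-distance highlight,
fixed 1/7 FRC threshold with 3 replicates, and 25 s / 0.5 s moving
reconstruction windows. Configs load from a YAML mapping; unknown keys are
rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml


@dataclass
class PipelineConfig:
    # acquisition
    exposure: float = 0.05              # s/frame
    # precision filter
    precision_threshold: float = 30.0   # nm, strict upper bound
    # merge / residence
    merge_radius: float = 20.0          # nm
    max_off_frames: int = 1
    # clustering (eps in um; localization nm coordinates are scaled by 1e-3)
    dbscan_eps: float = 0.3
    dbscan_min_pts: int = 5
    # nearest-neighbor analysis
    nn_radius_scale: float = 1.0
    nn_highlight_k: float = 5.0
    # FRC
    frc_threshold: float = 1.0 / 7.0
    frc_n_reps: int = 3
    frc_render_bin: float = 10.0        # nm/px
    # rendering / dynamics
    render_bin: float = 10.0            # nm/px
    window: float = 25.0                # s, moving-window reconstruction
    step: float = 0.5                   # s
    # reproducibility
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")
        if self.precision_threshold <= 0:
            raise ValueError("precision_threshold must be positive")
        if self.merge_radius < 0:
            raise ValueError("merge_radius must be non-negative")
        if self.dbscan_eps <= 0 or self.dbscan_min_pts < 1:
            raise ValueError("invalid DBSCAN parameters")
        if not 0 < self.frc_threshold < 1:
            raise ValueError("frc_threshold must be in (0, 1)")
        if self.step <= 0 or self.window <= 0:
            raise ValueError("window and step must be positive")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Load a YAML config; unknown keys raise, omitted keys keep defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data).validate()


def save_config(config: PipelineConfig, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
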