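"""Localization table container shared across the pipeline stages.

A :class:`LocalizationTable` wraps a :class:`pandas.DataFrame` in the
ThunderSTORM column convention (internal names ``frame, x, y, sigma,
intensity, offset, bkgstd, uncertainty, time``; coordinates in nm, frames
1-based, ``time = (frame - 1) * exposure`` in seconds) together with the
acquisition metadata needed downstream (pixel size, exposure, field of view).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Internal column order; ``time`` is derived and appended on construction.
COLUMNS = ["frame", "x", "y", "sigma", "intensity", "offset", "bkgstd", "uncertainty"]

#: Columns every table must carry.
MANDATORY = ["frame", "x", "y", "uncertainty"]


@dataclass
class LocalizationTable:
    """Ordered localization records plus acquisition metadata.

    Parameters
    ----------
    df:
        One row per localization, sorted by (frame, detection order).
    pixel_size:
        Camera pixel size in nm (0 when the table was produced in direct
        simulation mode and no camera was involved).
    exposure:
        Frame exposure in seconds.
    fov:
        Field of view (width_nm, height_nm).
    """

    df: pd.DataFrame
    pixel_size: float = 0.0
    exposure: float = 0.05
    fov: tuple[float, float] = field(default=(0.0, 0.0))

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY if c not in self.df.columns]
        if missing:
            raise ValueError(f"localization table missing mandatory columns {missing}")
        for c in COLUMNS:
            if c not in self.df.columns:
                self.df[c] = np.nan
        self.df = self.df.reset_index(drop=True)
        self.df["time"] = (self.df["frame"].to_numpy(dtype=float) - 1.0) * self.exposure

    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of coordinates in nm."""
        return self.df[["x", "y"]].to_numpy(dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.df["time"].to_numpy(dtype=float)

    def select(self, mask: np.ndarray) -> "LocalizationTable":
        """Row subset preserving order and metadata."""
        return replace(self, df=self.df.loc[np.asarray(mask)].reset_index(drop=True))

    def copy(self) -> "LocalizationTable":
        return replace(self, df=self.df.copy())
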