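"""File formats: ThunderSTORM-style localization CSV, scene/trace TSV, TIFF.

The localization CSV dialect is comma-separated with dot decimals and the
quoted headers ``"id","frame","x [nm]","y [nm]","sigma [nm]",
"intensity [photon]","offset [photon]","bkgstd [photon]",
"uncertainty [nm]"``; a subset of columns is tolerated on read but
``frame``, ``x [nm]``, ``y [nm]`` and ``uncertainty [nm]`` are mandatory.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import tifffile

from paintkit.sim import BindingEventTrace, GroundTruthScene
from paintkit.table import LocalizationTable

_CSV_COLUMNS = {
    "frame": "frame",
    "x [nm]": "x",
    "y [nm]": "y",
    "sigma [nm]": "sigma",
    "intensity [photon]": "intensity",
    "offset [photon]": "offset",
    "bkgstd [photon]": "bkgstd",
    "uncertainty [nm]": "uncertainty",
}
_MANDATORY_CSV = ["frame", "x [nm]", "y [nm]", "uncertainty [nm]"]

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """A required column is absent from a localization CSV."""


def read_localization_csv(
    path: PathLike,
    pixel_size: float = 0.0,
    exposure: float = 0.05,
    fov: tuple[float, float] | None = None,
) -> LocalizationTable:
    """Parse a ThunderSTORM-dialect CSV into a LocalizationTable.

    Raises :class:`SchemaError` naming the first missing mandatory column,
    and ValueError with the 1-based data row number for non-numeric cells.
    """
    raw = pd.read_csv(path, dtype=str)
    raw.columns = [c.strip().strip('"') for c in raw.columns]
    for col in _MANDATORY_CSV:
        if col not in raw.columns:
            raise SchemaError(f'missing mandatory column "{col}"')
    data = {}
    for csv_name, internal in _CSV_COLUMNS.items():
        if csv_name not in raw.columns:
            continue
        try:
            data[internal] = pd.to_numeric(raw[csv_name], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(raw[csv_name], errors="coerce")
            row = int(np.flatnonzero(bad.isna() & raw[csv_name].notna())[0]) + 1
            raise ValueError(
                f'non-numeric value in column "{csv_name}" at data row {row}'
            ) from None
    df = pd.DataFrame(data)
    if fov is None:
        fov = (float(df["x"].max()) if len(df) else 0.0,
               float(df["y"].max()) if len(df) else 0.0)
    return LocalizationTable(df, pixel_size=pixel_size, exposure=exposure, fov=fov)


def write_localization_csv(table: LocalizationTable, path: PathLike) -> None:
    """Write the full dialect, one row per record, fixed column order."""
    df = table.df
    out = pd.DataFrame(
        {
            "id": np.arange(1, len(df) + 1),
            "frame": df["frame"].astype(int),
            "x [nm]": df["x"],
            "y [nm]": df["y"],
            "sigma [nm]": df["sigma"],
            "intensity [photon]": df["intensity"],
            "offset [photon]": df["offset"],
            "bkgstd [photon]": df["bkgstd"],
            "uncertainty [nm]": df["uncertainty"],
        }
    )
    header = ",".join(f'"{c}"' for c in out.columns)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        out.to_csv(fh, index=False, header=False, float_format="%.4f")


def write_scene_tsv(scene: GroundTruthScene, path: PathLike) -> None:
    """One row per site: x_nm, y_nm, structure_id (tab-separated, header)."""
    pd.DataFrame(
        {"x_nm": scene.sites[:, 0], "y_nm": scene.sites[:, 1],
         "structure_id": scene.structure_ids}
    ).to_csv(path, sep="\t", index=False)


def read_scene_tsv(path: PathLike, fov: tuple[float, float], scene_kind: str = "clutch") -> GroundTruthScene:
    df = pd.read_csv(path, sep="\t")
    return GroundTruthScene(
        df[["x_nm", "y_nm"]].to_numpy(), df["structure_id"].to_numpy(),
        fov, scene_kind=scene_kind,
    )


def write_trace_tsv(trace: BindingEventTrace, path: PathLike) -> None:
    """One row per binding event: site_index, start_s, duration_s."""
    pd.DataFrame(
        {"site_index": trace.site_index, "start_s": trace.start,
         "duration_s": trace.duration}
    ).to_csv(path, sep="\t", index=False)


def read_trace_tsv(path: PathLike, rng_seed: int = 0) -> BindingEventTrace:
    df = pd.read_csv(path, sep="\t")
    return BindingEventTrace(
        df["site_index"].to_numpy(), df["start_s"].to_numpy(),
        df["duration_s"].to_numpy(), rng_seed=rng_seed,
    )


def write_stack_tiff(stack: np.ndarray, path: PathLike) -> None:
    """Multi-page TIFF, 16-bit unsigned, one page per frame."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16))


def read_stack_tiff(path: PathLike) -> np.ndarray:
    return tifffile.imread(path)


def write_image_tiff(image: np.ndarray, path: PathLike) -> None:
    """Float32 TIFF for rendered reconstructions."""
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
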