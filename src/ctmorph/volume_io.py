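"""Reading and writing volumes and cell tables.

Volumes travel as multi-page TIFF stacks (or directories of per-slice
TIFFs) with a JSON sidecar carrying the voxel size and bit depth; cell
tables are CSV with units embedded in the column names.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .core import VolumeImage, bit_depth_range

log = logging.getLogger(__name__)

#: Stable cell-table column order; units live in the header.
CELL_TABLE_COLUMNS = [
    "label_id",
    "volume_um3",
    "equivalent_diameter_um",
    "surface_area_um2",
    "sphericity",
    "anisotropy",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "touches_border",
    "structure_class",
]


def _sidecar_path(path: Path) -> Path:
    if path.is_dir():
        return path / "volume.json"
    return path.with_suffix(".json")


def write_volume(volume: VolumeImage, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF plus a JSON metadata sidecar.

    Returns the TIFF path. Round-trips bit-identically through
    :func:`read_volume`.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.data)
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps(
            {
                "voxel_size_um": volume.voxel_size,
                "bit_depth": volume.bit_depth,
                "shape_zyx": list(volume.data.shape),
            },
            indent=2,
        )
    )
    return path


def read_volume(
    path: str | Path,
    voxel_size: float | None = None,
    bit_depth: int | None = None,
) -> VolumeImage:
    """Read a multi-page TIFF or a directory of single-slice TIFFs.

    The voxel size must come from the JSON sidecar or the ``voxel_size``
    argument; there is no silent default.
    """
    path = Path(path)
    if path.is_dir():
        slice_paths = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff"}
        )
        if not slice_paths:
            raise FileNotFoundError(f"no TIFF slices found in {path}")
        slices = [tifffile.imread(p) for p in slice_paths]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"slices in {path} have mixed shapes: {sorted(shapes)}")
        data = np.stack(slices, axis=0)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]

    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if voxel_size is None:
        voxel_size = meta.get("voxel_size_um")
    if voxel_size is None:
        raise ValueError(
            f"voxel size for {path} not given and no sidecar {sidecar} found"
        )
    if bit_depth is None:
        bit_depth = meta.get("bit_depth", 8 if data.dtype == np.uint8 else 16)
    return VolumeImage(data=data, voxel_size=float(voxel_size), bit_depth=bit_depth)


def write_slices(volume: VolumeImage, directory: str | Path) -> Path:
    """Write a volume as one TIFF per z-slice (``slice_0000.tif`` …)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, plane in enumerate(volume.data):
        tifffile.imwrite(directory / f"slice_{i:04d}.tif", plane)
    _sidecar_path(directory).write_text(
        json.dumps(
            {"voxel_size_um": volume.voxel_size, "bit_depth": volume.bit_depth},
            indent=2,
        )
    )
    return directory


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # round-half-away-from-zero (inputs here are always non-negative)
    return np.floor(x + 0.5)


def rescale_to_8bit(volume: VolumeImage) -> VolumeImage:
    """Linearly map the observed [min, max] onto [0, 255].

    Rounding is half-away-from-zero; the map is monotone. A constant
    volume maps to all zeros with a warning.
    """
    if volume.bit_depth <= 8:
        raise ValueError("volume is already 8-bit or less")
    data = volume.data.astype(np.float64)
    lo, hi = data.min(), data.max()
    if hi == lo:
        warnings.warn("constant volume: rescaled output is all zeros")
        out = np.zeros(volume.data.shape, dtype=np.uint8)
    else:
        out = _round_half_away((data - lo) / (hi - lo) * 255.0).astype(np.uint8)
    return VolumeImage(data=out, voxel_size=volume.voxel_size, bit_depth=8)


def write_cell_table(cells: Sequence, path: str | Path) -> Path:
    """Write cell records to CSV with a stable column order.

    Accepts any iterable of objects exposing the
    :class:`~ctmorph.morphometry.CellRecord` fields.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in cells:
        cz, cy, cx = c.centroid
        rows.append(
            {
                "label_id": c.label_id,
                "volume_um3": c.volume,
                "equivalent_diameter_um": c.equivalent_diameter,
                "surface_area_um2": c.surface_area,
                "sphericity": c.sphericity,
                "anisotropy": c.anisotropy,
                "centroid_z_um": cz,
                "centroid_y_um": cy,
                "centroid_x_um": cx,
                "touches_border": c.touches_border,
                "structure_class": c.structure_class,
            }
        )
    df = pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_cell_table(path: str | Path) -> list:
    """Read a CSV written by :func:`write_cell_table` back into records."""
    from .morphometry import CellRecord

    df = pd.read_csv(Path(path))
    records = []
    for _, r in df.iterrows():
        records.append(
            CellRecord(
                label_id=int(r["label_id"]),
                volume=float(r["volume_um3"]),
                equivalent_diameter=float(r["equivalent_diameter_um"]),
                surface_area=float(r["surface_area_um2"]),
                sphericity=float(r["sphericity"]),
                anisotropy=float(r["anisotropy"]),
                centroid=(
                    float(r["centroid_z_um"]),
                    float(r["centroid_y_um"]),
                    float(r["centroid_x_um"]),
                ),
                touches_border=bool(r["touches_border"]),
                structure_class=str(r["structure_class"]),
            )
        )
    return records


__all__ = [
    "read_volume",
    "write_volume",
    "write_slices",
    "rescale_to_8bit",
    "write_cell_table",
    "read_cell_table",
    "CELL_TABLE_COLUMNS",
]
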