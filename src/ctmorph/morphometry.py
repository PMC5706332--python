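"""Per-label 3D measurements and VOI-level summaries.

Shape descriptors follow the conventions of classical particle analysis:
equivalent spherical diameter ``(6V/pi)^(1/3)``, Wadell sphericity
``pi^(1/3) (6V)^(2/3) / A`` and anisotropy ``1 - lambda_min/lambda_max``
of the second-central-moment tensor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure as skmeasure

from .core import LabelVolume, VolumeImage

#: Minimum representative analysis volume, µm³ (1.3 mm³).
MIN_VOI_VOLUME_UM3 = 1.3e9

#: Gaussian pre-filter applied before iso-surfacing a binary mask. Chosen so
#: that mesh areas of digitized balls land within 3% of 4*pi*r^2 while cubes
#: stay within 5% of 6*s^2 (raw binary marching cubes overstates curved
#: surfaces by ~9%).
SURFACE_SMOOTHING_SIGMA = 0.58


@dataclass
class CellRecord:
    """Morphometry of one labeled object. Lengths µm, areas µm², volumes µm³."""

    label_id: int
    volume: float
    equivalent_diameter: float
    surface_area: float
    sphericity: float
    anisotropy: float
    centroid: tuple[float, float, float]  # (z, y, x) in µm
    touches_border: bool = False
    structure_class: str = "cell"


@dataclass
class AnalysisSummary:
    """VOI-level result row: percentages of the VOI volume plus counts."""

    voi_volume: float  # µm³
    borderkilled_cell_volume_pct: float
    filtered_cell_volume_pct: float
    structures_volume_pct: float
    cell_count: int
    mean_equivalent_diameter: float
    mean_anisotropy: float


@dataclass
class VOISpec:
    """Axis-aligned sub-volume request: voxel origin plus physical edge lengths."""

    origin: tuple[int, int, int]  # (z, y, x) voxels
    edge_lengths: tuple[float, float, float]  # µm

    def shape_voxels(self, voxel_size: float) -> tuple[int, int, int]:
        return tuple(int(round(e / voxel_size)) for e in self.edge_lengths)  # type: ignore[return-value]

    def volume_um3(self) -> float:
        return float(np.prod(self.edge_lengths))


def extract_voi(
    volume: VolumeImage | LabelVolume,
    spec: VOISpec,
    voxel_size: float | None = None,
    enforce_minimum: bool = True,
) -> VolumeImage | LabelVolume:
    """Copy out a half-open axis-aligned sub-grid.

    VOIs below the minimum representative volume (1.3 mm³) or falling
    outside the parent grid are rejected.
    """
    if isinstance(volume, VolumeImage):
        data, vs = volume.data, volume.voxel_size
    else:
        data = np.asarray(volume)
        if voxel_size is None:
            raise ValueError("voxel_size required when extracting from a label array")
        vs = voxel_size
    if enforce_minimum and spec.volume_um3() < MIN_VOI_VOLUME_UM3:
        raise ValueError(
            f"VOI volume {spec.volume_um3():.3g} µm³ is below the minimum "
            f"representative volume of {MIN_VOI_VOLUME_UM3:.3g} µm³"
        )
    shape = spec.shape_voxels(vs)
    sl = []
    for o, n, lim in zip(spec.origin, shape, data.shape):
        if o < 0 or o + n > lim:
            raise ValueError(f"VOI [{o}, {o + n}) exceeds volume extent {lim}")
        sl.append(slice(o, o + n))
    sub = data[tuple(sl)].copy()
    if isinstance(volume, VolumeImage):
        return volume.with_data(sub)
    return sub


def equivalent_diameter(volume_um3: float) -> float:
    """Diameter of the sphere with the given volume: ``(6V/pi)^(1/3)``."""
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    return (6.0 * volume_um3 / math.pi) ** (1.0 / 3.0)


def sphericity(volume_um3: float, area_um2: float) -> float:
    """Wadell sphericity ``pi^(1/3) (6V)^(2/3) / A``; 1 for a sphere."""
    if volume_um3 <= 0 or area_um2 <= 0:
        raise ValueError("volume and area must be positive")
    return math.pi ** (1.0 / 3.0) * (6.0 * volume_um3) ** (2.0 / 3.0) / area_um2


def surface_area(mask: np.ndarray, voxel_size: float) -> float:
    """Area (µm²) of the triangulated 0.5-level iso-surface of a binary mask.

    The mask is padded and lightly Gaussian-filtered before marching
    cubes to suppress voxelization bias.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    padded = np.pad(mask, 2).astype(np.float64)
    if SURFACE_SMOOTHING_SIGMA > 0:
        padded = ndi.gaussian_filter(padded, SURFACE_SMOOTHING_SIGMA)
    # single-voxel / flat objects never cross 0.5 after smoothing; fall back
    # to the raw binary surface
    if padded.max() <= 0.5:
        padded = np.pad(mask, 2).astype(np.float64)
    verts, faces, _, _ = skmeasure.marching_cubes(padded, level=0.5)
    return float(skmeasure.mesh_surface_area(verts, faces)) * voxel_size**2


def anisotropy(mask: np.ndarray, voxel_size: float = 1.0) -> float:
    """``1 - lambda_min / lambda_max`` of the voxel second-central-moment tensor.

    0 for isotropic bodies, approaching 1 for elongated ones. A single
    voxel is 0 by convention. ``voxel_size`` is accepted for interface
    symmetry; the ratio is scale-invariant for isotropic voxels.
    """
    coords = np.argwhere(np.asarray(mask).astype(bool))
    if coords.shape[0] == 0:
        raise ValueError("empty mask")
    if coords.shape[0] == 1:
        return 0.0
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / coords.shape[0]
    eigvals = np.linalg.eigvalsh(cov)
    lam_max = eigvals[-1]
    if lam_max <= 0:
        return 0.0
    return float(1.0 - max(eigvals[0], 0.0) / lam_max)


def _touches_border(slices: tuple[slice, ...], shape: tuple[int, ...]) -> bool:
    return any(s.start == 0 or s.stop == n for s, n in zip(slices, shape))


def measure_labels(
    labels: LabelVolume,
    voxel_size: float,
    structure_class: str = "cell",
    compute_surface: bool = True,
) -> list[CellRecord]:
    """One :class:`CellRecord` per label.

    The sum of record volumes equals the labeled voxel count times the
    voxel volume exactly. ``compute_surface=False`` skips the (costly)
    mesh step and reports NaN surface/sphericity.
    """
    labels = np.asarray(labels)
    if labels.size == 0 or labels.max() == 0:
        return []
    voxvol = float(voxel_size) ** 3
    objects = ndi.find_objects(labels)
    records: list[CellRecord] = []
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        mask = labels[sl] == idx
        n_vox = int(mask.sum())
        vol = n_vox * voxvol
        coords = np.argwhere(mask)
        centroid_vox = coords.mean(axis=0) + np.array([s.start for s in sl])
        if compute_surface:
            area = surface_area(mask, voxel_size)
            sph = min(sphericity(vol, area), 1.0 + 0.05)
        else:
            area = float("nan")
            sph = float("nan")
        records.append(
            CellRecord(
                label_id=idx,
                volume=vol,
                equivalent_diameter=equivalent_diameter(vol),
                surface_area=area,
                sphericity=sph,
                anisotropy=anisotropy(mask) if n_vox > 1 else 0.0,
                centroid=tuple(float(c) * voxel_size for c in centroid_vox),
                touches_border=_touches_border(sl, labels.shape),
                structure_class=structure_class,
            )
        )
    return records


def summarize_voi(
    borderkilled_cells: list[CellRecord],
    filtered_cells: list[CellRecord],
    structures: list[CellRecord],
    voi_volume_um3: float,
) -> AnalysisSummary:
    """Collapse cell records into one VOI summary row.

    Volume percentages are total member volume over the VOI volume;
    count, mean diameter and mean anisotropy are taken over the filtered
    cells.
    """
    if voi_volume_um3 <= 0:
        raise ValueError("VOI volume must be positive")

    def pct(cells: list[CellRecord]) -> float:
        return 100.0 * sum(c.volume for c in cells) / voi_volume_um3

    n = len(filtered_cells)
    return AnalysisSummary(
        voi_volume=voi_volume_um3,
        borderkilled_cell_volume_pct=pct(borderkilled_cells),
        filtered_cell_volume_pct=pct(filtered_cells),
        structures_volume_pct=pct(structures),
        cell_count=n,
        mean_equivalent_diameter=(
            float(np.mean([c.equivalent_diameter for c in filtered_cells])) if n else 0.0
        ),
        mean_anisotropy=(
            float(np.mean([c.anisotropy for c in filtered_cells])) if n else 0.0
        ),
    )


def sem(values: list[float] | np.ndarray) -> float | None:
    """Standard error of the mean across replicate VOIs (ddof=1).

    ``None`` for fewer than two replicates: a single VOI has no
    dispersion estimate.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return None
    return float(values.std(ddof=1) / math.sqrt(values.size))


def percent_increase(control_value: float, enhanced_value: float) -> float:
    """Relative change in percent, reported to 2 decimals."""
    if control_value <= 0:
        raise ValueError("control value must be positive")
    return round((enhanced_value - control_value) / control_value * 100.0, 2)


__all__ = [
    "CellRecord",
    "AnalysisSummary",
    "VOISpec",
    "MIN_VOI_VOLUME_UM3",
    "extract_voi",
    "equivalent_diameter",
    "sphericity",
    "surface_area",
    "anisotropy",
    "measure_labels",
    "summarize_voi",
    "sem",
    "percent_increase",
]
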