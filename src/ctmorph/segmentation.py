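"""Greyscale VOI -> labeled candidate cells.

Stages: histogram multi-thresholding (edge-assisted), despeckle/opening
cleanup, marker-based watershed separation, border kill, size/shape
filtering and edge-constrained recovery of lost cell volume. Every step
is deterministic given its input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters as skfilters
from skimage import measure as skmeasure
from skimage import morphology as skmorph
from skimage import segmentation as skseg

from .core import LabelVolume, VolumeImage
from .morphometry import CellRecord, anisotropy, equivalent_diameter, measure_labels

log = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_CONN6 = ndi.generate_binary_structure(3, 1)


@dataclass
class ClassVolume:
    """Per-voxel intensity classes: 0 = air, 1 = cell, 2 = contrast/bright."""

    data: np.ndarray
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.thresholds) + 1


@dataclass
class FilterSpec:
    """Equivalent-diameter window and sphericity cutoff for the debris filter."""

    d_min: float | None = None  # µm
    d_max: float | None = None  # µm
    sphericity_min: float | None = None

    def __post_init__(self) -> None:
        if self.d_min is not None and self.d_max is not None and not (
            0 < self.d_min < self.d_max
        ):
            raise ValueError("need 0 < d_min < d_max")
        if self.sphericity_min is not None and not 0 <= self.sphericity_min <= 1:
            raise ValueError("sphericity_min must be in [0, 1]")


def classify_intensities(volume: VolumeImage, class_count: int = 3) -> ClassVolume:
    """Threshold the 256-bin histogram into ``class_count`` intensity classes.

    Cut points minimize the within-class intensity variance (multi-Otsu,
    exhaustive over the histogram).
    """
    if class_count not in (2, 3, 4):
        raise ValueError("class_count must be 2, 3 or 4")
    data = volume.data
    if data.min() == data.max():
        raise ValueError("constant volume has no histogram structure")
    try:
        thresholds = skfilters.threshold_multiotsu(
            data, classes=class_count, nbins=256
        )
    except ValueError as exc:  # fewer distinct grey levels than classes
        raise ValueError(f"degenerate histogram: {exc}") from exc
    # skimage convention: a class is strictly above its lower threshold
    class_map = np.digitize(data, bins=thresholds, right=True).astype(np.uint8)
    return ClassVolume(data=class_map, thresholds=tuple(float(t) for t in thresholds))


def sobel_edge_magnitude(volume: VolumeImage | np.ndarray) -> np.ndarray:
    """Gradient magnitude from the three separable 3x3x3 Sobel kernels."""
    data = volume.data if isinstance(volume, VolumeImage) else np.asarray(volume)
    if min(data.shape) < 3:
        raise ValueError("volume must be at least 3 voxels per axis")
    data = data.astype(np.float64)
    sq = np.zeros_like(data)
    for axis in range(3):
        g = ndi.sobel(data, axis=axis, mode="nearest")
        sq += g * g
    return np.sqrt(sq)


def morphological_clean(
    binary: np.ndarray, min_component_voxels: int = 27, opening_radius: int = 1
) -> np.ndarray:
    """Despeckle (26-connectivity) then open with a ball structuring element."""
    if min_component_voxels < 0 or opening_radius < 0:
        raise ValueError("sizes must be non-negative")
    out = np.asarray(binary).astype(bool)
    if min_component_voxels > 1:
        # keep components with >= min_component_voxels voxels (26-connectivity)
        out = skmorph.remove_small_objects(
            out, max_size=min_component_voxels - 1, connectivity=3
        )
    if opening_radius > 0:
        out = ndi.binary_opening(out, structure=skmorph.ball(opening_radius))
    return out


def watershed_separate(
    binary: np.ndarray,
    edge_map: np.ndarray | None = None,
    h: float = 2.0,
    edge_weight: float = 1.0,
) -> LabelVolume:
    """Split a merged foreground mask into labels by marker-based watershed.

    Markers are the maxima of the interior Euclidean distance transform
    after depth-``h`` suppression of shallow maxima. When an edge map is
    supplied it is rescaled to the distance-transform range and added to
    the inverted-distance landscape, so watershed lines prefer bright
    boundaries.
    """
    binary = np.asarray(binary).astype(bool)
    if not binary.any():
        return np.zeros(binary.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(binary)
    if h > 0:
        suppressed = skmorph.reconstruction(
            np.clip(dist - h, 0, None), dist, method="dilation"
        )
    else:
        suppressed = dist
    maxima = skmorph.local_maxima(suppressed, connectivity=3) & binary
    markers, n_markers = ndi.label(maxima, structure=_CONN26)
    if n_markers == 0:  # flat plateau edge case: a single marker suffices
        markers = binary.astype(np.int32)
        n_markers = 1
    landscape = -dist
    if edge_map is not None:
        edge_map = np.asarray(edge_map, dtype=np.float64)
        if edge_map.shape != binary.shape:
            raise ValueError("edge_map shape mismatch")
        emax = edge_map.max()
        if emax > 0:
            landscape = landscape + edge_weight * (edge_map / emax) * dist.max()
    labels = skseg.watershed(landscape, markers=markers, mask=binary)
    return labels.astype(np.int32)


def border_kill(labels: LabelVolume) -> LabelVolume:
    """Delete every label owning at least one voxel on a VOI face."""
    labels = np.asarray(labels)
    out = skseg.clear_border(labels)
    return out.astype(labels.dtype)


def apply_filters(cells: list[CellRecord], spec: FilterSpec) -> list[CellRecord]:
    """Debris filter: keep cells inside the diameter window and above the
    sphericity cutoff (strict). Idempotent; output is a subset of input."""
    kept = []
    for c in cells:
        if spec.d_min is not None and c.equivalent_diameter < spec.d_min:
            continue
        if spec.d_max is not None and c.equivalent_diameter > spec.d_max:
            continue
        if spec.sphericity_min is not None and not (
            c.sphericity > spec.sphericity_min
        ):
            continue
        kept.append(c)
    return kept


def keep_labels(labels: LabelVolume, ids: set[int] | list[int]) -> LabelVolume:
    """Zero out all labels not in ``ids`` (helper for filter application)."""
    labels = np.asarray(labels)
    keep = np.zeros(int(labels.max()) + 1, dtype=bool)
    for i in ids:
        keep[i] = True
    return np.where(keep[labels], labels, 0).astype(labels.dtype)


def recover_volume(
    labels: LabelVolume,
    cell_mask: np.ndarray,
    edge_map: np.ndarray,
    max_iterations: int = 10,
    ridge_percentile: float = 75.0,
) -> LabelVolume:
    """Grow labels back toward their true boundaries.

    One-voxel geodesic dilation steps (face adjacency) restricted to
    ``cell_mask``, blocked at voxels whose Sobel magnitude exceeds the
    ridge threshold (a percentile of the nonzero edge magnitudes) and at
    voxels contested by another label (ties go to the smaller label id).
    Labels never merge; growth is monotone.
    """
    labels = np.asarray(labels).astype(np.int32)
    if max_iterations <= 0 or labels.max() == 0:
        return labels.copy()
    cell_mask = np.asarray(cell_mask).astype(bool)
    edge_map = np.asarray(edge_map, dtype=np.float64)
    nonzero = edge_map[edge_map > 0]
    ridge = np.percentile(nonzero, ridge_percentile) if nonzero.size else np.inf
    allowed = cell_mask & (edge_map <= ridge)

    out = labels.copy()
    big = np.iinfo(np.int32).max
    for _ in range(max_iterations):
        fg = out > 0
        frontier = ndi.binary_dilation(fg, structure=_CONN6) & allowed & ~fg
        if not frontier.any():
            break
        # smallest nonzero neighbouring label wins contested voxels
        inverted = np.where(fg, out, big)
        neigh_min = ndi.minimum_filter(inverted, footprint=_CONN6)
        claim = frontier & (neigh_min < big)
        if not claim.any():
            break
        out[claim] = neigh_min[claim]
    return out


@dataclass
class DenseStructure:
    """A recovered vasculature or stone-cell component."""

    structure_id: int
    structure_class: str  # "vasculature" | "brachysclereid"
    volume: float  # µm³
    anisotropy: float
    max_extent: float  # µm, bounding-box diagonal


def extract_dense_structures(
    classes: ClassVolume,
    labels: LabelVolume,
    voxel_size: float,
    opening_radius: int = 2,
    min_volume_um3: float = 6.5e4,
    vasculature_anisotropy: float = 0.9,
    vasculature_extent_um: float = 500.0,
) -> tuple[LabelVolume, list[DenseStructure]]:
    """Group bright-class voxels outside accepted cells into structures.

    Thin contrast boundaries are removed by a ball opening before the
    component analysis, leaving only thick bright bodies. Elongated
    components (anisotropy and maximal extent above the vasculature
    cutoffs) are classed ``vasculature``; the rest above the minimum size
    are ``brachysclereid`` clusters. Control scans (no bright class)
    return an empty result with a warning.
    """
    if classes.n_classes < 3:
        warnings.warn("no bright intensity class: structures not separable")
        return np.zeros(classes.data.shape, dtype=np.int32), []
    bright = classes.data == classes.n_classes - 1
    bright &= np.asarray(labels) == 0
    if opening_radius > 0:
        bright = ndi.binary_opening(bright, structure=skmorph.ball(opening_radius))
    comps, n = ndi.label(bright, structure=_CONN26)
    out = np.zeros(classes.data.shape, dtype=np.int32)
    records: list[DenseStructure] = []
    voxvol = voxel_size**3
    next_id = 1
    for idx, sl in enumerate(ndi.find_objects(comps), start=1):
        if sl is None:
            continue
        mask = comps[sl] == idx
        vol = float(mask.sum()) * voxvol
        if vol < min_volume_um3:
            continue
        extent = float(
            np.sqrt(sum((s.stop - s.start) ** 2 for s in sl)) * voxel_size
        )
        aniso = anisotropy(mask)
        if aniso > vasculature_anisotropy and extent > vasculature_extent_um:
            cls = "vasculature"
        else:
            cls = "brachysclereid"
        out[sl][mask] = next_id
        records.append(
            DenseStructure(
                structure_id=next_id,
                structure_class=cls,
                volume=vol,
                anisotropy=aniso,
                max_extent=extent,
            )
        )
        next_id += 1
    return out, records


@dataclass
class SegmentationParams:
    """Tunable knobs for the composed segmentation pipeline."""

    class_count_enhanced: int = 3
    class_count_control: int = 2
    despeckle_voxels: int = 27
    opening_radius: int = 1
    watershed_h: float = 2.0
    edge_weight: float = 1.0
    recover_iterations: int = 10
    ridge_percentile: float = 75.0


@dataclass
class SegmentationResult:
    labels: LabelVolume  # accepted, recovered cells
    borderkilled_labels: LabelVolume  # before debris filtering
    classes: ClassVolume
    edge_map: np.ndarray
    cells: list[CellRecord]  # measured after recovery
    borderkilled_cells: list[CellRecord]
    structures_labels: LabelVolume
    structures: list[DenseStructure]
    stage_log: list[dict]


def segment_cells(
    volume: VolumeImage,
    mode: str = "enhanced",
    filter_spec: FilterSpec | None = None,
    params: SegmentationParams | None = None,
    recover_before_filter: bool = False,
) -> SegmentationResult:
    """Run the full stage chain on one greyscale VOI.

    classify -> clean -> watershed -> border kill -> measure -> filter ->
    recover -> re-measure -> dense structures. ``mode`` selects the class
    count (control scans have no bright class).
    """
    if mode not in ("control", "enhanced"):
        raise ValueError("mode must be 'control' or 'enhanced'")
    params = params or SegmentationParams()
    filter_spec = filter_spec or FilterSpec()
    stage_log: list[dict] = []

    def log_stage(stage: str, **info) -> None:
        stage_log.append({"stage": stage, **info})
        log.info("%s: %s", stage, info)

    n_classes = (
        params.class_count_enhanced if mode == "enhanced" else params.class_count_control
    )
    classes = classify_intensities(volume, n_classes)
    cell_mask = classes.data == 1
    log_stage("classify", thresholds=classes.thresholds, cell_voxels=int(cell_mask.sum()))

    edge_map = sobel_edge_magnitude(volume)

    cleaned = morphological_clean(
        cell_mask, params.despeckle_voxels, params.opening_radius
    )
    log_stage("clean", cell_voxels=int(cleaned.sum()))

    labels = watershed_separate(
        cleaned,
        edge_map=edge_map if mode == "enhanced" else None,
        h=params.watershed_h,
        edge_weight=params.edge_weight,
    )
    log_stage("watershed", objects=int(labels.max()))

    labels = border_kill(labels)
    n_after_bk = len(np.unique(labels)) - 1
    log_stage("border_kill", objects=n_after_bk)

    borderkilled_labels = labels
    borderkilled_cells = measure_labels(labels, volume.voxel_size)

    def recover(lab: LabelVolume) -> LabelVolume:
        return recover_volume(
            lab,
            cell_mask=cell_mask,
            edge_map=edge_map,
            max_iterations=params.recover_iterations,
            ridge_percentile=params.ridge_percentile,
        )

    if recover_before_filter:
        labels = recover(labels)
        cells = measure_labels(labels, volume.voxel_size)
        kept = apply_filters(cells, filter_spec)
        labels = keep_labels(labels, {c.label_id for c in kept})
        cells = kept
    else:
        kept = apply_filters(borderkilled_cells, filter_spec)
        labels = keep_labels(labels, {c.label_id for c in kept})
        labels = recover(labels)
        cells = measure_labels(labels, volume.voxel_size)
    log_stage("filter_recover", objects=len(cells))

    structures_labels, structures = extract_dense_structures(
        classes, labels, volume.voxel_size
    )
    log_stage("dense_structures", structures=len(structures))

    return SegmentationResult(
        labels=labels,
        borderkilled_labels=borderkilled_labels,
        classes=classes,
        edge_map=edge_map,
        cells=cells,
        borderkilled_cells=borderkilled_cells,
        structures_labels=structures_labels,
        structures=structures,
        stage_log=stage_log,
    )


__all__ = [
    "ClassVolume",
    "FilterSpec",
    "SegmentationParams",
    "SegmentationResult",
    "DenseStructure",
    "classify_intensities",
    "sobel_edge_magnitude",
    "morphological_clean",
    "watershed_separate",
    "border_kill",
    "apply_filters",
    "keep_labels",
    "recover_volume",
    "extract_dense_structures",
    "segment_cells",
]
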