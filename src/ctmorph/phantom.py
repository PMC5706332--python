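"""Synthetic tissue phantoms with voxel-exact ground truth.

A phantom is a Voronoi-like tessellation of Poisson-disc seed points
(parenchyma-style cells), with intercellular air channels carved along a
random subset of cell-cell interfaces until a target porosity is hit.
In ``contrast_mode`` every cell-cell interface is additionally painted as
a thin bright boundary and most airspace is flooded bright, mimicking a
contrast-perfused scan; control mode leaves cells touching at identical
grey, which is what makes un-enhanced scans hard to segment.

All randomness flows from ``PhantomSpec.random_seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import LabelVolume, VolumeImage

#: Tissue porosity presets (air volume fraction).
PRESET_POROSITY = {"apple": 0.20, "pear": 0.10, "tomato": 0.05}


class PorosityError(RuntimeError):
    """Target porosity unreachable for the realized geometry."""

    def __init__(self, target: float, achieved: float):
        super().__init__(
            f"target porosity {target:.3f} unreachable; best achieved {achieved:.3f}"
        )
        self.target = target
        self.achieved = achieved


class InclusionError(ValueError):
    """A requested inclusion does not fit inside the volume."""


@dataclass
class IntensityLevels:
    """Grey levels (0-255) for each tissue class.

    Defaults keep the ordering bright contrast > cell > air seen in
    contrast-enhanced scans.
    """

    air: int = 5
    cell: int = 120
    contrast_boundary: int = 230
    flooded_airspace: int = 200
    vasculature: int = 240
    stone_cell: int = 210

    def validate(self, contrast_mode: bool) -> None:
        for name, v in dataclasses.asdict(self).items():
            if not 0 <= v <= 255:
                raise ValueError(f"intensity level {name}={v} outside [0, 255]")
        if contrast_mode and not (self.contrast_boundary > self.cell > self.air):
            raise ValueError(
                "contrast_mode requires contrast_boundary > cell > air grey levels"
            )


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic tissue volume."""

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 2.5  # µm
    target_porosity: float = 0.10
    mean_cell_diameter: float = 60.0  # µm
    wall_thickness: int = 2  # voxels
    intensity_levels: IntensityLevels = field(default_factory=IntensityLevels)
    noise_sd: float = 0.0  # grey levels
    contrast_mode: bool = False
    flooded_fraction: float = 0.8  # fraction of air voxels flooded in contrast mode
    include_vasculature: bool = False
    include_stone_cells: bool = False
    random_seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 32:
            raise ValueError("shape must be 3 axes of >= 32 voxels each")
        if not 0 <= self.target_porosity < 0.5:
            raise ValueError("target_porosity must be in [0, 0.5)")
        if self.wall_thickness < 1:
            raise ValueError("wall_thickness must be >= 1 voxel")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.mean_cell_diameter / self.voxel_size < 4:
            raise ValueError("mean_cell_diameter below 4 voxels is degenerate")
        if not 0 <= self.flooded_fraction <= 1:
            raise ValueError("flooded_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        self.intensity_levels.validate(self.contrast_mode)


@dataclass
class PhantomOutput:
    """Greyscale phantom plus its voxel-exact ground truth."""

    greyscale: VolumeImage
    truth_labels: LabelVolume  # cells; 0 = not-a-cell
    truth_air: np.ndarray  # boolean airspace mask
    truth_flooded: np.ndarray  # air voxels flooded bright by contrast
    truth_structures: LabelVolume  # vasculature / stone-cell inclusions
    structure_classes: dict[int, str]
    spec: PhantomSpec
    achieved_porosity: float


def _poisson_disc_points(
    shape: tuple[int, int, int], min_sep: float, rng: np.random.Generator
) -> np.ndarray:
    """Dart-throwing Poisson-disc sampling over the full grid extent."""
    vol = float(np.prod(shape))
    est = max(int(vol / min_sep**3), 8)
    max_attempts = 40 * est
    pts: list[np.ndarray] = []
    arr = np.empty((0, 3))
    min_sep2 = min_sep * min_sep
    failures = 0
    for _ in range(max_attempts):
        cand = rng.uniform(0, 1, 3) * np.array(shape)
        if arr.shape[0] and (((arr - cand) ** 2).sum(axis=1) < min_sep2).any():
            failures += 1
            if failures > 500:
                break
            continue
        failures = 0
        pts.append(cand)
        arr = np.asarray(pts)
    return arr


def _group_indices(keys: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Group flat voxel indices by pair key; returns unique keys + index lists."""
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    uniq, starts = np.unique(sorted_keys, return_index=True)
    splits = np.split(order, starts[1:])
    return uniq, splits


def generate_tissue(spec: PhantomSpec) -> PhantomOutput:
    """Generate one phantom volume from a validated spec.

    Deterministic: identical specs (including seed) give bit-identical
    output. Raises :class:`PorosityError` if the interface-channel model
    cannot carve enough air for ``target_porosity``.
    """
    spec.validate()
    seq = np.random.SeedSequence(spec.random_seed)
    rng_pts, rng_air, rng_flood, rng_incl, rng_noise = (
        np.random.default_rng(s) for s in seq.spawn(5)
    )

    shape = tuple(spec.shape)
    n_vox = int(np.prod(shape))
    min_sep = 0.7 * spec.mean_cell_diameter / spec.voxel_size
    seeds = _poisson_disc_points(shape, min_sep, rng_pts)
    if seeds.shape[0] < 2:
        raise ValueError("degenerate spec: fewer than 2 seed points realized")

    # nearest- and second-nearest-seed fields drive both the tessellation and
    # the interface geometry
    grid = np.indices(shape).reshape(3, -1).T.astype(np.float64) + 0.5
    dist, idx = cKDTree(seeds).query(grid, k=2)
    owner = idx[:, 0].astype(np.int32)
    dd = (dist[:, 1] - dist[:, 0]).astype(np.float32)  # 0 on the bisector
    pair_key = np.where(
        idx[:, 0] < idx[:, 1],
        idx[:, 0].astype(np.int64) * seeds.shape[0] + idx[:, 1],
        idx[:, 1].astype(np.int64) * seeds.shape[0] + idx[:, 0],
    )
    del dist, idx, grid

    # --- carve airspace along randomly chosen cell-cell interfaces ---
    air = np.zeros(n_vox, dtype=bool)
    target_air = int(round(spec.target_porosity * n_vox))
    tol = int(0.01 * n_vox)
    achieved = 0
    if target_air > 0:
        for width in (2.0, 3.0, 4.0, 6.0, 8.0):
            cand = (dd <= width) & ~air
            uniq, groups = _group_indices(pair_key[np.flatnonzero(cand)])
            flat = np.flatnonzero(cand)
            order = rng_air.permutation(len(uniq))
            for gi in order:
                need = target_air - achieved
                if need <= 0:
                    break
                vox = flat[groups[gi]]
                if vox.size > need:
                    # partial interface: fill from the bisector outward so the
                    # carved piece stays channel-shaped
                    vox = vox[np.argsort(dd[vox], kind="stable")[:need]]
                air[vox] = True
                achieved += vox.size
            if achieved >= target_air:
                break
        if abs(achieved - target_air) > tol:
            raise PorosityError(spec.target_porosity, achieved / n_vox)

    # --- paint greyscale and assemble truth ---
    levels = spec.intensity_levels
    grey = np.full(n_vox, levels.cell, dtype=np.uint8)
    labels = (owner + 1).astype(np.int32)
    grey[air] = levels.air
    labels[air] = 0

    flooded = np.zeros(n_vox, dtype=bool)
    if spec.contrast_mode:
        wall = (dd <= spec.wall_thickness) & ~air
        grey[wall] = levels.contrast_boundary
        labels[wall] = 0  # boundaries are intercellular, not cell interior
        air_idx = np.flatnonzero(air)
        n_flood = int(round(spec.flooded_fraction * air_idx.size))
        flooded[rng_flood.choice(air_idx, size=n_flood, replace=False)] = True
        grey[flooded] = levels.flooded_airspace

    grey = grey.reshape(shape)
    labels = labels.reshape(shape)
    air = air.reshape(shape)
    flooded = flooded.reshape(shape)

    out = PhantomOutput(
        greyscale=VolumeImage(grey, voxel_size=spec.voxel_size, bit_depth=8),
        truth_labels=labels,
        truth_air=air,
        truth_flooded=flooded,
        truth_structures=np.zeros(shape, dtype=np.int32),
        structure_classes={},
        spec=spec,
        achieved_porosity=achieved / n_vox,
    )

    if spec.include_vasculature or spec.include_stone_cells:
        out = add_inclusions(
            out,
            vessel_radius=25.0 if spec.include_vasculature else None,
            cluster_diameter=150.0 if spec.include_stone_cells else None,
            n_clusters=3,
            rng=rng_incl,
        )

    if spec.noise_sd > 0:
        noisy = add_imaging_noise(
            out.greyscale, spec.noise_sd, seed=int(rng_noise.integers(2**31))
        )
        out = dataclasses.replace(out, greyscale=noisy)
    return out


def add_imaging_noise(
    volume: VolumeImage, noise_sd: float, seed: int
) -> VolumeImage:
    """Additive zero-mean Gaussian noise, clipped to the intensity range."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return volume.with_data(volume.data.copy())
    rng = np.random.default_rng(seed)
    hi = 255 if volume.bit_depth == 8 else (1 << volume.bit_depth) - 1
    noisy = volume.data.astype(np.float64) + rng.normal(
        0.0, noise_sd, volume.data.shape
    )
    noisy = np.clip(np.rint(noisy), 0, hi)
    return volume.with_data(noisy.astype(volume.data.dtype))


def add_inclusions(
    output: PhantomOutput,
    vessel_radius: float | None = 25.0,
    cluster_diameter: float | None = 150.0,
    n_clusters: int = 3,
    rng: np.random.Generator | None = None,
) -> PhantomOutput:
    """Paint a vasculature tube and/or dense stone-cell clusters.

    The tube traverses the volume along z; clusters are compact balls.
    Both replace whatever tissue they intersect and are recorded in
    ``truth_structures`` with their class names. Requires contrast mode
    (the structures are only separable in enhanced scans).
    """
    spec = output.spec
    if not spec.contrast_mode:
        raise ValueError("inclusions require contrast_mode")
    if rng is None:
        rng = np.random.default_rng(spec.random_seed + 7919)
    shape = output.greyscale.shape
    vs = spec.voxel_size
    levels = spec.intensity_levels

    grey = output.greyscale.data.copy()
    labels = output.truth_labels.copy()
    air = output.truth_air.copy()
    flooded = output.truth_flooded.copy()
    structures = output.truth_structures.copy()
    classes = dict(output.structure_classes)
    next_id = int(structures.max()) + 1

    zz, yy, xx = np.indices(shape)

    placed_centers: list[tuple[float, float, float]] = []  # (y, x, r_vox)

    if vessel_radius is not None:
        r = vessel_radius / vs
        if 2 * r + 2 >= min(shape[1], shape[2]):
            raise InclusionError("vessel does not fit inside the volume cross-section")
        cy = rng.uniform(r + 1, shape[1] - r - 1)
        cx = rng.uniform(r + 1, shape[2] - r - 1)
        tube = ((yy - cy) ** 2 + (xx - cx) ** 2) <= r * r
        grey[tube] = levels.vasculature
        labels[tube] = 0
        air[tube] = False
        flooded[tube] = False
        structures[tube] = next_id
        classes[next_id] = "vasculature"
        placed_centers.append((cy, cx, r))
        next_id += 1

    if cluster_diameter is not None and n_clusters > 0:
        rc = cluster_diameter / 2.0 / vs
        if any(2 * rc + 2 >= s for s in shape):
            raise InclusionError("cluster does not fit inside the volume")
        placed_balls: list[np.ndarray] = []
        for _ in range(n_clusters):
            for _attempt in range(200):
                c = rng.uniform(rc + 1, np.array(shape) - rc - 1)
                clear_of_tube = all(
                    np.hypot(c[1] - cy, c[2] - cx) > r0 + rc + 2
                    for cy, cx, r0 in placed_centers
                )
                clear_of_balls = all(
                    np.linalg.norm(c - b) > 2 * rc + 2 for b in placed_balls
                )
                if clear_of_tube and clear_of_balls:
                    break
            else:
                raise InclusionError("could not place all stone-cell clusters")
            ball = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= rc * rc
            grey[ball] = levels.stone_cell
            labels[ball] = 0
            air[ball] = False
            flooded[ball] = False
            structures[ball] = next_id
            classes[next_id] = "brachysclereid"
            placed_balls.append(c)
            next_id += 1

    return dataclasses.replace(
        output,
        greyscale=output.greyscale.with_data(grey),
        truth_labels=labels,
        truth_air=air,
        truth_flooded=flooded,
        truth_structures=structures,
        structure_classes=classes,
    )


def truth_class_map(output: PhantomOutput) -> np.ndarray:
    """Intensity-semantics class map of the noiseless phantom.

    0 = dark air, 1 = cell, 2 = bright (boundaries, flooded airspace and
    inclusions). Used to score intensity classification against truth.
    """
    # built from the truth masks, so valid for noisy greyscales too
    classes = np.ones(output.greyscale.shape, dtype=np.uint8)
    classes[output.truth_air] = 0
    if output.spec.contrast_mode:
        bright = (output.truth_labels == 0) & ~output.truth_air
        classes[bright] = 2
        classes[output.truth_flooded] = 2
    return classes


__all__ = [
    "PhantomSpec",
    "PhantomOutput",
    "IntensityLevels",
    "PRESET_POROSITY",
    "PorosityError",
    "InclusionError",
    "generate_tissue",
    "add_imaging_noise",
    "add_inclusions",
    "truth_class_map",
]
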