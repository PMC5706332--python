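from collections import deque

import numpy as np
import pytest

from ctmorph.core import VolumeImage
from ctmorph.morphometry import CellRecord
from ctmorph.phantom import truth_class_map
from ctmorph.segmentation import (
    FilterSpec,
    apply_filters,
    border_kill,
    classify_intensities,
    extract_dense_structures,
    morphological_clean,
    recover_volume,
    segment_cells,
    sobel_edge_magnitude,
    watershed_separate,
)

# ---------------------------------------------------------------- oracles


def brute_force_sobel(data: np.ndarray) -> np.ndarray:
    """Direct convolution with the hand-written 3x3x3 Sobel kernels.

    Valid only for interior voxels (no boundary handling); returns NaN on
    the 1-voxel border.
    """
    deriv = np.array([1.0, 0.0, -1.0])  # correlation form of the derivative
    smooth = np.array([1.0, 2.0, 1.0])
    out = np.full(data.shape, np.nan)
    interior = [range(1, n - 1) for n in data.shape]
    for z in interior[0]:
        for y in interior[1]:
            for x in interior[2]:
                patch = data[z - 1:z + 2, y - 1:y + 2, x - 1:x + 2].astype(float)
                sq = 0.0
                for axis in range(3):
                    parts = [smooth, smooth, smooth]
                    parts[axis] = deriv
                    k = (
                        parts[0][:, None, None]
                        * parts[1][None, :, None]
                        * parts[2][None, None, :]
                    )
                    g = (patch * k).sum()
                    sq += g * g
                out[z, y, x] = np.sqrt(sq)
    return out


def flood_fill_components(mask: np.ndarray) -> list[set]:
    """Independent BFS connected components, 26-connectivity."""
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            v = q.popleft()
            comp.add(v)
            for dz, dy, dx in offsets:
                w = (v[0] + dz, v[1] + dy, v[2] + dx)
                if all(0 <= w[i] < mask.shape[i] for i in range(3)):
                    if mask[w] and not seen[w]:
                        seen[w] = True
                        q.append(w)
        comps.append(comp)
    return comps


def face_scan_border_labels(labels: np.ndarray) -> set:
    """Labels owning voxels on any of the 6 VOI faces, by explicit scan."""
    found = set()
    for axis in range(3):
        for face in (0, labels.shape[axis] - 1):
            sl = [slice(None)] * 3
            sl[axis] = face
            found.update(np.unique(labels[tuple(sl)]).tolist())
    found.discard(0)
    return found


def ball(radius, center, shape):
    z, y, x = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        (z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2
    ) <= radius**2


# ---------------------------------------------------------- classification


class TestClassifyIntensities:
    def test_separated_bimodal(self, rng):
        data = np.where(rng.random((32, 32, 32)) < 0.5, 10, 200).astype(np.uint8)
        cv = classify_intensities(VolumeImage(data, 2.5), class_count=2)
        assert 10 <= cv.thresholds[0] < 200
        assert ((cv.data == 1) == (data == 200)).all()

    def test_phantom_misclassification_under_2pct(self, enhanced_phantom_128):
        cv = classify_intensities(enhanced_phantom_128.greyscale, class_count=3)
        truth = truth_class_map(enhanced_phantom_128)
        assert (cv.data != truth).mean() < 0.02

    def test_constant_volume_rejected(self):
        vol = VolumeImage(np.full((8, 8, 8), 7, dtype=np.uint8), 2.5)
        with pytest.raises(ValueError):
            classify_intensities(vol, 2)

    def test_invalid_class_count(self, rng):
        vol = VolumeImage(rng.integers(0, 255, (8, 8, 8), dtype=np.uint8), 2.5)
        with pytest.raises(ValueError):
            classify_intensities(vol, 5)

    def test_thresholds_strictly_increasing(self, enhanced_phantom_64):
        cv = classify_intensities(enhanced_phantom_64.greyscale, class_count=3)
        assert cv.thresholds[0] < cv.thresholds[1]


# ------------------------------------------------------------------ sobel


class TestSobel:
    def test_constant_is_zero(self):
        assert not sobel_edge_magnitude(np.full((5, 5, 5), 9.0)).any()

    def test_matches_brute_force_convolution(self, rng):
        data = rng.integers(0, 255, size=(7, 7, 7)).astype(np.uint8)
        ours = sobel_edge_magnitude(data)
        oracle = brute_force_sobel(data)
        interior = ~np.isnan(oracle)
        np.testing.assert_allclose(ours[interior], oracle[interior], rtol=1e-10)

    def test_step_response_maximal_on_plane(self):
        data = np.zeros((9, 9, 9))
        data[:, :, 5:] = 100.0
        mag = sobel_edge_magnitude(data)
        peak_x = mag[4, 4, :].argmax()
        assert peak_x in (4, 5)
        assert mag[4, 4, peak_x] == mag.max()

    def test_axis_permutation_symmetry(self, rng):
        data = rng.random((6, 7, 8))
        a = sobel_edge_magnitude(data)
        b = sobel_edge_magnitude(np.transpose(data, (2, 0, 1)))
        np.testing.assert_allclose(np.transpose(a, (2, 0, 1)), b, rtol=1e-10)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            sobel_edge_magnitude(np.zeros((2, 5, 5)))


# ------------------------------------------------------------------ clean


class TestMorphologicalClean:
    def test_isolated_voxel_removed(self):
        m = np.zeros((8, 8, 8), bool)
        m[4, 4, 4] = True
        assert not morphological_clean(m, min_component_voxels=2,
                                       opening_radius=0).any()

    def test_diagonal_pair_retained_26conn(self):
        m = np.zeros((8, 8, 8), bool)
        m[3, 3, 3] = m[4, 4, 4] = True
        out = morphological_clean(m, min_component_voxels=2, opening_radius=0)
        assert out.sum() == 2

    def test_surviving_components_meet_minimum_flood_fill_oracle(self, rng):
        m = rng.random((24, 24, 24)) < 0.08
        out = morphological_clean(m, min_component_voxels=5, opening_radius=0)
        for comp in flood_fill_components(out):
            assert len(comp) >= 5
        # and no component of the input with >= 5 voxels was dropped
        big_in = {frozenset(c) for c in flood_fill_components(m) if len(c) >= 5}
        big_out = {frozenset(c) for c in flood_fill_components(out)}
        assert big_in == big_out

    def test_opening_output_subset_of_input(self, rng):
        m = rng.random((20, 20, 20)) < 0.4
        out = morphological_clean(m, min_component_voxels=0, opening_radius=1)
        assert not (out & ~m).any()


# -------------------------------------------------------------- watershed


class TestWatershed:
    def test_single_ball_one_label(self):
        m = ball(10, (24, 24, 24), (48, 48, 48))
        labels = watershed_separate(m)
        assert labels.max() == 1
        assert ((labels > 0) == m).all()

    def test_two_ball_split_matches_nearest_center(self):
        c1, c2 = (24, 24, 16), (24, 24, 32)
        m = ball(10, c1, (48, 48, 48)) | ball(10, c2, (48, 48, 48))
        labels = watershed_separate(m)
        assert labels.max() == 2
        assert ((labels > 0) == m).all()
        # oracle: each voxel belongs to its nearer seed; allow 1 voxel of slack
        # around the equidistant plane
        coords = np.argwhere(m)
        d1 = np.linalg.norm(coords - c1, axis=1)
        d2 = np.linalg.norm(coords - c2, axis=1)
        lab1 = labels[tuple(coords[np.argmin(np.linalg.norm(coords - c1, axis=1))])]
        lab2 = labels[tuple(coords[np.argmin(np.linalg.norm(coords - c2, axis=1))])]
        assert lab1 != lab2
        off_plane = np.abs(d1 - d2) > 2.0  # strictly > 1 voxel from the plane
        got = labels[tuple(coords[off_plane].T)]
        want = np.where(d1[off_plane] < d2[off_plane], lab1, lab2)
        assert (got == want).all()

    def test_empty_mask(self):
        labels = watershed_separate(np.zeros((8, 8, 8), bool))
        assert labels.max() == 0

    def test_partition_property(self, enhanced_phantom_64):
        cv = classify_intensities(enhanced_phantom_64.greyscale, 3)
        m = cv.data == 1
        labels = watershed_separate(m)
        assert ((labels > 0) == m).all()  # every foreground voxel labeled

    def test_deterministic(self, rng):
        m = rng.random((24, 24, 24)) < 0.3
        a = watershed_separate(m)
        b = watershed_separate(m.copy())
        np.testing.assert_array_equal(a, b)


# ------------------------------------------------------------ border kill


class TestBorderKill:
    def test_touching_label_removed_interior_kept(self):
        labels = np.zeros((10, 10, 10), np.int32)
        labels[0, 5, 5] = 1  # touches z=0 face
        labels[4:6, 4:6, 4:6] = 2  # interior
        out = border_kill(labels)
        assert 1 not in out
        assert (out == 2).sum() == 8

    def test_matches_face_scan_oracle(self, rng):
        from scipy import ndimage as ndi

        m = rng.random((20, 20, 20)) < 0.3
        labels, _ = ndi.label(m)
        killed = face_scan_border_labels(labels)
        out = border_kill(labels)
        survivors = set(np.unique(out).tolist()) - {0}
        assert survivors == set(np.unique(labels).tolist()) - {0} - killed
        for lab in survivors:  # untouched voxel sets
            np.testing.assert_array_equal(out == lab, labels == lab)


# ---------------------------------------------------------------- filters


def _cell(d, sph=0.9):
    vol = np.pi / 6 * d**3
    return CellRecord(1, vol, d, 1.0, sph, 0.1, (0, 0, 0))


class TestApplyFilters:
    def test_apple_spec_keeps_only_mid_diameter(self):
        spec = FilterSpec(d_min=40, d_max=200, sphericity_min=0.75)
        cells = [_cell(30), _cell(100), _cell(250)]
        kept = apply_filters(cells, spec)
        assert [c.equivalent_diameter for c in kept] == [100]

    def test_sphericity_cutoff_is_strict(self):
        spec = FilterSpec(sphericity_min=0.75)
        assert apply_filters([_cell(100, sph=0.75)], spec) == []
        assert len(apply_filters([_cell(100, sph=0.751)], spec)) == 1

    def test_empty_spec_is_identity(self):
        cells = [_cell(30), _cell(100)]
        assert apply_filters(cells, FilterSpec()) == cells

    def test_idempotent(self):
        spec = FilterSpec(d_min=40, d_max=200, sphericity_min=0.75)
        cells = [_cell(d, s) for d in (10, 50, 150, 300) for s in (0.5, 0.9)]
        once = apply_filters(cells, spec)
        assert apply_filters(once, spec) == once

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            FilterSpec(d_min=200, d_max=100)
        with pytest.raises(ValueError):
            FilterSpec(sphericity_min=1.5)


# -------------------------------------------------------- volume recovery


class TestRecoverVolume:
    def test_zero_iterations_is_identity(self, rng):
        labels = (rng.random((12, 12, 12)) < 0.2).astype(np.int32)
        out = recover_volume(labels, np.ones_like(labels, bool),
                             np.zeros(labels.shape), max_iterations=0)
        np.testing.assert_array_equal(out, labels)

    def test_grows_back_to_bright_shell(self):
        shape = (32, 32, 32)
        center = (16, 16, 16)
        cell_region = ball(12, center, shape)
        # bright shell at radius 8..10, faint background response elsewhere
        z, y, x = np.indices(shape)
        r = np.sqrt(sum((c - g) ** 2 for c, g in zip(center, (z, y, x))))
        edge = np.zeros(shape)
        edge[(r > 8) & (r <= 10)] = 10.0
        rng = np.random.default_rng(0)
        noise_sites = (rng.random(shape) < 0.5) & (edge == 0)
        edge[noise_sites] = 1.0
        labels = ball(5, center, shape).astype(np.int32)
        out = recover_volume(labels, cell_region, edge, max_iterations=20,
                             ridge_percentile=75.0)
        grown = out > 0
        assert (grown & ~labels.astype(bool)).any()  # it grew
        assert not grown[r > 8.5].any()  # blocked at the shell
        interior = r <= 7
        assert grown[interior].mean() > 0.95  # and filled the inside

    def test_two_labels_never_merge(self):
        shape = (20, 20, 41)
        labels = np.zeros(shape, np.int32)
        labels[8:12, 8:12, 5:15] = 1
        labels[8:12, 8:12, 26:36] = 2
        edge = np.zeros(shape)
        edge[:, :, 20] = 100.0  # bright wall between them
        mask = np.ones(shape, bool)
        out = recover_volume(labels, mask, edge, max_iterations=100,
                             ridge_percentile=50.0)
        ids = set(np.unique(out).tolist()) - {0}
        assert ids == {1, 2}
        # geodesic growth is face-connected, so the two label sets can never
        # share a voxel
        assert not ((out == 1) & (out == 2)).any()
        for lab in (1, 2):  # monotone growth
            assert (out[labels == lab] == lab).all()

    def test_restricted_to_cell_mask(self, rng):
        labels = np.zeros((16, 16, 16), np.int32)
        labels[7:9, 7:9, 7:9] = 1
        mask = ball(5, (8, 8, 8), (16, 16, 16))
        out = recover_volume(labels, mask, np.zeros((16, 16, 16)), 50)
        assert not (out.astype(bool) & ~mask).any()


# --------------------------------------------------------- dense structures


class TestDenseStructures:
    def test_tube_recovered_with_dice(self, structures_phantom):
        cv = classify_intensities(structures_phantom.greyscale, 3)
        no_cells = np.zeros(structures_phantom.greyscale.shape, np.int32)
        slabels, records = extract_dense_structures(
            cv, no_cells, structures_phantom.spec.voxel_size
        )
        vess = [r for r in records if r.structure_class == "vasculature"]
        assert len(vess) == 1
        truth_id = next(
            k for k, v in structures_phantom.structure_classes.items()
            if v == "vasculature"
        )
        truth = structures_phantom.truth_structures == truth_id
        got = slabels == vess[0].structure_id
        dice = 2 * (truth & got).sum() / (truth.sum() + got.sum())
        assert dice > 0.8

    def test_three_clusters_recovered(self, structures_phantom):
        cv = classify_intensities(structures_phantom.greyscale, 3)
        no_cells = np.zeros(structures_phantom.greyscale.shape, np.int32)
        _, records = extract_dense_structures(
            cv, no_cells, structures_phantom.spec.voxel_size
        )
        clusters = [r for r in records if r.structure_class == "brachysclereid"]
        assert len(clusters) == 3

    def test_control_mode_empty_with_warning(self, rng):
        data = np.where(rng.random((32, 32, 32)) < 0.5, 10, 200).astype(np.uint8)
        cv = classify_intensities(VolumeImage(data, 2.5), 2)
        with pytest.warns(UserWarning, match="bright"):
            slabels, records = extract_dense_structures(
                cv, np.zeros((32, 32, 32), np.int32), 2.5
            )
        assert records == []
        assert not slabels.any()


# ------------------------------------------------------------ composition


class TestSegmentCells:
    def test_enhanced_phantom_cell_count_and_volumes(self, enhanced_phantom_64):
        res = segment_cells(
            enhanced_phantom_64.greyscale, mode="enhanced",
            filter_spec=FilterSpec(d_min=20.0),
        )
        truth_interior = border_kill(enhanced_phantom_64.truth_labels)
        n_truth = len(set(np.unique(truth_interior).tolist()) - {0})
        assert n_truth > 0
        assert abs(len(res.cells) - n_truth) / n_truth <= 0.15  # coarse at 64³

    def test_control_vs_enhanced_direction(self):
        from ctmorph.phantom import PhantomSpec, generate_tissue

        results = {}
        for mode in ("control", "enhanced"):
            spec = PhantomSpec(
                shape=(64, 64, 64), voxel_size=2.5, target_porosity=0.05,
                mean_cell_diameter=45.0, noise_sd=8.0, random_seed=13,
                contrast_mode=(mode == "enhanced"),
            )
            out = generate_tissue(spec)
            with np.errstate(all="ignore"):
                res = segment_cells(
                    out.greyscale, mode=mode,
                    filter_spec=FilterSpec(d_min=20.0, sphericity_min=0.75),
                )
            results[mode] = sum(c.volume for c in res.cells)
        assert results["enhanced"] > results["control"]

    def test_stage_log_complete(self, enhanced_phantom_64):
        res = segment_cells(enhanced_phantom_64.greyscale, mode="enhanced")
        stages = [s["stage"] for s in res.stage_log]
        assert stages == [
            "classify", "clean", "watershed", "border_kill",
            "filter_recover", "dense_structures",
        ]

    def test_invalid_mode(self, enhanced_phantom_64):
        with pytest.raises(ValueError):
            segment_cells(enhanced_phantom_64.greyscale, mode="fancy")
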