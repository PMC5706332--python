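"""Rigid + anisotropic-scale registration and XOR change quantification.

The transform model maps fixed-grid voxel coordinates x to moving-grid
coordinates via ``m(x) = S R (x - c) + c + t`` (scales applied after
rotation, about the volume center). Optimization maximizes normalized
cross-correlation with a derivative-free local search over a 3-level
multi-resolution pyramid, started from a principal-axes pre-alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy import optimize

from .core import VolumeImage


def _rotation_matrix(angles: tuple[float, float, float]) -> np.ndarray:
    """Intrinsic rotations about the z, y, x array axes (radians)."""
    az, ay, ax = angles
    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    rz = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])  # rotate (y,x) plane
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rx = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
    return rz @ ry @ rx


@dataclass
class RegistrationTransform:
    """Rigid + per-axis-scale transform in voxel coordinates (z, y, x)."""

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # radians
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # voxels
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)  # voxels
    final_metric: float | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scale):
            raise ValueError("scales must be positive")

    def matrix_offset(self) -> tuple[np.ndarray, np.ndarray]:
        """(A, b) such that moving coords = A @ fixed coords + b."""
        r = _rotation_matrix(self.rotation)
        a = np.diag(self.scale) @ r
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        return a, c + t - a @ c

    def apply(
        self, moving: np.ndarray, output_shape: tuple[int, ...], order: int = 1
    ) -> np.ndarray:
        """Resample ``moving`` onto a fixed grid of ``output_shape``.

        ``order=1`` for greyscale, ``order=0`` (nearest) for labels/masks.
        """
        a, b = self.matrix_offset()
        return ndi.affine_transform(
            moving,
            matrix=a,
            offset=b,
            output_shape=output_shape,
            order=order,
            mode="constant",
            cval=0.0,
        )

    def params(self) -> np.ndarray:
        return np.array(
            [*self.rotation, *self.translation, *np.log(self.scale)], dtype=float
        )

    @classmethod
    def from_params(
        cls, p: np.ndarray, center: tuple[float, float, float], metric: float | None = None
    ) -> "RegistrationTransform":
        return cls(
            rotation=tuple(p[0:3]),
            translation=tuple(p[3:6]),
            scale=tuple(np.exp(p[6:9])),
            center=center,
            final_metric=metric,
        )


def _principal_axes(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    coords = np.argwhere(mask)
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    cov = centred.T @ centred / coords.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    # deterministic sign: largest-magnitude component of each axis positive
    for j in range(3):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    return centroid, eigvals, eigvecs


def principal_axes_prealign(
    fixed: np.ndarray, moving: np.ndarray
) -> RegistrationTransform:
    """Map the moving mask's centroid and inertia axes onto the fixed mask's.

    Nearly isotropic mass distributions (relative eigenvalue spread below
    5%) fall back to centroid-only alignment with a warning.
    """
    fixed = np.asarray(fixed).astype(bool)
    moving = np.asarray(moving).astype(bool)
    if not fixed.any() or not moving.any():
        raise ValueError("both masks must be non-empty")
    c_f, ev_f, ax_f = _principal_axes(fixed)
    c_m, ev_m, ax_m = _principal_axes(moving)

    degenerate = (ev_f[-1] - ev_f[0]) < 0.05 * ev_f[-1] or (
        ev_m[-1] - ev_m[0]
    ) < 0.05 * ev_m[-1]
    if degenerate:
        warnings.warn("near-isotropic mass distribution: centroid-only pre-alignment")
        r = np.eye(3)
    else:
        r = ax_m @ ax_f.T

    center = tuple((np.array(fixed.shape) - 1) / 2.0)
    c = np.asarray(center)
    # want: A (x - c) + c + t = c_m + R (x - c_f) for all x, with A = R
    t = c_m + r @ (c - c_f) - c
    angles = _fit_angles(r)
    return RegistrationTransform(
        rotation=tuple(angles), translation=tuple(t), scale=(1.0, 1.0, 1.0), center=center
    )


def _fit_angles(r: np.ndarray) -> np.ndarray:
    """Recover (az, ay, ax) with a small numerical fit to the rotation matrix."""

    def residual(p):
        return (_rotation_matrix(tuple(p)) - r).ravel()

    sol = optimize.least_squares(residual, x0=np.zeros(3), method="lm")
    return sol.x


def normalized_cross_correlation(
    a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Pearson correlation of two equal-shape volumes over an optional mask."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if mask is not None:
        m = np.asarray(mask).ravel()
        a, b = a[m], b[m]
    if a.size < 2:
        return 0.0
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


@dataclass
class RegistrationResult:
    transform: RegistrationTransform
    resampled: np.ndarray
    success: bool
    message: str


def _downsample(data: np.ndarray, factor: int) -> np.ndarray:
    # smoothing also at the finest level: uncorrelated voxel noise otherwise
    # biases the NCC optimum through interpolation-dependent correlation
    smoothed = ndi.gaussian_filter(
        data.astype(np.float64), sigma=max(0.8, factor / 2.0)
    )
    if factor == 1:
        return smoothed
    return smoothed[::factor, ::factor, ::factor]


#: Natural step sizes per parameter (angles rad, translation voxels,
#: log-scales); Powell works in these units so its unit initial steps are
#: sensible for every parameter.
_PARAM_SCALES = np.array([0.02] * 3 + [1.0] * 3 + [0.01] * 3)


def register(
    fixed: VolumeImage | np.ndarray,
    moving: VolumeImage | np.ndarray,
    init: RegistrationTransform | None = None,
    pyramid: tuple[int, ...] = (4, 2, 1),
    maxiter: tuple[int, ...] = (60, 25, 8),
    min_metric: float = 0.2,
    edge_margin: int = 6,
) -> RegistrationResult:
    """Optimize rigid + aniso-scale parameters by NCC over a pyramid.

    ``edge_margin`` voxels at the fixed-volume faces are excluded from
    the metric: border voxels sample partially outside the moving volume
    and would otherwise bias the recovered scales. Returns the refined
    transform, the moving volume resampled onto the fixed grid, and a
    success flag. Failure (no overlap / metric not improving past
    ``min_metric``) is reported explicitly, never as a silent identity.
    """
    fixed_data = fixed.data if isinstance(fixed, VolumeImage) else np.asarray(fixed)
    moving_data = moving.data if isinstance(moving, VolumeImage) else np.asarray(moving)
    fixed_data = fixed_data.astype(np.float64)
    moving_data = moving_data.astype(np.float64)

    center = tuple((np.array(fixed_data.shape) - 1) / 2.0)
    if init is None:
        init = RegistrationTransform(center=center)
    p = init.params()
    center = init.center

    def metric_at(level: int, p_scaled: np.ndarray) -> float:
        t = RegistrationTransform.from_params(p_scaled * _PARAM_SCALES, center)
        a, b = t.matrix_offset()
        # decimation by [::level] keeps voxel 0, so full-res coords are
        # level * level-coords and the offset simply rescales
        res = ndi.affine_transform(
            _mov[level],
            matrix=a,
            offset=b / level,
            output_shape=_fix[level].shape,
            order=1,
            mode="constant",
            cval=np.nan,
        )
        valid = ~np.isnan(res)
        m = max(1, round(edge_margin / level))
        inner = np.zeros(res.shape, dtype=bool)
        inner[m:-m, m:-m, m:-m] = True
        valid &= inner
        if valid.sum() < 0.05 * res.size:
            return 1.0  # essentially no overlap
        return 1.0 - normalized_cross_correlation(_fix[level], np.nan_to_num(res), valid)

    _fix = {lv: _downsample(fixed_data, lv) for lv in pyramid}
    _mov = {lv: _downsample(moving_data, lv) for lv in pyramid}

    p = p / _PARAM_SCALES
    for lv, mi in zip(pyramid, maxiter):
        res = optimize.minimize(
            lambda q: metric_at(lv, q),
            p,
            method="Powell",
            options={"maxiter": mi, "xtol": 1e-2, "ftol": 1e-6},
        )
        p = res.x
    final_metric = 1.0 - metric_at(1, p) if 1 in _fix else 1.0 - res.fun

    transform = RegistrationTransform.from_params(
        p * _PARAM_SCALES, center, metric=final_metric
    )
    resampled = transform.apply(moving_data, fixed_data.shape, order=1)
    if final_metric < min_metric:
        return RegistrationResult(
            transform,
            resampled,
            success=False,
            message=(
                f"registration failed: final correlation {final_metric:.3f} "
                f"below {min_metric}"
            ),
        )
    return RegistrationResult(
        transform, resampled, success=True, message=f"correlation {final_metric:.3f}"
    )


def xor_fraction(a: np.ndarray, b: np.ndarray) -> float:
    """Percent of voxels where two equal-shape binary masks disagree."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(100.0 * np.count_nonzero(a ^ b) / a.size)


def corrected_cell_difference(mismatch_pct: float, noncell_pct: float) -> float:
    """XOR mismatch attributable to cells after removing the non-cell
    (airspace + vasculature) fraction of the VOI."""
    if not 0 <= noncell_pct <= mismatch_pct:
        raise ValueError("need 0 <= noncell_pct <= mismatch_pct")
    return float(round(mismatch_pct - noncell_pct, 6))


__all__ = [
    "RegistrationTransform",
    "RegistrationResult",
    "principal_axes_prealign",
    "register",
    "normalized_cross_correlation",
    "xor_fraction",
    "corrected_cell_difference",
]
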