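"""Coordinate conventions, volume containers and tensor eigensystem math.

Conventions used package-wide:

* world space is RAS+ millimetres; voxel indices are 0-based and the affine
  maps voxel *centres* to world coordinates;
* slab / gate intervals are half-open ``[lo, hi)``;
* diffusion tensors are stored as 6 components in lower-triangular order
  (xx, xy, xz, yy, yz, zz), units mm^2/s;
* eigenvalues are sorted descending and eigenvector signs are fixed by
  making the first non-zero component non-negative, so outputs reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import shbasis
from .shbasis import REAL_SYM_BASIS_ID


class OutOfSupportError(ValueError):
    """A world point fell outside the field's masked support."""


# ---------------------------------------------------------------------------
# grids and interpolation


@dataclass(frozen=True)
class AffineGrid:
    """A regular voxel grid with a voxel-to-world (RAS+ mm) affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # (4, 4)

    def __post_init__(self):
        A = np.asarray(self.affine, dtype=float)
        if A.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(A[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", A)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "_inv", np.linalg.inv(A))

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, vox: np.ndarray) -> np.ndarray:
        vox = np.asarray(vox, dtype=float)
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        inv = self._inv
        return world @ inv[:3, :3].T + inv[:3, 3]

    def contains_voxel(self, vox: np.ndarray) -> np.ndarray:
        """True where a continuous voxel coordinate is inside the grid."""
        vox = np.atleast_2d(vox)
        lo = vox >= -0.5
        hi = vox <= np.asarray(self.shape) - 0.5
        return (lo & hi).all(axis=-1)


def world_to_voxel(grid: AffineGrid, point: np.ndarray) -> np.ndarray:
    return grid.world_to_voxel(point)


def voxel_to_world(grid: AffineGrid, vox: np.ndarray) -> np.ndarray:
    return grid.voxel_to_world(vox)


def trilinear(volume: np.ndarray, vox: np.ndarray) -> np.ndarray:
    """Trilinearly interpolate a (X, Y, Z, C) volume at (N, 3) voxel coords.

    Coordinates are clamped to the valid interpolation cube; callers are
    responsible for bounds/support checks (see :meth:`TensorField.support`).
    """
    v = np.atleast_2d(np.asarray(vox, dtype=float))
    shape = np.asarray(volume.shape[:3])
    v = np.clip(v, 0.0, shape - 1.0)
    f = np.floor(np.minimum(v, shape - 2.0)).astype(int)
    f = np.maximum(f, 0)
    t = v - f
    out = 0.0
    for dx in (0, 1):
        wx = t[:, 0] if dx else 1.0 - t[:, 0]
        for dy in (0, 1):
            wy = t[:, 1] if dy else 1.0 - t[:, 1]
            for dz in (0, 1):
                wz = t[:, 2] if dz else 1.0 - t[:, 2]
                w = (wx * wy * wz)[:, None]
                out = out + w * volume[f[:, 0] + dx, f[:, 1] + dy, f[:, 2] + dz]
    return out


def trilinear_one(volume: np.ndarray, vox: np.ndarray) -> np.ndarray:
    """Single-point trilinear sample of a (X, Y, Z, C) volume (hot path)."""
    shape = volume.shape
    x = min(max(vox[0], 0.0), shape[0] - 1.0)
    y = min(max(vox[1], 0.0), shape[1] - 1.0)
    z = min(max(vox[2], 0.0), shape[2] - 1.0)
    i = min(int(x), shape[0] - 2)
    j = min(int(y), shape[1] - 2)
    k = min(int(z), shape[2] - 2)
    tx, ty, tz = x - i, y - j, z - k
    block = volume[i : i + 2, j : j + 2, k : k + 2]
    bx = block[0] + (block[1] - block[0]) * tx
    by = bx[0] + (bx[1] - bx[0]) * ty
    return by[0] + (by[1] - by[0]) * tz


# ---------------------------------------------------------------------------
# eigensystems


@dataclass(frozen=True)
class EigenSystem:
    """Sorted eigenvalues (descending, mm^2/s) and matching eigenvectors.

    ``eigenvectors[:, i]`` pairs with ``eigenvalues[i]``; signs are fixed so
    the first non-zero component of each eigenvector is non-negative.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def principal(self) -> np.ndarray:
        return self.eigenvectors[:, 0]


def tensor6_to_matrix(six: np.ndarray) -> np.ndarray:
    """(..., 6) lower-triangular components -> (..., 3, 3) symmetric."""
    six = np.asarray(six, dtype=float)
    m = np.empty(six.shape[:-1] + (3, 3))
    xx, xy, xz, yy, yz, zz = np.moveaxis(six, -1, 0)
    m[..., 0, 0] = xx
    m[..., 1, 1] = yy
    m[..., 2, 2] = zz
    m[..., 0, 1] = m[..., 1, 0] = xy
    m[..., 0, 2] = m[..., 2, 0] = xz
    m[..., 1, 2] = m[..., 2, 1] = yz
    return m


def matrix_to_tensor6(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    return np.stack(
        [m[..., 0, 0], m[..., 0, 1], m[..., 0, 2], m[..., 1, 1], m[..., 1, 2], m[..., 2, 2]],
        axis=-1,
    )


def _fix_sign(vecs: np.ndarray) -> np.ndarray:
    """Make the first component with |v| > 1e-12 of each column non-negative."""
    v = vecs.copy()
    # columns are the eigenvectors: iterate the 3 columns, vectorized in batch
    for i in range(3):
        col = v[..., :, i]
        big = np.abs(col) > 1e-12
        first = np.argmax(big, axis=-1)
        sign = np.take_along_axis(col, first[..., None], axis=-1)[..., 0]
        flip = sign < 0
        v[..., :, i] = np.where(flip[..., None], -col, col)
    return v


def eigensystems(six: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched eigendecomposition of (..., 6) tensors.

    Returns descending eigenvalues (..., 3) and eigenvectors (..., 3, 3)
    with the package sign convention.
    """
    w, v = np.linalg.eigh(tensor6_to_matrix(six))
    w = w[..., ::-1]
    v = v[..., :, ::-1]
    return w, _fix_sign(v)


def eigensystem(six: np.ndarray) -> EigenSystem:
    w, v = eigensystems(np.asarray(six)[None])
    return EigenSystem(w[0], v[0])


# ---------------------------------------------------------------------------
# fields


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors on an affine grid."""

    grid: AffineGrid
    components: np.ndarray  # (X, Y, Z, 6)
    mask: np.ndarray  # (X, Y, Z) bool

    def __post_init__(self):
        if self.components.shape != self.grid.shape + (6,):
            raise ValueError("components shape does not match grid")
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        self.mask = self.mask.astype(bool)

    def support(self, points: np.ndarray) -> np.ndarray:
        """True where a world point is in-grid and its nearest voxel masked."""
        vox = self.grid.world_to_voxel(np.atleast_2d(points))
        ok = self.grid.contains_voxel(vox)
        idx = np.clip(
            np.rint(vox).astype(int), 0, np.asarray(self.grid.shape) - 1
        )
        ok &= self.mask[idx[:, 0], idx[:, 1], idx[:, 2]]
        return ok

    def interpolate6(self, points: np.ndarray, check_support: bool = True) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if check_support and not self.support(pts).all():
            raise OutOfSupportError("point(s) outside masked tensor support")
        return trilinear(self.components, self.grid.world_to_voxel(pts))


def interpolate_tensor(field: TensorField, point: np.ndarray) -> EigenSystem:
    """Trilinear interpolation of the 6 components, then eigendecomposition.

    Interpolating components (not eigenvalues) keeps the field smooth at
    fibre crossings; a constant field returns exactly the voxel eigensystem.
    """
    six = field.interpolate6(point)[0]
    return eigensystem(six)


@dataclass
class FODField:
    """Per-voxel real even-order SH coefficient field."""

    grid: AffineGrid
    sh_coeffs: np.ndarray  # (X, Y, Z, C)
    mask: np.ndarray
    sh_ordering: str = REAL_SYM_BASIS_ID
    order: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.sh_ordering != REAL_SYM_BASIS_ID:
            raise ValueError(
                f"SH ordering {self.sh_ordering!r} does not match the "
                f"package basis {REAL_SYM_BASIS_ID!r}; refusing to guess"
            )
        inferred = shbasis.order_from_ncoeffs(self.sh_coeffs.shape[-1])
        if self.order is None:
            self.order = inferred
        elif self.order != inferred:
            raise ValueError("declared SH order disagrees with coefficient count")
        if self.sh_coeffs.shape[:3] != self.grid.shape:
            raise ValueError("sh_coeffs shape does not match grid")
        self.mask = self.mask.astype(bool)

    def support(self, points: np.ndarray) -> np.ndarray:
        vox = self.grid.world_to_voxel(np.atleast_2d(points))
        ok = self.grid.contains_voxel(vox)
        idx = np.clip(np.rint(vox).astype(int), 0, np.asarray(self.grid.shape) - 1)
        ok &= self.mask[idx[:, 0], idx[:, 1], idx[:, 2]]
        return ok

    def coeffs_at(self, points: np.ndarray, check_support: bool = True) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if check_support and not self.support(pts).all():
            raise OutOfSupportError("point(s) outside masked FOD support")
        return trilinear(self.sh_coeffs, self.grid.world_to_voxel(pts))


def fod_amplitude(field: FODField, point: np.ndarray, direction: np.ndarray) -> float:
    """Amplitude of the interpolated FOD along a unit direction."""
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-8:
        raise ValueError("direction must be a unit vector")
    coeffs = field.coeffs_at(point)[0]
    return float(shbasis.sh_basis(direction, field.order) @ coeffs)
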