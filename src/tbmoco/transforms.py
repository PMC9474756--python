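"""Spatial transforms: affine maps, dense displacement fields, resampling,
composition, inversion and diffeomorphism diagnostics.

All transforms act on world coordinates (mm) and use the *pull* (backward
warping) convention: a transform T applied to image ``I`` produces
``out(x) = I(T(x))``; for a displacement field u, ``T(x) = x + u(x)``.
Fields are stored in mm in world space so composition is grid-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .core import VoxelGrid
from .errors import FormatError, InvalidArgumentError

__all__ = [
    "AffineTransform",
    "DisplacementField",
    "DiffeoTransform",
    "resample",
    "compose",
    "jacobian_determinant",
    "invert",
    "affine_to_field",
]

_INTERP_ORDER = {"nearest": 0, "linear": 1}


@dataclass(frozen=True)
class AffineTransform:
    """World-space affine: x -> M (x - c) + c + t.

    The linear part M is composed of rotations and (anisotropic) scalings —
    no shear — matching a translation/rotation/scaling motion model; c is the
    center of rotation (mm) and t the translation (mm).
    """

    matrix: tuple[tuple[float, float, float], ...]
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.shape != (3, 3):
            raise InvalidArgumentError("affine matrix must be 3x3")
        if abs(np.linalg.det(M)) < 1e-12:
            raise InvalidArgumentError("affine linear part is singular")
        object.__setattr__(self, "matrix", tuple(tuple(float(x) for x in r) for r in M))
        object.__setattr__(self, "translation", tuple(float(x) for x in self.translation))
        object.__setattr__(self, "center", tuple(float(x) for x in self.center))

    # -- constructors -------------------------------------------------------
    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(matrix=tuple(tuple(r) for r in np.eye(3)))

    @classmethod
    def from_params(
        cls,
        translation=(0.0, 0.0, 0.0),
        rotation_rad=(0.0, 0.0, 0.0),
        log_scale=(0.0, 0.0, 0.0),
        center=(0.0, 0.0, 0.0),
    ) -> "AffineTransform":
        """9-parameter transform: 3 translations (mm), 3 Euler rotations
        (radians, applied Rz Ry Rx) and 3 per-axis log-scales."""
        rx, ry, rz = rotation_rad
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        M = Rz @ Ry @ Rx @ np.diag(np.exp(np.asarray(log_scale, dtype=float)))
        return cls(matrix=tuple(tuple(r) for r in M), translation=tuple(translation), center=tuple(center))

    # -- algebra ------------------------------------------------------------
    @property
    def matrix_np(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (..., 3) world points through the transform."""
        p = np.asarray(points, dtype=float)
        c = np.asarray(self.center)
        return (p - c) @ self.matrix_np.T + c + np.asarray(self.translation)

    def then(self, other: "AffineTransform") -> "AffineTransform":
        """Function composition self o other: (self.then(other))(x) = self(other(x)).

        In pull convention this is the total map for resampling an image first
        warped by ``self`` and then by ``other`` — matching field
        :func:`compose` with ``outer=self, inner=other``.
        """
        # express both as x -> A x + b, compose, keep center at self.center
        A1, b1 = self._homogeneous()
        A2, b2 = other._homogeneous()
        A = A1 @ A2
        b = A1 @ b2 + b1
        c = np.asarray(self.center)
        t = b - c + A @ c
        return AffineTransform(matrix=tuple(tuple(r) for r in A), translation=tuple(t), center=self.center)

    def _homogeneous(self) -> tuple[np.ndarray, np.ndarray]:
        M = self.matrix_np
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return M, c + t - M @ c

    def inverse(self) -> "AffineTransform":
        A, b = self._homogeneous()
        Ai = np.linalg.inv(A)
        bi = -Ai @ b
        c = np.asarray(self.center)
        t = bi - c + Ai @ c
        return AffineTransform(matrix=tuple(tuple(r) for r in Ai), translation=tuple(t), center=self.center)

    # -- I/O ----------------------------------------------------------------
    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "matrix": [list(r) for r in self.matrix],
                    "translation": list(self.translation),
                    "center": list(self.center),
                }
            )
        )

    @classmethod
    def from_json(cls, path) -> "AffineTransform":
        d = json.loads(Path(path).read_text())
        return cls(
            matrix=tuple(tuple(r) for r in d["matrix"]),
            translation=tuple(d["translation"]),
            center=tuple(d["center"]),
        )


@dataclass
class DisplacementField:
    """Dense per-voxel displacement u (mm, world space), pull convention."""

    vectors: np.ndarray  # (nx, ny, nz, 3)
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != self.grid.shape + (3,):
            raise InvalidArgumentError(
                f"field shape {self.vectors.shape} does not match grid "
                f"{self.grid.shape} + (3,)"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise InvalidArgumentError("displacement field contains non-finite values")

    @classmethod
    def zero(cls, grid: VoxelGrid) -> "DisplacementField":
        return cls(np.zeros(grid.shape + (3,)), grid)

    @classmethod
    def constant(cls, grid: VoxelGrid, t) -> "DisplacementField":
        v = np.zeros(grid.shape + (3,))
        v[...] = np.asarray(t, dtype=float)
        return cls(v, grid)

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    def sample_world(self, points: np.ndarray) -> np.ndarray:
        """Linearly interpolate the field at (..., 3) world points (mm);
        points outside the grid take the nearest-edge value."""
        pts = np.asarray(points, dtype=float)
        idx = self.grid.world_to_voxel(pts.reshape(-1, 3)).T
        out = np.empty((pts.reshape(-1, 3).shape[0], 3))
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(
                self.vectors[..., c], idx, order=1, mode="nearest"
            )
        return out.reshape(pts.shape)

    # -- I/O ----------------------------------------------------------------
    def to_nifti(self, path) -> None:
        nib.save(
            nib.Nifti1Image(self.vectors.astype(np.float32), self.grid.affine),
            str(path),
        )

    @classmethod
    def from_nifti(cls, path) -> "DisplacementField":
        img = nib.load(str(path))
        if img.ndim != 4 or img.shape[-1] != 3:
            raise FormatError(f"expected a 3-component vector NIfTI: {path}")
        from .core import _grid_from_nifti  # local import to avoid cycle

        canon = nib.as_closest_canonical(img)
        data = np.asarray(canon.dataobj, dtype=np.float64)
        grid3 = _grid_from_nifti(
            nib.Nifti1Image(np.zeros(img.shape[:3], dtype=np.int8), img.affine)
        )
        return cls(data, grid3)


@dataclass
class DiffeoTransform:
    """Paired forward/inverse displacement fields of a diffeomorphism.

    ``forward`` pulls the moving image into the fixed/reference space;
    ``inverse`` undoes it, with forward o inverse ~ identity.
    """

    forward: DisplacementField
    inverse: DisplacementField

    def roundtrip_residual(self) -> float:
        """Mean |compose(forward, inverse)| in mm (identity check)."""
        return float(compose(self.forward, self.inverse).magnitude.mean())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _sample_points(image: np.ndarray, grid: VoxelGrid, pts_world: np.ndarray,
                   order: int, cval: float = 0.0) -> np.ndarray:
    idx = grid.world_to_voxel(pts_world.reshape(-1, 3)).T
    vals = ndimage.map_coordinates(
        np.asarray(image, dtype=float), idx, order=order, mode="constant", cval=cval
    )
    return vals.reshape(pts_world.shape[:-1])


def resample(
    image: np.ndarray,
    grid: VoxelGrid,
    transform: AffineTransform | DisplacementField,
    out_grid: VoxelGrid | None = None,
    interp: str = "linear",
    fill: float = 0.0,
) -> np.ndarray:
    """Pull-convention resampling: ``out(x) = image(T(x))`` on ``out_grid``.

    Out-of-domain samples take the ``fill`` value (default 0, i.e. air).
    """
    if interp not in _INTERP_ORDER:
        raise InvalidArgumentError(f"unknown interpolation mode {interp!r}")
    out_grid = out_grid or grid
    x = out_grid.world_coordinates()
    if isinstance(transform, AffineTransform):
        pts = transform.apply(x)
    elif isinstance(transform, DisplacementField):
        if transform.grid != out_grid:
            raise InvalidArgumentError("displacement field must live on the output grid")
        pts = x + transform.vectors
    else:
        raise InvalidArgumentError(f"unsupported transform type {type(transform)}")
    return _sample_points(image, grid, pts, _INTERP_ORDER[interp], fill)


def compose(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Concatenate two pull fields: w(x) = inner(x) + outer(x + inner(x)).

    Pulling once with w equals pulling with ``outer`` first and then with
    ``inner`` (i.e. the point map (id+outer) o (id+inner)); this is the
    single-resampling concatenation used to chain pairwise motion fields.
    """
    if outer.grid != inner.grid:
        raise InvalidArgumentError("cannot compose fields on different grids")
    x = inner.grid.world_coordinates()
    w = inner.vectors + outer.sample_world(x + inner.vectors)
    return DisplacementField(w, inner.grid)


def jacobian_determinant(field: DisplacementField) -> np.ndarray:
    """Voxelwise det of the Jacobian of x -> x + u(x), by central differences
    (one-sided at borders). Strictly positive for orientation-preserving
    (diffeomorphic) fields; 1 everywhere for the identity."""
    if any(n < 3 for n in field.grid.shape):
        raise InvalidArgumentError("grid must span at least 3 voxels per axis")
    # derivative w.r.t. world coordinates: chain rule through the index->world map
    M = field.grid.direction_matrix @ np.diag(field.grid.spacing)
    Minv = np.linalg.inv(M)
    J = np.zeros(field.grid.shape + (3, 3))
    for c in range(3):
        grads = np.gradient(field.vectors[..., c], axis=(0, 1, 2))
        dudx = np.stack(grads, axis=-1) @ Minv  # d u_c / d world
        J[..., c, :] = dudx
    J += np.eye(3)
    return np.linalg.det(J)


def invert(
    field: DisplacementField, iters: int = 50, tol_mm: float = 0.01
) -> DisplacementField:
    """Fixed-point inversion v_{n+1}(x) = -u(x + v_n(x)).

    Converges for fields that are (approximately) diffeomorphic; stops when
    the mean update falls below ``tol_mm`` or after ``iters`` sweeps. On
    non-convergence the best iterate is returned and a warning emitted.
    """
    import warnings

    x = field.grid.world_coordinates()
    v = -field.vectors.copy()
    for _ in range(int(iters)):
        v_new = -field.sample_world(x + v)
        delta = float(np.abs(v_new - v).mean())
        v = v_new
        if delta < tol_mm:
            break
    else:
        residual = float(np.abs(v + field.sample_world(x + v)).mean())
        if residual > 3.0 * tol_mm:
            warnings.warn(
                f"field inversion did not reach tol={tol_mm} mm in {iters} "
                f"iterations (mean residual {residual:.3g} mm)",
                RuntimeWarning,
                stacklevel=2,
            )
    return DisplacementField(v, field.grid)


def affine_to_field(A: AffineTransform, grid: VoxelGrid) -> DisplacementField:
    """Sample an affine map as a dense displacement field u(x) = A(x) - x."""
    x = grid.world_coordinates()
    return DisplacementField(A.apply(x) - x, grid)
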