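"""Core data structures for landmark pose datasets and fitted shape models.

A *pose* is one frame's set of body-point coordinates, stored as an
``(n_points, d)`` array with ``d`` in ``{2, 3}``.  A dataset stacks poses
along the first axis.  Missingness is tracked per *point* (all ``d``
coordinates of a landmark are either observed or missing together) with an
explicit boolean mask; masked coordinates are stored as NaN, but the mask is
authoritative.

Vectorised poses use C-order flattening, i.e. ``[x1, y1, (z1,) x2, ...]``,
so the coordinates of point ``i`` occupy the slice ``[i*d, (i+1)*d)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class ShapePoseError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ShapePoseError):
    """Malformed input file or inconsistent dataset structure."""


class ModelError(ShapePoseError):
    """A fitted model violates its invariants or cannot be applied."""


class AlignmentError(ShapePoseError):
    """Rigid alignment is infeasible (too few commonly observed points)."""

    def __init__(self, message: str, n_common: int | None = None):
        super().__init__(message)
        self.n_common = n_common


def coord_indices(points, d: int) -> np.ndarray:
    """Flat coordinate indices for a set of point indices.

    Parameters
    ----------
    points : array-like of int
        Point (landmark) indices.
    d : int
        Spatial dimensionality.

    Returns
    -------
    ndarray of int, shape (len(points) * d,)
    """
    points = np.asarray(points, dtype=int)
    return (points[:, None] * d + np.arange(d)[None, :]).reshape(-1)


@dataclass
class PoseDataset:
    """Frames x body-points x d coordinate array with an explicit missing mask.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_points, d)
        Landmark coordinates (unitless reals).  Non-finite values are
        promoted to whole-point missing entries.
    missing_mask : ndarray of bool, shape (n_frames, n_points), optional
        True where a point is unobserved.  Derived from NaNs when omitted.
    point_names : list of str, optional
    frame_ids : ndarray of int, optional
    """

    coords: np.ndarray
    missing_mask: np.ndarray | None = None
    point_names: list[str] | None = None
    frame_ids: np.ndarray | None = None

    def __post_init__(self):
        coords = np.array(self.coords, dtype=float)
        if coords.ndim != 3:
            raise FormatError(
                f"coords must be 3-dimensional (frames, points, d); got shape {coords.shape}"
            )
        n, n_points, d = coords.shape
        if d not in (2, 3):
            raise FormatError(f"spatial dimensionality must be 2 or 3, got {d}")
        if n_points < 3:
            raise FormatError(f"at least 3 body points are required, got {n_points}")
        if self.missing_mask is None:
            mask = ~np.isfinite(coords).all(axis=2)
        else:
            mask = np.array(self.missing_mask, dtype=bool)
            if mask.shape != (n, n_points):
                raise FormatError(
                    f"missing_mask shape {mask.shape} does not match frames/points {(n, n_points)}"
                )
            # per-axis missingness is promoted to whole-point missing
            mask |= ~np.isfinite(coords).all(axis=2)
        coords[mask] = np.nan
        self.coords = coords
        self.missing_mask = mask
        if self.point_names is None:
            self.point_names = [f"p{i}" for i in range(n_points)]
        else:
            self.point_names = list(self.point_names)
            if len(self.point_names) != n_points:
                raise FormatError("point_names length does not match number of points")
        if self.frame_ids is None:
            self.frame_ids = np.arange(n, dtype=int)
        else:
            self.frame_ids = np.asarray(self.frame_ids, dtype=int)
            if self.frame_ids.shape != (n,):
                raise FormatError("frame_ids length does not match number of frames")

    # -- shape accessors ---------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]

    @property
    def d(self) -> int:
        return self.coords.shape[2]

    @property
    def n_coords(self) -> int:
        """Length of a vectorised pose (``n_points * d``)."""
        return self.n_points * self.d

    # -- views and helpers -------------------------------------------------
    def vectors(self) -> np.ndarray:
        """Vectorised poses, shape (n_frames, n_points * d); masked -> NaN."""
        return self.coords.reshape(self.n_frames, -1)

    def complete(self) -> np.ndarray:
        """Boolean mask of frames with no missing points."""
        return ~self.missing_mask.any(axis=1)

    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def copy(self) -> "PoseDataset":
        return PoseDataset(
            coords=self.coords.copy(),
            missing_mask=self.missing_mask.copy(),
            point_names=list(self.point_names),
            frame_ids=self.frame_ids.copy(),
        )

    def subset(self, index) -> "PoseDataset":
        """New dataset restricted to the given frame indices."""
        index = np.asarray(index)
        return PoseDataset(
            coords=self.coords[index].copy(),
            missing_mask=self.missing_mask[index].copy(),
            point_names=list(self.point_names),
            frame_ids=self.frame_ids[index].copy(),
        )

    def validate(self):
        """Re-check structural invariants, raising :class:`FormatError`."""
        if self.coords.shape[:2] != self.missing_mask.shape:
            raise FormatError("mask/coords shape mismatch")
        obs = ~self.missing_mask
        if not np.isfinite(self.coords[obs]).all():
            raise FormatError("non-finite coordinates outside the missing mask")
        if not np.isnan(self.coords[self.missing_mask]).all():
            raise FormatError("masked coordinates must hold the NaN sentinel")


@dataclass
class RigidTransform:
    """Rigid (or similarity) map ``y = scale * R @ x + t`` acting on row points.

    ``rotation`` is a proper orthogonal ``d x d`` matrix; ``scale`` is fixed
    at 1.0 under the rigid alignment policy.
    """

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.scale = float(self.scale)

    @property
    def d(self) -> int:
        return self.rotation.shape[0]

    @classmethod
    def identity(cls, d: int) -> "RigidTransform":
        return cls(np.eye(d), np.zeros(d), 1.0)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an ``(..., d)`` array of row points (NaN passes through)."""
        points = np.asarray(points, dtype=float)
        return self.scale * points @ self.rotation.T + self.translation

    def apply_vector(self, vec: np.ndarray) -> np.ndarray:
        """Apply to a vectorised pose of length ``n_points * d``."""
        pts = np.asarray(vec, dtype=float).reshape(-1, self.d)
        return self.apply(pts).reshape(-1)

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        return RigidTransform(
            rotation=rot,
            translation=-(rot @ self.translation) / self.scale,
            scale=1.0 / self.scale,
        )

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to ``self(inner(x))``."""
        return RigidTransform(
            rotation=self.rotation @ inner.rotation,
            translation=self.scale * self.rotation @ inner.translation + self.translation,
            scale=self.scale * inner.scale,
        )

    def validate(self, tol: float = 1e-10):
        d = self.d
        if self.rotation.shape != (d, d) or self.translation.shape != (d,):
            raise ModelError("transform shape mismatch")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(d), atol=tol):
            raise ModelError("rotation is not orthogonal")
        if np.linalg.det(self.rotation) < 0:
            raise ModelError("rotation has negative determinant (reflection)")
        if not self.scale > 0:
            raise ModelError("scale must be positive")


@dataclass
class ShapeModel:
    """Gaussian shape model: mean pose, orthonormal deformation modes, noise floor.

    The regularised covariance is
    ``C = sigma2 * I + V @ diag(eigenvalues - sigma2) @ V.T``
    with ``V`` the ``(n_points*d, r)`` matrix of orthonormal eigenposes; it is
    full-rank SPD whenever ``sigma2 > 0`` and ``eigenvalues >= sigma2``.
    """

    mu: np.ndarray
    eigenposes: np.ndarray
    eigenvalues: np.ndarray
    sigma2: float
    d: int
    alignment_policy: str = "rigid"

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float).reshape(-1)
        self.eigenposes = np.asarray(self.eigenposes, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float).reshape(-1)
        self.sigma2 = float(self.sigma2)
        self.d = int(self.d)

    @property
    def n_coords(self) -> int:
        return self.mu.shape[0]

    @property
    def n_points(self) -> int:
        return self.n_coords // self.d

    @property
    def r(self) -> int:
        return self.eigenposes.shape[1]

    def mean_shape(self) -> np.ndarray:
        """Mean pose as an ``(n_points, d)`` array."""
        return self.mu.reshape(self.n_points, self.d)

    def covariance(self) -> np.ndarray:
        """Full regularised covariance matrix, shape (n_coords, n_coords)."""
        v = self.eigenposes
        c = v @ np.diag(self.eigenvalues - self.sigma2) @ v.T
        c[np.diag_indices_from(c)] += self.sigma2
        return 0.5 * (c + c.T)

    def validate(self, tol: float = 1e-10):
        p, r = self.eigenposes.shape
        if p != self.n_coords or self.eigenvalues.shape != (r,):
            raise ModelError("model field shapes are inconsistent")
        if self.n_coords % self.d != 0:
            raise ModelError("mu length is not a multiple of d")
        gram = self.eigenposes.T @ self.eigenposes
        if not np.allclose(gram, np.eye(r), atol=tol):
            raise ModelError("eigenposes are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > tol):
            raise ModelError("eigenvalues must be nonincreasing")
        if self.sigma2 <= 0:
            raise ModelError("sigma2 must be positive")
        if np.any(self.eigenvalues < self.sigma2 - tol):
            raise ModelError("eigenvalues must not fall below the noise floor")
        if self.alignment_policy not in ("rigid", "similarity"):
            raise ModelError(f"unknown alignment policy {self.alignment_policy!r}")
        try:
            np.linalg.cholesky(self.covariance())
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise ModelError("regularised covariance is not SPD") from exc


__all__ = [
    "ShapePoseError",
    "FormatError",
    "ModelError",
    "AlignmentError",
    "coord_indices",
    "PoseDataset",
    "RigidTransform",
    "ShapeModel",
    "replace",
]
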