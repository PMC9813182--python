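"""Synthetic landmark datasets with known deformation modes and contamination.

Generates poses as ``(M + sum_j P_j b_j) @ R.T + T + noise`` from a fixture
mean shape, orthonormalised random deformation modes, per-pose uniform
rotations and translations, isotropic Gaussian noise, and parametrised
outlier / missing contamination with ground-truth masks recorded.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import special_ortho_group

from .datamodel import PoseDataset, ShapePoseError

# ---------------------------------------------------------------------------
# Fixture shapes (artifact-defined vertex sets; unit RMS radius after
# normalisation, increasing vertex counts: poly < plus < L)
# ---------------------------------------------------------------------------

# Irregular radii/arm lengths deliberately break every rotational symmetry:
# a symmetric outline makes Procrustes alignment ambiguous under deformation.
_POLY_RADII = np.array([1.0, 1.3, 0.8, 1.1, 0.7, 1.25, 0.9, 1.15, 0.75, 1.05])
_POLY_2D = _POLY_RADII[:, None] * np.column_stack(
    [np.cos(2 * np.pi * np.arange(10) / 10), np.sin(2 * np.pi * np.arange(10) / 10)]
)

_PLUS_2D = np.array(
    [
        [0.4, 0.4], [0.4, 1.2], [-0.4, 1.2], [-0.4, 0.4],
        [-0.9, 0.4], [-0.9, -0.4], [-0.4, -0.4], [-0.4, -1.4],
        [0.4, -1.4], [0.4, -0.4], [1.1, -0.4], [1.1, 0.4],
    ]
)

_L_2D = np.array(
    [
        [0.0, 0.0], [0.375, 0.0], [0.75, 0.0], [1.125, 0.0], [1.5, 0.0],
        [1.5, 0.6], [1.05, 0.6], [0.6, 0.6], [0.6, 1.3], [0.6, 1.65],
        [0.6, 2.0], [0.3, 2.0], [0.0, 2.0], [0.0, 1.5], [0.0, 1.0],
        [0.0, 0.5],
    ]
)

_SHAPES_2D = {"poly": _POLY_2D, "plus": _PLUS_2D, "l": _L_2D}


def _normalize(shape: np.ndarray, scale: float) -> np.ndarray:
    shape = shape - shape.mean(axis=0)
    rms = np.sqrt((shape ** 2).sum(axis=1).mean())
    return shape * (scale / rms)


def make_shape(
    name: str,
    d: int = 3,
    vertices: np.ndarray | None = None,
    scale: float = 3.0,
) -> np.ndarray:
    """Fixture mean pose for a named artificial shape (or a custom vertex set).

    Built-in shapes are centred and scaled to an RMS vertex radius of
    ``scale`` (default 3 length units, so the default measurement noise of
    0.1 is small relative to the body, as for a real tracked animal); for
    ``d=3`` a deterministic out-of-plane undulation is added so the point
    set is non-coplanar.  ``custom`` requires ``vertices`` of shape
    (n_points, d), returned as given.
    """
    name = name.lower()
    if name == "custom":
        if vertices is None:
            raise ShapePoseError("custom shape requires a vertex array")
        verts = np.asarray(vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != d:
            raise ShapePoseError(f"custom vertices must have shape (n_points, {d})")
        if verts.shape[0] < 3:
            raise ShapePoseError("custom shape needs at least 3 vertices")
        centred = verts - verts.mean(axis=0)
        if np.linalg.matrix_rank(centred, tol=1e-10) <= 1:
            warnings.warn(
                "custom shape is collinear; rigid alignment is degenerate",
                RuntimeWarning,
                stacklevel=2,
            )
        return verts
    if name not in _SHAPES_2D:
        raise ShapePoseError(f"unknown shape {name!r}; choose poly, plus, L or custom")
    base = _SHAPES_2D[name]
    n = base.shape[0]
    if d == 2:
        return _normalize(base.copy(), scale)
    if d == 3:
        # golden-angle sequence: aperiodic, so no symmetry is reintroduced
        z = 0.35 * np.cos(2.39996322972865332 * np.arange(n))
        return _normalize(np.column_stack([base, z]), scale)
    raise ShapePoseError("d must be 2 or 3")


def rigid_motion_basis(shape: np.ndarray) -> np.ndarray:
    """Orthonormal basis of infinitesimal rigid motions at a mean shape.

    Spans the d translation directions and the d(d-1)/2 infinitesimal
    rotation directions of the centred shape, in vectorised-pose space.
    Deformation modes orthogonal to this subspace are identifiable from
    rotated/translated data; modes inside it are absorbed by alignment.
    """
    shape = np.asarray(shape, dtype=float)
    n, d = shape.shape
    centred = shape - shape.mean(axis=0)
    cols = []
    for a in range(d):
        e = np.zeros((n, d))
        e[:, a] = 1.0
        cols.append(e.reshape(-1))
    for a in range(d):
        for b in range(a + 1, d):
            w = np.zeros((d, d))
            w[a, b], w[b, a] = -1.0, 1.0
            cols.append((centred @ w.T).reshape(-1))
    basis = np.column_stack(cols)
    q, rr = np.linalg.qr(basis)
    keep = np.abs(np.diag(rr)) > 1e-10 * max(1.0, np.abs(rr).max())
    return q[:, keep]


def make_eigenposes(
    n_points: int,
    d: int,
    n_ep: int,
    rng: np.random.Generator | int | None = None,
    mean_shape: np.ndarray | None = None,
) -> np.ndarray:
    """Random orthonormal deformation modes (Gram-Schmidt on Gaussian draws).

    When ``mean_shape`` is given, the draws are first projected out of the
    rigid-motion subspace at that shape so the generated modes are
    identifiable under per-pose rotation/translation nuisance.
    """
    rng = np.random.default_rng(rng)
    p = n_points * d
    if not 1 <= n_ep <= p:
        raise ShapePoseError(f"n_ep must be in [1, {p}]")
    g = rng.standard_normal((p, n_ep))
    if mean_shape is not None:
        if n_ep > p - rigid_motion_basis(mean_shape).shape[1]:
            raise ShapePoseError("n_ep exceeds the identifiable subspace dimension")
        b = rigid_motion_basis(mean_shape)
        g = g - b @ (b.T @ g)
    q, rr = np.linalg.qr(g)
    if np.any(np.abs(np.diag(rr)) < 1e-12):
        raise ShapePoseError("degenerate random draws; could not orthonormalise")
    signs = np.sign(np.diag(rr))
    return q * signs


@dataclass
class ContaminationSpec:
    """Noise and contamination parameters of a simulated dataset.

    ``p_op``/``p_mp`` give the probability that a pose contains at least one
    outlier / missing point; ``p_oep``/``p_mep`` the per-point contamination
    probability inside such poses (one point is always forced so the
    pose-level probability is exact).  Outliers are additive Gaussian
    displacements of scale ``sigma_o``; the base measurement noise has scale
    ``sigma_n``.  A point that is both displaced and missing counts as
    missing only.
    """

    sigma_n: float = 0.1
    sigma_o: float = 1.0
    p_op: float = 0.0
    p_oep: float = 0.15
    p_mp: float = 0.0
    p_mep: float = 0.15
    seed: int = 0

    def validate(self):
        for name in ("p_op", "p_oep", "p_mp", "p_mep"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ShapePoseError(f"{name} must be in [0, 1], got {v}")
        if self.sigma_n < 0:
            raise ShapePoseError("sigma_n must be nonnegative")
        if self.p_op > 0:
            if self.p_oep <= 0:
                raise ShapePoseError("p_oep must be in (0, 1] when outliers are requested")
            if self.sigma_o <= self.sigma_n:
                raise ShapePoseError("sigma_o must exceed sigma_n when outliers are requested")
        if self.p_mp > 0 and self.p_mep <= 0:
            raise ShapePoseError("p_mep must be in (0, 1] when missing data are requested")


@dataclass
class SimulatedTruth:
    """Ground truth recorded alongside a contaminated dataset.

    ``clean`` is noise-free in the original frame; ``noisy`` adds the
    measurement noise (the contaminated data differ from ``noisy`` exactly
    on outlier-mask entries, plus NaN at missing-mask entries).
    ``aligned_clean`` holds the deformed shapes before rotation/translation.
    """

    clean: np.ndarray            # (n, n_points, d) original frame, noise-free
    noisy: np.ndarray            # (n, n_points, d) clean + measurement noise
    aligned_clean: np.ndarray    # (n, n_points, d) pre-rotation deformed shapes
    mean_shape: np.ndarray       # (n_points, d)
    eigenposes: np.ndarray       # (n_points*d, n_ep)
    b: np.ndarray                # (n, n_ep)
    rotations: np.ndarray        # (n, d, d), model frame -> original
    translations: np.ndarray     # (n, d)
    outlier_mask: np.ndarray     # (n, n_points) bool
    missing_mask: np.ndarray     # (n, n_points) bool

    @property
    def n_ep(self) -> int:
        return self.eigenposes.shape[1]


def _bernoulli_with_forced_hit(rng, n_rows, n_cols, row_prob, col_prob):
    rows = rng.random(n_rows) < row_prob
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    for i in np.flatnonzero(rows):
        flags = rng.random(n_cols) < col_prob
        if not flags.any():
            flags[rng.integers(n_cols)] = True
        mask[i] = flags
    return mask


def simulate_dataset(
    shape: np.ndarray,
    eigenposes: np.ndarray,
    n_poses: int,
    b_scales: np.ndarray,
    spec: ContaminationSpec,
    translation_scale: float = 5.0,
    rng: np.random.Generator | None = None,
) -> tuple[PoseDataset, SimulatedTruth]:
    """Draw a contaminated dataset and its ground truth.

    Shape parameters are independent zero-mean Gaussians with SDs
    ``b_scales``; each pose receives an independent uniform rotation and a
    Gaussian translation, then isotropic noise and the contamination
    described by ``spec``.
    """
    spec.validate()
    shape = np.asarray(shape, dtype=float)
    n_points, d = shape.shape
    p = n_points * d
    eigenposes = np.asarray(eigenposes, dtype=float)
    n_ep = eigenposes.shape[1]
    b_scales = np.asarray(b_scales, dtype=float).reshape(-1)
    if b_scales.shape[0] != n_ep:
        raise ShapePoseError(
            f"b_scales length {b_scales.shape[0]} does not match n_ep {n_ep}"
        )
    if eigenposes.shape[0] != p:
        raise ShapePoseError("eigenpose matrix does not match shape dimensions")
    rng = np.random.default_rng(spec.seed) if rng is None else rng

    b = rng.standard_normal((n_poses, n_ep)) * b_scales
    aligned_clean = (shape.reshape(-1)[None, :] + b @ eigenposes.T).reshape(
        n_poses, n_points, d
    )
    rotations = special_ortho_group.rvs(dim=d, size=n_poses, random_state=rng)
    rotations = rotations.reshape(n_poses, d, d)
    translations = translation_scale * rng.standard_normal((n_poses, d))
    clean = (
        np.einsum("nab,npb->npa", rotations, aligned_clean)
        + translations[:, None, :]
    )
    noisy = clean + rng.normal(0.0, spec.sigma_n, size=clean.shape)

    outlier_mask = _bernoulli_with_forced_hit(rng, n_poses, n_points, spec.p_op, spec.p_oep)
    missing_mask = _bernoulli_with_forced_hit(rng, n_poses, n_points, spec.p_mp, spec.p_mep)
    outlier_mask &= ~missing_mask  # missing wins on overlap

    contaminated = noisy.copy()
    n_out = int(outlier_mask.sum())
    if n_out:
        contaminated[outlier_mask] += rng.normal(0.0, spec.sigma_o, size=(n_out, d))
    contaminated[missing_mask] = np.nan

    dataset = PoseDataset(coords=contaminated, missing_mask=missing_mask)
    truth = SimulatedTruth(
        clean=clean,
        noisy=noisy,
        aligned_clean=aligned_clean,
        mean_shape=shape,
        eigenposes=eigenposes,
        b=b,
        rotations=rotations,
        translations=translations,
        outlier_mask=outlier_mask,
        missing_mask=missing_mask,
    )
    return dataset, truth


DEFAULT_P_OP_GRID = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
DEFAULT_P_OEP_GRID = (0.05, 0.15, 0.25)


def contamination_grid(
    shape: np.ndarray,
    eigenposes: np.ndarray,
    n_poses: int,
    b_scales: np.ndarray,
    base_spec: ContaminationSpec,
    p_op_values=DEFAULT_P_OP_GRID,
    p_oep_values=DEFAULT_P_OEP_GRID,
    p_mp_values=(0.0,),
    p_mep_values=(0.0,),
    n_reps: int = 1,
    base_seed: int = 0,
):
    """Iterate over the contamination cross-product used for recovery curves.

    Yields ``(spec, dataset, truth)`` for every combination of the four
    contamination levels and repetition, with reproducible per-cell seeds.
    """
    counter = 0
    for p_op, p_oep, p_mp, p_mep in itertools.product(
        p_op_values, p_oep_values, p_mp_values, p_mep_values
    ):
        for rep in range(n_reps):
            spec = replace(
                base_spec,
                p_op=p_op, p_oep=p_oep, p_mp=p_mp, p_mep=p_mep,
                seed=base_seed + counter,
            )
            counter += 1
            dataset, truth = simulate_dataset(shape, eigenposes, n_poses, b_scales, spec)
            yield spec, dataset, truth


def default_b_scales(n_ep: int, top: float = 1.0, decay: float = 0.8) -> np.ndarray:
    """Geometrically decaying shape-parameter SDs (well-ordered eigenvalues)."""
    return top * decay ** np.arange(n_ep)


__all__ = [
    "make_shape",
    "rigid_motion_basis",
    "make_eigenposes",
    "ContaminationSpec",
    "SimulatedTruth",
    "simulate_dataset",
    "contamination_grid",
    "default_b_scales",
    "DEFAULT_P_OP_GRID",
    "DEFAULT_P_OEP_GRID",
]
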