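"""Performance metrics, estimator ablations and resampling convergence.

Three metrics quantify recovery against simulation ground truth: RMSE over
coordinates, the absolute scalar product between matched true and estimated
deformation modes (after rotating the estimated modes into the truth frame
via the mean-shape alignment), and the absolute Pearson correlation between
true and estimated shape parameters.
"""

from __future__ import annotations

from dataclasses import replace as dc_replace

import numpy as np
import pandas as pd

from .alignment import procrustes_align
from .datamodel import PoseDataset, ShapeModel, ShapePoseError
from .simulate import SimulatedTruth
from .ssm_fit import FitConfig, FitResult, fit_ssm


def _as_coords_and_mask(x):
    if isinstance(x, PoseDataset):
        return x.coords, x.missing_mask
    arr = np.asarray(x, dtype=float)
    return arr, ~np.isfinite(arr).all(axis=2)


def rmse(a, b, scope: str = "all", point_mask: np.ndarray | None = None) -> float:
    """Root-mean-square error between two datasets over included coordinates.

    ``scope="all"`` includes every point observed in both inputs;
    ``scope="masked_only"`` restricts further to ``point_mask`` (defaulting
    to the union of the two missing masks).  Poses with missing data simply
    contribute their observed entries.
    """
    ca, ma = _as_coords_and_mask(a)
    cb, mb = _as_coords_and_mask(b)
    if ca.shape != cb.shape:
        raise ShapePoseError(f"shape mismatch: {ca.shape} vs {cb.shape}")
    include = ~ma & ~mb
    if scope == "masked_only":
        if point_mask is None:
            point_mask = ma | mb
        include &= np.asarray(point_mask, bool)
    elif scope == "all":
        if point_mask is not None:
            include &= np.asarray(point_mask, bool)
    else:
        raise ShapePoseError(f"unknown scope {scope!r}")
    if not include.any():
        raise ShapePoseError("no commonly observed coordinates to compare")
    diff = ca[include] - cb[include]
    return float(np.sqrt(np.mean(diff ** 2)))


def mean_alignment_rotation(shape_est: np.ndarray, shape_true: np.ndarray) -> np.ndarray:
    """Rotation taking the estimated mean shape frame into the truth frame."""
    _, transform, _ = procrustes_align(shape_est, shape_true, policy="rigid")
    return transform.rotation


def rotate_eigenposes(eigenposes: np.ndarray, rotation: np.ndarray, d: int) -> np.ndarray:
    """Apply a frame rotation to each vectorised deformation mode."""
    p, k = eigenposes.shape
    modes = eigenposes.T.reshape(k, p // d, d)
    return np.einsum("ab,kpb->kpa", rotation, modes).reshape(k, p).T


def eigenpose_similarity(
    p_true: np.ndarray,
    p_est: np.ndarray,
    matching: str = "rank",
) -> np.ndarray:
    """Absolute scalar products between matched true and estimated modes.

    ``matching="rank"`` pairs columns in order (eigenvalue rank);
    ``"greedy"`` assigns each true mode its best remaining |dot| partner,
    which is robust when adjacent eigenvalues are nearly degenerate.
    Inputs must already live in a common frame.
    """
    p_true = np.asarray(p_true, dtype=float)
    p_est = np.asarray(p_est, dtype=float)
    if p_true.shape != p_est.shape:
        raise ShapePoseError("eigenpose matrices must have matching shapes")
    dots = np.abs(p_true.T @ p_est)
    k = dots.shape[0]
    if matching == "rank":
        return np.diag(dots).copy()
    if matching == "greedy":
        sp = np.zeros(k)
        remaining = list(range(k))
        for j in range(k):
            best = max(remaining, key=lambda c: dots[j, c])
            sp[j] = dots[j, best]
            remaining.remove(best)
        return sp
    raise ShapePoseError(f"unknown matching {matching!r}")


def _auto_matching(eigenvalues: np.ndarray) -> str:
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size < 2:
        return "rank"
    gaps = np.abs(np.diff(ev)) / np.maximum(np.abs(ev[:-1]), np.finfo(float).tiny)
    return "greedy" if np.any(gaps < 0.05) else "rank"


def model_similarity(
    truth: SimulatedTruth,
    model: ShapeModel,
    matching: str = "auto",
) -> np.ndarray:
    """Matched |SP| between a fitted model and simulation ground truth.

    Rotates the estimated modes into the truth frame via the mean-shape
    alignment before comparing.  ``matching="auto"`` falls back to greedy
    assignment when adjacent fitted eigenvalues differ by less than 5%.
    """
    k = min(truth.n_ep, model.r)
    rot = mean_alignment_rotation(model.mean_shape(), truth.mean_shape)
    est = rotate_eigenposes(model.eigenposes[:, :k], rot, model.d)
    if matching == "auto":
        matching = _auto_matching(model.eigenvalues[:k])
    return eigenpose_similarity(truth.eigenposes[:, :k], est, matching=matching)


def model_pair_similarity(model_a: ShapeModel, model_b: ShapeModel) -> np.ndarray:
    """Matched |SP| between two fitted models (b rotated into a's frame)."""
    k = min(model_a.r, model_b.r)
    rot = mean_alignment_rotation(model_b.mean_shape(), model_a.mean_shape())
    est = rotate_eigenposes(model_b.eigenposes[:, :k], rot, model_b.d)
    return eigenpose_similarity(model_a.eigenposes[:, :k], est, matching="rank")


def shape_param_correlation(b_true: np.ndarray, b_est: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation per matched deformation mode.

    Sign and affine rescaling of either argument leave the result unchanged
    (mode signs are inherently ambiguous).
    """
    b_true = np.asarray(b_true, dtype=float)
    b_est = np.asarray(b_est, dtype=float)
    if b_true.shape != b_est.shape:
        raise ShapePoseError("shape parameter matrices must match")
    out = np.zeros(b_true.shape[1])
    for j in range(b_true.shape[1]):
        x, y = b_true[:, j], b_est[:, j]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            out[j] = 0.0
            continue
        out[j] = abs(np.corrcoef(x, y)[0, 1])
    return out


def reconstruction_mode_correlation(
    truth: SimulatedTruth,
    recovered: PoseDataset,
) -> np.ndarray:
    """|Pearson| between true shape parameters and those of recovered poses.

    Each recovered pose is aligned to the true mean shape and projected onto
    the true deformation modes; the result measures how faithfully the
    reconstruction preserves each mode of shape variation, independent of
    the fitted model's basis (whose accuracy the scalar product measures).
    Frames that could not be completed are skipped.
    """
    from .alignment import align_stack

    res = align_stack(
        recovered.coords, recovered.missing_mask, truth.mean_shape, None
    )
    x = res.aligned.reshape(recovered.n_frames, -1)
    ok = res.valid & np.isfinite(x).all(axis=1)
    if not ok.any():
        raise ShapePoseError("no complete recovered poses to correlate")
    b_est = (x[ok] - truth.mean_shape.reshape(-1)) @ truth.eigenposes
    return shape_param_correlation(truth.b[ok], b_est)


def naive_fit(dataset: PoseDataset, cfg: FitConfig, ablation: str) -> FitResult:
    """Single-switch ablations of the robust fit.

    ``mu_naive`` replaces the consensus mean with a plain mask-aware mean of
    poses aligned to a random complete reference; ``C_naive`` replaces the
    robust covariance with the maximum-likelihood sample covariance.
    Everything else is identical to :func:`shapepose.ssm_fit.fit_ssm`.
    """
    if ablation == "mu_naive":
        return fit_ssm(dataset, cfg, mean_method="random_reference")
    if ablation in ("C_naive", "c_naive"):
        return fit_ssm(dataset, cfg, cov_method="sample")
    raise ShapePoseError(f"unknown ablation {ablation!r}; use mu_naive or C_naive")


def convergence_analysis(
    dataset: PoseDataset,
    set_sizes,
    n_resamples: int = 10,
    cfg: FitConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Stability of the fitted deformation modes under resampling.

    For each set size, draws ``n_resamples`` independent random subsets,
    fits a model on each, and reports mean and SD of the matched |SP|
    over all fit pairs.  Approaches 1 when fits agree.
    """
    cfg = FitConfig() if cfg is None else cfg
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    rows = []
    for size in set_sizes:
        size = int(size)
        if size > dataset.n_frames:
            raise ShapePoseError(f"set size {size} exceeds dataset size {dataset.n_frames}")
        models = []
        for _ in range(n_resamples):
            idx = rng.choice(dataset.n_frames, size=size, replace=False)
            sub_cfg = dc_replace(cfg, seed=int(rng.integers(2 ** 31)))
            models.append(fit_ssm(dataset.subset(idx), sub_cfg).model)
        sims = []
        for i in range(len(models)):
            for j in range(i + 1, len(models)):
                sims.append(model_pair_similarity(models[i], models[j]).mean())
        sims = np.asarray(sims)
        rows.append(
            dict(
                set_size=size,
                mean_sp=float(sims.mean()),
                sd_sp=float(sims.std(ddof=1)) if sims.size > 1 else 0.0,
                n_pairs=int(sims.size),
                n_resamples=n_resamples,
            )
        )
    return pd.DataFrame(rows)


__all__ = [
    "rmse",
    "mean_alignment_rotation",
    "rotate_eigenposes",
    "eigenpose_similarity",
    "model_similarity",
    "model_pair_similarity",
    "shape_param_correlation",
    "reconstruction_mode_correlation",
    "naive_fit",
    "convergence_analysis",
]
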