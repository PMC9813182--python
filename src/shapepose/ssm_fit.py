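"""Unsupervised estimation of the statistical shape model.

The fit chains four stages: a RANSAC-style consensus choice of a complete
reference pose, mask-aware averaging of all poses aligned to that reference
(robust mean), K-nearest-neighbour pre-imputation of missing landmarks, and
robust covariance estimation (Orthogonalized Gnanadesikan-Kettenring)
followed by a probabilistic-PCA regularisation that floors the trailing
eigenvalues at their average to obtain a full-rank SPD covariance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .alignment import DEFAULT_MIN_COMMON, align_stack, pairwise_distance_quartile
from .datamodel import (
    ModelError,
    PoseDataset,
    RigidTransform,
    ShapeModel,
    ShapePoseError,
)


@dataclass
class FitConfig:
    """Configuration of the unsupervised shape-model fit.

    Defaults reproduce the reference protocol: 100 consensus iterations on
    50% subsamples, neighbour threshold auto-tuned to the first quartile of
    pairwise aligned distances, K=5 imputation neighbours, and a fixed rank
    of 5 deformation modes.
    """

    n_ransac_iter: int = 100
    subsample_frac: float = 0.5
    neighbour_threshold: float | str = "auto"
    knn_k: int = 5
    rank_policy: str = "fixed_r"          # or "variance_fraction"
    r: float = 5
    seed: int = 0
    policy: str = "rigid"
    min_common: int = DEFAULT_MIN_COMMON
    n_threshold_pairs: int = 2000
    mean_inclusion_factor: float = 5.0
    refine_to_mean: bool = False
    ogk_beta: float = 0.9
    ogk_reweight: bool = True
    ogk_iters: int = 1

    def validate(self):
        if not 0 < self.subsample_frac <= 1:
            raise ShapePoseError("subsample_frac must be in (0, 1]")
        if self.n_ransac_iter < 1:
            raise ShapePoseError("n_ransac_iter must be >= 1")
        if self.knn_k < 1:
            raise ShapePoseError("knn_k must be >= 1")
        if self.rank_policy not in ("fixed_r", "variance_fraction"):
            raise ShapePoseError(f"unknown rank_policy {self.rank_policy!r}")
        if self.rank_policy == "variance_fraction" and not 0 < self.r < 1:
            raise ShapePoseError("variance_fraction target must be in (0, 1)")
        if isinstance(self.neighbour_threshold, str) and self.neighbour_threshold != "auto":
            raise ShapePoseError("neighbour_threshold must be a number or 'auto'")
        if self.policy not in ("rigid", "similarity"):
            raise ShapePoseError(f"unknown alignment policy {self.policy!r}")


@dataclass
class MeanPoseResult:
    mu: np.ndarray                      # (n_points*d,)
    transforms: list[RigidTransform]    # original frame -> model frame
    aligned: PoseDataset
    valid: np.ndarray                   # (n_frames,) bool, alignable to reference
    reference_index: int
    reference_score: int | None
    threshold: float | None


@dataclass
class FitResult:
    model: ShapeModel
    transforms: list[RigidTransform]
    aligned: PoseDataset
    valid: np.ndarray
    report: dict


def _resolve_threshold(dataset, cfg, rng):
    if cfg.neighbour_threshold == "auto":
        return pairwise_distance_quartile(
            dataset, n_pairs=cfg.n_threshold_pairs, rng=rng,
            policy=cfg.policy, min_common=cfg.min_common,
        )
    return float(cfg.neighbour_threshold)


def select_reference_pose(
    dataset: PoseDataset,
    cfg: FitConfig,
    rng: np.random.Generator | None = None,
    threshold: float | None = None,
) -> tuple[int, int]:
    """Consensus (RANSAC-style) choice of the reference pose.

    Each iteration draws a complete candidate reference and a fresh random
    subsample, aligns every subsample pose to the candidate, and scores the
    candidate by the number of aligned poses closer than the neighbour
    threshold.  Ties are broken by smaller mean residual, then lower index.

    Returns the winning frame index and its score.
    """
    cfg.validate()
    if dataset.n_frames < 10:
        raise ShapePoseError(f"dataset too small ({dataset.n_frames} poses; >= 10 required)")
    complete = np.flatnonzero(dataset.complete())
    if complete.size == 0:
        raise ShapePoseError("no complete pose available to serve as reference")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if threshold is None:
        threshold = _resolve_threshold(dataset, cfg, rng)

    n = dataset.n_frames
    n_sub = math.ceil(cfg.subsample_frac * n)
    best = None  # (score, -mean_residual comparator handled manually)
    for _ in range(cfg.n_ransac_iter):
        cand = int(rng.choice(complete))
        sub = rng.choice(n, size=n_sub, replace=False)
        res = align_stack(
            dataset.coords[sub], dataset.missing_mask[sub],
            dataset.coords[cand], dataset.missing_mask[cand],
            policy=cfg.policy, min_common=cfg.min_common,
        )
        hits = res.valid & (res.residuals <= threshold + 1e-12)
        score = int(hits.sum())
        mean_res = float(np.nanmean(res.residuals)) if res.valid.any() else np.inf
        key = (score, -mean_res, -cand)
        if best is None or key > best[0]:
            best = (key, cand, score)
    return best[1], best[2]


def estimate_mean_pose(
    dataset: PoseDataset,
    cfg: FitConfig,
    reference_index: int | None = None,
    rng: np.random.Generator | None = None,
    threshold: float | None = None,
) -> MeanPoseResult:
    """Robust mean pose: align everything to the consensus reference, average.

    The mean is computed per coordinate over observed entries only, over the
    poses aligned with the reference — poses whose alignment residual
    exceeds ``mean_inclusion_factor`` times the neighbour threshold (a
    different body shape, not a deformation of this one) are excluded from
    the average.  Poses that cannot be aligned at all (too few common
    points) are flagged in ``valid`` rather than dropped.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    score = None
    if reference_index is None:
        if threshold is None:
            threshold = _resolve_threshold(dataset, cfg, rng)
        reference_index, score = select_reference_pose(dataset, cfg, rng=rng, threshold=threshold)

    def _included(res):
        if threshold is None or not np.isfinite(cfg.mean_inclusion_factor):
            return res.valid
        cut = cfg.mean_inclusion_factor * threshold
        include = res.valid & (res.residuals <= cut)
        return include if include.any() else res.valid

    ref_coords = dataset.coords[reference_index]
    ref_mask = dataset.missing_mask[reference_index]
    res = align_stack(
        dataset.coords, dataset.missing_mask, ref_coords, ref_mask,
        policy=cfg.policy, min_common=cfg.min_common,
    )
    mu = _masked_mean(res.aligned, dataset.missing_mask, _included(res))

    if cfg.refine_to_mean:
        res = align_stack(
            dataset.coords, dataset.missing_mask,
            mu.reshape(dataset.n_points, dataset.d), None,
            policy=cfg.policy, min_common=cfg.min_common,
        )
        mu = _masked_mean(res.aligned, dataset.missing_mask, _included(res))

    aligned = PoseDataset(
        coords=np.where(res.valid[:, None, None], res.aligned, np.nan),
        missing_mask=dataset.missing_mask | ~res.valid[:, None],
        point_names=list(dataset.point_names),
        frame_ids=dataset.frame_ids.copy(),
    )
    return MeanPoseResult(
        mu=mu,
        transforms=res.transforms(),
        aligned=aligned,
        valid=res.valid.copy(),
        reference_index=int(reference_index),
        reference_score=score,
        threshold=threshold,
    )


def _masked_mean(aligned, missing_mask, valid):
    obs = (~missing_mask) & valid[:, None]
    w = obs.astype(float)[:, :, None]
    x = np.where(w > 0, aligned, 0.0)
    counts = w.sum(axis=0)
    if np.any(counts == 0):
        never = np.flatnonzero(counts[:, 0] == 0)
        raise ShapePoseError(f"points never observed among alignable poses: {never.tolist()}")
    return (x.sum(axis=0) / counts).reshape(-1)


def knn_impute(
    dataset: PoseDataset,
    k: int = 5,
    policy: str = "rigid",
    min_common: int = DEFAULT_MIN_COMMON,
) -> PoseDataset:
    """Fill missing landmarks by averaging the K nearest recovering poses.

    For each target pose with missing points, candidate recovering poses are
    all poses observed at every one of the target's missing positions; each
    is aligned to the target, ranked by RMS distance over the commonly
    observed points, and the nearest ``min(k, available)`` are averaged at
    the missing positions.  Observed entries are never modified.
    """
    out = dataset.copy()
    obs = ~dataset.missing_mask
    targets = np.flatnonzero(dataset.missing_mask.any(axis=1))
    for ti in targets:
        miss = np.flatnonzero(dataset.missing_mask[ti])
        cand = np.flatnonzero(obs[:, miss].all(axis=1))
        cand = cand[cand != ti]
        if cand.size == 0:
            raise ShapePoseError(
                f"no recovering poses for frame {int(dataset.frame_ids[ti])}, "
                f"missing point(s) {miss.tolist()}"
            )
        res = align_stack(
            dataset.coords[cand], dataset.missing_mask[cand],
            dataset.coords[ti], dataset.missing_mask[ti],
            policy=policy, min_common=min_common,
        )
        ok = np.flatnonzero(res.valid)
        if ok.size == 0:
            raise ShapePoseError(
                f"no alignable recovering poses for frame {int(dataset.frame_ids[ti])}"
            )
        order = ok[np.argsort(res.residuals[ok], kind="stable")]
        take = order[: min(k, order.size)]
        out.coords[ti, miss] = res.aligned[take][:, miss, :].mean(axis=0)
        out.missing_mask[ti, miss] = False
    return out


# ---------------------------------------------------------------------------
# Robust covariance (Orthogonalized Gnanadesikan-Kettenring)
# ---------------------------------------------------------------------------

_MAD_CONSISTENCY = 1.482602218505602  # 1 / Phi^{-1}(3/4)


def _mad_location_scale(x):
    """Column-wise median and consistency-corrected MAD scale."""
    loc = np.median(x, axis=0)
    scale = _MAD_CONSISTENCY * np.median(np.abs(x - loc), axis=0)
    return loc, scale


def ogk_covariance(
    data: np.ndarray,
    beta: float = 0.9,
    reweight: bool = True,
    n_iters: int = 1,
    return_location: bool = False,
):
    """Orthogonalized Gnanadesikan-Kettenring robust covariance estimate.

    Deterministic pipeline: MAD-standardise columns, build the pairwise GK
    matrix ``u_jk = (s(yj+yk)^2 - s(yj-yk)^2) / 4``, orthogonalise through its
    eigenbasis, take robust scales in that basis and transform back.  A final
    hard-rejection reweighting step (chi-square cutoff at ``beta``, adaptively
    rescaled by the median squared distance) with a Gaussian consistency
    correction makes the estimator consistent at the normal model.

    Parameters
    ----------
    data : ndarray (n, p)
        Complete data matrix, n > 2.
    beta : float
        Nominal retention quantile of the reweighting step.
    reweight : bool
        Apply the reweighting step (recommended).
    n_iters : int
        Number of orthogonalisation sweeps (1 is standard).
    return_location : bool
        Also return the robust location estimate.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if n <= 2:
        raise ShapePoseError("OGK needs more than 2 observations")
    if not np.isfinite(x).all():
        raise ShapePoseError("OGK requires complete (finite) data")

    a = np.eye(p)
    y = x
    for _ in range(n_iters):
        _, s = _mad_location_scale(y)
        if np.any(s == 0):
            floor = 1e-12 * max(s.max(), 1.0)
            warnings.warn(
                "degenerate coordinate(s) with zero MAD; flooring robust scale",
                RuntimeWarning,
                stacklevel=2,
            )
            s = np.where(s == 0, floor, s)
        y1 = y / s
        plus = y1[:, :, None] + y1[:, None, :]
        minus = y1[:, :, None] - y1[:, None, :]
        _, sp = _mad_location_scale(plus.reshape(n, -1))
        _, sm = _mad_location_scale(minus.reshape(n, -1))
        u = 0.25 * (sp ** 2 - sm ** 2).reshape(p, p)
        u = 0.5 * (u + u.T)
        np.fill_diagonal(u, 1.0)
        _, evecs = np.linalg.eigh(u)
        y = y1 @ evecs
        a = a @ (s[:, None] * evecs)

    loc_z, s_z = _mad_location_scale(y)
    s_z = np.where(s_z == 0, 1e-12 * max(s_z.max(), 1.0), s_z)
    cov = (a * s_z[None, :] ** 2) @ a.T
    cov = 0.5 * (cov + cov.T)
    center = a @ loc_z

    if reweight:
        diff = x - center
        try:
            factor = cho_factor(cov)
            d2 = np.einsum("ij,ji->i", diff, cho_solve(factor, diff.T))
        except np.linalg.LinAlgError:
            d2 = np.einsum("ij,ji->i", diff, np.linalg.pinv(cov) @ diff.T)
        cutoff = stats.chi2.ppf(beta, p) * np.median(d2) / stats.chi2.ppf(0.5, p)
        keep = d2 <= cutoff
        if keep.sum() > p + 1:
            xk = x[keep]
            center = xk.mean(axis=0)
            resid = xk - center
            raw = resid.T @ resid / keep.sum()
            # consistency at the Gaussian model for hard truncation at beta
            q = stats.chi2.ppf(beta, p)
            correction = stats.chi2.cdf(q, p + 2) / beta
            cov = raw / correction

    cov = 0.5 * (cov + cov.T)
    if return_location:
        return cov, center
    return cov


def ppca_regularize(
    c: np.ndarray,
    rank_policy: str = "fixed_r",
    r_or_frac: float = 5,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Replace the trailing eigenvalues of a covariance by their average.

    Eigendecomposes ``c``, keeps the top-``r`` eigenpairs, and sets the noise
    floor ``sigma2`` to the mean of the remaining ``p - r`` eigenvalues.
    Under the ``variance_fraction`` policy, ``r`` is the smallest rank whose
    cumulative eigenvalue share reaches the target.  ``sigma2`` is floored at
    ``1e-12 * trace(c) / p`` so the regularised covariance is always SPD.

    Returns ``(V, eigenvalues, sigma2)`` with orthonormal columns in ``V``
    and nonincreasing eigenvalues.
    """
    c = np.asarray(c, dtype=float)
    p = c.shape[0]
    if c.shape != (p, p):
        raise ShapePoseError("covariance must be square")
    if not np.allclose(c, c.T, atol=1e-8 * max(1.0, np.abs(c).max())):
        raise ShapePoseError("covariance must be symmetric")
    evals, evecs = np.linalg.eigh(0.5 * (c + c.T))
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    if rank_policy == "variance_fraction":
        if not 0 < r_or_frac < 1:
            raise ShapePoseError("variance fraction target must be in (0, 1)")
        total = evals.sum()
        share = np.cumsum(evals) / total if total > 0 else np.ones(p)
        r = int(np.searchsorted(share, r_or_frac) + 1)
        r = min(r, p - 1)
    elif rank_policy == "fixed_r":
        r = int(r_or_frac)
    else:
        raise ShapePoseError(f"unknown rank_policy {rank_policy!r}")
    if r < 1:
        raise ModelError("rank must be >= 1")
    if r >= p:
        raise ModelError(f"rank {r} leaves no noise subspace (p = {p})")

    sigma2 = float(np.mean(evals[r:]))
    floor = 1e-12 * max(np.trace(c), 0.0) / p
    sigma2 = max(sigma2, floor, np.finfo(float).tiny)
    v = evecs[:, :r]
    # deterministic sign: largest-magnitude component positive
    idx = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[idx, np.arange(r)])
    signs[signs == 0] = 1.0
    v = v * signs
    lead = np.maximum(evals[:r], sigma2)
    return v, lead, sigma2


def fit_ssm(
    dataset: PoseDataset,
    cfg: FitConfig | None = None,
    mean_method: str = "ransac",
    cov_method: str = "ogk",
) -> FitResult:
    """Full unsupervised shape-model fit.

    Chains consensus mean estimation, KNN pre-imputation, robust (OGK)
    covariance on the vectorised aligned poses, and PPCA regularisation.
    ``mean_method`` / ``cov_method`` expose the naive ablations
    (``"random_reference"`` and ``"sample"``).
    """
    cfg = FitConfig() if cfg is None else cfg
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    threshold = _resolve_threshold(dataset, cfg, rng)

    if mean_method == "ransac":
        ref_idx, score = select_reference_pose(dataset, cfg, rng=rng, threshold=threshold)
    elif mean_method == "random_reference":
        complete = np.flatnonzero(dataset.complete())
        if complete.size == 0:
            raise ShapePoseError("no complete pose available to serve as reference")
        ref_idx, score = int(rng.choice(complete)), None
    else:
        raise ShapePoseError(f"unknown mean_method {mean_method!r}")

    mean_cfg = cfg
    if mean_method == "random_reference":
        # the naive ablation takes the plain mean of all aligned poses
        from dataclasses import replace as _replace

        mean_cfg = _replace(cfg, mean_inclusion_factor=np.inf)
    mres = estimate_mean_pose(
        dataset, mean_cfg, reference_index=ref_idx, rng=rng, threshold=threshold
    )

    valid_idx = np.flatnonzero(mres.valid)
    fit_ds = mres.aligned.subset(valid_idx)
    if fit_ds.missing_mask.any():
        fit_ds = knn_impute(fit_ds, k=cfg.knn_k, policy=cfg.policy, min_common=cfg.min_common)
    xmat = fit_ds.vectors()

    if cov_method == "ogk":
        cov = ogk_covariance(
            xmat, beta=cfg.ogk_beta, reweight=cfg.ogk_reweight, n_iters=cfg.ogk_iters
        )
    elif cov_method == "sample":
        centered = xmat - xmat.mean(axis=0)
        cov = centered.T @ centered / xmat.shape[0]
    else:
        raise ShapePoseError(f"unknown cov_method {cov_method!r}")

    v, evals, sigma2 = ppca_regularize(cov, cfg.rank_policy, cfg.r)
    model = ShapeModel(
        mu=mres.mu,
        eigenposes=v,
        eigenvalues=evals,
        sigma2=sigma2,
        d=dataset.d,
        alignment_policy=cfg.policy,
    )

    full_evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    total = full_evals.sum()
    report = {
        "reference_index": int(mres.reference_index),
        "reference_score": mres.reference_score,
        "neighbour_threshold": float(threshold),
        "n_frames": int(dataset.n_frames),
        "n_unalignable": int((~mres.valid).sum()),
        "unalignable_frames": dataset.frame_ids[~mres.valid].tolist(),
        "rank": int(model.r),
        "sigma2": float(sigma2),
        "explained_variance": (np.cumsum(full_evals) / total).tolist() if total > 0 else [],
        "mean_method": mean_method,
        "cov_method": cov_method,
        "config": asdict(cfg),
    }
    return FitResult(
        model=model,
        transforms=mres.transforms,
        aligned=mres.aligned,
        valid=mres.valid,
        report=report,
    )


__all__ = [
    "FitConfig",
    "MeanPoseResult",
    "FitResult",
    "select_reference_pose",
    "estimate_mean_pose",
    "knn_impute",
    "ogk_covariance",
    "ppca_regularize",
    "fit_ssm",
]
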