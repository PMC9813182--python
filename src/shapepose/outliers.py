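"""Model-based outlier detection for landmark poses.

A pose aligned to the model frame is scored by its squared Mahalanobis
distance to the model mean; under the Gaussian shape model this statistic is
chi-square distributed with one degree of freedom per observed coordinate.
Poses exceeding the (1 - alpha) quantile are searched greedily for the
responsible landmarks: the point whose exclusion most reduces the distance
is removed, the threshold's degrees of freedom are adjusted to the retained
coordinates, and the loop stops once the distance falls below threshold
(``recovered``) or no more points may be removed (``exhausted``).

By default the pose is re-aligned to the model mean on the retained points
at every exclusion step (``realign=True``): a single gross outlier corrupts
the initial Procrustes fit badly enough that, without re-alignment, the
distance of the remaining good points stays inflated and true outliers
cannot be isolated.  ``realign=False`` skips all alignment and treats the
input as already expressed in the model frame (the right choice for
calibration studies on model-generated data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .alignment import DEFAULT_MIN_COMMON, align_stack, procrustes_align
from .datamodel import (
    AlignmentError,
    ModelError,
    PoseDataset,
    ShapeModel,
    coord_indices,
)


def chi2_threshold(n_points_retained: int, d: int, alpha: float) -> float:
    """(1 - alpha) quantile of chi-square with ``d * n_points_retained`` df."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.chi2.ppf(1.0 - alpha, d * n_points_retained))


def mahalanobis_sq(
    x: np.ndarray,
    model: ShapeModel,
    points: np.ndarray | None = None,
    cov: np.ndarray | None = None,
) -> float:
    """Squared Mahalanobis distance of a (sub-)pose from the model mean.

    ``points`` selects the retained landmarks; the model mean and covariance
    are marginalised to their coordinates.  Solved via Cholesky, never an
    explicit inverse.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    if cov is None:
        cov = model.covariance()
    if points is None:
        idx = np.arange(model.n_coords)
    else:
        points = np.asarray(points, dtype=int)
        if points.size == 0:
            raise ModelError("point subset must be nonempty")
        idx = coord_indices(points, model.d)
    diff = x[idx] - model.mu[idx]
    sub = cov[np.ix_(idx, idx)]
    try:
        factor = cho_factor(sub)
    except np.linalg.LinAlgError as exc:
        raise ModelError("marginal covariance is not SPD (model invariant violated)") from exc
    return float(diff @ cho_solve(factor, diff))


@dataclass
class FrameOutlierRecord:
    """Per-frame trace of the greedy outlier search."""

    frame_index: int
    frame_id: int
    status: str                      # clean | recovered | exhausted
    initial_md2: float | None
    removed_points: list[int] = field(default_factory=list)
    md2_sequence: list[float] = field(default_factory=list)
    thresholds: list[float] = field(default_factory=list)


@dataclass
class OutlierReport:
    alpha: float
    realign: bool = True
    records: list[FrameOutlierRecord] = field(default_factory=list)

    def flagged_frames(self) -> np.ndarray:
        return np.array(
            [r.frame_index for r in self.records if r.removed_points], dtype=int
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            if not rec.md2_sequence:
                rows.append(
                    dict(frame=rec.frame_id, point=-1, iteration=0,
                         md2=np.nan, threshold=np.nan, status=rec.status)
                )
                continue
            removed = [-1] + rec.removed_points
            for it, (md2, thr) in enumerate(zip(rec.md2_sequence, rec.thresholds)):
                rows.append(
                    dict(frame=rec.frame_id, point=removed[it] if it < len(removed) else -1,
                         iteration=it, md2=md2, threshold=thr, status=rec.status)
                )
        return pd.DataFrame(rows, columns=["frame", "point", "iteration", "md2", "threshold", "status"])

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


def _complete_and_project(x, pts, model, cov):
    """Conditional completion of a model-frame pose observed on ``pts`` and
    its rank-r reconstruction (the model-consistent alignment target)."""
    all_points = np.arange(model.n_points)
    miss = np.setdiff1d(all_points, pts)
    xc = x.copy()
    if miss.size:
        m_idx = coord_indices(miss, model.d)
        in_idx = coord_indices(pts, model.d)
        c_in = cov[np.ix_(in_idx, in_idx)]
        sol = cho_solve(cho_factor(c_in), x[in_idx] - model.mu[in_idx])
        xc[m_idx] = model.mu[m_idx] + cov[np.ix_(m_idx, in_idx)] @ sol
    b = model.eigenposes.T @ (xc - model.mu)
    return (model.mu + model.eigenposes @ b).reshape(model.n_points, model.d)


def _subset_md2(coords, pts, model, cov, realign, mean_shape, min_points,
                model_iters: int = 2):
    """MD^2 of the sub-pose on ``pts``, optionally after re-alignment.

    With ``realign`` the pose is aligned to the model mean on ``pts`` and the
    alignment target is then refined against the model's rank-r
    reconstruction (``model_iters`` passes): aligning a deformed subset to
    the plain mean lets deformation leak into the fitted rotation, which
    would inflate the distance of genuinely clean poses.
    """
    if realign:
        mask = np.ones(model.n_points, dtype=bool)
        mask[pts] = False
        target = mean_shape
        x = None
        try:
            for _ in range(max(1, model_iters)):
                aligned, _, _ = procrustes_align(
                    coords, target, source_mask=mask, target_mask=None,
                    policy=model.alignment_policy, min_common=min_points,
                )
                x = aligned.reshape(-1)
                target = _complete_and_project(np.nan_to_num(x), pts, model, cov)
        except AlignmentError:
            return np.inf
    else:
        x = coords.reshape(-1)
    return mahalanobis_sq(x, model, pts, cov=cov)


def detect_outlier_points(
    pose: np.ndarray,
    model: ShapeModel,
    observed_points: np.ndarray | None = None,
    alpha: float = 0.01,
    max_removals: int | None = None,
    min_points: int = DEFAULT_MIN_COMMON,
    cov: np.ndarray | None = None,
    realign: bool = True,
) -> tuple[list[int], FrameOutlierRecord]:
    """Greedy identification of outlier landmarks in one pose.

    Parameters
    ----------
    pose : ndarray (n_points, d) or flat (n_points * d,)
        With ``realign=True`` any rigid frame is accepted (the pose is
        aligned to the model mean on the points under test at each step);
        with ``realign=False`` the pose must already be in the model frame.
    observed_points : ndarray of int, optional
        Landmark indices with observed coordinates; inferred from NaNs when
        omitted.
    alpha : float
        Significance level of the chi-square test.
    max_removals : int, optional
        Cap on removed points; defaults to ``n_observed - min_points``.
    min_points : int
        Minimum retained points (the alignment minimum).

    Returns the removed point indices (possibly empty) and the per-frame
    record with the tested distance/threshold trajectory.
    """
    coords = np.asarray(pose, dtype=float).reshape(model.n_points, model.d)
    if cov is None:
        cov = model.covariance()
    if observed_points is None:
        observed_points = np.flatnonzero(np.isfinite(coords).all(axis=1))
    mean_shape = model.mean_shape()
    retained = [int(i) for i in observed_points]
    rec = FrameOutlierRecord(frame_index=-1, frame_id=-1, status="clean", initial_md2=None)
    if len(retained) < min_points:
        rec.status = "exhausted"
        return [], rec

    md2 = _subset_md2(coords, retained, model, cov, realign, mean_shape, min_points)
    thr = chi2_threshold(len(retained), model.d, alpha)
    rec.initial_md2 = md2
    rec.md2_sequence.append(md2)
    rec.thresholds.append(thr)
    if md2 <= thr:
        return [], rec

    if max_removals is None:
        max_removals = len(retained) - min_points
    removed: list[int] = []
    while True:
        if len(retained) - 1 < min_points or len(removed) >= max_removals:
            rec.status = "exhausted"
            break
        best_j, best_md2 = None, np.inf
        for j in retained:
            sub = [q for q in retained if q != j]
            v = _subset_md2(coords, sub, model, cov, realign, mean_shape, min_points)
            if v < best_md2:
                best_j, best_md2 = j, v
        if best_j is None:
            rec.status = "exhausted"
            break
        retained.remove(best_j)
        removed.append(best_j)
        thr = chi2_threshold(len(retained), model.d, alpha)
        rec.md2_sequence.append(best_md2)
        rec.thresholds.append(thr)
        if best_md2 <= thr:
            rec.status = "recovered"
            break
    rec.removed_points = removed
    return removed, rec


def detect_dataset(
    dataset: PoseDataset,
    model: ShapeModel,
    transforms=None,
    alpha: float = 0.01,
    min_points: int = DEFAULT_MIN_COMMON,
    max_removals: int | None = None,
    realign: bool = True,
) -> tuple[PoseDataset, OutlierReport]:
    """Run the per-frame outlier search over a dataset.

    With ``realign=True`` (default) every pose is aligned to the model mean
    on the points under test, and ``transforms`` are ignored.  With
    ``realign=False``, ``transforms`` (e.g. from the fit) map each pose into
    the model frame; when omitted, a single alignment to the model mean on
    the observed points is used instead.

    Landmarks flagged in frames with status ``recovered`` are re-masked
    (converted to missing) in the returned working copy, which stays in the
    original coordinate frame; ``exhausted`` frames are left untouched.
    """
    cov = model.covariance()
    out = dataset.copy()
    report = OutlierReport(alpha=alpha, realign=realign)
    mean_shape = model.mean_shape()

    if realign:
        aligned_all = dataset.coords
    elif transforms is not None:
        aligned_all = np.stack(
            [transforms[i].apply(dataset.coords[i]) for i in range(dataset.n_frames)]
        )
    else:
        res = align_stack(
            dataset.coords, dataset.missing_mask, mean_shape, None,
            policy=model.alignment_policy, min_common=min_points,
        )
        aligned_all = res.aligned

    for i in range(dataset.n_frames):
        obs = np.flatnonzero(~dataset.missing_mask[i])
        pose = aligned_all[i]
        if obs.size < min_points or not np.isfinite(pose[obs]).all():
            rec = FrameOutlierRecord(
                frame_index=i, frame_id=int(dataset.frame_ids[i]),
                status="exhausted", initial_md2=None,
            )
            report.records.append(rec)
            continue
        removed, rec = detect_outlier_points(
            pose, model, observed_points=obs, alpha=alpha,
            max_removals=max_removals, min_points=min_points, cov=cov,
            realign=realign,
        )
        rec.frame_index = i
        rec.frame_id = int(dataset.frame_ids[i])
        report.records.append(rec)
        if removed and rec.status == "recovered":
            out.coords[i, removed] = np.nan
            out.missing_mask[i, removed] = True
    return out, report


__all__ = [
    "chi2_threshold",
    "mahalanobis_sq",
    "FrameOutlierRecord",
    "OutlierReport",
    "detect_outlier_points",
    "detect_dataset",
]
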