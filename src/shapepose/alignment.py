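"""Procrustes superimposition of partially observed poses.

The rigid (optionally similarity) transform is estimated on the commonly
observed points of source and target via SVD of their cross-covariance
(Kabsch), with reflections excluded by forcing ``det(R) = +1``, and is then
applied to *all* observed points of the source.  Distances between aligned
poses are root-mean-square over the common points, so poses with different
missing counts remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import AlignmentError, PoseDataset, RigidTransform, ShapePoseError

DEFAULT_MIN_COMMON = 3


@dataclass
class StackAlignment:
    """Result of aligning a stack of poses onto one reference pose."""

    aligned: np.ndarray        # (n, n_points, d); NaN where masked or invalid
    rotations: np.ndarray      # (n, d, d)
    translations: np.ndarray   # (n, d)
    scales: np.ndarray         # (n,)
    residuals: np.ndarray      # (n,) RMS over common points; NaN if invalid
    counts: np.ndarray         # (n,) number of common points used
    valid: np.ndarray          # (n,) bool

    def transform(self, i: int) -> RigidTransform:
        return RigidTransform(self.rotations[i], self.translations[i], self.scales[i])

    def transforms(self) -> list[RigidTransform]:
        return [self.transform(i) for i in range(len(self.valid))]


def _align_stack(coords, weights, ref, policy, min_common):
    """Weighted batched Procrustes of ``coords`` (n, p, d) onto ``ref`` (p, d).

    ``weights`` is an (n, p) 0/1 array marking the commonly observed points
    of each pose and the reference.
    """
    n, n_points, d = coords.shape
    w = weights.astype(float)
    w3 = w[:, :, None]
    counts = w.sum(axis=1)
    valid = counts >= min_common
    safe = np.maximum(counts, 1.0)

    x = np.where(w3 > 0, coords, 0.0)
    y = np.where(w3 > 0, ref[None], 0.0)
    cs = x.sum(axis=1) / safe[:, None]
    ct = y.sum(axis=1) / safe[:, None]
    xc = (x - cs[:, None, :]) * w3
    yc = (y - ct[:, None, :]) * w3

    h = np.einsum("npa,npb->nab", xc, yc)
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u) * np.linalg.det(vt))
    sign[sign == 0] = 1.0
    vt_adj = vt.copy()
    vt_adj[:, -1, :] *= sign[:, None]
    rot = np.transpose(vt_adj, (0, 2, 1)) @ np.transpose(u, (0, 2, 1))
    s_adj = s.copy()
    s_adj[:, -1] *= sign

    if policy == "similarity":
        denom = (xc ** 2).sum(axis=(1, 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(denom > 0, s_adj.sum(axis=1) / denom, 1.0)
        scale = np.where(scale > 0, scale, 1.0)
    elif policy == "rigid":
        scale = np.ones(n)
    else:
        raise ShapePoseError(f"unknown alignment policy {policy!r}")

    trans = ct - scale[:, None] * np.einsum("nab,nb->na", rot, cs)
    aligned = scale[:, None, None] * np.einsum("nab,npb->npa", rot, coords) + trans[:, None, :]

    diff = np.where(w3 > 0, aligned - ref[None], 0.0)
    with np.errstate(invalid="ignore"):
        residuals = np.sqrt((diff ** 2).sum(axis=(1, 2)) / safe)
    residuals[~valid] = np.nan
    aligned[~valid] = np.nan
    rot[~valid] = np.eye(d)
    trans[~valid] = 0.0
    scale = scale.copy()
    scale[~valid] = 1.0

    return StackAlignment(aligned, rot, trans, scale, residuals, counts, valid)


def align_stack(
    coords: np.ndarray,
    mask: np.ndarray,
    ref_coords: np.ndarray,
    ref_mask: np.ndarray | None = None,
    policy: str = "rigid",
    min_common: int = DEFAULT_MIN_COMMON,
) -> StackAlignment:
    """Align every pose in a stack onto a single reference pose.

    Parameters
    ----------
    coords : ndarray (n, n_points, d)
    mask : ndarray of bool (n, n_points)
        True where a point is missing.
    ref_coords : ndarray (n_points, d)
    ref_mask : ndarray of bool (n_points,), optional
    policy : {"rigid", "similarity"}
    min_common : int
        Minimum number of commonly observed points per pose.
    """
    coords = np.asarray(coords, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    ref_coords = np.asarray(ref_coords, dtype=float)
    if ref_mask is None:
        ref_mask = ~np.isfinite(ref_coords).all(axis=1)
    weights = (~mask) & (~ref_mask)[None, :]
    return _align_stack(coords, weights, np.nan_to_num(ref_coords), policy, min_common)


def procrustes_align(
    source: np.ndarray,
    target: np.ndarray,
    source_mask: np.ndarray | None = None,
    target_mask: np.ndarray | None = None,
    policy: str = "rigid",
    min_common: int = DEFAULT_MIN_COMMON,
) -> tuple[np.ndarray, RigidTransform, float]:
    """Procrustes superimposition of one pose onto another.

    Returns
    -------
    aligned : ndarray (n_points, d)
        Source after the fitted transform; masked points stay NaN.
    transform : RigidTransform
        Maps source coordinates into the target frame.
    residual : float
        RMS Euclidean distance over the common points after alignment.

    Raises
    ------
    AlignmentError
        If fewer than ``min_common`` points are observed in both poses.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source_mask is None:
        source_mask = ~np.isfinite(source).all(axis=1)
    if target_mask is None:
        target_mask = ~np.isfinite(target).all(axis=1)
    res = align_stack(
        source[None], np.asarray(source_mask, bool)[None], target, target_mask,
        policy=policy, min_common=min_common,
    )
    if not res.valid[0]:
        n_common = int(res.counts[0])
        raise AlignmentError(
            f"only {n_common} commonly observed points; {min_common} required",
            n_common=n_common,
        )
    return res.aligned[0], res.transform(0), float(res.residuals[0])


def apply_transform(pose: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Apply a rigid/similarity transform to an ``(n_points, d)`` pose."""
    return transform.apply(pose)


def invert_transform(transform: RigidTransform) -> RigidTransform:
    return transform.inverse()


def pairwise_distance_quartile(
    dataset: PoseDataset,
    n_pairs: int = 2000,
    rng: np.random.Generator | int | None = None,
    policy: str = "rigid",
    min_common: int = DEFAULT_MIN_COMMON,
) -> float:
    """First quartile of post-alignment RMS distances over sampled pose pairs.

    All distinct pairs are used when there are at most ``n_pairs`` of them;
    otherwise ``n_pairs`` pairs are sampled with the given generator.
    """
    n = dataset.n_frames
    if n < 2:
        raise ShapePoseError("need at least 2 poses for pairwise distances")
    rng = np.random.default_rng(rng)
    total = n * (n - 1) // 2
    if total <= n_pairs:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        ii = rng.integers(0, n, size=n_pairs)
        jj = rng.integers(0, n - 1, size=n_pairs)
        jj = np.where(jj >= ii, jj + 1, jj)
        pairs = list(zip(ii.tolist(), jj.tolist()))

    residuals = []
    for i, j in pairs:
        try:
            _, _, res = procrustes_align(
                dataset.coords[j], dataset.coords[i],
                dataset.missing_mask[j], dataset.missing_mask[i],
                policy=policy, min_common=min_common,
            )
        except AlignmentError:
            continue
        residuals.append(res)
    if not residuals:
        raise AlignmentError("no alignable pose pairs in dataset")
    return float(np.percentile(residuals, 25))


__all__ = [
    "DEFAULT_MIN_COMMON",
    "StackAlignment",
    "align_stack",
    "procrustes_align",
    "apply_transform",
    "invert_transform",
    "pairwise_distance_quartile",
]
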