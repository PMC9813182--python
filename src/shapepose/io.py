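"""Readers and writers for landmark tables, fitted models and truth bundles.

Supported table dialects:

``long_csv``
    Columns ``frame,point,x,y[,z]``; one row per frame/point, empty or NaN
    coordinate cells mark missing points.  Lossless round trip.
``wide_csv``
    One row per frame: ``frame,<name>_x,<name>_y[,<name>_z],...``.
``dlc_csv``
    The DeepLabCut-style export with three header rows
    (scorer / bodyparts / coords) and optional per-point likelihood columns;
    a likelihood cutoff maps low-confidence detections to missing.
``hdf5``
    Container with datasets ``/coords``, ``/mask``, ``/point_names``,
    ``/frame_ids``.  Lossless round trip.

Fitted models are stored as a single JSON document (version-tagged metadata
plus arrays; JSON float repr round-trips exactly in Python).
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .datamodel import FormatError, PoseDataset, ShapeModel
from .simulate import SimulatedTruth

DIALECTS = ("long_csv", "wide_csv", "dlc_csv", "hdf5")

MODEL_FORMAT = "shapepose-model"
MODEL_VERSION = 1


# ---------------------------------------------------------------------------
# pose tables
# ---------------------------------------------------------------------------

def read_pose_table(
    path,
    dialect: str = "long_csv",
    likelihood_threshold: float | None = None,
) -> PoseDataset:
    """Read a landmark table into a :class:`PoseDataset`.

    ``likelihood_threshold`` only applies to the DLC dialect: points whose
    likelihood falls strictly below it are masked.
    """
    if dialect == "long_csv":
        return _read_long_csv(path)
    if dialect == "wide_csv":
        return _read_wide_csv(path)
    if dialect == "dlc_csv":
        return _read_dlc_csv(path, likelihood_threshold)
    if dialect == "hdf5":
        return _read_hdf5(path)
    raise FormatError(f"unsupported dialect {dialect!r}; choose one of {DIALECTS}")


def write_pose_table(dataset: PoseDataset, path, dialect: str = "long_csv") -> None:
    """Write a dataset; ``long_csv`` and ``hdf5`` round-trip losslessly."""
    if dialect == "long_csv":
        _write_long_csv(dataset, path)
    elif dialect == "wide_csv":
        _write_wide_csv(dataset, path)
    elif dialect == "dlc_csv":
        _write_dlc_csv(dataset, path)
    elif dialect == "hdf5":
        _write_hdf5(dataset, path)
    else:
        raise FormatError(f"unsupported dialect {dialect!r}; choose one of {DIALECTS}")


def _coord_columns(d):
    return ["x", "y", "z"][:d]


def _read_long_csv(path) -> PoseDataset:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if cols[:2] != ["frame", "point"]:
        raise FormatError("long CSV must start with columns frame,point")
    if cols[2:5] == ["x", "y", "z"]:
        d = 3
    elif cols[2:4] == ["x", "y"]:
        d = 2
    else:
        raise FormatError("long CSV must provide x,y[,z] coordinate columns")
    ccols = _coord_columns(d)

    frames = list(dict.fromkeys(df["frame"].tolist()))
    points = list(dict.fromkeys(df["point"].astype(str).tolist()))
    f_idx = {f: i for i, f in enumerate(frames)}
    p_idx = {p: i for i, p in enumerate(points)}
    coords = np.full((len(frames), len(points), d), np.nan)
    seen = set()
    for row in df.itertuples(index=False):
        key = (f_idx[row.frame], p_idx[str(row.point)])
        if key in seen:
            raise FormatError(f"duplicate entry for frame {row.frame}, point {row.point}")
        seen.add(key)
        coords[key[0], key[1]] = [getattr(row, c) for c in ccols]
    return PoseDataset(
        coords=coords,
        point_names=points,
        frame_ids=np.asarray(frames, dtype=int),
    )


def _write_long_csv(dataset: PoseDataset, path) -> None:
    ccols = _coord_columns(dataset.d)
    rows = []
    for i in range(dataset.n_frames):
        for j, name in enumerate(dataset.point_names):
            row = {"frame": int(dataset.frame_ids[i]), "point": name}
            for k, c in enumerate(ccols):
                v = dataset.coords[i, j, k]
                row[c] = "" if dataset.missing_mask[i, j] else repr(float(v))
            rows.append(row)
    pd.DataFrame(rows, columns=["frame", "point", *ccols]).to_csv(path, index=False)


def _read_wide_csv(path) -> PoseDataset:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if df.columns[0].strip().lower() != "frame":
        raise FormatError("wide CSV must start with a frame column")
    names, d = [], None
    for col in df.columns[1:]:
        if "_" not in col:
            raise FormatError(f"wide CSV column {col!r} lacks an _x/_y/_z suffix")
        name, axis = col.rsplit("_", 1)
        if axis not in ("x", "y", "z"):
            raise FormatError(f"unknown coordinate suffix in column {col!r}")
        if name not in names:
            names.append(name)
    per_name = {n: [c.rsplit("_", 1)[1] for c in df.columns[1:] if c.rsplit("_", 1)[0] == n]
                for n in names}
    axes0 = per_name[names[0]]
    if any(per_name[n] != axes0 for n in names):
        raise FormatError("inconsistent coordinate columns across points")
    d = len(axes0)
    if axes0 != _coord_columns(d):
        raise FormatError("coordinate columns must be ordered x,y[,z]")
    coords = np.full((len(df), len(names), d), np.nan)
    for j, n in enumerate(names):
        for k, axis in enumerate(axes0):
            coords[:, j, k] = pd.to_numeric(df[f"{n}_{axis}"], errors="coerce").to_numpy()
    return PoseDataset(
        coords=coords,
        point_names=names,
        frame_ids=df.iloc[:, 0].to_numpy(dtype=int),
    )


def _write_wide_csv(dataset: PoseDataset, path) -> None:
    ccols = _coord_columns(dataset.d)
    data = {"frame": dataset.frame_ids}
    for j, name in enumerate(dataset.point_names):
        for k, axis in enumerate(ccols):
            col = dataset.coords[:, j, k].astype(object)
            col[dataset.missing_mask[:, j]] = ""
            data[f"{name}_{axis}"] = col
    pd.DataFrame(data).to_csv(path, index=False)


def _read_dlc_csv(path, likelihood_threshold) -> PoseDataset:
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except Exception as exc:
        raise FormatError(f"could not parse DLC CSV {path}: {exc}") from exc
    if df.columns.nlevels != 3:
        raise FormatError("DLC CSV needs three header rows (scorer/bodyparts/coords)")
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    axes = [a for a in ("x", "y", "z") if a in set(df.columns.get_level_values(2))]
    if axes[: len(axes)] != _coord_columns(len(axes)) or not axes:
        raise FormatError("DLC CSV coordinate rows must provide x,y[,z]")
    d = len(axes)
    n = len(df)
    coords = np.full((n, len(bodyparts), d), np.nan)
    mask = np.zeros((n, len(bodyparts)), dtype=bool)
    scorer = df.columns.get_level_values(0)[0]
    for j, bp in enumerate(bodyparts):
        for k, axis in enumerate(axes):
            try:
                coords[:, j, k] = pd.to_numeric(df[(scorer, bp, axis)], errors="coerce")
            except KeyError as exc:
                raise FormatError(f"missing column {axis!r} for bodypart {bp!r}") from exc
        if likelihood_threshold is not None and (scorer, bp, "likelihood") in df.columns:
            lik = pd.to_numeric(df[(scorer, bp, "likelihood")], errors="coerce").to_numpy()
            mask[:, j] |= ~(lik >= likelihood_threshold)
    return PoseDataset(
        coords=coords,
        missing_mask=mask,
        point_names=bodyparts,
        frame_ids=np.asarray(df.index, dtype=int),
    )


def _write_dlc_csv(dataset: PoseDataset, path) -> None:
    ccols = _coord_columns(dataset.d)
    columns = pd.MultiIndex.from_tuples(
        [("shapepose", bp, axis) for bp in dataset.point_names for axis in ccols],
        names=["scorer", "bodyparts", "coords"],
    )
    values = dataset.coords.reshape(dataset.n_frames, -1)
    out = pd.DataFrame(values, index=dataset.frame_ids, columns=columns)
    out.to_csv(path)


def _read_hdf5(path) -> PoseDataset:
    try:
        with h5py.File(path, "r") as f:
            coords = f["coords"][...]
            mask = f["mask"][...].astype(bool)
            names = [s.decode() if isinstance(s, bytes) else str(s) for s in f["point_names"][...]]
            frame_ids = f["frame_ids"][...]
    except (OSError, KeyError) as exc:
        raise FormatError(f"could not read HDF5 container {path}: {exc}") from exc
    return PoseDataset(coords=coords, missing_mask=mask, point_names=names, frame_ids=frame_ids)


def _write_hdf5(dataset: PoseDataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=dataset.coords)
        f.create_dataset("mask", data=dataset.missing_mask)
        f.create_dataset(
            "point_names",
            data=np.array([n.encode() for n in dataset.point_names]),
        )
        f.create_dataset("frame_ids", data=dataset.frame_ids)


# ---------------------------------------------------------------------------
# fitted models
# ---------------------------------------------------------------------------

def save_model(model: ShapeModel, path) -> None:
    """Serialise a fitted model to a version-tagged JSON document."""
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "d": model.d,
        "alignment_policy": model.alignment_policy,
        "sigma2": model.sigma2,
        "mu": model.mu.tolist(),
        "eigenposes": model.eigenposes.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> ShapeModel:
    """Load a model file, re-validating orthonormality and SPD invariants."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"could not read model file {path}: {exc}") from exc
    if doc.get("format") != MODEL_FORMAT:
        raise FormatError(f"{path} is not a shapepose model file")
    if doc.get("version") != MODEL_VERSION:
        raise FormatError(
            f"model file version {doc.get('version')} not supported "
            f"(expected {MODEL_VERSION})"
        )
    model = ShapeModel(
        mu=np.asarray(doc["mu"], dtype=float),
        eigenposes=np.asarray(doc["eigenposes"], dtype=float),
        eigenvalues=np.asarray(doc["eigenvalues"], dtype=float),
        sigma2=float(doc["sigma2"]),
        d=int(doc["d"]),
        alignment_policy=doc.get("alignment_policy", "rigid"),
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# simulation truth bundles
# ---------------------------------------------------------------------------

def save_truth(truth: SimulatedTruth, path) -> None:
    """Write a simulation ground-truth bundle to an HDF5 container."""
    with h5py.File(path, "w") as f:
        for name in (
            "clean", "noisy", "aligned_clean", "mean_shape", "eigenposes",
            "b", "rotations", "translations",
        ):
            f.create_dataset(name, data=getattr(truth, name))
        f.create_dataset("outlier_mask", data=truth.outlier_mask)
        f.create_dataset("missing_mask", data=truth.missing_mask)


def load_truth(path) -> SimulatedTruth:
    try:
        with h5py.File(path, "r") as f:
            kwargs = {
                name: f[name][...]
                for name in (
                    "clean", "noisy", "aligned_clean", "mean_shape", "eigenposes",
                    "b", "rotations", "translations",
                )
            }
            kwargs["outlier_mask"] = f["outlier_mask"][...].astype(bool)
            kwargs["missing_mask"] = f["missing_mask"][...].astype(bool)
    except (OSError, KeyError) as exc:
        raise FormatError(f"could not read truth bundle {path}: {exc}") from exc
    return SimulatedTruth(**kwargs)


__all__ = [
    "DIALECTS",
    "read_pose_table",
    "write_pose_table",
    "save_model",
    "load_model",
    "save_truth",
    "load_truth",
]
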