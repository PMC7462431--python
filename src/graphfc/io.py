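"""Readers/writers for on-disk artifacts.

All matrices are delimited text (comma or tab, auto-detected) with a
mandatory header row of ROI labels, so that ROI order is always explicit and
misalignment fails loudly instead of silently. Epochs live one file per
artifact-free interval in a study directory, described by a JSON manifest
that records the sampling rate. A ``.npy`` dialect is accepted for epochs
as a faster alternative at run time.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import Parcellation, SourceEpoch

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_parcellation",
    "write_parcellation",
    "read_epochs",
    "write_epochs",
]

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-9


def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_matrix(path, expect_symmetric: bool = False):
    """Read a labelled square matrix from delimited text.

    Returns ``(matrix, labels)``. The first row must hold N ROI labels and
    be followed by N rows of N numeric fields.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, header=0, index_col=None)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"{path}: cannot parse delimited matrix: {exc}") from exc
    labels = [str(c) for c in df.columns]
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"{path}: matrix is not square ({df.shape[0]} rows, {df.shape[1]} labels)"
        )
    try:
        a = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in matrix body: {exc}") from exc
    if expect_symmetric:
        scale = np.max(np.abs(a)) if a.size else 0.0
        if scale > 0 and np.max(np.abs(a - a.T)) > _SYM_TOL * scale:
            raise ValueError(f"{path}: matrix expected symmetric but is not")
    return a, labels


def write_matrix(matrix, labels, path, sep: str = ",") -> None:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(labels), len(labels)):
        raise ValueError("labels do not match matrix dimension")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(matrix, columns=[str(l) for l in labels]).to_csv(
        path, sep=sep, index=False, float_format="%.17g"
    )


_PARC_COLUMNS = ["name", "hemisphere", "x", "y", "z", "size"]


def read_parcellation(path) -> Parcellation:
    """Read a parcellation table (name, hemisphere, x, y, z, size)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), header=0)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _PARC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: parcellation table missing columns {missing}")
    return Parcellation(
        roi_names=tuple(df["name"].astype(str)),
        hemisphere=df["hemisphere"].to_numpy(dtype="U1"),
        centroids=df[["x", "y", "z"]].to_numpy(dtype=float),
        roi_size=df["size"].to_numpy(dtype=int),
    )


def write_parcellation(parc: Parcellation, path, sep: str = ",") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "name": parc.roi_names,
            "hemisphere": parc.hemisphere,
            "x": parc.centroids[:, 0],
            "y": parc.centroids[:, 1],
            "z": parc.centroids[:, 2],
            "size": parc.roi_size,
        }
    )
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


_EPOCH_RE = re.compile(r"(?P<subject>.+)_epoch-(?P<interval>\d+)\.(csv|tsv|npy)$")


def write_epochs(epochs_by_subject: dict, directory, fmt: str = "npy") -> None:
    """Write a study's epochs plus the ``epochs.json`` manifest.

    ``epochs_by_subject`` maps subject id -> list of SourceEpoch. ``fmt`` is
    'npy' (binary container, fast) or 'csv'.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"rate": None, "files": []}
    for subject, epochs in epochs_by_subject.items():
        for ep in epochs:
            if manifest["rate"] is None:
                manifest["rate"] = ep.rate
            elif manifest["rate"] != ep.rate:
                raise ValueError("all epochs in a study must share one sampling rate")
            name = f"{subject}_epoch-{ep.interval:03d}.{fmt}"
            if fmt == "npy":
                np.save(directory / name, ep.data)
            elif fmt == "csv":
                np.savetxt(directory / name, ep.data, delimiter=",", fmt="%.17g")
            else:
                raise ValueError("fmt must be 'npy' or 'csv'")
            manifest["files"].append(
                {
                    "subject": subject,
                    "interval": ep.interval,
                    "file": name,
                    "n_rois": ep.n_rois,
                    "n_samples": ep.n_samples,
                }
            )
    with open(directory / "epochs.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_epochs(directory, rate: float | None = None, n_rois: int | None = None) -> dict:
    """Read per-subject epochs from a study directory.

    Returns a dict mapping subject id -> list of :class:`SourceEpoch`.
    Empty intervals are skipped with a warning; an interval whose row count
    disagrees with ``n_rois`` raises.
    """
    directory = Path(directory)
    manifest_path = directory / "epochs.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"{directory}: no epochs.json manifest")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if rate is None:
        rate = manifest.get("rate")
    if rate is None:
        raise ValueError("sampling rate neither given nor present in the manifest")
    out: dict = {}
    for entry in manifest["files"]:
        fp = directory / entry["file"]
        if fp.suffix == ".npy":
            data = np.load(fp)
        else:
            data = np.loadtxt(fp, delimiter="," if fp.suffix == ".csv" else "\t", ndmin=2)
        if data.size == 0:
            logger.warning("skipping empty interval %s", fp.name)
            continue
        if n_rois is not None and data.shape[0] != n_rois:
            raise ValueError(
                f"{fp.name}: expected {n_rois} ROIs, found {data.shape[0]} rows"
            )
        ep = SourceEpoch(
            data=data, rate=float(rate), subject=entry["subject"], interval=entry["interval"]
        )
        out.setdefault(entry["subject"], []).append(ep)
    for eps in out.values():
        eps.sort(key=lambda e: e.interval)
    return out
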