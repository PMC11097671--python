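"""Voxel-wise functional connectivity and the group connections x subjects matrix.

For each subject, functional connectivity (FC) is the Pearson correlation
between every pair of voxel time series, computed over the volumes that
survived censoring.  The upper triangle of each subject's V x V matrix is
vectorized in fixed row-major order — position ``(i, j)`` with ``i < j``
maps to a linear index, identically for every subject — and the vectors
are stacked column-wise into the group matrix (connections x subjects).
For the 325-voxel cerebellar mask this gives 52,650 connections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .qc import CensorMask

__all__ = [
    "BoldSeries",
    "ConnectomeVector",
    "GroupMatrix",
    "fc_matrix",
    "vectorize_upper",
    "devectorize",
    "assemble_group_matrix",
    "load_bold_tsv",
    "write_bold_tsv",
    "load_bold_nifti",
    "save_group_matrix",
    "load_group_matrix",
]


@dataclass
class BoldSeries:
    """One subject's preprocessed BOLD signal.

    Parameters
    ----------
    data
        ``(n_voxels, n_volumes)`` signal matrix.
    roi_labels
        Per-voxel region label (one of the 8 cerebellar ROIs).  Voxel order
        is fixed and must be identical across subjects.
    voxel_ids
        Optional per-voxel identifiers; defaults to 0..V-1.
    """

    data: np.ndarray
    roi_labels: np.ndarray
    subject_id: str | None = None
    voxel_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roi_labels = np.asarray(self.roi_labels)
        if self.data.ndim != 2:
            raise ValueError("BOLD data must be a voxels x time matrix")
        if self.roi_labels.shape[0] != self.data.shape[0]:
            raise ValueError(
                f"{self.roi_labels.shape[0]} ROI labels for {self.data.shape[0]} voxels"
            )
        if self.voxel_ids is None:
            self.voxel_ids = np.arange(self.data.shape[0])
        else:
            self.voxel_ids = np.asarray(self.voxel_ids)

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectomeVector:
    """Upper-triangle FC profile of one subject.

    ``values`` has length ``C = V (V - 1) / 2`` ordered row-major over the
    strict upper triangle: (0,1), (0,2), ..., (0,V-1), (1,2), ...
    """

    values: np.ndarray
    n_voxels: int
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.n_voxels * (self.n_voxels - 1) // 2
        if self.values.shape != (expected,):
            raise ValueError(
                f"expected {expected} connections for {self.n_voxels} voxels, "
                f"got shape {self.values.shape}"
            )

    @property
    def n_connections(self) -> int:
        return self.values.size

    def pair_index(self) -> tuple[np.ndarray, np.ndarray]:
        """(i, j) voxel indices of each linear connection position."""
        return np.triu_indices(self.n_voxels, k=1)


@dataclass
class GroupMatrix:
    """Connections x subjects stack of FC profiles."""

    data: np.ndarray
    subject_ids: list[str]
    n_voxels: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("group matrix must be 2-D (connections x subjects)")
        if self.data.shape[1] != len(self.subject_ids):
            raise ValueError("subject id count does not match columns")
        expected = self.n_voxels * (self.n_voxels - 1) // 2
        if self.data.shape[0] != expected:
            raise ValueError(
                f"{self.data.shape[0]} connections inconsistent with {self.n_voxels} voxels"
            )

    @property
    def n_connections(self) -> int:
        return self.data.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.data.shape[1]

    def subset(self, column_indices) -> "GroupMatrix":
        idx = np.asarray(column_indices, dtype=int)
        return GroupMatrix(
            data=self.data[:, idx],
            subject_ids=[self.subject_ids[i] for i in idx],
            n_voxels=self.n_voxels,
        )


def fc_matrix(bold: BoldSeries, mask: CensorMask | None = None) -> np.ndarray:
    """Pearson FC over retained volumes.

    Returns a symmetric V x V matrix with unit diagonal.  Raises if fewer
    than 3 volumes survive or any retained voxel row is constant (the
    correlation is undefined there; the offending voxel is named).
    """
    data = bold.data
    if mask is not None:
        if mask.n_volumes != bold.n_volumes:
            raise ValueError(
                f"censor mask length {mask.n_volumes} != {bold.n_volumes} volumes"
            )
        data = data[:, mask.keep]
    if data.shape[1] < 3:
        raise ValueError(
            f"only {data.shape[1]} retained volumes; need at least 3 for correlation"
        )
    variances = data.var(axis=1)
    bad = np.flatnonzero(variances == 0)
    if bad.size:
        raise ValueError(
            f"zero-variance voxel(s) in retained volumes: {bold.voxel_ids[bad[:5]].tolist()}"
        )
    fc = np.corrcoef(data)
    fc = np.clip(fc, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return fc


def vectorize_upper(fc: np.ndarray, subject_id: str | None = None) -> ConnectomeVector:
    """Row-major strict-upper-triangle vectorization of a symmetric matrix."""
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError(f"FC matrix must be square, got {fc.shape}")
    if not np.allclose(fc, fc.T, atol=1e-10):
        raise ValueError("FC matrix is not symmetric")
    v = fc.shape[0]
    iu = np.triu_indices(v, k=1)
    return ConnectomeVector(values=fc[iu], n_voxels=v, subject_id=subject_id)


def devectorize(vec: ConnectomeVector) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`; unit diagonal restored."""
    v = vec.n_voxels
    fc = np.eye(v)
    iu = np.triu_indices(v, k=1)
    fc[iu] = vec.values
    fc[(iu[1], iu[0])] = vec.values
    return fc


def assemble_group_matrix(vectors: list[ConnectomeVector]) -> GroupMatrix:
    """Stack subject FC profiles into a connections x subjects matrix."""
    if not vectors:
        raise ValueError("no connectome vectors given")
    n_vox = vectors[0].n_voxels
    length = vectors[0].n_connections
    for i, vec in enumerate(vectors):
        if vec.n_connections != length or vec.n_voxels != n_vox:
            raise ValueError(
                f"vector {i} has {vec.n_connections} connections, expected {length}"
            )
    ids = [
        vec.subject_id if vec.subject_id is not None else f"S{i:04d}"
        for i, vec in enumerate(vectors)
    ]
    data = np.column_stack([vec.values for vec in vectors])
    return GroupMatrix(data=data, subject_ids=ids, n_voxels=n_vox)


# ---------------------------------------------------------------------------
# I/O


def write_bold_tsv(bold: BoldSeries, path: str | Path) -> None:
    """Write voxels x time TSV with a leading voxel_id and roi columns."""
    import pandas as pd

    cols = {f"t{t:04d}": bold.data[:, t] for t in range(bold.n_volumes)}
    df = pd.DataFrame({"voxel_id": bold.voxel_ids, "roi": bold.roi_labels, **cols})
    df.to_csv(path, sep="\t", index=False)


def load_bold_tsv(path: str | Path, subject_id: str | None = None) -> BoldSeries:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    time_cols = [c for c in df.columns if c.startswith("t")]
    return BoldSeries(
        data=df[time_cols].to_numpy(float),
        roi_labels=df["roi"].to_numpy(),
        voxel_ids=df["voxel_id"].to_numpy(),
        subject_id=subject_id,
    )


def load_bold_nifti(
    bold_path: str | Path,
    label_path: str | Path,
    subject_id: str | None = None,
    label_names: dict[int, str] | None = None,
) -> BoldSeries:
    """Extract voxel time series from a 4D NIfTI within a labelled mask.

    Voxels are the nonzero positions of the integer label image, ordered by
    linear (C-ravel) index so the ordering is reproducible across subjects
    sharing one mask.
    """
    import nibabel as nib

    img = nib.load(str(bold_path))
    labels_img = nib.load(str(label_path))
    labels = np.asarray(labels_img.dataobj).astype(int)
    data4d = np.asarray(img.dataobj, dtype=float)
    if data4d.ndim != 4:
        raise ValueError(f"expected 4D BOLD image, got {data4d.ndim}D")
    if labels.shape != data4d.shape[:3]:
        raise ValueError("label image shape does not match BOLD spatial shape")
    flat_labels = labels.ravel(order="C")
    voxel_lin = np.flatnonzero(flat_labels)
    series = data4d.reshape(-1, data4d.shape[3], order="C")[voxel_lin]
    lab = flat_labels[voxel_lin]
    roi = (
        np.array([label_names[int(v)] for v in lab])
        if label_names
        else lab.astype(str)
    )
    return BoldSeries(data=series, roi_labels=roi, voxel_ids=voxel_lin, subject_id=subject_id)


def save_group_matrix(group: GroupMatrix, prefix: str | Path) -> None:
    """Persist as <prefix>.npy plus a JSON sidecar with ids and index map."""
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), group.data)
    meta = {
        "subject_ids": group.subject_ids,
        "n_voxels": group.n_voxels,
        "n_connections": group.n_connections,
        "triangle_order": "row-major strict upper triangle, (0,1),(0,2),...",
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_group_matrix(prefix: str | Path) -> GroupMatrix:
    prefix = Path(prefix)
    data = np.load(prefix.with_suffix(".npy"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return GroupMatrix(data=data, subject_ids=meta["subject_ids"], n_voxels=meta["n_voxels"])
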