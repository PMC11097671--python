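"""Motion-based volume censoring and scan-level quality control.

Resting-state volumes are dropped when volume-to-volume head motion
(framewise displacement, FD) exceeds a millimetre threshold or when too
large a fraction of voxels is flagged as an intensity outlier; a scan is
excluded altogether when fewer than a minimum number of motion-free
volumes survive.

FD follows the common "sum of absolute backward differences" convention:
the six rigid-body parameters (three translations in mm, three rotations
in radians) are differenced volume-to-volume, rotations are converted to
arc length on a sphere (default radius 50 mm, a standard small-head
convention), and the absolute differences are summed.  The first volume's
FD is defined as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MotionTrace",
    "CensorMask",
    "framewise_displacement",
    "outlier_fraction",
    "censor_volumes",
    "scan_passes_qc",
    "read_motion_par",
    "write_motion_par",
    "write_censor_mask",
    "qc_report",
]

#: Default conversion radius for rotational displacement, in mm.
DEFAULT_SPHERE_RADIUS_MM = 50.0

#: FD threshold above which a volume is censored, in mm.
DEFAULT_FD_THRESH_MM = 0.2

#: Outlier-voxel fraction above which a volume is censored.
DEFAULT_OUTLIER_FRAC_THRESH = 0.10

#: Minimum retained volumes for a scan to pass QC (strict `<` exclusion).
DEFAULT_MIN_VOLUMES = 120


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters per volume.

    Parameters
    ----------
    params
        Array of shape ``(n_volumes, 6)``: columns 0-2 are translations in
        mm, columns 3-5 rotations in radians.
    subject_id
        Optional identifier carried through reports.
    """

    params: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(
                f"motion trace must be (n_volumes, 6), got {self.params.shape}"
            )

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]


@dataclass
class CensorMask:
    """Per-volume keep/censor decision with reasons.

    ``keep`` is a boolean vector; ``reasons`` maps censored volume index to
    ``"motion"``, ``"outlier"`` or ``"motion+outlier"``.
    """

    keep: np.ndarray
    reasons: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def n_volumes(self) -> int:
        return self.keep.size

    @property
    def retained(self) -> int:
        return int(self.keep.sum())


def framewise_displacement(
    trace: MotionTrace | np.ndarray,
    sphere_radius_mm: float = DEFAULT_SPHERE_RADIUS_MM,
) -> np.ndarray:
    """Scalar head-motion series from six rigid-body parameters.

    ``FD[t] = sum_i |Δtrans_i[t]| + r * sum_j |Δrot_j[t]|`` with the first
    volume defined as 0.  Rotations are scaled by ``sphere_radius_mm`` so
    that all six terms are in mm.
    """
    params = trace.params if isinstance(trace, MotionTrace) else np.asarray(trace, float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError(f"expected (n_volumes, 6) parameters, got {params.shape}")
    if params.shape[0] < 2:
        raise ValueError("framewise displacement needs at least 2 volumes")
    if not np.all(np.isfinite(params)):
        raise ValueError("motion parameters contain non-finite values")
    scaled = params.copy()
    scaled[:, 3:] *= sphere_radius_mm
    fd = np.zeros(params.shape[0])
    fd[1:] = np.abs(np.diff(scaled, axis=0)).sum(axis=1)
    return fd


def outlier_fraction(bold, k: float = 3.5) -> np.ndarray:
    """Per-volume fraction of voxels that are intensity outliers.

    A voxel is an outlier at volume *t* when its value deviates from the
    voxel's temporal median by more than ``k`` times the voxel's median
    absolute deviation (raw MAD, no consistency factor).  Voxel rows with
    exactly zero temporal variance carry no intensity information and are
    excluded from the denominator; if every row is constant the matrix is
    degenerate and an error is raised.
    """
    data = np.asarray(getattr(bold, "data", bold), dtype=float)
    if data.ndim != 2:
        raise ValueError("expected a voxels x time matrix")
    if data.shape[1] < 2:
        raise ValueError("outlier detection needs at least 2 volumes")
    variances = data.var(axis=1)
    informative = variances > 0
    if not informative.any():
        raise ValueError("all voxel rows have zero variance; degenerate signal matrix")
    sub = data[informative]
    med = np.median(sub, axis=1, keepdims=True)
    mad = np.median(np.abs(sub - med), axis=1, keepdims=True)
    outliers = np.abs(sub - med) > k * mad
    return outliers.mean(axis=0)


def censor_volumes(
    fd: np.ndarray,
    outfrac: np.ndarray,
    fd_thresh: float = DEFAULT_FD_THRESH_MM,
    frac_thresh: float = DEFAULT_OUTLIER_FRAC_THRESH,
) -> CensorMask:
    """Censor volumes exceeding either the motion or the outlier threshold.

    A volume is censored iff ``fd > fd_thresh`` or ``outfrac > frac_thresh``
    (strict inequalities: a volume exactly at threshold is retained).
    """
    fd = np.asarray(fd, dtype=float)
    outfrac = np.asarray(outfrac, dtype=float)
    if fd.shape != outfrac.shape:
        raise ValueError(
            f"fd and outlier-fraction series differ in length: {fd.shape} vs {outfrac.shape}"
        )
    bad_motion = fd > fd_thresh
    bad_outlier = outfrac > frac_thresh
    keep = ~(bad_motion | bad_outlier)
    reasons: dict[int, str] = {}
    for idx in np.flatnonzero(~keep):
        tags = []
        if bad_motion[idx]:
            tags.append("motion")
        if bad_outlier[idx]:
            tags.append("outlier")
        reasons[int(idx)] = "+".join(tags)
    return CensorMask(keep=keep, reasons=reasons)


def scan_passes_qc(mask: CensorMask, min_volumes: int = DEFAULT_MIN_VOLUMES) -> bool:
    """True iff at least ``min_volumes`` volumes survive censoring."""
    return mask.retained >= min_volumes


# ---------------------------------------------------------------------------
# file I/O


def read_motion_par(path: str | Path, subject_id: str | None = None) -> MotionTrace:
    """Read a 6-column whitespace-delimited motion parameter file."""
    params = np.loadtxt(path, dtype=float, ndmin=2)
    return MotionTrace(params=params, subject_id=subject_id)


def write_motion_par(trace: MotionTrace, path: str | Path) -> None:
    np.savetxt(path, trace.params, fmt="%.6f")


def write_censor_mask(mask: CensorMask, path: str | Path) -> None:
    """Write the keep flags as a single column of 0/1."""
    np.savetxt(path, mask.keep.astype(int), fmt="%d")


def qc_report(
    mask: CensorMask,
    min_volumes: int = DEFAULT_MIN_VOLUMES,
    subject_id: str | None = None,
    path: str | Path | None = None,
) -> dict:
    """Summarise a censor mask; optionally write the summary as JSON."""
    report = {
        "subject_id": subject_id,
        "n_volumes": mask.n_volumes,
        "retained": mask.retained,
        "censored": mask.n_volumes - mask.retained,
        "passes_qc": scan_passes_qc(mask, min_volumes),
        "min_volumes": min_volumes,
        "reasons": {str(k): v for k, v in sorted(mask.reasons.items())},
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2))
    return report
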