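"""Reduction of the fine newborn cerebellar parcellation to 8 lobar ROIs.

The newborn cerebellar atlas distinguishes 28 regions (lateral lobules of
each hemisphere plus vermal subdivisions).  For lobe-level analysis these
collapse to eight: left/right anterior lobe (lobules I-IV and V),
left/right central lobe (VI, Crus I, Crus II, VIIb, VIIIa, VIIIb, IX),
left/right posterior lobe (X), central vermis (vermal VI-IX) and
posterior vermis (vermal X).  The default grouping table below encodes
that membership and is user-editable: pass any mapping covering your
label set.
"""

from __future__ import annotations

import numpy as np

__all__ = ["NEWBORN_FINE_LABELS", "DEFAULT_GROUPING", "reduce_atlas_labels"]

_LATERAL_LOBULES = [
    "I-IV", "V", "VI", "Crus I", "Crus II", "VIIb", "VIIIa", "VIIIb", "IX", "X",
]
_VERMIS_LOBULES = ["VI", "Crus I", "Crus II", "VIIb", "VIIIa", "VIIIb", "IX", "X"]

#: 28 fine region names: 10 lobules x {L, R} + 8 vermal subdivisions.
NEWBORN_FINE_LABELS = (
    [f"Left {lob}" for lob in _LATERAL_LOBULES]
    + [f"Right {lob}" for lob in _LATERAL_LOBULES]
    + [f"Vermis {lob}" for lob in _VERMIS_LOBULES]
)


def _default_grouping() -> dict[str, str]:
    grouping: dict[str, str] = {}
    for side, tag in (("Left", "L"), ("Right", "R")):
        for lob in _LATERAL_LOBULES:
            fine = f"{side} {lob}"
            if lob in ("I-IV", "V"):
                grouping[fine] = f"Anterior lobe {tag}"
            elif lob == "X":
                grouping[fine] = f"Posterior lobe {tag}"
            else:
                grouping[fine] = f"Central lobe {tag}"
    for lob in _VERMIS_LOBULES:
        grouping[f"Vermis {lob}"] = (
            "Posterior vermis" if lob == "X" else "Central vermis"
        )
    return grouping


#: Default 28 -> 8 membership table.
DEFAULT_GROUPING = _default_grouping()


def reduce_atlas_labels(fine_labels, grouping: dict | None = None) -> np.ndarray:
    """Map a fine-grained voxel label array to the 8-ROI scheme.

    Parameters
    ----------
    fine_labels
        Array (any shape) of fine region names.
    grouping
        fine-name -> coarse-name mapping; must cover every label present.
        Defaults to :data:`DEFAULT_GROUPING`.

    Raises
    ------
    ValueError
        If a label in the input has no entry in the grouping table.
    """
    if grouping is None:
        grouping = DEFAULT_GROUPING
    fine = np.asarray(fine_labels)
    out = np.empty(fine.shape, dtype=object)
    for lab in np.unique(fine):
        if lab not in grouping:
            raise ValueError(f"unmapped atlas label: {lab!r}")
        out[fine == lab] = grouping[lab]
    return out.astype(str)
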