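"""Segmentation evaluation: Dice, Recall, Precision and Hausdorff distance.

All four metrics are evaluated on voxel sets: T is the reference (manual)
tissue set, F the segmented set.  Dice = 2|T∩F| / (|T|+|F|),
Recall = |T∩F| / |T|, Precision = |T∩F| / |F|.  The Hausdorff distance is
the larger of the two directed farthest-nearest-neighbour distances over
the full sets, Euclidean in mm via the voxel spacing.

Empty-set conventions: Dice of two empty sets is 1 (perfect agreement);
metrics with an empty denominator set are reported as NaN (missing), never
as 0, so averages are not silently biased.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import distance_transform_edt

from .volumes import LabelVolume, VolumeShapeError

__all__ = ["SegmentationMetrics", "dice", "recall", "precision",
           "hausdorff", "evaluate"]


def _as_bool(vol) -> np.ndarray:
    data = vol.data if isinstance(vol, LabelVolume) else np.asarray(vol)
    return data.astype(bool)


def _pair(t, f) -> tuple[np.ndarray, np.ndarray]:
    a, b = _as_bool(t), _as_bool(f)
    if a.shape != b.shape:
        raise VolumeShapeError(f"grid mismatch: {a.shape} vs {b.shape}")
    return a, b


def dice(t, f) -> float:
    a, b = _pair(t, f)
    st, sf = int(a.sum()), int(b.sum())
    if st + sf == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (st + sf)


def recall(t, f) -> float:
    """|T∩F| / |T|; NaN when the reference set is empty."""
    a, b = _pair(t, f)
    st = int(a.sum())
    if st == 0:
        return float("nan")
    return int((a & b).sum()) / st


def precision(t, f) -> float:
    """|T∩F| / |F|; NaN when the segmented set is empty."""
    a, b = _pair(t, f)
    sf = int(b.sum())
    if sf == 0:
        return float("nan")
    return int((a & b).sum()) / sf


def hausdorff(t, f, spacing=None) -> float:
    """Symmetric Hausdorff distance in mm (or voxel units if spacing None).

    Computed with exact Euclidean distance transforms; equals the
    brute-force max-min pairwise definition.  NaN if either set is empty.
    """
    a, b = _pair(t, f)
    if not a.any() or not b.any():
        return float("nan")
    if spacing is None:
        for v in (t, f):
            if isinstance(v, LabelVolume):
                spacing = v.spacing
                break
        else:
            spacing = (1.0,) * a.ndim
    sampling = tuple(float(s) for s in spacing)
    d_to_b = distance_transform_edt(~b, sampling=sampling)
    d_to_a = distance_transform_edt(~a, sampling=sampling)
    h1 = float(d_to_b[a].max())
    h2 = float(d_to_a[b].max())
    return max(h1, h2)


@dataclasses.dataclass(frozen=True)
class SegmentationMetrics:
    """Bundle of the four evaluation indices (hd in mm)."""

    dsc: float
    recall: float
    precision: float
    hd: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def evaluate(t, f, spacing=None) -> SegmentationMetrics:
    """All four metrics for a (reference, segmentation) pair."""
    return SegmentationMetrics(dice(t, f), recall(t, f), precision(t, f),
                               hausdorff(t, f, spacing))
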