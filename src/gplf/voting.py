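"""Patch-similarity weighted voting (PSWV).

The fusion value at a voxel is the weight-normalized vote
``Fv = sum(w_i * l_i) / sum(w_i)`` over the retained patches, with NCC
similarities (clamped at 0) as weights.  ``Fv >= threshold`` assigns the
target-organization label when PSWV is used standalone.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .patches import PatchLibrary

__all__ = ["VoteResult", "weighted_vote", "pswv_fuse_voxel", "binarize"]


@dataclasses.dataclass(frozen=True)
class VoteResult:
    """fv: the fusion value in [0, 1]; n_effective: patches with weight > 0."""

    fv: float
    n_effective: int


def weighted_vote(weights, labels) -> VoteResult:
    """``Fv = sum(w_i l_i) / sum(w_i)``; 0 when all weights vanish.

    Weights must be nonnegative (negative similarities are clamped upstream)
    and labels binary.
    """
    w = np.asarray(weights, dtype=np.float64).ravel()
    l = np.asarray(labels).ravel()
    if w.size != l.size:
        raise ValueError(f"length mismatch: {w.size} weights vs {l.size} labels")
    if w.size < 1:
        raise ValueError("weighted_vote needs at least one voter")
    if (w < 0).any():
        raise ValueError("negative weight; clamp before voting")
    if not np.isin(np.unique(l), (0, 1)).all():
        raise ValueError("labels must be binary")
    s = w.sum()
    if s <= 0:
        return VoteResult(0.0, 0)
    return VoteResult(float((w * l).sum() / s), int((w > 0).sum()))


def pswv_fuse_voxel(library: PatchLibrary) -> VoteResult:
    """PSWV at one voxel: vote with NCC weights clamped at zero."""
    if len(library) == 0:
        raise ValueError("empty patch library")
    weights = np.clip(library.similarities, 0.0, None)
    return weighted_vote(weights, library.center_labels)


def binarize(fv: float, threshold: float = 0.5) -> int:
    """Label 1 iff ``fv >= threshold`` (the comparison is inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return 1 if fv >= threshold else 0
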