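"""The GP-LF piecewise fusion model and whole-volume segmentation.

Per voxel, two fusion values are available: Fv_SRLF (sparse-representation
weights) and Fv_PSWV (NCC-similarity weights).  The piecewise decision is:

    label = 1                      if Fv_SRLF > 0.9  or Fv_PSWV > 0.9
    label = Lf1                    if 0.4 < Fv_SRLF <= 0.9 and 0.4 < Fv_PSWV < 0.9
    label = Lf2                    if Fv_SRLF <= 0.4
    label = Lf3                    if Fv_PSWV <= 0.4

with Lf1 = [beta1 * Fv_SRLF * Fv_PSWV * P > 0.5],
     Lf2 = [beta2 * Fv_SRLF * P > 0.5],
     Lf3 = [beta3 * Fv_PSWV * P > 0.5],

where P is the trained per-intensity-bin greyscale probability of the
target tissue.  The four conditions neither partition nor cover [0,1]^2, so
they are evaluated strictly in the printed order (first match wins) and any
uncovered residual combination falls through to Lf1.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .greyscale import TissueConfig, bin_index, get_tissue
from .patches import NoCandidatesError, SelectionConfig, _POSITION_TOL
from .sparse import SrlfConfig, sparse_code
from .voting import weighted_vote
from .volumes import Atlas, IntensityVolume, LabelVolume, VolumeShapeError

__all__ = [
    "GplfThresholds",
    "FusionScores",
    "gplf_fuse_voxel",
    "gplf_decide",
    "compute_fusion_scores",
    "segment_volume",
    "segment_pswv",
    "segment_srlf",
]


@dataclasses.dataclass(frozen=True)
class GplfThresholds:
    """Piecewise-model cut points: high/low Fv cuts and the fusion decision cut."""

    high: float = 0.9
    low: float = 0.4
    decision: float = 0.5

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("low threshold must be below high threshold")


@dataclasses.dataclass(frozen=True)
class FusionScores:
    """Per-voxel Fv_SRLF and Fv_PSWV maps on the target grid."""

    fv_srlf: np.ndarray
    fv_pswv: np.ndarray


def gplf_fuse_voxel(fs: float, fp: float, p: float,
                    cfg: TissueConfig | str,
                    th: GplfThresholds | None = None) -> int:
    """Piecewise fusion decision at one voxel (branches in printed order)."""
    th = th or GplfThresholds()
    cfg = get_tissue(cfg)
    for name, v in (("Fv_SRLF", fs), ("Fv_PSWV", fp), ("P", p)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if fs > th.high or fp > th.high:
        return 1
    if th.low < fs <= th.high and th.low < fp < th.high:
        return 1 if cfg.beta1 * fs * fp * p > th.decision else 0
    if fs <= th.low:
        return 1 if cfg.beta2 * fs * p > th.decision else 0
    if fp <= th.low:
        return 1 if cfg.beta3 * fp * p > th.decision else 0
    # uncovered residual combinations (e.g. fp exactly at the high cut)
    return 1 if cfg.beta1 * fs * fp * p > th.decision else 0


def gplf_decide(fs: np.ndarray, fp: np.ndarray, p: np.ndarray,
                cfg: TissueConfig | str,
                th: GplfThresholds | None = None) -> np.ndarray:
    """Vectorized piecewise decision; same branch order as gplf_fuse_voxel."""
    th = th or GplfThresholds()
    cfg = get_tissue(cfg)
    fs = np.asarray(fs, dtype=np.float64)
    fp = np.asarray(fp, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    lf1 = (cfg.beta1 * fs * fp * p > th.decision).astype(np.uint8)
    lf2 = (cfg.beta2 * fs * p > th.decision).astype(np.uint8)
    lf3 = (cfg.beta3 * fp * p > th.decision).astype(np.uint8)
    cond1 = (fs > th.high) | (fp > th.high)
    cond2 = (fs > th.low) & (fs <= th.high) & (fp > th.low) & (fp < th.high)
    cond3 = fs <= th.low
    cond4 = fp <= th.low
    ones = np.ones_like(lf1)
    return np.select([cond1, cond2, cond3, cond4], [ones, lf1, lf2, lf3],
                     default=lf1).astype(np.uint8)


def _patch_windows(data: np.ndarray, patch_shape) -> np.ndarray:
    """(X, Y, Z, len) view of all patches, edge-replicated at the borders."""
    pads = [(s // 2, s // 2) for s in patch_shape]
    padded = np.pad(data.astype(np.float64), pads, mode="edge")
    win = sliding_window_view(padded, patch_shape)
    return win.reshape(data.shape + (-1,))


def _check_grids(target: IntensityVolume, atlases: Sequence[Atlas]) -> None:
    if not atlases:
        raise NoCandidatesError("no atlases supplied")
    for a in atlases:
        if a.intensity.shape != target.shape:
            raise VolumeShapeError(
                f"atlas {a.id!r} shape {a.intensity.shape} != target {target.shape}")
        if not np.allclose(a.intensity.spacing, target.spacing):
            raise VolumeShapeError(f"atlas {a.id!r} spacing differs from target")


def compute_fusion_scores(target: IntensityVolume, atlases: Sequence[Atlas],
                          sel: SelectionConfig | None = None,
                          srlf_cfg: SrlfConfig | None = None,
                          active: str | np.ndarray = "auto",
                          compute_srlf: bool = True,
                          ) -> tuple[FusionScores, np.ndarray]:
    """Fv_SRLF and Fv_PSWV maps over the target grid.

    For each target slice, candidate patches come from every atlas slice
    within the SR window, at the same in-plane coordinate (ordered by atlas,
    then slice index); NCC ranks them and the top-K are retained.

    ``active`` selects which voxels are computed: ``"auto"`` skips voxels
    whose candidate centre labels are all 0 — there both fusion values are
    exactly 0 by Eq.-level arithmetic, so skipping is lossless; ``"all"``
    computes everything; an explicit boolean mask restricts further.
    Returns the score maps and the "any candidate centre label is 1" mask.
    """
    sel = sel or SelectionConfig()
    srlf_cfg = srlf_cfg or SrlfConfig()
    _check_grids(target, atlases)
    nx, ny, nz = target.shape

    t_win = _patch_windows(target.data, sel.patch_shape)
    a_win = [_patch_windows(a.intensity.data, sel.patch_shape) for a in atlases]
    positions = target.axial_positions
    atlas_positions = [a.intensity.axial_positions for a in atlases]

    fv_s = np.zeros((nx, ny, nz))
    fv_p = np.zeros((nx, ny, nz))
    any_label = np.zeros((nx, ny, nz), dtype=bool)

    for k in range(nz):
        tsp = positions[k]
        cand = [(ai, kk)
                for ai in range(len(atlases))
                for kk in np.flatnonzero(
                    np.abs(atlas_positions[ai] - tsp) <= sel.sr + _POSITION_TOL)]
        if not cand:
            raise NoCandidatesError(
                f"no atlas slice within {sel.sr} mm of slice {k} ({tsp} mm)")
        labs = np.stack([atlases[ai].label.data[:, :, kk] for ai, kk in cand])
        any_l = labs.any(axis=0)
        any_label[:, :, k] = any_l

        if isinstance(active, str):
            act = any_l if active == "auto" else np.ones((nx, ny), dtype=bool)
        else:
            act = np.asarray(active[:, :, k], dtype=bool)
        if not act.any():
            continue

        T = t_win[:, :, k, :]                                  # (X, Y, len)
        P = np.stack([a_win[ai][:, :, kk, :] for ai, kk in cand])  # (C, X, Y, len)
        Tm = T - T.mean(axis=-1, keepdims=True)
        Pm = P - P.mean(axis=-1, keepdims=True)
        tn = np.sqrt((Tm * Tm).sum(axis=-1))
        pn = np.sqrt((Pm * Pm).sum(axis=-1))
        num = (Pm * Tm[None]).sum(axis=-1)
        denom = pn * tn[None]
        sims = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
        sims = np.clip(sims, -1.0, 1.0)

        C = len(cand)
        if C > sel.top_k:
            order = np.argsort(-sims, axis=0, kind="stable")[: sel.top_k]
            sims_k = np.take_along_axis(sims, order, axis=0)
            labs_k = np.take_along_axis(labs, order, axis=0)
        else:
            order = None
            sims_k, labs_k = sims, labs

        w = np.clip(sims_k, 0.0, None)
        sw = w.sum(axis=0)
        vote = (w * labs_k).sum(axis=0) / np.where(sw > 0, sw, 1.0)
        fv_p[:, :, k] = np.where(act & (sw > 0), vote, 0.0)

        if not compute_srlf:
            continue
        for x, y in zip(*np.nonzero(act)):
            if order is None:
                cols = P[:, x, y, :].T
                clabs = labs[:, x, y]
            else:
                idx = order[:, x, y]
                cols = P[idx, x, y, :].T
                clabs = labs[idx, x, y]
            sol = sparse_code(T[x, y], cols, srlf_cfg)
            weights = np.clip(sol.alpha, 0.0, None)
            fv_s[x, y, k] = weighted_vote(weights, clabs).fv

    return FusionScores(fv_s, fv_p), any_label


def segment_volume(target: IntensityVolume, atlases: Sequence[Atlas],
                   pcoeffs, cfg: TissueConfig | str,
                   sel: SelectionConfig | None = None,
                   srlf_cfg: SrlfConfig | None = None,
                   th: GplfThresholds | None = None,
                   fast: bool = True) -> LabelVolume:
    """GP-LF segmentation of a normalized target against warped atlases.

    ``fast=True`` skips voxels whose candidate centre labels are all
    background; the output is bit-identical to the exhaustive path because
    both fusion values are exactly zero there and every piecewise branch
    then returns 0.
    """
    cfg = get_tissue(cfg)
    th = th or GplfThresholds()
    scores, _ = compute_fusion_scores(target, atlases, sel, srlf_cfg,
                                      active="auto" if fast else "all")
    bins = bin_index(target.data, pcoeffs.model)
    p_map = pcoeffs.p[bins]
    dec = gplf_decide(scores.fv_srlf, scores.fv_pswv, p_map, cfg, th)
    return LabelVolume(dec, target.spacing)


def _threshold_scores(fv: np.ndarray, spacing, threshold: float) -> LabelVolume:
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return LabelVolume((fv >= threshold).astype(np.uint8), spacing)


def segment_pswv(target: IntensityVolume, atlases: Sequence[Atlas],
                 sel: SelectionConfig | None = None,
                 threshold: float = 0.5, fast: bool = True) -> LabelVolume:
    """Standalone PSWV segmentation (Fv_PSWV >= threshold)."""
    scores, _ = compute_fusion_scores(target, atlases, sel,
                                      active="auto" if fast else "all",
                                      compute_srlf=False)
    return _threshold_scores(scores.fv_pswv, target.spacing, threshold)


def segment_srlf(target: IntensityVolume, atlases: Sequence[Atlas],
                 sel: SelectionConfig | None = None,
                 srlf_cfg: SrlfConfig | None = None,
                 threshold: float = 0.5, fast: bool = True) -> LabelVolume:
    """Standalone SRLF segmentation (Fv_SRLF >= threshold)."""
    scores, _ = compute_fusion_scores(target, atlases, sel, srlf_cfg,
                                      active="auto" if fast else "all")
    return _threshold_scores(scores.fv_srlf, target.spacing, threshold)
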