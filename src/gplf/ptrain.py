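"""Training of the per-bin greyscale probability coefficients P(x_j).

P assigns each intensity bin of the greyscale model a probability that a
voxel of that intensity belongs to the target tissue; bins outside the
detected tissue range are fixed at 0.  Training maximizes the l1-norm of
the Dice vector obtained by leave-one-out segmentation within the training
atlas set: each atlas in turn is the pseudo-target, segmented by the
piecewise fusion model from the remaining atlases, and scored against its
own label image.

Because the fusion values Fv_SRLF/Fv_PSWV do not depend on P, they are
computed once per pseudo-target and cached; candidate P vectors then only
re-evaluate the (cheap, vectorized) piecewise decision.  The objective is
piecewise-constant in P — the decision thresholds the products beta*Fv*P —
so the optimizer is a deterministic coordinate ascent over a finite
probability grid, not a gradient method.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_dilation

from .fuse import GplfThresholds, compute_fusion_scores, gplf_decide
from .greyscale import (GreyscaleModel, TissueConfig, _set_range_from_values,
                        bin_index, get_tissue)
from .patches import SelectionConfig
from .sparse import SrlfConfig
from .volumes import Atlas

__all__ = ["PCoefficients", "TrainingReport", "evaluate_p_objective",
           "train_p", "save_p", "load_p"]


@dataclasses.dataclass(frozen=True)
class PCoefficients:
    """Trained per-bin probabilities tied to a greyscale model."""

    model: GreyscaleModel
    p: np.ndarray
    tissue: str

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64)
        if p.size != self.model.n_intervals:
            raise ValueError("p length must equal the number of intensity bins")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("p values must lie in [0, 1]")
        outside = np.setdiff1d(np.arange(p.size), self.model.in_range_bins())
        if p[outside].any():
            raise ValueError("p must be 0 outside the tissue range")
        object.__setattr__(self, "p", p)


@dataclasses.dataclass(frozen=True)
class TrainingReport:
    """Per-training-atlas Dice values and their l1 sum (the objective)."""

    dsc_vector: np.ndarray
    objective: float
    n_atlases: int
    iterations: int

    def __post_init__(self) -> None:
        v = np.asarray(self.dsc_vector, dtype=np.float64)
        object.__setattr__(self, "dsc_vector", v)


@dataclasses.dataclass
class _Cache:
    fs: np.ndarray        # Fv_SRLF at active voxels
    fp: np.ndarray        # Fv_PSWV at active voxels
    bins: np.ndarray      # intensity bin of each active voxel
    truth: np.ndarray     # reference label at active voxels
    n_truth: int          # |T| over the whole volume


def _build_caches(training_set: Sequence[Atlas], gs_model: GreyscaleModel,
                  sel: SelectionConfig, srlf_cfg: SrlfConfig) -> list[_Cache]:
    caches = []
    for i, atlas in enumerate(training_set):
        if atlas.label.data.sum() == 0:
            warnings.warn(f"training atlas {atlas.id!r} has an empty tissue "
                          "label; excluded", stacklevel=3)
            continue
        others = [a for j, a in enumerate(training_set) if j != i]
        if not others:
            raise ValueError("need at least 2 usable training atlases")
        data = atlas.intensity.data
        if data.min() < 0 or data.max() > 1:
            raise ValueError(f"training atlas {atlas.id!r} is not normalized")
        scores, any_l = compute_fusion_scores(atlas.intensity, others, sel,
                                              srlf_cfg, active="auto")
        act = any_l
        caches.append(_Cache(
            fs=scores.fv_srlf[act], fp=scores.fv_pswv[act],
            bins=bin_index(data, gs_model)[act],
            truth=atlas.label.data[act].astype(bool),
            n_truth=int(atlas.label.data.sum()),
        ))
    if not caches:
        raise ValueError("no usable training atlases (all labels empty)")
    return caches


def _dsc_vector(p: np.ndarray, caches: Sequence[_Cache], cfg: TissueConfig,
                th: GplfThresholds) -> np.ndarray:
    out = np.empty(len(caches))
    for i, c in enumerate(caches):
        dec = gplf_decide(c.fs, c.fp, p[c.bins], cfg, th).astype(bool)
        nf = int(dec.sum())
        inter = int((dec & c.truth).sum())
        out[i] = 1.0 if c.n_truth + nf == 0 else 2.0 * inter / (c.n_truth + nf)
    return out


def evaluate_p_objective(pcoeffs: PCoefficients, training_set: Sequence[Atlas],
                         cfg: TissueConfig | str,
                         sel: SelectionConfig | None = None,
                         srlf_cfg: SrlfConfig | None = None,
                         th: GplfThresholds | None = None) -> TrainingReport:
    """Leave-one-out Dice vector of a P candidate over the training set."""
    cfg = get_tissue(cfg)
    caches = _build_caches(training_set, pcoeffs.model, sel or SelectionConfig(),
                           srlf_cfg or SrlfConfig())
    dsc = _dsc_vector(pcoeffs.p, caches, cfg, th or GplfThresholds())
    return TrainingReport(dsc, float(dsc.sum()), len(caches), 0)


def train_p(training_set: Sequence[Atlas], cfg: TissueConfig | str,
            sel: SelectionConfig | None = None,
            grid: Sequence[float] | None = None, seed: int = 0,
            max_sweeps: int = 5,
            srlf_cfg: SrlfConfig | None = None,
            th: GplfThresholds | None = None,
            n_start: int = 20, min_fraction: float = 0.01,
            roi_dilation: int = 0,
            ) -> tuple[PCoefficients, TrainingReport]:
    """Coordinate-ascent training of P on a probability grid.

    The greyscale model (bins + tissue range) is built once from the pooled
    tissue intensities of the training atlases — each atlas's intensities at
    its own label voxels, dilated by ``roi_dilation`` voxels — so all
    pseudo-targets share the same bins.  In-range bins start at 0.5 and are swept in ascending
    order; each bin takes the smallest grid value maximizing the summed
    leave-one-out Dice with the other bins held fixed, until a sweep changes
    nothing or ``max_sweeps`` is hit.  Fully deterministic (``seed`` is kept
    for interface symmetry; no randomness is consumed).
    """
    del seed  # the optimizer is deterministic
    cfg = get_tissue(cfg)
    sel = sel or SelectionConfig()
    srlf_cfg = srlf_cfg or SrlfConfig()
    th = th or GplfThresholds()
    if len(training_set) < 2:
        raise ValueError("training needs at least 2 atlases")
    if grid is None:
        grid = np.round(np.linspace(0.0, 1.0, 11), 10)
    grid = np.asarray(sorted(set(float(g) for g in grid)))
    if grid.min() != 0.0 or grid.max() != 1.0:
        raise ValueError("grid must contain 0 and 1")

    # The tissue's greyscale distribution map is read from each atlas's
    # intensities over its own label voxels (optionally dilated into the
    # boundary neighbourhood) — not over the whole head, where a small deep
    # structure would drown and surrounding modes derail the peak count.
    pools = []
    for a in training_set:
        m = a.label.data.astype(bool)
        if roi_dilation:
            m = binary_dilation(m, iterations=roi_dilation)
        pools.append(a.intensity.data[m])
    pooled = np.concatenate(pools)
    if pooled.min() < 0 or pooled.max() > 1:
        raise ValueError("training atlases must be normalized to [0, 1]")
    gs_model = _set_range_from_values(pooled, cfg, n_start, min_fraction)
    caches = _build_caches(training_set, gs_model, sel, srlf_cfg)

    in_bins = gs_model.in_range_bins()
    p = np.zeros(gs_model.n_intervals)
    p[in_bins] = 0.5
    return _train_loop(p, in_bins, grid, caches, cfg, th, max_sweeps, gs_model)


def _train_loop(p, in_bins, grid, caches, cfg, th, max_sweeps, gs_model):
    sweeps = 0
    for _ in range(max_sweeps):
        sweeps += 1
        changed = False
        for b in in_bins:
            old = p[b]
            best_val, best_obj = old, -np.inf
            for g in grid:  # ascending: ties resolve to the smaller value
                p[b] = g
                obj = float(_dsc_vector(p, caches, cfg, th).sum())
                if obj > best_obj:
                    best_val, best_obj = g, obj
            p[b] = best_val
            if best_val != old:
                changed = True
        if not changed:
            break
    dsc = _dsc_vector(p, caches, cfg, th)
    report = TrainingReport(dsc, float(dsc.sum()), len(caches), sweeps)
    return PCoefficients(gs_model, p, cfg.name), report


def save_p(pcoeffs: PCoefficients, path) -> None:
    """JSON round-trip of the trained coefficients and their bin model."""
    m = pcoeffs.model
    payload = {
        "tissue": pcoeffs.tissue,
        "n_intervals": int(m.n_intervals),
        "bin_edges": m.bin_edges.tolist(),
        "peak_bins": m.peak_bins.tolist(),
        "isn_max": int(m.isn_max),
        "tissue_range": list(m.tissue_range),
        "p": pcoeffs.p.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_p(path) -> PCoefficients:
    with open(path) as fh:
        raw = json.load(fh)
    try:
        model = GreyscaleModel(
            n_intervals=int(raw["n_intervals"]),
            bin_edges=np.asarray(raw["bin_edges"], dtype=np.float64),
            peak_bins=np.asarray(raw["peak_bins"], dtype=np.intp),
            isn_max=int(raw["isn_max"]),
            tissue_range=tuple(raw["tissue_range"]),
        )
        return PCoefficients(model, np.asarray(raw["p"], dtype=np.float64),
                             str(raw["tissue"]))
    except KeyError as exc:
        raise ValueError(f"malformed coefficient file {path}: missing {exc}") from exc
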