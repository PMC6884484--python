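"""Sparse-representation label fusion (SRLF).

The target patch PT is approximated as a sparse combination of the
dictionary columns D_I (the retained atlas patches):

    min ||alpha||_0   subject to   ||PT - D_I alpha||_2 <= epsilon

solved greedily by orthogonal matching pursuit (OMP): repeatedly add the
column most correlated with the current residual, refit all coefficients on
the support by least squares, and stop once the residual tolerance or the
sparsity cap is reached.  The fitted coefficients, clipped at zero, are the
voting weights.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import nnls

from .patches import PatchLibrary
from .voting import VoteResult, weighted_vote

__all__ = ["SrlfConfig", "SparseSolution", "sparse_code", "srlf_fuse_voxel"]


@dataclasses.dataclass
class SrlfConfig:
    """OMP controls.

    epsilon : absolute residual-norm tolerance; ``None`` means the relative
        default ``0.01 * ||PT||_2``.
    max_support : sparsity cap (number of atoms), default 5.
    nonnegative : restrict atom selection to positively-correlated columns
        and refit coefficients under alpha >= 0.
    """

    epsilon: float | None = None
    max_support: int = 5
    nonnegative: bool = False

    def __post_init__(self) -> None:
        if self.epsilon is not None and self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.max_support < 1:
            raise ValueError("max_support must be >= 1")


@dataclasses.dataclass(frozen=True)
class SparseSolution:
    """alpha: full coefficient vector; support: indices with nonzero alpha."""

    alpha: np.ndarray
    residual_norm: float
    support: np.ndarray


def _as_matrix(dictionary) -> np.ndarray:
    if isinstance(dictionary, PatchLibrary):
        return dictionary.columns
    return np.asarray(dictionary, dtype=np.float64)


def sparse_code(target, dictionary, cfg: SrlfConfig | None = None) -> SparseSolution:
    """Greedy L0 approximation of the target over the dictionary columns.

    Columns are l2-normalized for correlation ranking only; coefficients are
    always fitted against the raw columns.  Deterministic: correlation ties
    resolve to the lowest column index.
    """
    cfg = cfg or SrlfConfig()
    D = _as_matrix(dictionary)
    if D.ndim != 2 or D.shape[1] == 0:
        raise ValueError("dictionary must be a non-empty (len, m) matrix")
    pt = np.asarray(target, dtype=np.float64).ravel()
    if pt.size != D.shape[0]:
        raise ValueError(f"target length {pt.size} != column length {D.shape[0]}")
    m = D.shape[1]
    eps = cfg.epsilon if cfg.epsilon is not None else 0.01 * float(np.linalg.norm(pt))

    norms = np.linalg.norm(D, axis=0)
    usable = norms > 1e-12
    N = np.where(usable, norms, 1.0)

    support: list[int] = []
    coef = np.zeros(0)
    residual = pt.copy()
    while len(support) < min(cfg.max_support, m):
        if np.linalg.norm(residual) <= eps:
            break
        corr = (D.T @ residual) / N
        score = corr if cfg.nonnegative else np.abs(corr)
        score[~usable] = -np.inf
        score[support] = -np.inf
        j = int(np.argmax(score))
        if score[j] <= 1e-12:
            break
        support.append(j)
        Ds = D[:, support]
        if cfg.nonnegative:
            coef, _ = nnls(Ds, pt)
        else:
            coef = np.linalg.lstsq(Ds, pt, rcond=None)[0]
        residual = pt - Ds @ coef

    alpha = np.zeros(m)
    if support:
        alpha[support] = coef
    residual_norm = float(np.linalg.norm(pt - D @ alpha))
    return SparseSolution(alpha, residual_norm, np.flatnonzero(alpha))


def srlf_fuse_voxel(target, library: PatchLibrary,
                    cfg: SrlfConfig | None = None) -> VoteResult:
    """SRLF at one voxel: sparse coefficients (clipped at 0) are the weights."""
    vec = target.vector if hasattr(target, "vector") else target
    sol = sparse_code(vec, library, cfg)
    weights = np.clip(sol.alpha, 0.0, None)
    return weighted_vote(weights, library.center_labels)
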