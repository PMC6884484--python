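"""Independent reference implementations used only by the test suite.

Everything here is deliberately naive — literal transcriptions, brute-force
set arithmetic and exhaustive enumeration — and shares no code with the
package paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def gplf_literal(fs: float, fp: float, p: float,
                 beta1: float, beta2: float, beta3: float,
                 high: float = 0.9, low: float = 0.4,
                 decision: float = 0.5) -> int:
    """Literal transcription of the piecewise fusion rule, branch by branch.

    Conditions are tested in the printed order; combinations matching no
    condition use the first fusion formula.
    """
    if fs > high or fp > high:
        return 1
    if low < fs <= high and low < fp < high:
        fusion1 = beta1 * fs * fp * p
        return 1 if fusion1 > decision else 0
    if fs <= low:
        fusion2 = beta2 * fs * p
        return 1 if fusion2 > decision else 0
    if fp <= low:
        fusion3 = beta3 * fp * p
        return 1 if fusion3 > decision else 0
    fusion1 = beta1 * fs * fp * p
    return 1 if fusion1 > decision else 0


# ---------------------------------------------------------------- metrics

def _voxel_sets(t: np.ndarray, f: np.ndarray):
    T = {tuple(v) for v in np.argwhere(np.asarray(t, dtype=bool))}
    F = {tuple(v) for v in np.argwhere(np.asarray(f, dtype=bool))}
    return T, F


def brute_dice(t, f) -> float:
    T, F = _voxel_sets(t, f)
    if not T and not F:
        return 1.0
    return 2 * len(T & F) / (len(T) + len(F))


def brute_recall(t, f) -> float:
    T, F = _voxel_sets(t, f)
    if not T:
        return float("nan")
    return len(T & F) / len(T)


def brute_precision(t, f) -> float:
    T, F = _voxel_sets(t, f)
    if not F:
        return float("nan")
    return len(T & F) / len(F)


def brute_hausdorff(t, f, spacing=(1.0, 1.0, 1.0)) -> float:
    """O(|T|*|F|) max-min pairwise Euclidean distance, both directions."""
    T, F = _voxel_sets(t, f)
    if not T or not F:
        return float("nan")

    def d(a, b):
        return math.sqrt(sum(((ai - bi) * s) ** 2
                             for ai, bi, s in zip(a, b, spacing)))

    h1 = max(min(d(pt, pf) for pf in F) for pt in T)
    h2 = max(min(d(pt, pf) for pt in T) for pf in F)
    return max(h1, h2)


# ---------------------------------------------------------------- sparse

def exhaustive_l0(pt: np.ndarray, D: np.ndarray, max_support: int):
    """Best residual over every column subset of size <= max_support."""
    pt = np.asarray(pt, dtype=float)
    D = np.asarray(D, dtype=float)
    best_res = float(np.linalg.norm(pt))
    best_sup: tuple[int, ...] = ()
    for r in range(1, max_support + 1):
        for sub in itertools.combinations(range(D.shape[1]), r):
            coef = np.linalg.lstsq(D[:, sub], pt, rcond=None)[0]
            res = float(np.linalg.norm(pt - D[:, sub] @ coef))
            if res < best_res - 1e-12:
                best_res, best_sup = res, sub
    return best_res, best_sup


def incoherent_dictionary(rng: np.random.Generator, max_len: int = 6,
                          max_m: int = 8, mu: float = 0.5) -> np.ndarray:
    """Random Gaussian dictionary rejection-sampled to mutual coherence < mu.

    The incoherent regime is where greedy pursuit is a faithful surrogate of
    the exhaustive L0 problem (the classical mu*(2k-1) < 1 condition).
    """
    while True:
        ln = int(rng.integers(4, max_len + 1))
        m = int(rng.integers(2, max_m + 1))
        D = rng.standard_normal((ln, m))
        Dn = D / np.linalg.norm(D, axis=0)
        G = np.abs(Dn.T @ Dn)
        np.fill_diagonal(G, 0.0)
        if G.max() < mu:
            return D


# ---------------------------------------------------------------- shapes

def ellipsoid_count(grid_shape, center, semi_axes) -> int:
    """Brute-force voxel membership count of the ellipsoid inequality."""
    n = 0
    for i in range(grid_shape[0]):
        for j in range(grid_shape[1]):
            for k in range(grid_shape[2]):
                v = sum(((c - cc) / s) ** 2
                        for c, cc, s in zip((i, j, k), center, semi_axes))
                if v <= 1.0:
                    n += 1
    return n


def majority_vote(labels) -> float:
    """Unweighted vote fraction by plain counting."""
    labels = list(labels)
    return sum(labels) / len(labels)
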