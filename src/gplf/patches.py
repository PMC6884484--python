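"""Atlas-slice selection, patch extraction and NCC-ranked patch libraries.

Atlas selection is positional: for a target slice at physical position TSP
(mm), every atlas slice whose axial position lies in the closed interval
[TSP - SR, TSP + SR] contributes one candidate patch, taken at the same
in-plane coordinate as the target voxel.  Candidates are ranked by
normalized correlation (NCC) against the target patch and only the top-K
most similar are kept for fusion.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .volumes import Atlas, IntensityVolume, LabelVolume

__all__ = [
    "Patch",
    "PatchLibrary",
    "SelectionConfig",
    "AtlasSlice",
    "NoCandidatesError",
    "select_atlases_by_position",
    "extract_patch",
    "ncc",
    "build_patch_library",
]

#: absolute slack on the closed selection interval, to absorb float position
#: arithmetic (e.g. 2 * 1.5 mm vs 3 mm)
_POSITION_TOL = 1e-9


class NoCandidatesError(ValueError):
    """No atlas slice / patch candidate satisfies the selection criteria."""


@dataclasses.dataclass(frozen=True)
class Patch:
    """A vectorized image patch in fixed raster (C) order."""

    vector: np.ndarray
    center: tuple[int, int, int]
    source_id: str = "target"

    def __post_init__(self) -> None:
        object.__setattr__(self, "vector",
                           np.asarray(self.vector, dtype=np.float64).ravel())


@dataclasses.dataclass
class SelectionConfig:
    """Atlas/patch selection parameters.

    sr : search radius in mm around the target slice position (default 3)
    top_k : number of most-similar patches kept for fusion (default 60)
    patch_shape : per-axis patch extent in voxels; all odd (default 7x7x3)
    """

    sr: float = 3.0
    top_k: int = 60
    patch_shape: tuple[int, int, int] = (7, 7, 3)

    def __post_init__(self) -> None:
        if self.sr < 0:
            raise ValueError("sr must be >= 0")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        ps = tuple(int(p) for p in self.patch_shape)
        if len(ps) != 3 or any(p < 1 or p % 2 == 0 for p in ps):
            raise ValueError(f"patch extents must be odd and >= 1, got {ps}")
        self.patch_shape = ps


@dataclasses.dataclass(frozen=True)
class AtlasSlice:
    """Reference to one axial slice of one atlas."""

    atlas: Atlas
    slice_index: int
    position: float


def select_atlases_by_position(atlases: Sequence[Atlas], tsp: float,
                               sr: float) -> list[AtlasSlice]:
    """Atlas slices with axial position in [TSP - SR, TSP + SR] (closed).

    Ordered by atlas input order, then ascending slice index.  Raises
    :class:`NoCandidatesError` when empty (the caller must widen SR).
    """
    out: list[AtlasSlice] = []
    for atlas in atlases:
        for k, pos in enumerate(atlas.intensity.axial_positions):
            if tsp - sr - _POSITION_TOL <= pos <= tsp + sr + _POSITION_TOL:
                out.append(AtlasSlice(atlas, k, float(pos)))
    if not out:
        raise NoCandidatesError(
            f"no atlas slice within {sr} mm of position {tsp} mm")
    return out


def extract_patch(vol: IntensityVolume | LabelVolume,
                  center: tuple[int, int, int],
                  patch_shape: tuple[int, int, int],
                  source_id: str = "target") -> Patch:
    """Vectorized patch centred at ``center``; borders use edge replication."""
    data = vol.data
    idx = []
    for ax in range(3):
        half = patch_shape[ax] // 2
        c = int(center[ax])
        idx.append(np.clip(np.arange(c - half, c + half + 1), 0, data.shape[ax] - 1))
    block = data[np.ix_(*idx)]
    return Patch(block.ravel(order="C"), tuple(int(c) for c in center), source_id)


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson-type normalized correlation in [-1, 1]; 0 if either is constant."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("ncc needs vectors of length >= 2")
    am = a - a.mean()
    bm = b - b.mean()
    na = np.sqrt((am * am).sum())
    nb = np.sqrt((bm * bm).sum())
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip((am * bm).sum() / (na * nb), -1.0, 1.0))


@dataclasses.dataclass
class PatchLibrary:
    """The retained, NCC-ranked patch dictionary at one target voxel.

    columns : (len, m) array whose columns are atlas patch vectors (D_I)
    center_labels : (m,) binary label of each patch's centre voxel
    similarities : (m,) NCC of each column against the target patch,
        non-increasing
    """

    columns: np.ndarray
    center_labels: np.ndarray
    similarities: np.ndarray

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=np.float64)
        self.center_labels = np.asarray(self.center_labels)
        self.similarities = np.asarray(self.similarities, dtype=np.float64)
        m = self.columns.shape[1] if self.columns.ndim == 2 else 0
        if not (m == self.center_labels.size == self.similarities.size):
            raise ValueError("columns, center_labels and similarities disagree on m")
        if not np.isin(np.unique(self.center_labels), (0, 1)).all():
            raise ValueError("center_labels must be binary")

    def __len__(self) -> int:
        return int(self.columns.shape[1])


def build_patch_library(target_patch: Patch,
                        candidates: Sequence[tuple[Patch, int]],
                        k: int = 60) -> PatchLibrary:
    """Rank candidates by NCC against the target patch and keep the top k.

    Ties are broken by candidate input order (stable sort).
    """
    if len(candidates) == 0:
        raise NoCandidatesError("empty candidate list")
    sims = np.array([ncc(target_patch.vector, p.vector) for p, _ in candidates])
    order = np.argsort(-sims, kind="stable")[: min(int(k), len(candidates))]
    columns = np.stack([candidates[i][0].vector for i in order], axis=1)
    labels = np.array([candidates[i][1] for i in order], dtype=np.uint8)
    return PatchLibrary(columns, labels, sims[order])
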