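"""Greyscale histogram model and target-tissue intensity range setting.

After min–max normalization all intensities live in [0, 1].  The range is
divided into N_I equal bins ([k/N, (k+1)/N), the last bin closed at 1) and
the target tissue's intensity range is located from the histogram peaks:
with 2 or 3 peaks the upper tissue bound is the value of the highest-index
peak bin (ISNmax) plus a per-tissue offset Ov, and the lower bound follows
from the tissue's known intensity span; with 1 peak the histogram is
re-binned at 2x resolution, with more than 3 peaks at half resolution.
"""

from __future__ import annotations

import dataclasses
import numpy as np
import yaml

from .volumes import IntensityVolume, LabelVolume

__all__ = [
    "TissueConfig",
    "GreyscaleModel",
    "RangeDetectionError",
    "DEFAULT_TISSUES",
    "get_tissue",
    "load_tissue_configs",
    "histogram_counts",
    "detect_peaks",
    "set_tissue_range",
    "bin_index",
]


class RangeDetectionError(RuntimeError):
    """No usable peak structure found at any binning scale."""


@dataclasses.dataclass(frozen=True)
class TissueConfig:
    """Per-tissue fusion coefficients and greyscale-range parameters.

    beta1..beta3 weight the three piecewise fusion formulas; ``span`` is the
    tissue's intensity span (normalized units) and ``offset`` the amount Ov
    added to the ISNmax bin value to place the upper intensity bound.
    """

    name: str
    beta1: float
    beta2: float
    beta3: float
    span: float
    offset: float

    def __post_init__(self) -> None:
        if min(self.beta1, self.beta2, self.beta3) <= 0:
            raise ValueError("beta coefficients must be positive")
        if not 0 < self.span <= 1:
            raise ValueError("span must lie in (0, 1]")


# Deep-brain structures with their trained fusion coefficients.  beta1 is
# shared (3.13); (beta2, beta3), span and offset are structure-specific.
DEFAULT_TISSUES: dict[str, TissueConfig] = {
    t.name: t
    for t in (
        TissueConfig("thalamus", 3.13, 1.25, 0.67, 0.60, +0.15),
        TissueConfig("hippocampus", 3.13, 1.67, 2.50, 0.50, 0.00),
        TissueConfig("caudate", 3.13, 0.625, 0.83, 0.50, 0.00),
        TissueConfig("putamen", 3.13, 0.72, 1.00, 0.50, +0.10),
        TissueConfig("pallidum", 3.13, 0.83, 1.25, 0.50, +0.15),
        TissueConfig("amygdala", 3.13, 1.00, 0.25, 0.50, -0.05),
    )
}


def get_tissue(name_or_cfg: str | TissueConfig) -> TissueConfig:
    if isinstance(name_or_cfg, TissueConfig):
        return name_or_cfg
    try:
        return DEFAULT_TISSUES[name_or_cfg]
    except KeyError:
        known = ", ".join(sorted(DEFAULT_TISSUES))
        raise KeyError(f"unknown tissue {name_or_cfg!r}; known tissues: {known}") from None


def load_tissue_configs(path) -> dict[str, TissueConfig]:
    """Load tissue configs from a YAML/JSON mapping name -> parameters."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, params in raw.items():
        out[name] = TissueConfig(name=name, **{k: float(v) for k, v in params.items()})
    return out


@dataclasses.dataclass(frozen=True)
class GreyscaleModel:
    """Binned intensity model with detected peaks and tissue range."""

    n_intervals: int
    bin_edges: np.ndarray
    peak_bins: np.ndarray
    isn_max: int
    tissue_range: tuple[float, float]

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        if edges.size != self.n_intervals + 1 or (np.diff(edges) <= 0).any():
            raise ValueError("bin_edges must be strictly increasing, N+1 long")
        lo, hi = self.tissue_range
        if not 0 <= lo < hi <= 1:
            raise ValueError(f"invalid tissue range [{lo}, {hi}]")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "peak_bins",
                           np.asarray(self.peak_bins, dtype=np.intp))

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def in_range_bins(self) -> np.ndarray:
        """Bins whose centre lies inside the tissue range (inclusive)."""
        lo, hi = self.tissue_range
        c = self.bin_centers
        return np.flatnonzero((c >= lo) & (c <= hi))


def _masked_values(vol: IntensityVolume, mask) -> np.ndarray:
    data = vol.data
    if mask is None:
        m = data != 0
    else:
        marr = mask.data if isinstance(mask, LabelVolume) else np.asarray(mask)
        m = marr.astype(bool)
    vals = data[m]
    if vals.size == 0:
        raise ValueError("mask selects no voxels")
    return vals


def _bin_of(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, edges.size - 2)


def histogram_counts(vol: IntensityVolume, mask=None, n_intervals: int = 20) -> np.ndarray:
    """Counts over ``n_intervals`` equal-width bins of [0, 1] (last closed)."""
    if n_intervals < 2:
        raise ValueError("n_intervals must be >= 2")
    vals = _masked_values(vol, mask)
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("volume must be normalized to [0, 1] before binning")
    edges = np.linspace(0.0, 1.0, n_intervals + 1)
    return np.bincount(_bin_of(vals, edges), minlength=n_intervals)


def detect_peaks(counts, min_fraction: float = 0.01) -> np.ndarray:
    """Strict interior local maxima carrying at least ``min_fraction`` of mass.

    Plateaus are not peaks and the first/last bins never qualify.
    """
    c = np.asarray(counts, dtype=np.float64)
    if c.size < 3:
        raise ValueError("need at least 3 bins to detect peaks")
    total = c.sum()
    interior = np.arange(1, c.size - 1)
    is_peak = (c[interior] > c[interior - 1]) & (c[interior] > c[interior + 1])
    if total > 0:
        is_peak &= c[interior] >= min_fraction * total
    return interior[is_peak]


def set_tissue_range(vol: IntensityVolume, mask, cfg: TissueConfig,
                     n_start: int = 20, min_fraction: float = 0.01,
                     max_rounds: int = 4) -> GreyscaleModel:
    """Iterative re-binning tissue range detection.

    At each round the histogram has N bins: 2 or 3 peaks fix the range
    (upper = value(ISNmax) + offset, lower = upper - span, both clipped to
    [0, 1]); 0 or 1 peaks double N; more than 3 peaks halve N.  After
    ``max_rounds`` rounds the round whose peak count is closest to 2 wins.
    The value of a bin is its upper edge.
    """
    vals = _masked_values(vol, mask)
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("volume must be normalized to [0, 1]")
    return _set_range_from_values(vals, cfg, n_start, min_fraction, max_rounds)


def _set_range_from_values(vals: np.ndarray, cfg: TissueConfig,
                           n_start: int = 20, min_fraction: float = 0.01,
                           max_rounds: int = 4) -> GreyscaleModel:
    n = int(n_start)
    rounds: list[tuple[int, np.ndarray, np.ndarray]] = []
    chosen = None
    for _ in range(max_rounds):
        edges = np.linspace(0.0, 1.0, n + 1)
        counts = np.bincount(_bin_of(vals, edges), minlength=n)
        peaks = detect_peaks(counts, min_fraction)
        rounds.append((n, edges, peaks))
        if len(peaks) in (2, 3):
            chosen = rounds[-1]
            break
        n = n * 2 if len(peaks) <= 1 else max(2, n // 2)
    if chosen is None:
        with_peaks = [r for r in rounds if len(r[2]) >= 1]
        if not with_peaks:
            raise RangeDetectionError(
                "no histogram peaks at any binning scale; cannot set tissue range")
        chosen = min(with_peaks, key=lambda r: abs(len(r[2]) - 2))
    n, edges, peaks = chosen
    isn_max = int(peaks.max())
    upper = float(edges[isn_max + 1]) + cfg.offset
    lower = upper - cfg.span
    upper = min(max(upper, 0.0), 1.0)
    lower = min(max(lower, 0.0), 1.0)
    if not lower < upper:
        raise RangeDetectionError(
            f"degenerate tissue range [{lower}, {upper}] for {cfg.name}")
    return GreyscaleModel(n, edges, peaks, isn_max, (lower, upper))


def bin_index(intensity, model: GreyscaleModel):
    """Bin index of an intensity (scalar or array) under the model's edges."""
    x = np.asarray(intensity, dtype=np.float64)
    if (x < 0).any() or (x > 1).any():
        raise ValueError("intensity outside [0, 1]")
    idx = _bin_of(x, model.bin_edges)
    return int(idx) if np.isscalar(intensity) or idx.ndim == 0 else idx
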