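"""Top-level modelling API: a fit/results pair in the statsmodels style.

``GPLFModel`` holds the warped-atlas training data and the tissue/selection
configuration; ``fit()`` trains the per-bin greyscale probabilities and
returns ``GPLFResults`` carrying the estimates, the training diagnostics,
a ``summary()`` table and the ``segment()`` method for new targets.
"""

from __future__ import annotations

import glob
import os
from typing import Sequence

import numpy as np

from .fuse import GplfThresholds, segment_pswv, segment_srlf, segment_volume
from .greyscale import TissueConfig, get_tissue
from .patches import SelectionConfig
from .ptrain import PCoefficients, TrainingReport, save_p, train_p
from .sparse import SrlfConfig
from .volumes import (Atlas, IntensityVolume, LabelVolume, normalize_intensity,
                      read_label, read_volume)

__all__ = ["GPLFModel", "GPLFResults"]


def _normalized(vol: IntensityVolume) -> IntensityVolume:
    """Pipeline normalization: min–max over the nonzero foreground."""
    data = vol.data
    if data.size and data.min() >= 0 and data.max() <= 1 \
            and data.min() == 0 and data.max() == 1:
        return vol
    return normalize_intensity(vol)


class GPLFModel:
    """Greyscale-probability label fusion model over a warped-atlas set.

    Parameters
    ----------
    atlases : sequence of Atlas
        Co-registered (warped) atlases; intensities are min–max normalized
        on construction unless ``normalize=False``.
    tissue : str or TissueConfig
        Target structure; a name selects the shipped deep-brain
        configuration (beta coefficients, intensity span, offset).
    selection, srlf, thresholds
        Patch-selection, sparse-coding and piecewise-model parameters.
    """

    def __init__(self, atlases: Sequence[Atlas],
                 tissue: str | TissueConfig = "thalamus",
                 selection: SelectionConfig | None = None,
                 srlf: SrlfConfig | None = None,
                 thresholds: GplfThresholds | None = None,
                 normalize: bool = True):
        self.tissue = get_tissue(tissue)
        self.selection = selection or SelectionConfig()
        self.srlf = srlf or SrlfConfig()
        self.thresholds = thresholds or GplfThresholds()
        self.normalize = normalize
        if normalize:
            atlases = [Atlas(a.id, _normalized(a.intensity), a.label)
                       for a in atlases]
        self.atlases = list(atlases)

    @classmethod
    def from_directory(cls, path, tissue: str | TissueConfig = "thalamus",
                       **kwargs) -> "GPLFModel":
        """Build from a directory of ``<id>_intensity.nii`` / ``<id>_label.nii``
        pairs (the layout written by :func:`gplf.synthetic.make_dataset`)."""
        atlases = []
        for ipath in sorted(glob.glob(os.path.join(str(path), "atlas_*_intensity.nii*"))):
            lpath = ipath.replace("_intensity.nii", "_label.nii")
            aid = os.path.basename(ipath).split("_intensity")[0]
            atlases.append(Atlas(aid, read_volume(ipath), read_label(lpath)))
        if not atlases:
            raise FileNotFoundError(f"no atlas_*_intensity.nii files under {path}")
        return cls(atlases, tissue=tissue, **kwargs)

    def fit(self, grid=None, max_sweeps: int = 5, seed: int = 0,
            n_bins: int = 20) -> "GPLFResults":
        """Train P(x_j) by coordinate ascent and return the results object."""
        pcoeffs, report = train_p(self.atlases, self.tissue, self.selection,
                                  grid=grid, seed=seed, max_sweeps=max_sweeps,
                                  srlf_cfg=self.srlf, th=self.thresholds,
                                  n_start=n_bins)
        return GPLFResults(self, pcoeffs, report)

    def results_from_coefficients(self, pcoeffs: PCoefficients) -> "GPLFResults":
        """Wrap pre-trained coefficients (e.g. from :func:`gplf.ptrain.load_p`)."""
        return GPLFResults(self, pcoeffs, None)


class GPLFResults:
    """Fit results: trained probabilities, diagnostics and segmentation."""

    def __init__(self, model: GPLFModel, pcoeffs: PCoefficients,
                 report: TrainingReport | None):
        self.model = model
        self.pcoeffs = pcoeffs
        self.report = report

    @property
    def params(self) -> np.ndarray:
        """The trained per-bin probability vector P."""
        return self.pcoeffs.p

    @property
    def tissue_range(self) -> tuple[float, float]:
        return self.pcoeffs.model.tissue_range

    def segment(self, target: IntensityVolume, method: str = "gplf",
                fast: bool = True, threshold: float = 0.5) -> LabelVolume:
        """Segment a target volume with GP-LF (or PSWV/SRLF baselines)."""
        m = self.model
        if m.normalize:
            target = _normalized(target)
        if method == "gplf":
            return segment_volume(target, m.atlases, self.pcoeffs, m.tissue,
                                  m.selection, m.srlf, m.thresholds, fast=fast)
        if method == "pswv":
            return segment_pswv(target, m.atlases, m.selection,
                                threshold=threshold, fast=fast)
        if method == "srlf":
            return segment_srlf(target, m.atlases, m.selection, m.srlf,
                                threshold=threshold, fast=fast)
        raise ValueError(f"unknown method {method!r}; use gplf, pswv or srlf")

    def save(self, path) -> None:
        save_p(self.pcoeffs, path)

    def summary(self) -> str:
        """Plain-text summary of the fit, statsmodels style."""
        t = self.model.tissue
        m = self.pcoeffs.model
        lo, hi = m.tissue_range
        lines = [
            "GP-LF greyscale-probability fit",
            "=" * 46,
            f"tissue:            {t.name}",
            f"beta1/beta2/beta3: {t.beta1:g} / {t.beta2:g} / {t.beta3:g}",
            f"atlases:           {len(self.model.atlases)}",
            f"intensity bins:    {m.n_intervals} (ISNmax bin {m.isn_max})",
            f"tissue range:      [{lo:.3f}, {hi:.3f}]",
        ]
        if self.report is not None:
            r = self.report
            lines += [
                f"objective ||Dsc||1: {r.objective:.4f} over {r.n_atlases} "
                f"pseudo-targets ({r.iterations} sweeps)",
                "per-atlas Dice:    "
                + ", ".join(f"{d:.3f}" for d in r.dsc_vector),
            ]
        lines.append("-" * 46)
        lines.append(" bin    interval          P")
        for b in m.in_range_bins():
            e0, e1 = m.bin_edges[b], m.bin_edges[b + 1]
            lines.append(f" {b:3d}  [{e0:.3f}, {e1:.3f})   {self.pcoeffs.p[b]:.2f}")
        return "\n".join(lines)
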