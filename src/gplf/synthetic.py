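"""Synthetic phantoms and warped-atlas sets.

The generator stands in for the registration stage of a real multi-atlas
pipeline: it builds a piecewise-constant tissue phantom (ellipsoid/box
primitives plus Gaussian noise) and derives "warped atlases" from it by
smooth random deformations — white-noise displacement fields smoothed with
a Gaussian kernel, rescaled to a chosen amplitude — emulating residual
registration error.  Intensity and label channels are warped with the same
field (linear vs nearest-neighbour interpolation) and each atlas receives a
small intensity scale/shift jitter emulating non-standard MR intensities.
Everything is deterministic per seed (numpy PCG64).
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .volumes import Atlas, IntensityVolume, LabelVolume, normalize_intensity, write_volume

__all__ = ["ShapeSpec", "PhantomSpec", "WarpSpec", "make_phantom",
           "make_warped_atlases", "make_dataset"]

MANIFEST_SCHEMA = 1


@dataclasses.dataclass(frozen=True)
class ShapeSpec:
    """One primitive: kind 'ellipsoid' (size = semi-axes, voxels) or
    'box' (size = half-extents, voxels), painted at ``intensity``."""

    kind: str
    center: tuple[float, float, float]
    size: tuple[float, float, float]
    intensity: float

    def mask(self, grid_shape) -> np.ndarray:
        coords = np.indices(grid_shape, dtype=np.float64)
        rel = [(coords[i] - self.center[i]) / self.size[i] for i in range(3)]
        if self.kind == "ellipsoid":
            return rel[0] ** 2 + rel[1] ** 2 + rel[2] ** 2 <= 1.0
        if self.kind == "box":
            return (np.abs(rel[0]) <= 1) & (np.abs(rel[1]) <= 1) & (np.abs(rel[2]) <= 1)
        raise ValueError(f"unknown shape kind {self.kind!r}")


def _default_shapes() -> tuple[ShapeSpec, ...]:
    # a "head" ellipsoid of surrounding tissue plus a deep target structure
    return (
        ShapeSpec("ellipsoid", (24.0, 24.0, 6.0), (20.0, 20.0, 5.5), 0.35),
        ShapeSpec("ellipsoid", (24.0, 22.0, 6.0), (8.0, 8.0, 3.0), 0.60),
    )


@dataclasses.dataclass
class PhantomSpec:
    """Piecewise-constant phantom description.

    The default grid (48x48x12 voxels at 1x1x1.5 mm) is a desk-scale stand-in
    for IBSR-style volumes; the last listed shape is the target structure.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 12)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.5)
    tissue_shapes: tuple[ShapeSpec, ...] = dataclasses.field(default_factory=_default_shapes)
    noise_sigma: float = 0.03
    background_intensity: float = 0.15
    target_index: int = -1
    enforce_separability: bool = True

    def __post_init__(self) -> None:
        self.tissue_shapes = tuple(self.tissue_shapes)
        if self.enforce_separability and self.noise_sigma > 0:
            for s in self.tissue_shapes:
                if abs(s.intensity - self.background_intensity) < 2 * self.noise_sigma:
                    raise ValueError(
                        f"shape intensity {s.intensity} within 2*noise_sigma of "
                        f"background {self.background_intensity}; set "
                        "enforce_separability=False to override")


@dataclasses.dataclass
class WarpSpec:
    """Deformation/jitter parameters for the warped-atlas generator.

    displacement_sigma is the per-axis displacement amplitude in voxels
    (std of the smoothed field); smoothness the Gaussian smoothing scale of
    the field in voxels; intensity_jitter = (max relative scale, max shift).
    """

    n_atlases: int = 6
    displacement_sigma: float = 1.5
    smoothness: float = 4.0
    intensity_jitter: tuple[float, float] = (0.10, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atlases < 1:
            raise ValueError("n_atlases must be >= 1")
        if self.displacement_sigma < 0:
            raise ValueError("displacement_sigma must be >= 0")


def make_phantom(spec: PhantomSpec | None = None,
                 seed: int = 0) -> tuple[IntensityVolume, LabelVolume]:
    """Noisy piecewise-constant phantom plus the target structure's label."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    shape = tuple(spec.grid_shape)
    data = np.full(shape, spec.background_intensity, dtype=np.float64)
    painted = np.zeros(shape, dtype=bool)
    masks = []
    for i, s in enumerate(spec.tissue_shapes):
        m = s.mask(shape)
        # nesting (full containment) is how deep structures are modelled;
        # only a partial overlap indicates clashing primitives
        if i > 0 and (m & painted).any() and not (m <= painted).all():
            warnings.warn(f"shape {i} partially overlaps an earlier primitive; "
                          "later wins", stacklevel=2)
        data[m] = s.intensity
        painted |= m
        masks.append(m)
    label = masks[spec.target_index].astype(np.uint8)
    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, shape)
    vol = IntensityVolume(data, spec.spacing)
    vol = normalize_intensity(vol, mask=np.ones(shape, dtype=bool))
    vol = IntensityVolume(np.clip(vol.data, 0.0, 1.0), spec.spacing)
    return vol, LabelVolume(label, spec.spacing)


def _displacement_field(rng: np.random.Generator, shape,
                        sigma: float, smoothness: float) -> list[np.ndarray]:
    field = []
    for _ in range(3):
        f = rng.standard_normal(shape)
        if smoothness > 0:
            f = gaussian_filter(f, smoothness)
        s = f.std()
        f = f * (sigma / s) if (s > 0 and sigma > 0) else np.zeros(shape)
        field.append(f)
    return field


def make_warped_atlases(truth: tuple[IntensityVolume, LabelVolume],
                        warp: WarpSpec | None = None) -> list[Atlas]:
    """Warp the ground-truth pair into n synthetic atlases.

    One smooth random displacement field per atlas deforms intensity
    (linear interpolation) and label (nearest neighbour) together; a
    per-atlas intensity scale/shift jitter is applied afterwards and the
    result clipped to [0, 1].
    """
    warp = warp or WarpSpec()
    intens, label = truth
    if intens.shape != label.shape:
        raise ValueError("truth intensity and label grids differ")
    shape = intens.shape
    rng = np.random.default_rng(warp.seed)
    base = np.indices(shape, dtype=np.float64)
    out = []
    for i in range(warp.n_atlases):
        disp = _displacement_field(rng, shape, warp.displacement_sigma,
                                   warp.smoothness)
        coords = [base[ax] + disp[ax] for ax in range(3)]
        wi = map_coordinates(intens.data, coords, order=1, mode="nearest")
        wl = map_coordinates(label.data, coords, order=0, mode="nearest")
        a, b = warp.intensity_jitter
        scale = 1.0 + rng.uniform(-a, a)
        shift = rng.uniform(-b, b)
        wi = np.clip(wi * scale + shift, 0.0, 1.0)
        out.append(Atlas(f"atlas_{i:02d}",
                         IntensityVolume(wi, intens.spacing),
                         LabelVolume(wl.astype(np.uint8), intens.spacing)))
    return out


def make_dataset(spec: PhantomSpec | None, warp: WarpSpec | None,
                 n_subjects: int, out_dir, seed: int = 0,
                 force: bool = False) -> dict:
    """Write phantom targets + warped atlases + a regeneration manifest.

    Each subject gets its own sub-directory with ``target_intensity.nii``,
    ``target_label.nii`` and per-atlas intensity/label pairs.  Refuses a
    non-empty output directory unless ``force``.
    """
    spec = spec or PhantomSpec()
    warp = warp or WarpSpec()
    out_dir = str(out_dir)
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not force:
        raise FileExistsError(f"{out_dir} is not empty; pass force=True to overwrite")
    os.makedirs(out_dir, exist_ok=True)

    manifest: dict = {
        "schema": MANIFEST_SCHEMA,
        "rng": "numpy.random.Generator(PCG64)",
        "seed": int(seed),
        "phantom": {
            "grid_shape": list(spec.grid_shape),
            "spacing": list(spec.spacing),
            "noise_sigma": spec.noise_sigma,
            "background_intensity": spec.background_intensity,
            "shapes": [dataclasses.asdict(s) for s in spec.tissue_shapes],
            "target_index": spec.target_index,
        },
        "warp": {
            "n_atlases": warp.n_atlases,
            "displacement_sigma": warp.displacement_sigma,
            "smoothness": warp.smoothness,
            "intensity_jitter": list(warp.intensity_jitter),
        },
        "subjects": [],
    }
    for s in range(n_subjects):
        phantom_seed = seed + 17 * s
        warp_seed = seed + 17 * s + 1
        sub = f"subject_{s:02d}"
        sub_dir = os.path.join(out_dir, sub)
        os.makedirs(sub_dir, exist_ok=True)
        intens, label = make_phantom(spec, seed=phantom_seed)
        atlases = make_warped_atlases(
            (intens, label), dataclasses.replace(warp, seed=warp_seed))
        write_volume(intens, os.path.join(sub_dir, "target_intensity.nii"))
        write_volume(label, os.path.join(sub_dir, "target_label.nii"))
        files = ["target_intensity.nii", "target_label.nii"]
        for a in atlases:
            write_volume(a.intensity, os.path.join(sub_dir, f"{a.id}_intensity.nii"))
            write_volume(a.label, os.path.join(sub_dir, f"{a.id}_label.nii"))
            files += [f"{a.id}_intensity.nii", f"{a.id}_label.nii"]
        manifest["subjects"].append({
            "name": sub, "phantom_seed": phantom_seed, "warp_seed": warp_seed,
            "files": files,
        })
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
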