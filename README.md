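# gplf — greyscale-probability label fusion for brain MR segmentation

`gplf` segments a target structure in a 3-D brain MR volume by **multi-atlas
label fusion**: a set of atlases (intensity image + expert binary label,
already warped into the target space by registration) votes on every voxel.
It is aimed at subcortical grey-matter structures — thalamus, hippocampus,
caudate, putamen, pallidum, amygdala — where the two standard patch-based
fusion families each fail in a characteristic way:

- **PSWV** (patch-similarity weighted voting) fuses *all* retained patches
  with NCC weights, `Fv(x_j) = Σ w_i l_i / Σ w_i`, and is blurred by label
  frequency at structure boundaries;
- **SRLF** (sparse-representation label fusion) solves
  `min ‖α‖₀ s.t. ‖PT − D_I α‖₂² ≤ ε` over the patch dictionary `D_I`
  (orthogonal matching pursuit here) and votes with `α`, which discards
  most patches and leaves holes inside the structure.

**GP-LF** combines both through the voxel's greyscale: a trained per-bin
probability `P(x_j)` that a voxel of that intensity belongs to the tissue
modulates a piecewise decision

```
L(x_j) = 1      if Fv_SRLF > 0.9 or Fv_PSWV > 0.9
       = [β₁·Fv_SRLF·Fv_PSWV·P > 0.5]   if both Fv in (0.4, 0.9)
       = [β₂·Fv_SRLF·P > 0.5]           if Fv_SRLF ≤ 0.4
       = [β₃·Fv_PSWV·P > 0.5]           if Fv_PSWV ≤ 0.4
```

with per-tissue coefficients β₁..β₃ shipped for the six structures.
`P` is estimated by maximizing the ℓ₁-norm of the leave-one-out Dice vector
over the training atlases (`argmax ‖Dsc‖₁, 0 ≤ P ≤ 1`), on a probability
grid by coordinate ascent; the tissue's intensity range is located first
from histogram peaks of the tissue's greyscale distribution map (ISNmax +
per-tissue offset and span).

Because registration itself is out of scope, the package ships a synthetic
generator (`gplf.synthetic`) producing tissue phantoms and "warped atlases"
via smooth random deformation fields — so the entire pipeline runs and is
tested offline.

## Worked example

```python
import numpy as np
from gplf import *

truth, label = make_phantom(seed=1)                      # 48x48x12 phantom
atlases = make_warped_atlases((truth, label), WarpSpec(n_atlases=6, seed=2))
model = GPLFModel(atlases, tissue="thalamus")
result = model.fit()
print(result.summary())
seg = result.segment(truth)
m = evaluate(label, seg, spacing=truth.spacing)
print(f"GP-LF: Dsc={m.dsc:.3f} Recall={m.recall:.3f} "
      f"Precision={m.precision:.3f} HD={m.hd:.2f} mm")
```

prints

```
GP-LF greyscale-probability fit
==============================================
tissue:            thalamus
beta1/beta2/beta3: 3.13 / 1.25 / 0.67
atlases:           6
intensity bins:    20 (ISNmax bin 18)
tissue range:      [0.500, 1.000]
objective ||Dsc||1: 4.6112 over 6 pseudo-targets (3 sweeps)
per-atlas Dice:    0.760, 0.830, 0.694, 0.806, 0.738, 0.784
...
GP-LF: Dsc=0.922 Recall=0.855 Precision=1.000 HD=1.50 mm
```

The summary table lists the detected tissue intensity range and the trained
per-bin probabilities: bins holding the structure's intensities get P near
1, darker in-range bins (surrounding tissue) get P = 0. On the same input
the single-method baselines reach Dsc 0.846 (PSWV) and 0.884 (SRLF) —
`result.segment(truth, method="pswv" | "srlf")` — so the piecewise
combination recovers boundary voxels both baselines miss.

## Command line

```
gplf simulate data/ --seed 7 --n-atlases 6          # phantom + warped atlases
gplf train-p data/subject_00 --tissue thalamus --out coeffs.json
gplf fuse data/subject_00/target_intensity.nii --atlas-dir data/subject_00 \
     --method gplf --coeffs coeffs.json -o seg.nii
gplf evaluate seg.nii data/subject_00/target_label.nii -o metrics.csv
```

Volumes are NIfTI-1 (`.nii`/`.nii.gz`); coefficients are JSON; metrics are
CSV (`tissue, dsc, recall, precision, hd_mm`). Defaults follow the method's
published constants: search radius 3 mm, top-60 patches, 20 intensity
bins, thresholds 0.9 / 0.4 / 0.5.

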