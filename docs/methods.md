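# Methods

## Problem setting

Multi-atlas segmentation propagates expert labels from registered atlas
images onto a target volume and fuses them voxel-wise. This package
implements the fusion stage only: its inputs are a target intensity volume
and n warped atlases (intensity + binary label) on the same grid, i.e. the
*output* of a non-linear registration step that is not part of the package.
All volumes are 3-D with anisotropic voxel spacing in mm; the slice axis is
the last array axis and slice k sits at physical position k·(slice spacing).

Intensities are min–max normalized to [0, 1] over the foreground (nonzero
voxels, or an explicit mask) before any fusion; normalization is idempotent
and invariant to positive affine rescaling of the raw data.

## Patch machinery

For a target voxel on the slice at position TSP, candidate patches are
taken from every atlas slice whose position lies in the closed interval
[TSP − SR, TSP + SR] (SR = 3 mm by default), at the same in-plane
coordinate — one candidate per selected atlas slice, no non-local search.
Patches are vectorized in raster order with edge replication at borders;
the default extent is 7×7×3 voxels, in-plane larger than through-plane to
match 1.5 mm slice spacing. Candidates are ranked by Pearson-type NCC
against the target patch (0 for constant patches, stable ties) and the
top K = 60 are retained; the retained patch vectors form the dictionary
`D_I`, and each contributes its centre-voxel label to the vote.

## The two base fusion values

*PSWV*: `Fv_PSWV = Σ w_i l_i / Σ w_i` with `w_i = max(NCC_i, 0)`; when all
weights vanish the value is 0 (no atlas evidence). The value is invariant
to weight rescaling and reduces to the majority fraction for equal weights.

*SRLF*: sparse coefficients are found by orthogonal matching pursuit —
iteratively select the column of `D_I` most correlated with the residual
(columns ℓ2-normalized for ranking only), refit all coefficients on the
support by least squares, stop when the residual norm falls below ε
(default 0.01·‖PT‖₂) or the support reaches `max_support` (default 5).
Negative coefficients are clipped to 0 before voting; a nonnegative-OMP
variant (positively-correlated atoms, NNLS refit) is available.

Ranking uses plain ℓ2 column normalization, not mean-removal: with the
column means subtracted, a target equal to a dictionary column is no longer
guaranteed to select that column, and exact-atom recovery is a property we
both test and rely on.

Greedy pursuit is only a faithful L0 surrogate on sufficiently incoherent
dictionaries (the classical μ·(2k−1) < 1 regime). The oracle suite
therefore evaluates it against exhaustive subset search on dictionaries
rejection-sampled to mutual coherence < 0.5 with planted sparse targets;
on highly coherent dictionaries greedy selection can be arbitrarily
suboptimal, which is a known limitation of the method class, not of this
implementation.

## The GP-LF piecewise decision

With both fusion values and the voxel's greyscale probability `p = P(x_j)`:

1. `Fv_SRLF > 0.9` or `Fv_PSWV > 0.9` → tissue (high-confidence shortcut);
2. both values in (0.4, 0.9) → tissue iff `β₁·Fv_SRLF·Fv_PSWV·p > 0.5`;
3. `Fv_SRLF ≤ 0.4` → tissue iff `β₂·Fv_SRLF·p > 0.5`;
4. `Fv_PSWV ≤ 0.4` → tissue iff `β₃·Fv_PSWV·p > 0.5`.

The four conditions neither partition nor cover the unit square (e.g.
`Fv_PSWV` exactly 0.9 with mid-range `Fv_SRLF` matches none; both values
≤ 0.4 matches 3 and 4). The branches are therefore evaluated strictly in
the printed order — first match wins — and uncovered residual combinations
fall through to the β₁ product formula. Raising `p` can never flip a voxel
from tissue to background. All cut points (0.9 / 0.4 / 0.5) are exposed in
`GplfThresholds`.

Per-tissue coefficients (β₁ = 3.13 everywhere; β₂, β₃, intensity span and
offset per structure) ship for thalamus, hippocampus, caudate, putamen,
pallidum and amygdala and can be overridden from YAML.

## Tissue greyscale range

The tissue's greyscale distribution map is the pooled histogram of each
training atlas's intensities *at its own label voxels* (optionally dilated
into the boundary; default no dilation). Reading the map over a whole-head
region instead lets surrounding-tissue and background modes, plus sampling
ripples, inflate the peak count; the re-binning rule then coarsens the
histogram until the tissue mode merges into an edge bin and the detected
range misses the tissue entirely — we observed exactly this failure before
restricting the map to the labelled voxels.

The range is set iteratively on [0, 1] split into N = 20 bins: peaks are
strict interior local maxima carrying at least 1% of the mass (plateaus
and edge bins never qualify); with 2–3 peaks, the upper bound is the upper
edge of the highest-index peak bin (ISNmax) plus the tissue offset Ov and
the lower bound is upper − span, both clipped to [0, 1]; with 0–1 peaks
the histogram is re-binned at 2N, with more than 3 at N/2. The iteration
is capped at 4 rounds, after which the round whose peak count is closest
to 2 wins; if no round produced any peak, range detection fails loudly.
Bin k of N is [k/N, (k+1)/N), the last bin closed at 1.

## Probability training

`P` is parameterized per intensity bin of the greyscale model, fixed at 0
outside the tissue range. The objective is the ℓ₁-norm (sum) of the Dice
vector obtained by leave-one-out fusion inside the training set: each
atlas in turn is the pseudo-target, segmented by GP-LF from the others,
and scored against its own label. Since `Fv_SRLF`/`Fv_PSWV` do not depend
on `P`, they are computed once per pseudo-target and cached; candidate `P`
vectors only re-evaluate the vectorized piecewise decision.

The objective is piecewise-constant in `P` (every appearance of `p` is
inside a thresholded product), so gradient methods are inapplicable; the
optimizer is deterministic coordinate ascent on a probability grid
(default {0, 0.1, …, 1}): bins are swept in ascending order, each taking
the smallest grid value that maximizes the objective with the others held
fixed, until a sweep changes nothing (max 5 sweeps; initialization 0.5
in-range). On problems small enough to enumerate (≤ 3 in-range bins,
5-value grid) the ascent attains the exhaustive-search maximum in the test
suite; in general coordinate ascent guarantees only a coordinate-wise
optimum.

## Segmentation and the fast path

Whole-volume segmentation computes both fusion-value maps, looks up `p`
from the voxel's intensity bin and applies the piecewise decision. By
default, voxels whose candidate centre labels are all background are
skipped: there every vote has label 0, both fusion values are exactly 0,
and each branch of the decision returns 0 for any `p` — so the shortcut is
provably lossless, and the suite asserts bit-identical output against the
exhaustive path. (A shortcut keyed on the voxel's intensity being outside
the tissue range would *not* be exact: `p = 0` does not disable the
high-confidence branch.)

## Evaluation metrics

Dice, Recall and Precision are voxel-set ratios; the Hausdorff distance is
the max of the two directed farthest-nearest-neighbour distances over the
full sets, Euclidean in mm via the voxel spacing, computed with exact
Euclidean distance transforms and verified against the brute-force pairwise
definition. Conventions: Dice of two empty sets is 1; a metric with an
empty denominator set is reported as NaN (missing), never 0, so averages
are not silently biased.

## Synthetic data

The generator emulates what the fusion stage sees after registration:

- `make_phantom` — piecewise-constant ellipsoid/box phantom (default
  48×48×12 voxels at 1×1×1.5 mm: a head ellipsoid of surrounding tissue at
  intensity 0.35 and a deep target structure at 0.60 over background 0.15)
  plus Gaussian noise (σ = 0.03), min–max normalized. Structure intensities
  must differ from background by ≥ 2σ unless the guard is overridden.
- `make_warped_atlases` — per atlas, a smooth random displacement field
  (white noise Gaussian-smoothed at scale 4 voxels, rescaled to a 1.5-voxel
  amplitude) warps intensity (linear) and label (nearest-neighbour) with
  the *same* field, followed by a per-atlas intensity scale/shift jitter
  (±10%, ±0.05) standing in for non-standard MR intensities. Defaults: 6
  atlases. Everything is deterministic per seed (numpy PCG64, recorded in
  the dataset manifest).

What this does and does not show: the phantom exercises every pipeline
stage — normalization, range detection on jittered intensities, training,
fusion, evaluation — under controlled residual-registration error, and the
relative ordering GP-LF ≥ SRLF/PSWV reproduces on it. It does not model MR
physics (bias fields, partial volume, Rician noise) or real anatomy, so
absolute Dice values on phantoms say nothing quantitative about clinical
data; problem sizes (48×48×12, 5 subjects, 6 atlases) were chosen so the
full study runs in minutes on one CPU.

## Numerical choices and degenerate inputs

- NCC of a constant patch is 0; tied similarities keep candidate order.
- OMP correlation ties resolve to the lowest column index; a zero target
  yields the zero solution; zero-norm columns are never selected.
- Histogram bin lookup uses the same half-open edges as counting, with 1.0
  in the last bin.
- Constant in-mask intensities make normalization fail loudly rather than
  return NaNs; empty atlas-slice selections raise instead of returning an
  empty fusion.
- Training atlases with empty labels are excluded with a warning; fewer
  than two usable atlases is an error.
- Label images with other integer codes must be reduced with
  `read_label(path, structure_code=...)`; code-to-structure mapping is
  configuration, not code.

## Known limitations

- One structure per run (binary labels); multi-structure fusion is out of
  scope.
- β coefficients are fixed per tissue, not adapted per target image.
- The positional atlas selection assumes consistent slice geometry across
  atlases (true post-registration).
- Coordinate ascent can in principle stop at a coordinate-wise optimum on
  large bin counts.
- Hausdorff is the full (not 95th-percentile) distance and is sensitive to
  single outlier voxels.
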