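import numpy as np
import pytest

from gplf.fuse import (GplfThresholds, compute_fusion_scores, gplf_decide,
                       gplf_fuse_voxel, segment_volume)
from gplf.greyscale import GreyscaleModel, get_tissue
from gplf.patches import (SelectionConfig, build_patch_library, extract_patch,
                          select_atlases_by_position)
from gplf.ptrain import PCoefficients
from gplf.sparse import SrlfConfig, srlf_fuse_voxel
from gplf.voting import pswv_fuse_voxel
from gplf.volumes import VolumeShapeError

from _oracles import gplf_literal


class TestPiecewiseDecision:
    @pytest.mark.parametrize("fs,fp,p,expected", [
        (0.95, 0.2, 0.0, 1),   # high-confidence shortcut branch
        (0.6, 0.6, 0.5, 1),    # fusion1 = 3.13*0.6*0.6*0.5 = 0.5634 > 0.5
        (0.3, 0.6, 0.5, 0),    # fusion2 = 1.25*0.3*0.5 = 0.1875 <= 0.5
        (0.0, 0.0, 1.0, 0),    # no atlas evidence at all
    ])
    def test_reference_decisions_thalamus(self, fs, fp, p, expected):
        assert gplf_fuse_voxel(fs, fp, p, "thalamus") == expected

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            gplf_fuse_voxel(1.2, 0.5, 0.5, "thalamus")

    def test_zero_probability_reduces_to_high_confidence_branch(self):
        rng = np.random.default_rng(0)
        fs, fp = rng.random(500), rng.random(500)
        dec = gplf_decide(fs, fp, np.zeros(500), "amygdala")
        assert np.array_equal(dec, ((fs > 0.9) | (fp > 0.9)).astype(np.uint8))

    def test_raising_p_never_flips_label_off(self):
        rng = np.random.default_rng(1)
        fs, fp = rng.random(2000), rng.random(2000)
        p1 = rng.random(2000)
        p2 = np.clip(p1 + rng.random(2000) * (1 - p1), 0, 1)
        for tissue in ("thalamus", "hippocampus", "amygdala"):
            d1 = gplf_decide(fs, fp, p1, tissue)
            d2 = gplf_decide(fs, fp, p2, tissue)
            assert (d2 >= d1).all()

    def test_vectorized_matches_scalar_everywhere(self):
        grid = np.linspace(0, 1, 11)
        fs, fp, p = (g.ravel() for g in np.meshgrid(grid, grid, grid))
        for tissue in ("thalamus", "caudate"):
            vec = gplf_decide(fs, fp, p, tissue)
            scalar = np.array([gplf_fuse_voxel(a, b, c, tissue)
                               for a, b, c in zip(fs, fp, p)])
            assert np.array_equal(vec, scalar)

    def test_matches_literal_transcription_spot_grid(self):
        t = get_tissue("pallidum")
        grid = np.linspace(0, 1, 9)
        for fs in grid:
            for fp in grid:
                for p in grid:
                    assert gplf_fuse_voxel(fs, fp, p, t) == gplf_literal(
                        fs, fp, p, t.beta1, t.beta2, t.beta3)

    def test_threshold_ordering_validated(self):
        with pytest.raises(ValueError):
            GplfThresholds(high=0.3, low=0.4)


class TestScoreMapsAgainstPerVoxelPath:
    def test_vectorized_engine_equals_manual_composition(self, small_truth,
                                                         small_atlases,
                                                         small_selection):
        target, _ = small_truth
        scores, any_l = compute_fusion_scores(target, small_atlases,
                                              small_selection, SrlfConfig())
        rng = np.random.default_rng(2)
        checked = 0
        xs, ys, zs = np.nonzero(any_l)
        order = rng.permutation(xs.size)[:8]
        for i in order:
            x, y, k = int(xs[i]), int(ys[i]), int(zs[i])
            tsp = target.axial_positions[k]
            refs = select_atlases_by_position(small_atlases, tsp,
                                              small_selection.sr)
            tp = extract_patch(target, (x, y, k), small_selection.patch_shape)
            cands = []
            for r in refs:
                ap = extract_patch(r.atlas.intensity, (x, y, r.slice_index),
                                   small_selection.patch_shape, r.atlas.id)
                cands.append((ap, int(r.atlas.label.data[x, y, r.slice_index])))
            lib = build_patch_library(tp, cands, small_selection.top_k)
            assert pswv_fuse_voxel(lib).fv == pytest.approx(
                scores.fv_pswv[x, y, k], abs=1e-10)
            assert srlf_fuse_voxel(tp, lib).fv == pytest.approx(
                scores.fv_srlf[x, y, k], abs=1e-10)
            checked += 1
        assert checked == 8

    def test_score_maps_lie_in_unit_interval(self, small_truth, small_atlases,
                                             small_selection):
        target, _ = small_truth
        scores, _ = compute_fusion_scores(target, small_atlases, small_selection)
        for m in (scores.fv_srlf, scores.fv_pswv):
            assert m.min() >= 0.0 and m.max() <= 1.0


def _uniform_pcoeffs(value=1.0, rng=(0.3, 1.0)):
    model = GreyscaleModel(20, np.linspace(0, 1, 21), [10], 10, rng)
    p = np.zeros(20)
    p[model.in_range_bins()] = value
    return PCoefficients(model, p, "thalamus")


class TestSegmentVolume:
    def test_identity_fixture_reproduces_shared_label(self, identical_atlases):
        intens, label, atlases = identical_atlases
        seg = segment_volume(intens, atlases, _uniform_pcoeffs(), "thalamus",
                             SelectionConfig(patch_shape=(5, 5, 3)))
        assert np.array_equal(seg.data, label.data)

    def test_zero_probability_everywhere_gives_background_without_shortcut(
            self, identical_atlases):
        intens, label, atlases = identical_atlases
        # raise the high cut to 1.0 so the Fv > high shortcut can never fire
        seg = segment_volume(intens, atlases, _uniform_pcoeffs(0.0), "thalamus",
                             SelectionConfig(patch_shape=(5, 5, 3)),
                             th=GplfThresholds(high=1.0, low=0.4))
        assert seg.data.sum() == 0

    def test_grid_mismatch_raises(self, identical_atlases, small_atlases):
        intens, _, _ = identical_atlases
        with pytest.raises(VolumeShapeError):
            segment_volume(intens, small_atlases, _uniform_pcoeffs(), "thalamus")

    def test_output_is_binary_and_total(self, small_truth, small_atlases,
                                        small_selection, fitted_small):
        target, _ = small_truth
        seg = fitted_small.segment(target)
        assert seg.data.shape == target.shape
        assert set(np.unique(seg.data)) <= {0, 1}
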