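import json

import numpy as np
import pytest

from gplf.metrics import dice
from gplf.patches import SelectionConfig
from gplf.ptrain import (PCoefficients, evaluate_p_objective, load_p, save_p,
                         train_p)
from gplf.synthetic import PhantomSpec, ShapeSpec, WarpSpec, make_phantom, \
    make_warped_atlases
from gplf.volumes import Atlas


TINY_SPEC = PhantomSpec(
    grid_shape=(18, 18, 6), spacing=(1.0, 1.0, 1.5),
    tissue_shapes=(
        ShapeSpec("ellipsoid", (9.0, 9.0, 3.0), (8.0, 8.0, 2.8), 0.35),
        ShapeSpec("ellipsoid", (9.0, 8.0, 3.0), (3.5, 3.5, 1.5), 0.62),
    ),
    noise_sigma=0.02,
)
TINY_SEL = SelectionConfig(sr=3.0, top_k=60, patch_shape=(3, 3, 3))


@pytest.fixture(scope="module")
def tiny_training_set():
    truth = make_phantom(TINY_SPEC, seed=21)
    return make_warped_atlases(truth, WarpSpec(n_atlases=3, seed=22,
                                               displacement_sigma=1.0))


@pytest.fixture(scope="module")
def tiny_fit(tiny_training_set):
    return train_p(tiny_training_set, "thalamus", TINY_SEL,
                   grid=[0.0, 0.25, 0.5, 0.75, 1.0], max_sweeps=3)


class TestObjective:
    def test_identical_atlases_reach_the_upper_bound(self, identical_atlases):
        intens, label, atlases = identical_atlases
        pc, report = train_p(atlases, "thalamus",
                             SelectionConfig(patch_shape=(3, 3, 3)),
                             grid=[0.0, 0.5, 1.0], max_sweeps=1)
        assert report.objective == pytest.approx(len(atlases))
        assert np.allclose(report.dsc_vector, 1.0)

    def test_objective_is_sum_of_dice_vector(self, tiny_fit):
        _, report = tiny_fit
        assert report.objective == pytest.approx(report.dsc_vector.sum())
        assert ((report.dsc_vector >= 0) & (report.dsc_vector <= 1)).all()

    def test_evaluate_matches_independent_dice_computation(self, tiny_training_set,
                                                           tiny_fit):
        """Leave-one-out objective cross-checked against segment_volume + dice."""
        from gplf.fuse import segment_volume
        pc, report = tiny_fit
        expected = []
        for i, atlas in enumerate(tiny_training_set):
            others = [a for j, a in enumerate(tiny_training_set) if j != i]
            seg = segment_volume(atlas.intensity, others, pc, "thalamus", TINY_SEL)
            expected.append(dice(atlas.label, seg))
        check = evaluate_p_objective(pc, tiny_training_set, "thalamus", TINY_SEL)
        assert np.allclose(check.dsc_vector, expected)

    def test_empty_label_atlas_excluded_with_warning(self, tiny_training_set):
        empty = Atlas("empty", tiny_training_set[0].intensity,
                      type(tiny_training_set[0].label)(
                          np.zeros(tiny_training_set[0].label.shape, np.uint8),
                          tiny_training_set[0].label.spacing))
        pc, _ = train_p(tiny_training_set, "thalamus", TINY_SEL,
                        grid=[0.0, 0.5, 1.0], max_sweeps=1)
        with pytest.warns(UserWarning, match="empty"):
            report = evaluate_p_objective(pc, list(tiny_training_set) + [empty],
                                          "thalamus", TINY_SEL)
        assert report.n_atlases == len(tiny_training_set)


class TestTrainP:
    def test_final_objective_not_below_initialization(self, tiny_training_set,
                                                      tiny_fit):
        pc, report = tiny_fit
        init = PCoefficients(pc.model,
                             np.where(np.isin(np.arange(pc.p.size),
                                              pc.model.in_range_bins()), 0.5, 0.0),
                             pc.tissue)
        base = evaluate_p_objective(init, tiny_training_set, "thalamus", TINY_SEL)
        assert report.objective >= base.objective - 1e-12

    def test_trained_p_peaks_on_tissue_bins(self, tiny_fit):
        """The target structure occupies the brightest bins; background bins
        inside the detected range must not receive larger probabilities."""
        pc, _ = tiny_fit
        in_bins = pc.model.in_range_bins()
        centers = pc.model.bin_centers[in_bins]
        tissue_bins = in_bins[centers > 0.7]
        other_bins = in_bins[centers <= 0.55]
        assert tissue_bins.size and other_bins.size
        assert pc.p[tissue_bins].max() >= pc.p[other_bins].max()

    def test_needs_at_least_two_atlases(self, tiny_training_set):
        with pytest.raises(ValueError):
            train_p(tiny_training_set[:1], "thalamus", TINY_SEL)

    def test_grid_must_span_unit_interval(self, tiny_training_set):
        with pytest.raises(ValueError):
            train_p(tiny_training_set, "thalamus", TINY_SEL, grid=[0.2, 0.8])


class TestCoefficientIO:
    def test_round_trip(self, tmp_path, tiny_fit):
        pc, _ = tiny_fit
        path = tmp_path / "coeffs.json"
        save_p(pc, path)
        back = load_p(path)
        assert back.tissue == pc.tissue
        assert np.array_equal(back.p, pc.p)
        assert np.array_equal(back.model.bin_edges, pc.model.bin_edges)
        assert back.model.tissue_range == pc.model.tissue_range

    def test_out_of_range_probability_rejected(self, tmp_path, tiny_fit):
        pc, _ = tiny_fit
        path = tmp_path / "bad.json"
        save_p(pc, path)
        raw = json.loads(path.read_text())
        raw["p"][int(pc.model.in_range_bins()[0])] = 1.2
        path.write_text(json.dumps(raw))
        with pytest.raises(ValueError):
            load_p(path)

    def test_missing_tissue_name_rejected(self, tmp_path, tiny_fit):
        pc, _ = tiny_fit
        path = tmp_path / "bad.json"
        save_p(pc, path)
        raw = json.loads(path.read_text())
        del raw["tissue"]
        path.write_text(json.dumps(raw))
        with pytest.raises(ValueError):
            load_p(path)

    def test_nonzero_probability_outside_range_rejected(self, tiny_fit):
        pc, _ = tiny_fit
        outside = np.setdiff1d(np.arange(pc.p.size), pc.model.in_range_bins())
        if outside.size == 0:
            pytest.skip("model covers every bin")
        bad = pc.p.copy()
        bad[outside[0]] = 0.3
        with pytest.raises(ValueError):
            PCoefficients(pc.model, bad, pc.tissue)
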