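import numpy as np
import pytest

from spglearn import (
    ArchitectureSpec,
    build_model,
    centroid_null_mde,
    cross_validate,
    mean_distance_error,
    plan_architecture,
    predict_coordinates,
    train_model,
)
from spglearn.network import MLPModel
from conftest import make_slide


class TestPlanArchitecture:
    def test_single_layer_is_half_input(self):
        assert plan_architecture(1000, 1) == [500]

    def test_three_layers_follow_halving_allocation(self):
        assert plan_architecture(1000, 3) == [286, 143, 71]

    def test_total_near_half_input(self):
        for L in (1, 3, 5):
            widths = plan_architecture(1000, L)
            assert abs(sum(widths) - 500) <= 2

    def test_too_small_input_raises(self):
        with pytest.raises(ValueError):
            plan_architecture(8, 5)
        with pytest.raises(ValueError, match="n_input"):
            plan_architecture(3, 1)

    def test_first_layer_half_reading(self):
        assert plan_architecture(1000, 3, first_layer_half=True) == [500, 250, 125]


class TestBuildModel:
    def test_parameter_count_small_model(self):
        # 8 inputs, one hidden layer of 4: dense 8*4+4, BN scale/shift 2*4, out 4*2+2
        spec = ArchitectureSpec(n_input=8, hidden_widths=[4], learning_rate=0.01)
        model = build_model(spec)
        assert model.n_trainable_parameters() == 54

    def test_same_seed_identical_weights(self):
        spec = ArchitectureSpec(n_input=6, hidden_widths=[3], learning_rate=0.01, seed=11)
        a, b = build_model(spec), build_model(spec)
        for pa, pb in zip(a.trainable_parameters(), b.trainable_parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_different_seed_different_weights(self):
        s1 = ArchitectureSpec(n_input=6, hidden_widths=[3], learning_rate=0.01, seed=1)
        s2 = ArchitectureSpec(n_input=6, hidden_widths=[3], learning_rate=0.01, seed=2)
        assert not np.allclose(build_model(s1).W[0], build_model(s2).W[0])

    def test_relu_behaviour_through_network(self):
        # identity-configured single unit: ReLU(x) = max(0, x)
        m = MLPModel(1, [2], seed=0)
        m.W[0] = np.array([[1.0, -1.0]])
        m.b[0] = np.zeros(2)
        m.gamma[0] = np.ones(2)
        m.beta[0] = np.zeros(2)
        m.run_mean[0] = np.zeros(2)
        m.run_var[0] = np.ones(2) - 1e-3  # so BN affine is the identity
        m.W_out = np.array([[1.0, 0.0], [0.0, 1.0]])
        m.b_out = np.zeros(2)
        out = m.predict(np.array([[3.0], [-3.0]]))
        np.testing.assert_allclose(out, [[3.0, 0.0], [0.0, 3.0]])

    def test_invalid_widths_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(n_input=8, hidden_widths=[4, 4], learning_rate=0.01)
        with pytest.raises(ValueError):
            ArchitectureSpec(n_input=8, hidden_widths=[1], learning_rate=0.01)


class TestMeanDistanceError:
    def test_identity_is_zero(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert mean_distance_error(a, a) == 0.0

    def test_three_four_five(self):
        assert mean_distance_error(np.array([[3.0, 4.0]]), np.array([[0.0, 0.0]])) == 5.0

    def test_mean_of_two_spots(self):
        pred = np.array([[3.0, 4.0], [0.0, 0.0]])
        act = np.zeros((2, 2))
        assert mean_distance_error(pred, act) == 2.5

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            mean_distance_error(np.zeros((2, 2)), np.zeros((3, 2)))


class TestTrainModel:
    def _split(self, slide, n_val=20, seed=0):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(slide.n_spots)
        return slide.subset_spots(perm[n_val:]), slide.subset_spots(perm[:n_val])

    def test_learns_planted_linear_map(self, planted_linear_slide):
        """Genes that are exact linear functions of (x, y) should be decoded
        to a small fraction of the slide diameter."""
        train, val = self._split(planted_linear_slide)
        spec = ArchitectureSpec(
            n_input=4, hidden_widths=[4], learning_rate=0.01,
            max_epochs=300, early_stopping_patience=60, seed=5,
        )
        model, history = train_model(train, val, spec)
        diameter = np.sqrt(2) * 18.0
        assert min(h["val_mde"] for h in history) < 0.05 * diameter

    def test_zero_epochs_returns_initialization(self, planted_linear_slide):
        train, val = self._split(planted_linear_slide)
        spec = ArchitectureSpec(
            n_input=4, hidden_widths=[2], learning_rate=0.01, max_epochs=0, seed=5
        )
        model, history = train_model(train, val, spec)
        assert history == []
        init = build_model(spec)
        for p, q in zip(model.trainable_parameters(), init.trainable_parameters()):
            np.testing.assert_array_equal(p, q)

    def test_same_seed_identical_history(self, planted_linear_slide):
        train, val = self._split(planted_linear_slide)
        spec = ArchitectureSpec(
            n_input=4, hidden_widths=[2], learning_rate=0.01, max_epochs=15, seed=5
        )
        _, h1 = train_model(train, val, spec)
        _, h2 = train_model(train, val, spec)
        assert h1 == h2

    def test_gene_set_mismatch_rejected(self, planted_linear_slide):
        train, val = self._split(planted_linear_slide)
        val = val.subset_genes(np.array([0, 1, 2]))
        spec = ArchitectureSpec(n_input=4, hidden_widths=[2], learning_rate=0.01)
        with pytest.raises(ValueError, match="gene set"):
            train_model(train, val, spec)


class TestPredictCoordinates:
    def test_deterministic_and_batch_consistent(self, planted_linear_slide):
        model = MLPModel(4, [2], seed=3)
        X = planted_linear_slide.expression[:7]
        full = predict_coordinates(model, X)
        np.testing.assert_array_equal(full, predict_coordinates(model, X))
        rows = np.vstack([predict_coordinates(model, X[i : i + 1]) for i in range(7)])
        np.testing.assert_allclose(full, rows, rtol=1e-12)

    def test_zero_input_finite(self):
        model = MLPModel(4, [2], seed=3)
        out = predict_coordinates(model, np.zeros((1, 4)))
        assert np.all(np.isfinite(out))

    def test_gene_count_mismatch(self):
        model = MLPModel(4, [2], seed=3)
        with pytest.raises(ValueError, match="genes"):
            predict_coordinates(model, np.zeros((1, 5)))


@pytest.fixture(scope="module")
def planted_cv():
    """Quick CV run on a noiseless planted-coordinate slide."""
    rng = np.random.default_rng(7)
    side = 10
    ax = np.arange(side) * 2.0
    xx, yy = np.meshgrid(ax, ax)
    coords = np.column_stack([xx.ravel(), yy.ravel()])
    X = np.column_stack(
        [coords[:, 0] / 18.0, coords[:, 1] / 18.0,
         coords.sum(axis=1) / 36.0, (coords[:, 0] - coords[:, 1]) / 36.0]
    )
    slide = make_slide(X, coords=coords, normalized=True)
    cv = cross_validate(
        slide,
        grid={"n_hidden_layers": (1,), "learning_rate": (0.01,)},
        k=10,
        seed=2,
    )
    return slide, cv


class TestCrossValidate:
    def test_fold_partition_is_exact(self, planted_cv):
        slide, cv = planted_cv
        sizes = [len(f) for f in cv.folds]
        assert sum(sizes) == slide.n_spots
        assert sizes == [10] * 10
        all_idx = np.sort(np.concatenate(cv.folds))
        np.testing.assert_array_equal(all_idx, np.arange(slide.n_spots))
        assert set(cv.fold_assignment) == set(slide.spot_ids)

    def test_cv_mde_matches_recomputation(self, planted_cv):
        slide, cv = planted_cv
        assert cv.cv_mde == pytest.approx(
            mean_distance_error(cv.test_predictions, slide.coords), abs=1e-6
        )

    def test_single_grid_point_is_best(self, planted_cv):
        _, cv = planted_cv
        assert cv.best_hyperparams == (1, 0.01)
        assert list(cv.grid_cv_mde) == [(1, 0.01)]

    def test_beats_centroid_null_on_planted_data(self, planted_cv):
        slide, cv = planted_cv
        assert cv.cv_mde < 0.5 * centroid_null_mde(slide.coords)

    def test_reproducible_with_same_seed(self, planted_cv):
        slide, cv = planted_cv
        cv2 = cross_validate(
            slide,
            grid={"n_hidden_layers": (1,), "learning_rate": (0.01,)},
            k=10,
            seed=2,
        )
        np.testing.assert_array_equal(cv.test_predictions, cv2.test_predictions)
        assert cv.cv_mde == cv2.cv_mde

    def test_small_k_rejected(self, planted_linear_slide):
        with pytest.raises(ValueError, match="k must be"):
            cross_validate(planted_linear_slide, k=2, seed=0)

    def test_more_folds_than_spots_rejected(self):
        slide = make_slide(np.ones((5, 4)), normalized=True)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(slide, k=10, seed=0)
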