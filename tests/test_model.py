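import numpy as np
import pytest
from scipy.stats import ortho_group

from kernelsurv import (
    IntervalPartition,
    MetricTransform,
    ModelLoadError,
    build_model,
    compute_weights,
    explain_prediction,
    hazard_profile,
    interval_index,
    load_model,
    make_partition,
    predict_survival,
    risk_matrix,
    risk_time,
    save_model,
)


class TestPartition:
    def test_single_interval(self):
        p = make_partition([1.0, 2.0, 3.0], [1, 1, 1], k=1)
        np.testing.assert_array_equal(p.boundaries, [0.0, np.inf])
        assert p.k == 1

    def test_quantile_boundaries_on_uniform_grid(self):
        times = np.arange(1.0, 101.0)
        p = make_partition(times, np.ones(100), k=4)
        np.testing.assert_allclose(p.boundaries[1:-1], [25.75, 50.5, 75.25])

    def test_too_few_distinct_event_times(self):
        with pytest.raises(ValueError, match="reduce k"):
            make_partition([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 0], k=4)

    def test_censored_times_do_not_move_boundaries(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 50.0, 60.0])
        d = np.array([1, 1, 1, 1, 0, 0])
        p = make_partition(t, d, k=2)
        assert p.boundaries[1] == np.quantile(t[:4], 0.5)


class TestRiskTime:
    @pytest.fixture
    def p(self):
        return IntervalPartition([0.0, 2.0, 4.0, np.inf])

    def test_beyond_last_boundary(self, p):
        assert [risk_time(p, 5.0, j) for j in (1, 2, 3)] == [2.0, 2.0, 1.0]
        assert interval_index(p, 5.0) == 3

    def test_interior(self, p):
        assert [risk_time(p, 3.0, j) for j in (1, 2, 3)] == [2.0, 1.0, 0.0]
        assert interval_index(p, 3.0) == 2

    def test_boundary_belongs_to_left_interval(self, p):
        assert interval_index(p, 2.0) == 1
        assert [risk_time(p, 2.0, j) for j in (1, 2, 3)] == [2.0, 0.0, 0.0]

    def test_exposure_conservation(self, p, rng):
        t = rng.uniform(0.01, 20.0, size=200)
        np.testing.assert_allclose(risk_matrix(p, t).sum(axis=1), t, rtol=1e-12)


class TestWeights:
    def test_self_weight_is_one_without_exclusion(self, rng):
        X = rng.normal(size=(5, 3))
        w = compute_weights(np.eye(3), X[2], X)
        assert w[2] == 1.0

    def test_zero_metric_gives_unit_weights(self, rng):
        X = rng.normal(size=(5, 3))
        np.testing.assert_array_equal(compute_weights(np.zeros((3, 3)), X[0], X), 1.0)

    def test_unit_distance_closed_form(self):
        X = np.array([[1.0, 0.0], [0.0, 0.0]])
        w = compute_weights(np.eye(2), X[1], X)
        assert w[0] == pytest.approx(np.exp(-1.0))

    def test_exclusion_forces_zero(self, rng):
        X = rng.normal(size=(4, 2))
        w = compute_weights(np.eye(2), X[1], X, exclude=1)
        assert w[1] == 0.0 and np.all(w[[0, 2, 3]] > 0)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            compute_weights(np.eye(2), np.zeros(3), rng.normal(size=(4, 2)))

    def test_invariant_under_rotation_of_u(self, rng):
        """Weights depend on U only through A = U'U."""
        X = rng.normal(size=(6, 3))
        U = np.triu(rng.normal(size=(3, 3)))
        Q = ortho_group.rvs(3, random_state=1)
        w1 = compute_weights(MetricTransform(U).U, X[0], X)
        w2 = compute_weights(Q @ U, X[0], X)
        np.testing.assert_allclose(w1, w2, rtol=1e-12)

    def test_bounds(self, rng):
        X = rng.normal(size=(20, 4))
        w = compute_weights(np.triu(rng.normal(size=(4, 4))), rng.normal(size=4), X)
        assert np.all(w > 0) and np.all(w <= 1)


class TestHazardProfile:
    times = np.array([1.0, 2.0, 3.0])
    events = np.array([1, 1, 0])

    def test_unit_weights_single_interval(self):
        p = IntervalPartition([0.0, np.inf])
        prof = hazard_profile(np.ones(3), self.times, self.events, p)
        assert prof.rates[0] == pytest.approx(2.0 / 6.0)

    def test_degenerate_weights_select_one_subject(self):
        p = IntervalPartition([0.0, np.inf])
        prof = hazard_profile([1.0, 0.0, 0.0], self.times, self.events, p)
        assert prof.rates[0] == pytest.approx(1.0)

    def test_two_intervals_hand_computed(self):
        p = IntervalPartition([0.0, 2.0, np.inf])
        prof = hazard_profile(np.ones(3), self.times, self.events, p)
        np.testing.assert_allclose(prof.rates, [2.0 / 5.0, 0.0])

    def test_zero_over_zero_interval_rate_is_zero(self):
        p = IntervalPartition([0.0, 2.0, np.inf])
        prof = hazard_profile([1.0, 1.0, 0.0], [1.0, 2.0, 5.0], [1, 1, 0], p)
        assert prof.rates[1] == 0.0


class TestPrediction:
    @pytest.fixture
    def model(self, random_dataset):
        return build_model(random_dataset, np.eye(3), k=2)

    def test_survival_starts_at_one(self, model, random_dataset):
        S = predict_survival(model, random_dataset.covariates[:5], 0.0)
        np.testing.assert_array_equal(S, 1.0)

    def test_single_interval_closed_form(self, toy_dataset):
        model = build_model(toy_dataset, np.zeros((2, 2)), k=1)
        # U = 0: rate is D / sum(phi(t_i)); query time with phi(t) known
        lam = model.hazard_profiles(np.zeros(2))[0, 0]
        t = 2.5
        expected = np.exp(-lam * model.time_transform(t))
        assert model.predict_survival(np.zeros(2), t) == pytest.approx(expected)

    def test_monotone_in_time(self, model, rng):
        x = rng.normal(size=3)
        grid = np.linspace(0.0, 20.0, 60)
        S = model.predict_survival(x, grid)
        assert np.all(np.diff(S) <= 1e-12)
        assert np.all((S >= 0) & (S <= 1))

    def test_zero_metric_degenerates_to_pooled_estimate(self, random_dataset, rng):
        """With U = 0 every query receives the unweighted pooled fit."""
        model = build_model(random_dataset, np.zeros((3, 3)), k=2)
        grid = np.linspace(0.1, 10.0, 20)
        S = model.predict_survival(rng.normal(size=(7, 3)), grid)
        assert np.allclose(S, S[0], rtol=1e-12)
        pooled = hazard_profile(
            np.ones(random_dataset.n_samples),
            model.train_transformed_times,
            model.train_events,
            model.partition,
        )
        R = risk_matrix(model.partition, model.time_transform(grid))
        np.testing.assert_allclose(S[0], np.exp(-R @ pooled.rates), rtol=1e-12)

    def test_non_proportional_profiles_possible(self, rng):
        """Hazard ratios may differ across intervals for k >= 2."""
        from kernelsurv import SurvivalDataset

        # two clusters with opposite early/late event patterns
        X = np.vstack([np.full((20, 1), -2.0), np.full((20, 1), 2.0)])
        X += rng.normal(scale=0.05, size=X.shape)
        t = np.concatenate([np.linspace(0.5, 1.0, 20), np.linspace(4.0, 6.0, 20)])
        ds = SurvivalDataset(X, t, np.ones(40))
        model = build_model(ds, 2.0 * np.eye(1), k=2)
        lam = model.hazard_profiles(np.array([[-2.0], [2.0]]))
        r1 = lam[0, 0] / lam[1, 0]
        r2 = (lam[0, 1] + 1e-300) / (lam[1, 1] + 1e-300)
        assert not np.isclose(r1, r2)


class TestExplain:
    @pytest.fixture
    def model(self, random_dataset):
        return build_model(random_dataset, np.eye(3), k=2)

    def test_training_point_ranks_first_with_weight_one(self, model, random_dataset):
        x_raw = random_dataset.covariates[4]
        top = explain_prediction(model, x_raw, 3)
        assert top[0][0] == 4
        assert top[0][1] == pytest.approx(1.0)

    def test_zero_metric_ties_broken_by_index(self, random_dataset):
        model = build_model(random_dataset, np.zeros((3, 3)), k=2)
        top = explain_prediction(model, np.zeros(3), 5)
        assert [i for i, *_ in top] == [0, 1, 2, 3, 4]
        assert all(w == 1.0 for _, w, *_ in top)

    def test_full_ranking_is_permutation_with_sorted_weights(self, model, rng):
        n = model.train_covariates.shape[0]
        top = explain_prediction(model, rng.normal(size=3), n)
        idx = [i for i, *_ in top]
        assert sorted(idx) == list(range(n))
        w = [w for _, w, *_ in top]
        assert np.all(np.diff(w) <= 0)

    def test_top_k_out_of_range(self, model):
        with pytest.raises(ValueError, match="top_k"):
            model.explain(np.zeros(3), 0)


class TestSerialization:
    def test_round_trip_bit_identical_predictions(self, random_dataset, rng, tmp_path):
        model = build_model(random_dataset, np.triu(rng.normal(size=(3, 3))), k=2)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        Xq = rng.normal(size=(10, 3))
        grid = np.linspace(0.0, 15.0, 30)
        np.testing.assert_array_equal(
            model.predict_survival(Xq, grid), back.predict_survival(Xq, grid)
        )

    def test_truncated_file_raises_load_error(self, random_dataset, tmp_path):
        model = build_model(random_dataset, np.eye(3), k=2)
        path = tmp_path / "model.json"
        save_model(model, path)
        path.write_text(path.read_text()[: 100])
        with pytest.raises(ModelLoadError):
            load_model(path)

    def test_wrong_format_rejected(self, tmp_path):
        p = tmp_path / "other.json"
        p.write_text('{"format": "something-else"}')
        with pytest.raises(ModelLoadError, match="not a kernelsurv"):
            load_model(p)

    def test_metadata_preserved(self, rng, tmp_path):
        from kernelsurv import SurvivalDataset

        ds = SurvivalDataset(
            rng.normal(size=(30, 2)),
            rng.exponential(size=30) + 0.1,
            np.ones(30),
            ("age", "grade"),
        )
        model = build_model(ds, np.eye(2), k=1)
        path = tmp_path / "m.json"
        save_model(model, path)
        back = load_model(path)
        assert back.feature_names == ("age", "grade")
        np.testing.assert_array_equal(back.standardizer.mean_, model.standardizer.mean_)
        np.testing.assert_array_equal(back.standardizer.scale_, model.standardizer.scale_)
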