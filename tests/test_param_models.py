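"""Power-law and k-nearest-neighbor meta-models for (Q_gen, UA)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from millitherm import (
    DomainError,
    KNNModel,
    ProcessCondition,
    PowerLawModel,
    leave_one_out,
    nearest_neighbors,
    predict_knn,
    predict_power_law,
    published_power_laws,
    train_knn,
    train_power_law,
)

# published nearest-neighbor predictions for the five test conditions
ML_EXPECTED = {
    (2500, 0.45, 400): (1792, 77),
    (2500, 0.55, 400): (2506, 95),
    (3500, 0.45, 400): (4555, 132),
    (3500, 0.55, 400): (5911, 162),
    (4200, 0.35, 100): (4359, 124),
}

condition_st = st.builds(
    ProcessCondition,
    omega=st.floats(1500.0, 4500.0),
    c=st.floats(0.35, 0.62, exclude_max=True),
    d_b=st.floats(100.0, 1000.0),
)


def _training_xy(training_runs):
    conds = [r.condition for r in training_runs]
    qgen = [r.params.q_gen for r in training_runs]
    ua = [r.params.ua for r in training_runs]
    return conds, qgen, ua


class TestPowerLaw:
    def test_both_modes_round_trip_noiseless_law(self, training_runs):
        conds, _, _ = _training_xy(training_runs)
        truth = PowerLawModel(1e-7, 3.0, 1.3, 0.2)
        y = [predict_power_law(truth, c) for c in conds]
        for mode in ("log_ols", "raw_nls"):
            model = train_power_law(conds, y, mode=mode)
            assert model.prefactor == pytest.approx(1e-7, rel=1e-6)
            assert model.exp_omega == pytest.approx(3.0, abs=1e-7)
            assert model.exp_c == pytest.approx(1.3, abs=1e-7)
            assert model.exp_db == pytest.approx(0.2, abs=1e-7)

    def test_log_ols_interpolates_its_own_noiseless_data(self, training_runs):
        conds, _, _ = _training_xy(training_runs)
        truth = PowerLawModel(2.5e-6, 2.4, 0.9, 0.15)
        model = train_power_law(
            conds, [predict_power_law(truth, c) for c in conds], mode="log_ols"
        )
        probe = ProcessCondition(omega=2750.0, c=0.47, d_b=555.0)
        assert predict_power_law(model, probe) == pytest.approx(
            predict_power_law(truth, probe), rel=1e-9
        )

    def test_log_ols_speed_exponent_on_published_table(self, training_runs):
        # closed-form OLS slope on the balanced 3-level design gives ~2.76,
        # notably below the published raw-scale exponent of 3.02
        conds, qgen, _ = _training_xy(training_runs)
        model = train_power_law(conds, qgen, mode="log_ols")
        lw = np.log([c.omega for c in conds])
        lq = np.log(qgen)
        dev = lw - lw.mean()
        # independent oracle: marginal slope is exact for an orthogonal design
        expected = float(np.sum(dev * lq) / np.sum(dev**2))
        assert model.exp_omega == pytest.approx(expected, abs=1e-9)
        assert model.exp_omega == pytest.approx(2.76, abs=0.01)

    def test_raw_nls_matches_published_exponents(self, training_runs):
        conds, qgen, ua = _training_xy(training_runs)
        model_q = train_power_law(conds, qgen, mode="raw_nls")
        assert model_q.exp_omega == pytest.approx(3.02, abs=0.35)
        assert model_q.exp_c == pytest.approx(1.29, abs=0.35)
        assert model_q.exp_db == pytest.approx(0.22, abs=0.35)
        model_u = train_power_law(conds, ua, mode="raw_nls")
        assert model_u.exp_omega == pytest.approx(1.68, abs=0.35)
        assert model_u.exp_c == pytest.approx(0.77, abs=0.35)
        assert model_u.exp_db == pytest.approx(0.12, abs=0.35)

    def test_published_coefficients_at_reference_conditions(self):
        pl_q, pl_ua = published_power_laws()
        # residual vs. the directly fitted 755.2 J/min, not an error
        assert predict_power_law(
            pl_q, ProcessCondition(2000, 0.4, 200)
        ) == pytest.approx(601.0, abs=1.0)
        assert predict_power_law(
            pl_ua, ProcessCondition(2500, 0.45, 400)
        ) == pytest.approx(74.9, abs=0.1)

    def test_zero_exponents_return_prefactor(self):
        model = PowerLawModel(42.0, 0.0, 0.0, 0.0)
        assert predict_power_law(model, ProcessCondition(3000, 0.5, 400)) == 42.0

    def test_nonpositive_response_rejected(self, training_runs):
        conds, qgen, _ = _training_xy(training_runs)
        bad = list(qgen)
        bad[0] = 0.0
        with pytest.raises(DomainError):
            train_power_law(conds, bad, mode="log_ols")

    def test_json_round_trip(self, training_runs):
        conds, qgen, _ = _training_xy(training_runs)
        model = train_power_law(conds, qgen, mode="raw_nls")
        clone = PowerLawModel.from_dict(model.to_dict())
        assert clone == model


class TestKNNTraining:
    def test_standardization_statistics_of_the_factorial_grid(self, training_runs):
        conds, qgen, _ = _training_xy(training_runs)
        model = train_knn(conds, qgen, k=5)
        assert model.feature_means == pytest.approx([3000.0, 0.5, 466.667], rel=1e-4)
        assert model.feature_scales == pytest.approx(
            [816.497, 0.0816497, 249.444], rel=1e-4
        )

    @pytest.mark.parametrize("k", [0, 28])
    def test_invalid_neighbor_counts_rejected(self, training_runs, k):
        conds, qgen, _ = _training_xy(training_runs)
        with pytest.raises(DomainError):
            train_knn(conds, qgen, k=k)

    def test_zero_variance_feature_rejected(self):
        conds = [ProcessCondition(3000, 0.5, d) for d in (200, 400, 800)]
        with pytest.raises(DomainError):
            train_knn(conds, [1.0, 2.0, 3.0], k=1)

    def test_single_row_k1_predicts_that_row_everywhere(self):
        # degenerate but valid: standardization impossible, so build directly
        model = KNNModel(
            feature_means=np.zeros(3),
            feature_scales=np.ones(3),
            training_features=np.array([[0.0, 0.0, 0.0]]),
            training_conditions=np.array([[3000.0, 0.5, 400.0]]),
            training_responses=np.array([1234.0]),
            k=1,
        )
        assert predict_knn(model, ProcessCondition(2000, 0.4, 800)) == 1234.0


class TestKNNPrediction:
    def test_zero_distance_neighbor_returned_exactly(self, training_runs):
        conds, qgen, _ = _training_xy(training_runs)
        model = train_knn(conds, qgen, k=1)
        assert predict_knn(model, conds[0]) == 755.2

    @pytest.mark.parametrize("condition, expected", list(ML_EXPECTED.items()))
    def test_reproduces_all_published_predictions(
        self, training_runs, condition, expected
    ):
        conds, qgen, ua = _training_xy(training_runs)
        probe = ProcessCondition(*condition)
        model_q = train_knn(conds, qgen, k=5)
        model_u = train_knn(conds, ua, k=5)
        assert round(predict_knn(model_q, probe)) == expected[0]
        assert round(predict_knn(model_u, probe)) == expected[1]

    def test_tie_free_test_condition_neighbors(self, training_runs):
        conds, qgen, _ = _training_xy(training_runs)
        model = train_knn(conds, qgen, k=5)
        _, idx = predict_knn(
            model, ProcessCondition(4200, 0.35, 100), return_neighbors=True
        )
        ids = {conds[i].run_id for i in idx}
        assert ids == {"19", "20", "10", "22", "11"}

    def test_tie_break_resolves_fifth_neighbor_by_policy(self, training_runs):
        # at (2500, 0.45, 400) four runs tie for fifth place; the policy
        # (lower speed, then higher loading) must select run 4
        conds, qgen, _ = _training_xy(training_runs)
        model = train_knn(conds, qgen, k=5)
        _, idx = predict_knn(
            model, ProcessCondition(2500, 0.45, 400), return_neighbors=True
        )
        ids = {conds[i].run_id for i in idx}
        assert ids == {"2", "5", "11", "14", "4"}

    def test_matches_sklearn_at_tie_free_condition(self, training_runs):
        from sklearn.neighbors import KNeighborsRegressor

        conds, qgen, _ = _training_xy(training_runs)
        model = train_knn(conds, qgen, k=5)
        X = np.array([[c.omega, c.c, c.d_b] for c in conds])
        Z = (X - model.feature_means) / model.feature_scales
        sk = KNeighborsRegressor(n_neighbors=5).fit(Z, qgen)
        probe = (
            np.array([4200.0, 0.35, 100.0]) - model.feature_means
        ) / model.feature_scales
        assert predict_knn(
            model, ProcessCondition(4200, 0.35, 100)
        ) == pytest.approx(float(sk.predict([probe])[0]), rel=1e-12)

    @settings(max_examples=30, derandomize=True)
    @given(condition=condition_st)
    def test_prediction_bounded_by_training_responses(self, condition):
        from millitherm import load_training_runs

        conds, qgen, _ = _training_xy(load_training_runs())
        model = train_knn(conds, qgen, k=5)
        pred = predict_knn(model, condition)
        assert min(qgen) <= pred <= max(qgen)

    @settings(max_examples=20, derandomize=True)
    @given(condition=condition_st, scale=st.floats(0.1, 10.0))
    def test_invariant_to_uniform_feature_rescaling(self, condition, scale):
        from dataclasses import replace

        from millitherm import load_training_runs

        conds, qgen, _ = _training_xy(load_training_runs())
        model = train_knn(conds, qgen, k=5)
        rescaled = replace(
            model,
            feature_scales=model.feature_scales * scale,
            training_features=model.training_features / scale,
        )
        assert predict_knn(rescaled, condition) == pytest.approx(
            predict_knn(model, condition), rel=1e-12
        )

    def test_json_round_trip(self, training_runs):
        conds, qgen, _ = _training_xy(training_runs)
        model = train_knn(conds, qgen, k=5)
        clone = KNNModel.from_dict(model.to_dict())
        probe = ProcessCondition(2500, 0.45, 400)
        assert predict_knn(clone, probe) == predict_knn(model, probe)


def test_leave_one_out_plumbing(training_runs):
    # a stride that keeps every feature varying in each leave-one-out subset
    conds = [r.condition for r in training_runs][::4]
    y = [r.params.q_gen for r in training_runs][::4]
    preds = leave_one_out(
        conds, y,
        trainer=lambda cs, ys: train_knn(cs, ys, k=2),
        predictor=predict_knn,
    )
    assert preds.shape == (len(y),)
    assert np.all(preds >= min(y)) and np.all(preds <= max(y))
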