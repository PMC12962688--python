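"""Training pipeline: variance filter, CV penalty selection, serialization,
and the Model/Results interface."""

import json

import numpy as np
import pytest

import smokestatus as ss
from smokestatus import solver
from smokestatus.labels import SmokingStatus
from smokestatus.model import (
    CVResult,
    SmokingStatusModel,
    TrainedModel,
    fit_multinomial_lasso,
    load_model,
    save_model,
    select_lambda_cv,
    variance_filter,
)


def make_matrix(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i:08d}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ss.BetaMatrix(np.array(probes, dtype=object),
                         np.array(samples, dtype=object), values)


class TestVarianceFilter:
    def test_hand_computed_quantile_selection(self):
        # 8 probes with strictly increasing variance; quantile 0.75 keeps
        # exactly the probes with variance above the interpolated threshold
        rng = np.random.default_rng(0)
        base = rng.uniform(0.3, 0.7, size=4)
        rows = [0.5 + scale * np.array([-1, -0.5, 0.5, 1.0]) / 10
                for scale in range(1, 9)]
        m = make_matrix(np.clip(rows, 0, 1))
        variances = np.var(m.values, axis=1, ddof=1)
        thr_expected = np.quantile(variances, 0.75)
        filtered, thr = variance_filter(m, 0.75)
        assert thr == pytest.approx(thr_expected)
        expected = m.probe_ids[variances > thr_expected]
        assert list(filtered.probe_ids) == list(expected)
        assert len(expected) == 2  # the two highest-variance probes

    def test_constant_probe_always_excluded(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0.2, 0.8, size=(10, 6))
        values[0, :] = 0.5
        filtered, thr = variance_filter(make_matrix(values), 0.75)
        assert thr >= 0
        assert "cg00000000" not in set(filtered.probe_ids)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(0, 1, size=(20, 8))
        m1 = make_matrix(values)
        perm = rng.permutation(8)
        m2 = ss.BetaMatrix(m1.probe_ids, m1.sample_ids[perm], values[:, perm])
        f1, t1 = variance_filter(m1)
        f2, t2 = variance_filter(m2)
        assert t1 == pytest.approx(t2)
        assert list(f1.probe_ids) == list(f2.probe_ids)

    def test_retention_fraction_close_to_one_minus_quantile(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.uniform(0, 1, size=(1000, 10)))
        filtered, _ = variance_filter(m, 0.75)
        assert filtered.n_probes == pytest.approx(250, abs=1)

    def test_undefined_variance_probe_dropped_with_warning(self):
        values = np.random.default_rng(4).uniform(0, 1, (5, 4))
        values[0, 1:] = np.nan  # single observation: variance undefined
        with pytest.warns(UserWarning, match="variance undefined"):
            filtered, _ = variance_filter(make_matrix(values), 0.5)
        assert "cg00000000" not in set(filtered.probe_ids)


def balanced_instance(n_per_class=20, p=6, seed=0):
    rng = np.random.default_rng(seed)
    n = 3 * n_per_class
    X = rng.uniform(0.1, 0.9, size=(p, n))
    statuses = ([SmokingStatus.CURRENT] * n_per_class
                + [SmokingStatus.FORMER] * n_per_class
                + [SmokingStatus.NEVER] * n_per_class)
    # inject separation on probe 0
    X[0, :n_per_class] -= 0.08
    X[0, 2 * n_per_class:] += 0.08
    X = np.clip(X, 0, 1)
    sex = rng.integers(0, 2, size=n).astype(float)
    return make_matrix(X), statuses, sex


class TestLambdaSelection:
    def test_single_lambda_grid_is_chosen(self):
        m, statuses, sex = balanced_instance()
        y = np.array([[SmokingStatus.CURRENT, SmokingStatus.FORMER,
                       SmokingStatus.NEVER].index(s) for s in statuses])
        Xs = (m.values.T - m.values.T.mean(0)) / m.values.T.std(0)
        cv = select_lambda_cv(Xs, y, sex, [0.05], n_folds=5, seed=0)
        assert cv.chosen_lambda == pytest.approx(0.05)

    def test_intercept_only_deviance_closed_form(self):
        """A penalty large enough to zero every CpG coefficient, balanced
        classes and balanced folds give uniform posteriors, so the total
        held-out deviance is 2 N ln 3."""
        m, statuses, _ = balanced_instance(n_per_class=30, p=5, seed=1)
        y = np.array([[SmokingStatus.CURRENT, SmokingStatus.FORMER,
                       SmokingStatus.NEVER].index(s) for s in statuses])
        Xs = (m.values.T - m.values.T.mean(0)) / m.values.T.std(0)
        sex = np.zeros(90)
        cv = select_lambda_cv(Xs, y, sex, [1e3], n_folds=10, seed=0,
                              tol=1e-11, max_iter=100000)
        assert cv.deviance[0] == pytest.approx(2 * 90 * np.log(3), abs=1e-6)

    def test_deviance_ties_break_toward_larger_lambda(self):
        cv = CVResult(lambda_grid=np.array([0.2, 0.1]),
                      deviance=np.array([50.0, 50.0]),
                      deviance_se=np.array([1.0, 1.0]),
                      fold_assignment=np.zeros(10, dtype=int),
                      chosen_lambda=0.2, chosen_index=0)
        assert cv.chosen_lambda == 0.2
        # the CV routine sorts the grid descending, so a tie resolves to
        # the larger (sparser) lambda via first-argmin
        m, statuses, sex = balanced_instance(seed=2)
        y = np.array([[SmokingStatus.CURRENT, SmokingStatus.FORMER,
                       SmokingStatus.NEVER].index(s) for s in statuses])
        Xs = (m.values.T - m.values.T.mean(0)) / m.values.T.std(0)
        cv2 = select_lambda_cv(Xs, y, sex, [0.01, 0.3, 0.05], n_folds=5, seed=0)
        assert list(cv2.lambda_grid) == sorted(cv2.lambda_grid, reverse=True)
        assert cv2.deviance[cv2.chosen_index] == cv2.deviance.min()

    def test_chosen_lambda_must_attain_minimum(self):
        with pytest.raises(ValueError, match="minimum"):
            CVResult(lambda_grid=np.array([0.2, 0.1]),
                     deviance=np.array([50.0, 40.0]),
                     deviance_se=np.array([1.0, 1.0]),
                     fold_assignment=np.zeros(4, dtype=int),
                     chosen_lambda=0.2, chosen_index=0)

    def test_too_few_folds_rejected(self):
        m, statuses, sex = balanced_instance()
        y = np.zeros(60, dtype=int)
        with pytest.raises(ValueError):
            select_lambda_cv(m.values.T, y, sex, [0.1], n_folds=1)


class TestFitMultinomialLasso:
    def test_missing_training_data_rejected(self):
        m, statuses, sex = balanced_instance()
        m.values[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            fit_multinomial_lasso(m, statuses, sex, lambda_grid=[0.1], n_folds=3)

    def test_absent_class_rejected(self):
        m, statuses, sex = balanced_instance()
        statuses = [SmokingStatus.CURRENT] * 30 + [SmokingStatus.NEVER] * 30
        with pytest.raises(ValueError, match="former"):
            fit_multinomial_lasso(m, statuses, sex, lambda_grid=[0.1], n_folds=3)

    def test_gauge_centered_and_sparse_model(self, trained_small):
        _, _, _, results = trained_small
        tm = results.trained_model
        assert tm.intercepts.sum() == pytest.approx(0.0, abs=1e-10)
        assert tm.sex_coefficients.sum() == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(tm.coefficients.sum(axis=1), 0.0, atol=1e-10)
        assert np.all(np.any(tm.coefficients != 0, axis=1))

    def test_intercept_shift_leaves_posteriors_unchanged(self, trained_small, toy_model):
        matrix, sheet, _, results = trained_small
        tm = results.trained_model
        pred1 = ss.predict(matrix, sheet, tm)
        shifted = TrainedModel(
            cpg_ids=tm.cpg_ids, intercepts=tm.intercepts + 7.3,
            coefficients=tm.coefficients, sex_coefficients=tm.sex_coefficients,
            training_means=tm.training_means, lam=tm.lam,
            variance_threshold=tm.variance_threshold, metadata=tm.metadata,
        )
        pred2 = ss.predict(matrix, sheet, shifted)
        np.testing.assert_allclose(pred1.probabilities.to_numpy(),
                                   pred2.probabilities.to_numpy(), atol=1e-12)


class TestSerialization:
    def test_save_load_round_trip(self, trained_small, tmp_path):
        _, _, _, results = trained_small
        path = tmp_path / "model.json"
        results.save(path)
        back = load_model(path)
        tm = results.trained_model
        np.testing.assert_array_equal(back.cpg_ids, tm.cpg_ids)
        np.testing.assert_allclose(back.coefficients, tm.coefficients)
        np.testing.assert_allclose(back.intercepts, tm.intercepts)
        np.testing.assert_allclose(back.sex_coefficients, tm.sex_coefficients)
        np.testing.assert_allclose(back.training_means, tm.training_means)
        assert back.lam == tm.lam
        assert back.metadata == tm.metadata

    def test_schema_version_mismatch_rejected(self, trained_small, tmp_path):
        _, _, _, results = trained_small
        path = tmp_path / "model.json"
        results.save(path)
        payload = json.loads(path.read_text())
        payload["schema_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="schema version"):
            load_model(path)

    def test_missing_mu_field_rejected(self, trained_small, tmp_path):
        _, _, _, results = trained_small
        path = tmp_path / "model.json"
        results.save(path)
        payload = json.loads(path.read_text())
        del payload["coefficients"][0]["mu"]
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="mu"):
            load_model(path)

    def test_zero_weight_cpgs_not_stored(self, trained_small, tmp_path):
        _, _, _, results = trained_small
        path = tmp_path / "model.json"
        results.save(path)
        payload = json.loads(path.read_text())
        for rec in payload["coefficients"]:
            assert any(rec[k] != 0.0 for k in ("w_current", "w_former", "w_never"))

    def test_all_zero_coefficient_row_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            TrainedModel(cpg_ids=np.array(["cg1"], dtype=object),
                         coefficients=np.zeros((1, 3)),
                         training_means=np.array([0.5]))


class TestModelResultsInterface:
    def test_fit_selects_signal_and_summarizes(self, trained_small):
        _, _, truth, results = trained_small
        selected = set(results.trained_model.cpg_ids)
        overlap = len(selected & set(truth.signal_cpg_ids)) / len(truth.signal_cpg_ids)
        assert overlap >= 0.5
        text = results.summary()
        assert "Selected CpGs" in text and str(results.n_selected_cpgs) in text

    def test_occasional_smokers_excluded_from_training(self, small_cohort):
        matrix, sheet, _ = small_cohort
        df = sheet.data.copy().reset_index(drop=True)
        df.loc[0, "status"] = "occasional"
        model = SmokingStatusModel(matrix, ss.SampleSheet(df))
        assert model.beta.n_samples == matrix.n_samples - 1
        assert model.n_excluded == 1
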