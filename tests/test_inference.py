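"""Prediction pipeline: imputation, log-odds, softmax, status calls."""

import numpy as np
import pytest

import smokestatus as ss
from smokestatus.inference import (
    assign_status,
    compute_log_odds,
    impute_missing,
    predict,
    softmax_probabilities,
)
from smokestatus.io import BetaMatrix, align_to_model
from smokestatus.labels import SmokingStatus


def aligned_matrix(toy_model, values, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return BetaMatrix(toy_model.cpg_ids.copy(),
                      np.array(samples, dtype=object), values)


class TestImputation:
    def test_no_missing_is_identity(self, toy_model):
        m = aligned_matrix(toy_model, [[0.2], [0.7]])
        out = impute_missing(m, toy_model)
        np.testing.assert_array_equal(out.values, m.values)

    def test_missing_entry_gets_training_mean(self, toy_model):
        m = aligned_matrix(toy_model, [[0.2], [np.nan]])
        out = impute_missing(m, toy_model)
        assert out.values[1, 0] == toy_model.training_means[1]
        assert out.values[0, 0] == 0.2

    def test_unaligned_matrix_rejected(self, toy_model):
        m = BetaMatrix(np.array(["cgX"], dtype=object),
                       np.array(["s1"], dtype=object), np.array([[0.2]]))
        with pytest.raises(ValueError, match="aligned"):
            impute_missing(m, toy_model)


class TestLogOdds:
    def test_hand_computed_log_odds(self, toy_model):
        # x = (0.2, 0.4), male: centered x - mu = (-0.3, 0.1)
        # eta_current = 0.2 + (-2)(-0.3) + 1(0.1) + 0.05 = 0.95
        # eta_former  = 0.1 + 0.5(-0.3) + (-0.2)(0.1) - 0.05 = -0.12
        # eta_never   = -0.3 + 1.5(-0.3) + (-0.8)(0.1) + 0 = -0.83
        m = aligned_matrix(toy_model, [[0.2], [0.4]])
        eta = compute_log_odds(m, np.array([1.0]), toy_model)
        np.testing.assert_allclose(eta.to_numpy()[0], [0.95, -0.12, -0.83],
                                   atol=1e-12)

    def test_training_mean_input_gives_prior_plus_sex(self, toy_model):
        m = aligned_matrix(toy_model, toy_model.training_means[:, None])
        eta = compute_log_odds(m, np.array([1.0]), toy_model)
        expected = toy_model.intercepts + toy_model.sex_coefficients
        np.testing.assert_allclose(eta.to_numpy()[0], expected, atol=1e-12)

    def test_missing_sex_names_sample(self, toy_model):
        m = aligned_matrix(toy_model, [[0.2, 0.2], [0.4, 0.4]], ["a", "b"])
        with pytest.raises(ValueError, match="'b'"):
            compute_log_odds(m, np.array([1.0, np.nan]), toy_model)

    def test_missing_values_rejected(self, toy_model):
        m = aligned_matrix(toy_model, [[np.nan], [0.4]])
        with pytest.raises(ValueError, match="impute"):
            compute_log_odds(m, np.array([1.0]), toy_model)


class TestSoftmax:
    def test_uniform_for_equal_log_odds(self):
        np.testing.assert_allclose(softmax_probabilities(np.zeros(3)),
                                   np.full(3, 1 / 3), atol=1e-15)

    def test_reference_triple(self):
        p = softmax_probabilities(np.array([1.0, 0.0, -1.0]))
        np.testing.assert_allclose(p, [0.66524, 0.24473, 0.09003], atol=1e-5)

    def test_shift_invariance(self, random_eta):
        p1 = softmax_probabilities(random_eta)
        p2 = softmax_probabilities(random_eta + 100.0)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_normalization(self, random_eta):
        p = softmax_probabilities(random_eta)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert (p > 0).all()

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            softmax_probabilities(np.array([np.inf, 0.0, 0.0]))


class TestAssignStatus:
    @pytest.mark.parametrize("prob,mode,expected", [
        ((0.6, 0.3, 0.1), "three_class", SmokingStatus.CURRENT),
        ((0.1, 0.2, 0.7), "three_class", SmokingStatus.NEVER),
        ((0.30, 0.50, 0.20), "two_class", SmokingStatus.CURRENT),  # 0.30 > 0.20
        ((0.30, 0.50, 0.20), "three_class", SmokingStatus.FORMER),
        ((0.5, 0.5, 0.0), "three_class", SmokingStatus.CURRENT),   # tie-break
        ((0.4, 0.2, 0.4), "two_class", SmokingStatus.CURRENT),     # tie-break
    ])
    def test_argmax_rules(self, prob, mode, expected):
        assert assign_status(np.array(prob), mode) == expected

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            assign_status(np.array([0.5, 0.3, 0.2]), "four_class")


class TestPredictPipeline:
    def test_full_pipeline_matches_hand_computation(self, toy_model):
        beta = aligned_matrix(toy_model, [[0.2], [0.4]], ["s1"])
        result = predict(beta, np.array([1.0]), toy_model)
        eta = np.array([0.95, -0.12, -0.83])
        expected_p = np.exp(eta) / np.exp(eta).sum()
        row = result.table.iloc[0]
        np.testing.assert_allclose(
            row[["p_current", "p_former", "p_never"]].to_numpy(float),
            expected_p, atol=1e-12)
        assert row["call_3class"] == "current"
        assert row["missing_fraction"] == 0.0

    def test_sample_order_invariance(self, trained_small):
        matrix, sheet, _, results = trained_small
        tm = results.trained_model
        perm = np.random.default_rng(0).permutation(matrix.n_samples)
        permuted = ss.BetaMatrix(matrix.probe_ids, matrix.sample_ids[perm],
                                 matrix.values[:, perm])
        p1 = predict(matrix, sheet, tm).table.set_index("sample_id")
        p2 = predict(permuted, sheet, tm).table.set_index("sample_id")
        num = [c for c in p1.columns if c.startswith(("eta_", "p_", "missing"))]
        np.testing.assert_allclose(p1.loc[p2.index, num].to_numpy(float),
                                   p2[num].to_numpy(float), atol=1e-14)
        assert (p1.loc[p2.index, "call_3class"] == p2["call_3class"]).all()

    def test_all_missing_sample_falls_back_to_prior_plus_sex(self, toy_model):
        beta = aligned_matrix(toy_model, [[np.nan], [np.nan]], ["s1"])
        with pytest.warns(UserWarning, match="missing"):
            result = predict(beta, np.array([0.0]), toy_model)
        np.testing.assert_allclose(
            result.table.iloc[0][["eta_current", "eta_former", "eta_never"]]
            .to_numpy(float), toy_model.intercepts, atol=1e-12)
        assert result.table.iloc[0]["missing_fraction"] == 1.0

    def test_hypomethylation_increases_current_probability(self, toy_model):
        # CpG 1 has w_current < 0: lowering its beta raises P(current)
        xs = np.linspace(0.9, 0.1, 9)
        p_current = []
        for x in xs:
            beta = aligned_matrix(toy_model, [[x], [0.3]], ["s1"])
            p_current.append(predict(beta, np.array([0.0]), toy_model)
                             .table.iloc[0]["p_current"])
        assert all(b > a for a, b in zip(p_current, p_current[1:]))

    def test_two_and_three_class_calls_agree_unless_former(self, random_eta):
        prob = softmax_probabilities(random_eta)
        for p in prob:
            call3 = assign_status(p, "three_class")
            call2 = assign_status(p, "two_class")
            if call3 != SmokingStatus.FORMER:
                assert call2 == call3

    def test_extra_probes_ignored(self, toy_model):
        base = aligned_matrix(toy_model, [[0.2], [0.4]], ["s1"])
        extra = ss.BetaMatrix(
            np.append(toy_model.cpg_ids, "cgJUNK"),
            np.array(["s1"], dtype=object),
            np.array([[0.2], [0.4], [0.99]]))
        p1 = predict(base, np.array([1.0]), toy_model).table
        p2 = predict(extra, np.array([1.0]), toy_model).table
        np.testing.assert_allclose(
            p1[["p_current", "p_former", "p_never"]].to_numpy(float),
            p2[["p_current", "p_former", "p_never"]].to_numpy(float),
            atol=1e-14)
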