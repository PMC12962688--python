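"""Shared fixtures: toy models, small synthetic cohorts, and the
session-scoped full-size training pipeline used by the end-to-end tests."""

import numpy as np
import pandas as pd
import pytest

import smokestatus as ss
from smokestatus.model import TrainedModel


@pytest.fixture
def toy_model() -> TrainedModel:
    """Hand-built 2-CpG model with gauge-centered coefficients."""
    return TrainedModel(
        cpg_ids=np.array(["cg00000001", "cg00000002"], dtype=object),
        intercepts=np.array([0.2, 0.1, -0.3]),
        coefficients=np.array([[-2.0, 0.5, 1.5], [1.0, -0.2, -0.8]]),
        sex_coefficients=np.array([0.05, -0.05, 0.0]),
        training_means=np.array([0.5, 0.3]),
        lam=0.1,
        variance_threshold=0.01,
        metadata={"n_train": 6},
    )


@pytest.fixture
def small_cohort():
    """Small complete cohort: 40 samples/class, 300 probes, 10 signal CpGs."""
    cfg = ss.SimulationConfig(n_current=40, n_former=40, n_never=40, p=300,
                              n_signal=10, missing_rate=0.0, seed=101)
    return ss.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def trained_small():
    """A quick real fit reused across tests (coarse grid, 5 folds)."""
    cfg = ss.SimulationConfig(n_current=40, n_former=40, n_never=40, p=300,
                              n_signal=10, missing_rate=0.0, seed=101)
    matrix, sheet, truth = ss.simulate_cohort(cfg)
    results = ss.SmokingStatusModel(matrix, sheet).fit(n_lambda=40, n_folds=5, seed=5)
    return matrix, sheet, truth, results


@pytest.fixture(scope="session")
def pipeline():
    """Full-size end-to-end pipeline: simulate 300/class x 5000 probes,
    train on 600 (stratified), hold out 300 with 7% baseline probe-level
    missingness. Shared by the parameter-recovery, robustness and
    correlation tests."""
    cfg = ss.SimulationConfig(seed=11, missing_rate=0.0)
    matrix, sheet, truth = ss.simulate_cohort(cfg)
    train_idx = np.r_[0:200, 300:500, 600:800]
    test_idx = np.setdiff1d(np.arange(900), train_idx)
    bm_train = ss.BetaMatrix(matrix.probe_ids, matrix.sample_ids[train_idx],
                             matrix.values[:, train_idx])
    bm_test = ss.BetaMatrix(matrix.probe_ids, matrix.sample_ids[test_idx],
                            matrix.values[:, test_idx])
    results = ss.SmokingStatusModel(bm_train, sheet).fit(seed=7)
    test7 = ss.simulate_missingness_pattern(bm_test, 0.07, seed=99)
    pred = ss.predict(test7, sheet, results.trained_model)
    reference = list(sheet.smoking_status(bm_test.sample_ids))
    return {
        "sheet": sheet,
        "truth": truth,
        "results": results,
        "test_matrix": test7,
        "predictions": pred,
        "reference": reference,
    }


@pytest.fixture
def random_eta():
    rng = np.random.default_rng(42)
    return rng.normal(scale=4.0, size=(1000, 3))
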