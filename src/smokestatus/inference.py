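"""Prediction: imputation, log-odds, softmax posteriors, status calls.

The full pipeline (:func:`predict`) composes harmonize -> align ->
impute -> log-odds -> softmax -> assign. Missing CpGs are imputed with
the model's training means, which in the centered parameterization makes
a missing CpG contribute exactly zero to every class's log-odds: a
sample with *all* CpGs missing falls back to the prior-plus-sex
prediction. Per-sample missing fractions are reported, and a warning is
emitted above 10% missingness — the envelope within which classification
accuracy has been shown to degrade only marginally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .io import BetaMatrix, MissingReport, SampleSheet, align_to_model, harmonize_probe_ids
from .labels import STATUS_ORDER, SmokingStatus
from .model import TrainedModel
from . import solver

__all__ = [
    "impute_missing",
    "compute_log_odds",
    "softmax_probabilities",
    "assign_status",
    "predict",
    "PredictionResult",
    "MISSINGNESS_WARNING_THRESHOLD",
]

#: Missing fraction above which a per-sample warning is emitted.
MISSINGNESS_WARNING_THRESHOLD = 0.10

_ETA_COLS = ["eta_current", "eta_former", "eta_never"]
_P_COLS = ["p_current", "p_former", "p_never"]


def impute_missing(aligned: BetaMatrix, model: TrainedModel) -> BetaMatrix:
    """Replace missing entries with the model's training means.

    ``aligned`` must already be in model CpG order (see
    :func:`smokestatus.io.align_to_model`). Non-missing values are never
    altered.
    """
    if list(aligned.probe_ids) != list(model.cpg_ids):
        raise ValueError("matrix is not aligned to the model's CpG set")
    out = aligned.copy()
    mask = np.isnan(out.values)
    if mask.any():
        fill = np.broadcast_to(model.training_means[:, None], out.values.shape)
        out.values[mask] = fill[mask]
    return out


def compute_log_odds(complete: BetaMatrix, sex: np.ndarray,
                     model: TrainedModel) -> pd.DataFrame:
    """Per-sample, per-class log-odds eta_k = b0_k + w_k.(x - mu) + gamma_k s.

    ``complete`` must be aligned to the model and have no missing entries;
    ``sex`` is female=0 / male=1 per sample.
    """
    if list(complete.probe_ids) != list(model.cpg_ids):
        raise ValueError("matrix is not aligned to the model's CpG set")
    if np.isnan(complete.values).any():
        raise ValueError("matrix has missing entries; impute before computing log-odds")
    sex = np.asarray(sex, dtype=float)
    if len(sex) != complete.n_samples:
        raise ValueError("sex vector length does not match the sample count")
    if np.isnan(sex).any():
        i = int(np.flatnonzero(np.isnan(sex))[0])
        raise ValueError(f"sex is missing for sample {complete.sample_ids[i]!r}")
    centered = complete.values - model.training_means[:, None]  # (M, n)
    eta = (model.intercepts[None, :]
           + centered.T @ model.coefficients
           + sex[:, None] * model.sex_coefficients[None, :])
    return pd.DataFrame(eta, index=complete.sample_ids.astype(str), columns=_ETA_COLS)


def softmax_probabilities(eta: np.ndarray) -> np.ndarray:
    """Softmax P_k = exp(eta_k) / sum_j exp(eta_j) with max-subtraction."""
    eta = np.asarray(eta, dtype=float)
    if not np.isfinite(eta).all():
        raise ValueError("log-odds must be finite")
    return solver.softmax(eta)


def assign_status(prob: np.ndarray, mode: str = "three_class") -> SmokingStatus:
    """Call the status with the highest posterior.

    ``three_class`` takes the argmax over all three classes. ``two_class``
    compares only the current- and never-smoker posteriors (the
    former-smoker probability is ignored). Ties break in the fixed order
    current > former > never.
    """
    prob = np.asarray(prob, dtype=float)
    if prob.shape != (3,):
        raise ValueError("expected 3 class probabilities (current, former, never)")
    if mode == "three_class":
        return STATUS_ORDER[int(np.argmax(prob))]  # argmax breaks ties by class order
    if mode == "two_class":
        return SmokingStatus.CURRENT if prob[0] >= prob[2] else SmokingStatus.NEVER
    raise ValueError(f"unknown mode: {mode!r}")


@dataclass
class PredictionResult:
    """Per-sample predictions plus the alignment missing-data report.

    ``table`` columns: sample_id, eta_*, p_* (posteriors), call_3class,
    call_2class, missing_fraction.
    """

    table: pd.DataFrame
    missing_report: MissingReport

    @property
    def probabilities(self) -> pd.DataFrame:
        return self.table[_P_COLS]

    def calls(self, mode: str = "three_class") -> pd.Series:
        col = "call_3class" if mode == "three_class" else "call_2class"
        return self.table[col]

    def to_tsv(self, path, delimiter: str = "\t") -> None:
        self.table.to_csv(path, sep=delimiter, index=False, na_rep="NA")


def predict(beta: BetaMatrix, sheet_or_sex: Union[SampleSheet, np.ndarray, None],
            model: TrainedModel, mode: str = "three_class",
            platform: Optional[str] = None) -> PredictionResult:
    """Classify every sample of a beta matrix.

    Parameters
    ----------
    beta : BetaMatrix
        Probe x sample matrix; probes outside the model are ignored and
        model CpGs absent from the input are mean-imputed.
    sheet_or_sex : SampleSheet or array
        Source of the sex covariate (female=0, male=1).
    model : TrainedModel
    mode : {'three_class', 'two_class'}
        Affects only which call is considered primary; both calls are
        always present in the output table.
    platform : str, optional
        'epicv2' to harmonize replicate probe ids first.
    """
    if mode not in ("three_class", "two_class"):
        raise ValueError(f"unknown mode: {mode!r}")
    if platform is not None:
        beta = harmonize_probe_ids(beta, platform)
    if isinstance(sheet_or_sex, SampleSheet):
        sex = sheet_or_sex.sex_vector(beta.sample_ids)
    elif sheet_or_sex is None:
        raise ValueError("a sample sheet or sex vector is required")
    else:
        sex = np.asarray(sheet_or_sex, dtype=float)
    aligned, report = align_to_model(beta, model)
    complete = impute_missing(aligned, model)
    eta = compute_log_odds(complete, sex, model)
    prob = softmax_probabilities(eta.to_numpy())
    frac = report.per_sample_missing_fraction.to_numpy()
    high = frac > MISSINGNESS_WARNING_THRESHOLD
    if high.any():
        warnings.warn(
            f"{int(high.sum())} sample(s) exceed {MISSINGNESS_WARNING_THRESHOLD:.0%} "
            "missing model CpGs; predictions degrade beyond this envelope",
            UserWarning, stacklevel=2,
        )
    table = pd.DataFrame({"sample_id": beta.sample_ids.astype(str)})
    table[_ETA_COLS] = eta.to_numpy()
    table[_P_COLS] = prob
    table["call_3class"] = [assign_status(p, "three_class").label for p in prob]
    table["call_2class"] = [assign_status(p, "two_class").label for p in prob]
    table["missing_fraction"] = frac
    return PredictionResult(table=table, missing_report=report)
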