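"""Training pipeline: variance pre-filter, cross-validated multinomial LASSO
with sex as an unpenalized covariate, and model (de)serialization.

The entry points are statsmodels-style::

    model = SmokingStatusModel(beta_matrix, sample_sheet)
    results = model.fit(seed=7)
    print(results.summary())
    predictions = results.predict(new_beta, new_sheet)

``SmokingStatusModel`` holds the training design (labels resolved from the
sample sheet, variance-filtered probes, sex covariate);
``SmokingStatusModel.fit`` selects the penalty by stratified
cross-validation minimizing the held-out multinomial deviance and returns a
``SmokingStatusResults`` wrapping the sparse :class:`TrainedModel`.

Model parameterization
----------------------
Per-class log-odds are evaluated with mean-centered CpG predictors::

    eta_k(x, s) = b0_k + sum_j w_kj * (x_j - mu_j) + gamma_k * s

where ``mu_j`` is the training mean of CpG j (stored in the model and also
used to impute missing CpGs at prediction time, so a missing CpG
contributes exactly zero to every class's log-odds). The softmax gauge is
fixed by centering intercepts, sex coefficients and each CpG's coefficient
row across the three classes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import BetaMatrix, SampleSheet, read_beta_matrix, read_sample_sheet
from .labels import STATUS_ORDER, SmokingStatus
from . import solver

__all__ = [
    "variance_filter",
    "CVResult",
    "TrainedModel",
    "save_model",
    "load_model",
    "select_lambda_cv",
    "fit_multinomial_lasso",
    "SmokingStatusModel",
    "SmokingStatusResults",
]

MODEL_SCHEMA_VERSION = 1
CLASS_LABELS = tuple(s.label for s in STATUS_ORDER)  # ("current", "former", "never")


def variance_filter(matrix: BetaMatrix, quantile: float = 0.75):
    """Drop low-variance probes.

    Per-probe sample variance (n-1 denominator, missing entries skipped)
    is computed; the threshold is the linear-interpolation empirical
    ``quantile`` of those variances, and probes with variance strictly
    greater than the threshold are retained. Probes with fewer than two
    non-missing values have undefined variance and are dropped with a
    warning.

    Returns
    -------
    (BetaMatrix, float)
        The filtered matrix and the variance threshold.
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must be in (0, 1)")
    if matrix.n_samples < 2:
        raise ValueError("variance filter needs at least 2 samples")
    counts = np.sum(~np.isnan(matrix.values), axis=1)
    defined = counts >= 2
    if not defined.all():
        warnings.warn(
            f"{int((~defined).sum())} probe(s) with <2 non-missing values dropped "
            "(variance undefined)", UserWarning, stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        variances = np.nanvar(matrix.values, axis=1, ddof=1)
    variances = np.where(defined, variances, np.nan)
    threshold = float(np.nanquantile(variances, quantile))
    keep = defined & (variances > threshold)
    filtered = BetaMatrix(matrix.probe_ids[keep], matrix.sample_ids.copy(),
                          matrix.values[keep, :].copy())
    return filtered, threshold


@dataclass
class CVResult:
    """Cross-validation trace for the penalty path.

    ``deviance`` is the total held-out multinomial deviance
    -2 * sum_n log P_{y_n} accumulated over all samples across folds
    (so an intercept-only model on balanced 3-class data of size N gives
    2 * N * ln 3). ``deviance_se`` is the across-fold standard error on
    the same scale.
    """

    lambda_grid: np.ndarray
    deviance: np.ndarray
    deviance_se: np.ndarray
    fold_assignment: np.ndarray
    chosen_lambda: float
    chosen_index: int

    def __post_init__(self) -> None:
        i = int(np.argmin(self.deviance))
        if self.deviance[self.chosen_index] > self.deviance[i] + 1e-12:
            raise ValueError("chosen lambda does not attain the minimum CV deviance")


@dataclass
class TrainedModel:
    """Sparse fitted classifier: the portable prediction artifact.

    Log-odds for class k: ``b0_k + sum_j w_kj (x_j - mu_j) + gamma_k * s``
    with sex s coded female=0, male=1. Only CpGs with at least one nonzero
    coefficient are stored.
    """

    classes: tuple = CLASS_LABELS
    cpg_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    intercepts: np.ndarray = field(default_factory=lambda: np.zeros(3))
    coefficients: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))  # (M, K)
    sex_coefficients: np.ndarray = field(default_factory=lambda: np.zeros(3))
    training_means: np.ndarray = field(default_factory=lambda: np.empty(0))  # mu_j
    lam: float = float("nan")
    variance_threshold: float = float("nan")
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cpg_ids = np.asarray(self.cpg_ids, dtype=object)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float).reshape(len(self.cpg_ids), -1)
        self.sex_coefficients = np.asarray(self.sex_coefficients, dtype=float)
        self.training_means = np.asarray(self.training_means, dtype=float)
        if tuple(self.classes) != CLASS_LABELS:
            raise ValueError(f"classes must be {CLASS_LABELS}")
        if len(self.training_means) != len(self.cpg_ids):
            raise ValueError("training_means must align with cpg_ids")
        if self.training_means.size and (
            self.training_means.min() < 0 or self.training_means.max() > 1
        ):
            raise ValueError("training means must lie in [0, 1]")
        if self.cpg_ids.size and not np.all(np.any(self.coefficients != 0, axis=1)):
            raise ValueError("every stored CpG must carry a nonzero coefficient")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    def coefficient_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coefficients, index=self.cpg_ids,
                          columns=[f"w_{c}" for c in self.classes])
        df["mu"] = self.training_means
        return df


def save_model(model: TrainedModel, path) -> None:
    """Serialize a model to versioned JSON (sparse coefficient records)."""
    records = [
        {
            "cpg_id": str(cpg),
            "w_current": float(w[0]),
            "w_former": float(w[1]),
            "w_never": float(w[2]),
            "mu": float(mu),
        }
        for cpg, w, mu in zip(model.cpg_ids, model.coefficients, model.training_means)
    ]
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "classes": list(model.classes),
        "intercepts": [float(v) for v in model.intercepts],
        "sex_coefficients": [float(v) for v in model.sex_coefficients],
        "lambda": float(model.lam),
        "variance_threshold": float(model.variance_threshold),
        "coefficients": records,
        "metadata": model.metadata,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> TrainedModel:
    """Load a model saved by :func:`save_model`."""
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version {version!r} "
            f"(this package reads version {MODEL_SCHEMA_VERSION})"
        )
    for key in ("classes", "intercepts", "sex_coefficients", "coefficients"):
        if key not in payload:
            raise ValueError(f"model file is missing required field {key!r}")
    records = payload["coefficients"]
    for rec in records:
        for key in ("cpg_id", "w_current", "w_former", "w_never", "mu"):
            if key not in rec:
                raise ValueError(f"coefficient record missing field {key!r}")
    return TrainedModel(
        classes=tuple(payload["classes"]),
        cpg_ids=np.array([r["cpg_id"] for r in records], dtype=object),
        intercepts=np.array(payload["intercepts"], dtype=float),
        coefficients=np.array(
            [[r["w_current"], r["w_former"], r["w_never"]] for r in records], dtype=float
        ).reshape(len(records), 3),
        sex_coefficients=np.array(payload["sex_coefficients"], dtype=float),
        training_means=np.array([r["mu"] for r in records], dtype=float),
        lam=float(payload.get("lambda", float("nan"))),
        variance_threshold=float(payload.get("variance_threshold", float("nan"))),
        metadata=payload.get("metadata", {}),
    )


def _stratified_folds(y_index: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic class-stratified fold assignment (0..n_folds-1)."""
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y_index), dtype=int)
    offset = 0
    for k in np.unique(y_index):
        idx = np.flatnonzero(y_index == k)
        perm = rng.permutation(idx)
        folds[perm] = (np.arange(len(perm)) + offset) % n_folds
        offset += len(perm)  # stagger classes across folds
    return folds


def _one_hot(y_index: np.ndarray, n_classes: int = 3) -> np.ndarray:
    Y = np.zeros((len(y_index), n_classes))
    Y[np.arange(len(y_index)), y_index] = 1.0
    return Y


def select_lambda_cv(
    X: np.ndarray,
    y_index: np.ndarray,
    s: np.ndarray,
    lambda_grid: Sequence[float],
    n_folds: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> CVResult:
    """Choose the penalty by stratified cross-validated multinomial deviance.

    For each lambda on the (descending) grid, the held-out deviance
    -2 log P of the true class is accumulated over all samples; the chosen
    lambda minimizes it, with ties broken toward the larger lambda
    (sparser model). Fold assignment is stratified by class and
    deterministic given ``seed``.

    ``X`` is the samples x probes predictor matrix (already standardized
    or not — the caller decides), ``s`` the sex covariate.
    """
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    n = len(y_index)
    folds = _stratified_folds(y_index, n_folds, seed)
    Y = _one_hot(y_index)
    U = np.column_stack([np.ones(n), s])
    total_dev = np.zeros(len(lambda_grid))
    fold_means = np.zeros((n_folds, len(lambda_grid)))
    for f in range(n_folds):
        train = folds != f
        test = ~train
        if len(np.unique(y_index[train])) < 3:
            raise ValueError(f"fold {f}: a smoking class is absent from the training split")
        fits = solver.multinomial_lasso_path(
            X[train], Y[train], U[train], lambda_grid, tol=tol, max_iter=max_iter
        )
        for li, fit in enumerate(fits):
            eta = U[test] @ fit.A + X[test] @ fit.B
            prob = solver.softmax(eta)
            dev = solver.multinomial_deviance(prob, y_index[test])
            total_dev[li] += dev
            fold_means[f, li] = dev / test.sum()
    se = fold_means.std(axis=0, ddof=1) / np.sqrt(n_folds) * n
    chosen = int(np.argmin(total_dev))  # descending grid: first argmin = largest lambda
    return CVResult(
        lambda_grid=lambda_grid,
        deviance=total_dev,
        deviance_se=se,
        fold_assignment=folds,
        chosen_lambda=float(lambda_grid[chosen]),
        chosen_index=chosen,
    )


def fit_multinomial_lasso(
    matrix: BetaMatrix,
    statuses: Sequence[SmokingStatus],
    sex: np.ndarray,
    lambda_grid: Optional[Sequence[float]] = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    n_folds: int = 10,
    seed: int = 0,
    variance_threshold: float = float("nan"),
    tol: float = 1e-6,
    max_iter: int = 2000,
    metadata: Optional[dict] = None,
):
    """Fit the penalized 3-class classifier on a complete, filtered matrix.

    Predictors are standardized internally (zero mean, unit variance) so
    the L1 penalty is comparable across CpGs; stored coefficients are
    back-transformed to the original beta scale with mean-centered
    predictors (see module docstring). Sex and the intercepts are never
    penalized.

    Returns
    -------
    (path, CVResult, TrainedModel)
        ``path`` is the list of per-lambda solver fits on the full data.
    """
    values = matrix.values
    if np.isnan(values).any():
        raise ValueError("training matrix must be complete (no missing entries); "
                         "imputation is a prediction-time concern")
    statuses = [SmokingStatus(s) for s in statuses]
    present = {s for s in statuses}
    if present != set(STATUS_ORDER):
        missing = [s.label for s in STATUS_ORDER if s not in present]
        raise ValueError(f"all 3 classes are required for training; missing: {missing}")
    y_index = np.array([STATUS_ORDER.index(s) for s in statuses])
    sex = np.asarray(sex, dtype=float)
    if np.isnan(sex).any():
        raise ValueError("sex covariate contains missing values")

    Xraw = values.T  # samples x probes
    n, p = Xraw.shape
    if len(y_index) != n or len(sex) != n:
        raise ValueError("statuses/sex length must match the sample count")
    mu = Xraw.mean(axis=0)
    sd = Xraw.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant probes must be removed before fitting (zero variance)")
    Xs = (Xraw - mu) / sd
    Y = _one_hot(y_index)
    U = np.column_stack([np.ones(n), sex])

    if lambda_grid is None:
        lam_max = solver.lambda_max(Xs, Y, U)
        lambda_grid = solver.default_lambda_grid(lam_max, n_lambda, lambda_min_ratio)
    cv = select_lambda_cv(Xs, y_index, sex, lambda_grid, n_folds=n_folds,
                          seed=seed, tol=tol, max_iter=max_iter)
    path = solver.multinomial_lasso_path(Xs, Y, U, cv.lambda_grid,
                                         tol=tol, max_iter=max_iter)
    best = path[cv.chosen_index]

    # back-transform to beta scale; gauge fixed by centering across classes
    W = best.B / sd[:, None]
    W = W - W.mean(axis=1, keepdims=True)
    intercepts = best.A[0] - best.A[0].mean()
    gamma = best.A[1] - best.A[1].mean()
    selected = np.any(W != 0.0, axis=1)
    meta = {
        "n_train": int(n),
        "class_counts": {
            lab: int((y_index == i).sum()) for i, lab in enumerate(CLASS_LABELS)
        },
        "n_candidate_cpgs": int(p),
        "n_folds": int(n_folds),
        "seed": int(seed),
    }
    meta.update(metadata or {})
    trained = TrainedModel(
        classes=CLASS_LABELS,
        cpg_ids=matrix.probe_ids[selected].copy(),
        intercepts=intercepts,
        coefficients=W[selected],
        sex_coefficients=gamma,
        training_means=mu[selected],
        lam=cv.chosen_lambda,
        variance_threshold=variance_threshold,
        metadata=meta,
    )
    return path, cv, trained


class SmokingStatusModel:
    """Three-class smoking-status classifier on methylation beta values.

    Parameters
    ----------
    beta : BetaMatrix
        Complete, quality-controlled training matrix (probes x samples).
    sheet : SampleSheet
        Phenotypes; smoking status is resolved from the ``status`` column
        or, failing that, from the questionnaire ``raw_answer`` codes.
        Occasional smokers (answer 3) and samples without a resolvable
        status are excluded.
    variance_quantile : float
        Quantile of the per-probe variance distribution below which probes
        are discarded before fitting (default 0.75, i.e. the most variable
        quarter of probes enters the LASSO).
    platform : str, optional
        'epicv2' to harmonize replicate probe ids first.
    exclude_flagged : bool
        If True and the sheet has an ``exclude`` column, drop flagged
        samples (e.g. passive smokers, inconsistent never smokers).
    """

    def __init__(self, beta: BetaMatrix, sheet: SampleSheet,
                 variance_quantile: float = 0.75,
                 platform: Optional[str] = None,
                 exclude_flagged: bool = False):
        from .io import harmonize_probe_ids

        if platform is not None:
            beta = harmonize_probe_ids(beta, platform)
        common = [sid for sid in beta.sample_ids if sid in set(sheet.sample_ids)]
        if not common:
            raise ValueError("no overlap between beta-matrix samples and sample sheet")
        statuses = sheet.smoking_status(common)
        usable = [sid for sid in common if isinstance(statuses[sid], SmokingStatus)]
        if exclude_flagged and "exclude" in sheet.data.columns:
            flagged = set(sheet.data.index[sheet.data["exclude"].fillna(0).astype(bool)])
            usable = [sid for sid in usable if sid not in flagged]
        if not usable:
            raise ValueError("no samples with a resolvable smoking status")
        cols = [list(beta.sample_ids).index(sid) for sid in usable]
        self.beta = BetaMatrix(beta.probe_ids.copy(),
                               np.asarray(usable, dtype=object),
                               beta.values[:, cols].copy())
        self.sheet = sheet
        self.statuses = [statuses[sid] for sid in usable]
        self.sex = sheet.sex_vector(usable)
        self.variance_quantile = variance_quantile
        self.n_excluded = len(common) - len(usable)

    @classmethod
    def from_files(cls, beta_path, sheet_path, delimiter=None, **kwargs):
        beta = read_beta_matrix(beta_path, delimiter=delimiter,
                                platform=kwargs.pop("platform", None))
        sheet = read_sample_sheet(sheet_path, delimiter=delimiter)
        return cls(beta, sheet, **kwargs)

    def fit(self, lambda_grid=None, n_lambda: int = 100,
            lambda_min_ratio: float = 1e-3, n_folds: int = 10,
            seed: int = 0, tol: float = 1e-6,
            max_iter: int = 2000) -> "SmokingStatusResults":
        """Variance-filter, cross-validate the penalty, and fit.

        Returns a :class:`SmokingStatusResults`.
        """
        filtered, threshold = variance_filter(self.beta, self.variance_quantile)
        path, cv, trained = fit_multinomial_lasso(
            filtered, self.statuses, self.sex,
            lambda_grid=lambda_grid, n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio, n_folds=n_folds, seed=seed,
            variance_threshold=threshold, tol=tol, max_iter=max_iter,
            metadata={"variance_quantile": self.variance_quantile},
        )
        return SmokingStatusResults(self, trained, cv, path)


class SmokingStatusResults:
    """Fitted classifier: sparse coefficients, CV trace, prediction."""

    def __init__(self, model: SmokingStatusModel, trained: TrainedModel,
                 cv: CVResult, path: list):
        self.model = model
        self.trained_model = trained
        self.cv = cv
        self.path = path

    @property
    def params(self) -> pd.DataFrame:
        """Per-CpG coefficient table on the beta scale."""
        return self.trained_model.coefficient_table()

    @property
    def n_selected_cpgs(self) -> int:
        return self.trained_model.n_cpgs

    def predict(self, beta: BetaMatrix, sheet: Optional[SampleSheet] = None,
                sex=None, mode: str = "three_class", platform=None):
        """Classify new samples; see :func:`smokestatus.inference.predict`."""
        from .inference import predict as _predict
        return _predict(beta, sheet if sheet is not None else sex,
                        self.trained_model, mode=mode, platform=platform)

    def save(self, path) -> None:
        save_model(self.trained_model, path)

    def summary(self) -> str:
        tm = self.trained_model
        meta = tm.metadata
        counts = meta.get("class_counts", {})
        top = (self.params.drop(columns="mu").abs().max(axis=1)
               .sort_values(ascending=False).head(5))
        lines = [
            "Penalized multinomial smoking-status classifier",
            "=" * 48,
            f"Training samples:      {meta.get('n_train', 'NA')} "
            f"(current {counts.get('current', '?')}, former {counts.get('former', '?')}, "
            f"never {counts.get('never', '?')})",
            f"Candidate CpGs:        {meta.get('n_candidate_cpgs', 'NA')} "
            f"(variance > {tm.variance_threshold:.4g})",
            f"Selected CpGs:         {tm.n_cpgs}",
            f"Penalty lambda:        {tm.lam:.6g} "
            f"({meta.get('n_folds', '?')}-fold CV deviance "
            f"{self.cv.deviance[self.cv.chosen_index]:.2f})",
            f"Sex coefficients:      "
            + ", ".join(f"{c}={g:+.4f}" for c, g in zip(tm.classes, tm.sex_coefficients)),
            f"Intercepts:            "
            + ", ".join(f"{c}={b:+.4f}" for c, b in zip(tm.classes, tm.intercepts)),
            "",
            "Largest-coefficient CpGs (max |w| across classes):",
        ]
        for cpg, w in top.items():
            lines.append(f"  {cpg}: {w:.4f}")
        return "\n".join(lines)
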