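"""Missing-CpG robustness simulation.

Real methylation matrices routinely lose probes to quality-control
filtering or platform differences. This module quantifies how gracefully
classification accuracy degrades: probes are masked at random at a series
of fractions (by default 8%-50%, bracketing typical baseline missingness
of ~7%), prediction is repeated over independent maskings, and the
resulting overall accuracies (3-class, and 2-class current-vs-never with
reference former smokers excluded) are compared against the unmasked
baseline. Masking is applied on top of any missingness already present
in the input, uniformly across the input matrix's probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import confusion_matrix, overall_accuracy, two_class_evaluation
from .inference import predict
from .io import BetaMatrix, SampleSheet
from .labels import SmokingStatus
from .model import TrainedModel
from .simulate import simulate_missingness_pattern

__all__ = ["mask_cpgs", "missingness_sweep", "RobustnessResult", "DEFAULT_MASKING_FRACTIONS"]

#: Masking fractions of the standard robustness protocol.
DEFAULT_MASKING_FRACTIONS = (0.08, 0.09, 0.10, 0.15, 0.20, 0.30, 0.50)


def mask_cpgs(matrix: BetaMatrix, fraction: float, seed: int) -> BetaMatrix:
    """Set ``round(fraction * n_probes)`` randomly chosen probes fully missing.

    Probes are drawn uniformly without replacement; reproducible from
    ``seed``. ``fraction`` must be in [0, 1); 0 is the identity.
    """
    return simulate_missingness_pattern(matrix, fraction, seed)


def _iteration_seed(base_seed: int, fraction_index: int, iteration: int) -> int:
    """Deterministic, cell-independent per-iteration seed."""
    ss = np.random.SeedSequence([int(base_seed), int(fraction_index), int(iteration)])
    return int(ss.generate_state(1)[0])


@dataclass
class RobustnessResult:
    """Outcome of a masking sweep."""

    fractions: np.ndarray
    accuracies_3class: dict  # fraction -> list of per-iteration accuracies (NaN = failed)
    accuracies_2class: dict
    baseline_3class: float
    baseline_2class: float
    n_iter: int
    base_seed: int
    seeds: dict = field(default_factory=dict)  # fraction -> list of seeds
    failures: list = field(default_factory=list)  # (fraction, iteration, message)

    def summary(self) -> pd.DataFrame:
        """Mean/sd/min/max accuracy per fraction and mode (long format)."""
        rows = []
        for mode, acc in (("three_class", self.accuracies_3class),
                          ("two_class", self.accuracies_2class)):
            for frac in self.fractions:
                a = np.asarray(acc[float(frac)], dtype=float)
                ok = a[~np.isnan(a)]
                rows.append({
                    "fraction": float(frac), "mode": mode,
                    "n_iter": len(a), "n_failed": int(np.isnan(a).sum()),
                    "mean": float(ok.mean()) if ok.size else float("nan"),
                    "sd": float(ok.std(ddof=1)) if ok.size > 1 else float("nan"),
                    "min": float(ok.min()) if ok.size else float("nan"),
                    "max": float(ok.max()) if ok.size else float("nan"),
                })
        return pd.DataFrame(rows)

    def long_table(self) -> pd.DataFrame:
        rows = []
        for mode, acc in (("three_class", self.accuracies_3class),
                          ("two_class", self.accuracies_2class)):
            for frac in self.fractions:
                for it, a in enumerate(acc[float(frac)]):
                    rows.append({"fraction": float(frac), "iteration": it,
                                 "mode": mode, "accuracy": a})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "fractions": [float(f) for f in self.fractions],
            "baseline_3class": self.baseline_3class,
            "baseline_2class": self.baseline_2class,
            "n_iter": self.n_iter,
            "base_seed": self.base_seed,
            "accuracies_3class": {str(k): list(v) for k, v in self.accuracies_3class.items()},
            "accuracies_2class": {str(k): list(v) for k, v in self.accuracies_2class.items()},
            "failures": self.failures,
        }


def _accuracies(beta, sheet, model, reference):
    pred = predict(beta, sheet, model)
    acc3 = overall_accuracy(confusion_matrix(reference, pred.table["call_3class"]))
    acc2 = two_class_evaluation(reference, pred.table["call_2class"]).overall_accuracy
    return acc3, acc2


def missingness_sweep(
    beta: BetaMatrix,
    sheet: SampleSheet,
    model: TrainedModel,
    fractions: Sequence[float] = DEFAULT_MASKING_FRACTIONS,
    n_iter: int = 50,
    base_seed: int = 0,
    reference: Optional[Sequence] = None,
) -> RobustnessResult:
    """Repeat random-masking + classification across masking fractions.

    For each fraction, ``n_iter`` independent probe maskings are drawn
    (seeds derived deterministically from ``base_seed``), the masked
    matrix is classified, and 3-class and 2-class overall accuracies are
    recorded. The baseline is the accuracy on the unmasked input. An
    iteration that cannot be classified (e.g. every model CpG masked) is
    recorded as failed (NaN accuracy), never silently dropped.

    ``reference`` defaults to the self-reported statuses resolved from the
    sample sheet.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if reference is None:
        statuses = sheet.smoking_status(beta.sample_ids)
        if not all(isinstance(s, SmokingStatus) for s in statuses):
            raise ValueError("every sample needs a reference smoking status")
        reference = list(statuses)
    base3, base2 = _accuracies(beta, sheet, model, reference)
    fractions = np.asarray(list(fractions), dtype=float)
    acc3, acc2, seeds, failures = {}, {}, {}, []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # expected high-missingness warnings
        for fi, frac in enumerate(fractions):
            a3, a2, ss = [], [], []
            for it in range(n_iter):
                seed = _iteration_seed(base_seed, fi, it)
                ss.append(seed)
                try:
                    masked = mask_cpgs(beta, float(frac), seed)
                    r3, r2 = _accuracies(masked, sheet, model, reference)
                except ValueError as exc:
                    failures.append((float(frac), it, str(exc)))
                    r3 = r2 = float("nan")
                a3.append(r3)
                a2.append(r2)
            acc3[float(frac)] = a3
            acc2[float(frac)] = a2
            seeds[float(frac)] = ss
    return RobustnessResult(
        fractions=fractions, accuracies_3class=acc3, accuracies_2class=acc2,
        baseline_3class=base3, baseline_2class=base2, n_iter=n_iter,
        base_seed=base_seed, seeds=seeds, failures=failures,
    )
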