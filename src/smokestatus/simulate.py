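"""Synthetic EPIC-like cohort generator with ground-truth smoking structure.

Real training cohorts for this classifier are access-restricted, so every
downstream stage is exercised on simulated data that reproduces the
statistical structure the method assumes:

* three self-reported classes (current / former / never smokers);
* hypomethylation at a subset of "signal" CpGs in current smokers, with a
  per-sample dose factor tied to pack-years;
* intermediate, cessation-time-dependent methylation in former smokers
  (exponential recovery toward the never-smoker baseline);
* sex-shifted CpGs (sex is a covariate in the model);
* beta-distributed measurement noise parameterized by (mean, concentration),
  keeping values in [0, 1] with realistic heteroscedasticity;
* log-normal blood cotinine, much higher in current smokers, mixed in
  former smokers;
* a configurable missingness rate (~7% by default, matching the baseline
  missing-probe rate of quality-controlled test matrices).

Array chemistry (type I/II probes, dye bias), batch effects, cell
composition and meQTL structure are deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import BetaMatrix, SampleSheet
from .labels import SmokingStatus

__all__ = ["SimulationConfig", "CohortTruth", "simulate_cohort", "simulate_missingness_pattern"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults give a cohort on which a fitted model is accurate but not
    perfect, so regressions remain visible in tests.

    Attributes
    ----------
    n_current, n_former, n_never : int
        Samples per smoking class.
    p : int
        Total probe count.
    n_signal : int
        Number of smoking-signal CpGs (hypomethylated in smokers).
    delta : float
        Mean beta decrease at signal CpGs in current smokers, in (0, 1).
    tau : float
        Former-smoker recovery time constant in years: the smoking effect
        decays as exp(-cessation_years / tau).
    n_sex_cpgs : int
        Number of CpGs shifted by ``delta_sex`` in males.
    delta_sex : float
        Beta shift at sex-effect CpGs in males.
    concentration : float
        Beta-distribution dispersion; shapes are (mean*c, (1-mean)*c).
    missing_rate : float
        Fraction of entries masked at random, in [0, 1). Entry-level by
        default; set ``probe_level_missingness`` for whole-probe masking.
    probe_level_missingness : bool
        If True, mask whole probes (round(missing_rate * p) of them)
        instead of individual entries.
    cotinine_meanlog, cotinine_sdlog : dict
        Per-class log-scale mean/sd of blood cotinine (ng/ml).
    seed : int
        Seed for full reproducibility.
    """

    n_current: int = 300
    n_former: int = 300
    n_never: int = 300
    p: int = 5000
    n_signal: int = 30
    delta: float = 0.12
    tau: float = 10.0
    n_sex_cpgs: int = 20
    delta_sex: float = 0.10
    concentration: float = 50.0
    missing_rate: float = 0.07
    probe_level_missingness: bool = False
    cotinine_meanlog: dict = field(
        default_factory=lambda: {"current": 5.0, "former": 1.5, "never": 0.0}
    )
    cotinine_sdlog: dict = field(
        default_factory=lambda: {"current": 0.5, "former": 1.5, "never": 0.5}
    )
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_current, self.n_former, self.n_never) < 0:
            raise ValueError("class sample counts must be >= 0")
        if self.p <= 0:
            raise ValueError("p must be positive")
        if self.n_signal < 0 or self.n_sex_cpgs < 0:
            raise ValueError("CpG counts must be >= 0")
        if self.n_signal + self.n_sex_cpgs > self.p:
            raise ValueError("signal + sex CpGs exceed total probe count")
        if not (0.0 < self.delta < 1.0):
            raise ValueError("delta must be in (0, 1)")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")


@dataclass
class CohortTruth:
    """Ground truth behind a simulated cohort."""

    true_status: pd.Series  # SmokingStatus per sample id
    signal_cpg_ids: np.ndarray
    sex_cpg_ids: np.ndarray
    pack_years: pd.Series
    cessation_years: pd.Series  # NaN except for former smokers
    cotinine: pd.Series


def simulate_cohort(config: SimulationConfig):
    """Generate a synthetic cohort.

    Background CpG j has a baseline mean m_j ~ Uniform(0.05, 0.95); each
    value is drawn from Beta(m*c, (1-m)*c). At signal CpGs the per-sample
    mean is lowered by delta * d_i for current smokers (d_i a pack-years
    dose factor in [0.5, 1.5] with mean 1) and by
    delta * d_i * exp(-cessation_years_i / tau) for former smokers; never
    smokers sit at baseline. Sex-effect CpGs are shifted by delta_sex in
    males. All means are clipped to [0.02, 0.98] before sampling.

    Returns
    -------
    (BetaMatrix, SampleSheet, CohortTruth)
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_current + config.n_former + config.n_never

    status = np.array(
        [SmokingStatus.CURRENT] * config.n_current
        + [SmokingStatus.FORMER] * config.n_former
        + [SmokingStatus.NEVER] * config.n_never,
        dtype=object,
    )
    sample_ids = np.array([f"S{i:04d}" for i in range(n)], dtype=object)
    probe_ids = np.array([f"cg{j:08d}" for j in range(config.p)], dtype=object)

    special = rng.choice(config.p, size=config.n_signal + config.n_sex_cpgs, replace=False)
    signal_idx = np.sort(special[: config.n_signal])
    sex_idx = np.sort(special[config.n_signal:])

    sex = rng.integers(0, 2, size=n).astype(float)  # female=0, male=1

    is_current = status == SmokingStatus.CURRENT
    is_former = status == SmokingStatus.FORMER
    ever = is_current | is_former

    pack_years = np.zeros(n)
    pack_years[ever] = rng.lognormal(mean=2.5, sigma=0.6, size=int(ever.sum()))
    # dose factor in [0.5, 1.5] with mean 1, monotone in pack-years
    dose = np.ones(n)
    if ever.sum() > 1:
        ranks = pd.Series(pack_years[ever]).rank(method="average").to_numpy()
        dose[ever] = 0.5 + (ranks - 0.5) / len(ranks)

    cessation = np.full(n, np.nan)
    cessation[is_former] = rng.uniform(0.5, 30.0, size=int(is_former.sum()))

    effect = np.zeros(n)
    effect[is_current] = dose[is_current]
    effect[is_former] = dose[is_former] * np.exp(-cessation[is_former] / config.tau)

    baseline = rng.uniform(0.05, 0.95, size=config.p)
    means = np.broadcast_to(baseline[:, None], (config.p, n)).copy()
    means[signal_idx, :] -= config.delta * effect[None, :]
    means[np.ix_(sex_idx, np.flatnonzero(sex == 1))] += config.delta_sex
    np.clip(means, 0.02, 0.98, out=means)

    c = config.concentration
    values = rng.beta(means * c, (1.0 - means) * c)

    if config.missing_rate > 0:
        if config.probe_level_missingness:
            n_mask = int(round(config.missing_rate * config.p))
            masked = rng.choice(config.p, size=n_mask, replace=False)
            values[masked, :] = np.nan
        else:
            mask = rng.random(values.shape) < config.missing_rate
            values[mask] = np.nan

    meanlog = np.array([config.cotinine_meanlog[s.label] for s in status])
    sdlog = np.array([config.cotinine_sdlog[s.label] for s in status])
    cotinine = np.exp(rng.normal(meanlog, sdlog))

    matrix = BetaMatrix(probe_ids, sample_ids, values)
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids.astype(str),
        "sex": np.where(sex == 1, "male", "female"),
        "status": [s.label for s in status],
        "cotinine": np.round(cotinine, 4),
        "pack_years": np.round(pack_years, 3),
        "cessation_years": np.round(cessation, 3),
        "age": np.round(rng.uniform(25, 65, size=n), 1),
    }))
    truth = CohortTruth(
        true_status=pd.Series(status, index=sample_ids.astype(str)),
        signal_cpg_ids=probe_ids[signal_idx].copy(),
        sex_cpg_ids=probe_ids[sex_idx].copy(),
        pack_years=pd.Series(pack_years, index=sample_ids.astype(str)),
        cessation_years=pd.Series(cessation, index=sample_ids.astype(str)),
        cotinine=pd.Series(cotinine, index=sample_ids.astype(str)),
    )
    return matrix, sheet, truth


def simulate_missingness_pattern(matrix: BetaMatrix, rate: float, seed: int) -> BetaMatrix:
    """Mask whole probes at random, emulating baseline probe-level missingness.

    Exactly ``round(rate * n_probes)`` probes are set fully missing across
    all samples (probe-level missingness mirrors quality-control probe
    filtering). Reproducible from ``seed``.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    out = matrix.copy()
    n_mask = int(round(rate * matrix.n_probes))
    if n_mask:
        rng = np.random.default_rng(seed)
        masked = rng.choice(matrix.n_probes, size=n_mask, replace=False)
        out.values[masked, :] = np.nan
    return out
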