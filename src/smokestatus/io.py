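"""Beta-matrix and sample-sheet containers with delimited-text I/O.

A *beta matrix* is a probes x samples table of methylation fractions in
[0, 1]; missing entries (filtered probes, failed detections) are allowed
and represented as NaN internally and as ``NA`` on disk. A *sample sheet*
is a per-sample phenotype table (sex, self-reported smoking answer or
status, optional cotinine, pack-years, cessation time, age).

Probe identifiers from the EPICv2 platform carry replicate suffixes after
an underscore (``cg05575921_BC11``); :func:`harmonize_probe_ids` strips
the suffix and collapses replicate rows by the mean of non-missing values
so EPICv2 data can be scored with an EPIC-trained model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

from .labels import SmokingStatus, categorize_smoking_status

if TYPE_CHECKING:  # pragma: no cover
    from .model import TrainedModel

__all__ = [
    "BetaMatrix",
    "SampleSheet",
    "MissingReport",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "harmonize_probe_ids",
    "align_to_model",
]

#: Strings accepted as missing on read; ``NA`` is written.
NA_VALUES = ("", "NA", "NaN", "nan")

SEX_CODES = {
    "f": 0, "female": 0, "0": 0,
    "m": 1, "male": 1, "1": 1,
}


@dataclass
class BetaMatrix:
    """Probe-by-sample matrix of methylation beta values.

    Parameters
    ----------
    probe_ids : array of str
        CpG identifiers, one per row; unique after harmonization.
    sample_ids : array of str
        Sample identifiers, one per column.
    values : ndarray of float, shape (n_probes, n_samples)
        Beta values in [0, 1]; NaN marks a missing entry.
    """

    probe_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D probes x samples array")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids are not unique")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            bad = np.argwhere((self.values < 0) | (self.values > 1))
            r, c = bad[0]
            raise ValueError(
                f"beta value out of [0, 1]: {self.values[r, c]!r} at probe "
                f"{self.probe_ids[r]!r}, sample {self.sample_ids[c]!r}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self.probe_ids.copy(), self.sample_ids.copy(), self.values.copy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BetaMatrix":
        return cls(df.index.to_numpy(object), df.columns.to_numpy(object), df.to_numpy(float))


@dataclass
class SampleSheet:
    """Per-sample phenotype table.

    Wraps a DataFrame indexed by unique sample id with typed accessors for
    the columns the classifier uses. ``sex`` is coded female=0, male=1.
    Unknown columns are preserved.
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id",)
    KNOWN = ("sample_id", "sex", "raw_answer", "status", "cotinine",
             "pack_years", "cessation_years", "age")

    def __post_init__(self) -> None:
        df = self.data
        if "sample_id" not in df.columns:
            raise ValueError("sample sheet must have a 'sample_id' column")
        df = df.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if "sex" in df.columns:
            df["sex"] = df["sex"].map(self._parse_sex)
        if "status" in df.columns:
            df["status"] = df["status"].map(self._parse_status)
        if "raw_answer" in df.columns:
            df["raw_answer"] = df["raw_answer"].astype("Int64")
            bad = df["raw_answer"].dropna()
            if len(bad) and ((bad < 1) | (bad > 6)).any():
                raise ValueError("raw_answer values must be in 1..6")
        for col in ("cotinine", "pack_years", "cessation_years", "age"):
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="raise")
        if "cotinine" in df.columns and (df["cotinine"].dropna() < 0).any():
            raise ValueError("cotinine must be >= 0 ng/ml")
        self.data = df.set_index("sample_id", drop=False)

    @staticmethod
    def _parse_sex(value):
        if pd.isna(value):
            return np.nan
        key = str(value).strip().lower()
        if key in SEX_CODES:
            return SEX_CODES[key]
        raise ValueError(f"unknown sex code: {value!r} (expected female/male or F/M or 0/1)")

    @staticmethod
    def _parse_status(value):
        if pd.isna(value):
            return np.nan
        key = str(value).strip().lower()
        if key in ("current", "former", "never", "occasional", "unknown"):
            return key
        raise ValueError(f"unknown smoking status: {value!r}")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.data["sample_id"].to_numpy(object)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, sample_ids) -> "SampleSheet":
        return SampleSheet(self.data.loc[list(sample_ids)].reset_index(drop=True))

    def sex_vector(self, sample_ids=None) -> np.ndarray:
        """Sex covariate (female=0, male=1) for the given samples; errors on missing."""
        df = self.data if sample_ids is None else self.data.loc[list(sample_ids)]
        if "sex" not in df.columns:
            raise ValueError("sample sheet has no 'sex' column, required here")
        sex = df["sex"].to_numpy(float)
        if np.isnan(sex).any():
            missing = df.index[np.isnan(sex)][0]
            raise ValueError(f"sex is missing for sample {missing!r}")
        return sex

    def smoking_status(self, sample_ids=None) -> pd.Series:
        """Resolve smoking status per sample from `status` or `raw_answer`.

        Returns a Series of :class:`SmokingStatus` values; NaN where the
        sample is excluded (occasional/unknown) or has no information.
        """
        df = self.data if sample_ids is None else self.data.loc[list(sample_ids)]
        out = pd.Series(np.nan, index=df.index, dtype=object)
        if "status" in df.columns:
            for sid, val in df["status"].items():
                if isinstance(val, str) and val in ("current", "former", "never"):
                    out[sid] = SmokingStatus.from_label(val)
        if "raw_answer" in df.columns:
            for sid, ans in df["raw_answer"].items():
                if out[sid] is np.nan or pd.isna(out[sid]):
                    if not pd.isna(ans):
                        out[sid] = categorize_smoking_status(int(ans))
        return out


@dataclass
class MissingReport:
    """Missing-data summary produced by :func:`align_to_model`."""

    overall_missing_fraction: float
    per_sample_missing_fraction: pd.Series
    n_model_cpgs: int
    n_matched_cpgs: int
    n_extra_probes_dropped: int


def _infer_delimiter(path: str, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def read_beta_matrix(path, delimiter: Optional[str] = None,
                     platform: Optional[str] = None) -> BetaMatrix:
    """Read a probes x samples beta matrix from delimited text.

    First column holds probe ids, header row holds sample ids. Missing
    entries may be encoded as empty, ``NA`` or ``NaN``. Values outside
    [0, 1] or non-numeric cells raise with the offending probe/sample
    named. Duplicate probe ids are an error unless ``platform`` is given,
    in which case :func:`harmonize_probe_ids` is applied.
    """
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     na_values=list(NA_VALUES), keep_default_na=False)
    raw = df.to_numpy(object)
    try:
        values = df.astype(float).to_numpy()
    except (ValueError, TypeError):
        for i in range(raw.shape[0]):
            for j in range(raw.shape[1]):
                cell = raw[i, j]
                if isinstance(cell, str):
                    try:
                        float(cell)
                    except ValueError:
                        raise ValueError(
                            f"non-numeric beta value {cell!r} at probe "
                            f"{df.index[i]!r}, sample {df.columns[j]!r}"
                        ) from None
        raise
    probe_ids = df.index.to_numpy(object)
    matrix = BetaMatrix(probe_ids, df.columns.to_numpy(object), values)
    if len(set(probe_ids)) != len(probe_ids):
        if platform is None:
            dup = pd.Index(probe_ids)[pd.Index(probe_ids).duplicated()][0]
            raise ValueError(
                f"duplicate probe id {dup!r}; pass platform='epicv2' to harmonize replicates"
            )
        matrix = harmonize_probe_ids(matrix, platform)
    elif platform is not None:
        matrix = harmonize_probe_ids(matrix, platform)
    return matrix


def write_beta_matrix(matrix: BetaMatrix, path, delimiter: Optional[str] = None) -> None:
    """Write a beta matrix as delimited text, missing entries as ``NA``."""
    sep = _infer_delimiter(path, delimiter)
    matrix.to_dataframe().to_csv(path, sep=sep, na_rep="NA", index_label="probe_id")


def read_sample_sheet(path, delimiter: Optional[str] = None) -> SampleSheet:
    """Read a sample sheet from delimited text (columns by name)."""
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str},
                     na_values=list(NA_VALUES), keep_default_na=False)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path, delimiter: Optional[str] = None) -> None:
    sep = _infer_delimiter(path, delimiter)
    sheet.data.to_csv(path, sep=sep, na_rep="NA", index=False)


def harmonize_probe_ids(matrix: BetaMatrix, platform: str = "epicv2") -> BetaMatrix:
    """Strip EPICv2 replicate suffixes and collapse replicate probe rows.

    EPICv2 probe ids carry a replicate suffix after an underscore
    (``cg05575921_BC11``); the suffix is dropped and rows sharing a base
    CpG id are collapsed to the mean of their non-missing values. EPIC
    ids without a suffix pass through unchanged, so the operation is
    idempotent and safe on either platform.
    """
    if str(platform).lower() not in ("epic", "epicv2"):
        raise ValueError(f"unknown platform: {platform!r} (expected 'epic' or 'epicv2')")
    base_ids = np.array([pid.split("_", 1)[0] for pid in matrix.probe_ids], dtype=object)
    if len(set(base_ids)) == len(base_ids):
        return BetaMatrix(base_ids, matrix.sample_ids.copy(), matrix.values.copy())
    df = pd.DataFrame(matrix.values, index=base_ids, columns=matrix.sample_ids)
    # mean of non-missing replicates per base id; all-NaN stays NaN
    collapsed = df.groupby(level=0, sort=False).mean()
    return BetaMatrix.from_dataframe(collapsed)


def align_to_model(matrix: BetaMatrix, model: "TrainedModel"):
    """Reorder/reindex a harmonized beta matrix to a model's CpG set.

    Rows are returned in model CpG order; model CpGs absent from the input
    become fully missing rows, and input probes outside the model are
    dropped. Non-missing values are never altered.

    Returns
    -------
    (BetaMatrix, MissingReport)
    """
    model_cpgs = list(model.cpg_ids)
    df = matrix.to_dataframe()
    if df.index.has_duplicates:
        raise ValueError("matrix has duplicate probe ids; harmonize before aligning")
    matched = df.index.intersection(model_cpgs)
    if len(matched) == 0:
        raise ValueError("none of the model CpGs are present in the input matrix")
    aligned = df.reindex(model_cpgs)
    values = aligned.to_numpy(float)
    missing = np.isnan(values)
    report = MissingReport(
        overall_missing_fraction=float(missing.mean()),
        per_sample_missing_fraction=pd.Series(
            missing.mean(axis=0), index=matrix.sample_ids.astype(str)
        ),
        n_model_cpgs=len(model_cpgs),
        n_matched_cpgs=int(len(matched)),
        n_extra_probes_dropped=int(len(df.index) - len(matched)),
    )
    out = BetaMatrix(np.asarray(model_cpgs, dtype=object), matrix.sample_ids.copy(), values)
    return out, report
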