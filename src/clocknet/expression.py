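"""Expression-matrix I/O and normalization for matched tumor/control cohorts.

The central container is :class:`PairedExpressionSet`: two log2 intensity
matrices (features x patients) with identical row and column ordering, one
per tissue condition.  Inputs are plain TSV files — an expression matrix
whose first column is ``symbol`` and whose remaining columns are sample IDs,
plus a sample sheet with columns ``sample_id``, ``patient_id``, ``tissue``
(tissue in {tumor, control}).  A patient enters the paired set only when it
has exactly one tumor and one control sample; extras are reported and
dropped.

Quantile normalization is provided as a stand-in for upstream array
summarization: inputs are assumed to be pre-normalized level-3-style
intensities, and the utility here only equalizes column distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

TISSUES = ("tumor", "control")

#: Values at or above this are treated as raw (linear) intensities and
#: log2(x+1)-transformed on load.
LOG_SCALE_MAX = 30.0

#: Features missing in more than this fraction of samples are dropped.
MAX_MISSING_FRAC = 0.2


@dataclass
class PairedExpressionSet:
    """Aligned log2 expression matrices for matched tumor/control samples.

    Both frames are indexed by feature symbol with one column per patient;
    the index and columns of ``control`` and ``tumor`` are identical and in
    the same order.
    """

    control: pd.DataFrame
    tumor: pd.DataFrame

    def __post_init__(self) -> None:
        for frame in (self.control, self.tumor):
            frame.index.name = "symbol"
            frame.columns.name = None
        if not self.control.index.equals(self.tumor.index):
            raise ValueError("control and tumor matrices must share the same symbols, in order")
        if not self.control.columns.equals(self.tumor.columns):
            raise ValueError("control and tumor matrices must share the same patients, in order")
        dup = self.control.index[self.control.index.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate feature symbol: {dup[0]!r}")

    @property
    def symbols(self) -> list[str]:
        return list(self.control.index)

    @property
    def patients(self) -> list[str]:
        return list(self.control.columns)

    @property
    def n_patients(self) -> int:
        return self.control.shape[1]

    def diffs(self) -> pd.DataFrame:
        """Per-patient log2 differences, tumor minus control."""
        return self.tumor - self.control

    def subset(self, symbols) -> "PairedExpressionSet":
        symbols = list(symbols)
        return PairedExpressionSet(self.control.loc[symbols], self.tumor.loc[symbols])


def _read_matrix(matrix_path) -> pd.DataFrame:
    df = pd.read_csv(matrix_path, sep="\t", dtype={0: str})
    first = df.columns[0]
    if first.lower() != "symbol":
        raise ValueError(f"expected first column 'symbol', got {first!r}")
    df = df.set_index(first)
    df.index.name = "symbol"
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate feature symbol: {dup[0]!r}")
    return df.apply(pd.to_numeric, errors="coerce")


def _read_samplesheet(samplesheet_path) -> pd.DataFrame:
    sheet = pd.read_csv(samplesheet_path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "tissue"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    bad = set(sheet["tissue"]) - set(TISSUES)
    if bad:
        raise ValueError(f"unknown tissue labels: {sorted(bad)}; expected {TISSUES}")
    return sheet


def load_paired_set(matrix_path, samplesheet_path) -> PairedExpressionSet:
    """Load an expression TSV plus sample sheet into a paired set.

    Patients lacking either a tumor or a control sample are excluded with a
    warning; a patient with two samples of the same tissue is an error.
    Values are coerced to numeric (empty cells become missing); matrices
    whose maximum is >= 30 are assumed linear and log2(x+1)-transformed.
    Features missing in more than 20% of retained samples are dropped.
    """
    df = _read_matrix(matrix_path)
    sheet = _read_samplesheet(samplesheet_path)

    unknown = set(sheet["sample_id"]) - set(df.columns)
    if unknown:
        raise ValueError(f"sample sheet references absent columns: {sorted(unknown)}")

    by_patient: dict[str, dict[str, str]] = {}
    for row in sheet.itertuples(index=False):
        slot = by_patient.setdefault(row.patient_id, {})
        if row.tissue in slot:
            raise ValueError(
                f"patient {row.patient_id!r} has two {row.tissue} samples "
                f"({slot[row.tissue]!r}, {row.sample_id!r})"
            )
        slot[row.tissue] = row.sample_id

    patients, tumor_cols, control_cols = [], [], []
    for pid, slot in by_patient.items():  # insertion order == sheet order
        if len(slot) == 2:
            patients.append(pid)
            tumor_cols.append(slot["tumor"])
            control_cols.append(slot["control"])
        else:
            have = next(iter(slot))
            warnings.warn(f"patient {pid!r} lacks a {'control' if have == 'tumor' else 'tumor'} sample; dropped")
    if not patients:
        raise ValueError("no complete tumor/control patient pairs in sample sheet")

    values = df[tumor_cols + control_cols]
    if np.nanmax(values.to_numpy()) >= LOG_SCALE_MAX:
        warnings.warn(f"matrix maximum >= {LOG_SCALE_MAX:g}: assuming linear scale, applying log2(x+1)")
        values = np.log2(values + 1.0)

    missing_frac = values.isna().mean(axis=1)
    dropped = values.index[missing_frac > MAX_MISSING_FRAC]
    if len(dropped):
        warnings.warn(f"dropping {len(dropped)} features missing in >{MAX_MISSING_FRAC:.0%} of samples")
        values = values.drop(index=dropped)

    tumor = values[tumor_cols].copy()
    tumor.columns = patients
    control = values[control_cols].copy()
    control.columns = patients
    return PairedExpressionSet(control=control, tumor=tumor)


def write_paired_set(pset: PairedExpressionSet, matrix_path, samplesheet_path) -> dict:
    """Write the paired set back to the TSV dialect read by load_paired_set.

    Sample IDs are synthesized as ``<patient>_T`` / ``<patient>_C``.  Values
    round-trip exactly (full float repr).  Returns a small manifest with row
    and column counts per file.
    """
    tumor = pset.tumor.copy()
    tumor.columns = [f"{p}_T" for p in pset.patients]
    control = pset.control.copy()
    control.columns = [f"{p}_C" for p in pset.patients]
    matrix = pd.concat([tumor, control], axis=1)
    matrix.index.name = "symbol"
    matrix.to_csv(matrix_path, sep="\t")

    rows = [(f"{p}_T", p, "tumor") for p in pset.patients]
    rows += [(f"{p}_C", p, "control") for p in pset.patients]
    sheet = pd.DataFrame(rows, columns=["sample_id", "patient_id", "tissue"])
    sheet.to_csv(samplesheet_path, sep="\t", index=False)
    return {
        "matrix": {"path": str(matrix_path), "rows": matrix.shape[0], "cols": matrix.shape[1]},
        "samplesheet": {"path": str(samplesheet_path), "rows": len(sheet), "cols": sheet.shape[1]},
    }


def _quantile_normalize_frame(values: pd.DataFrame) -> pd.DataFrame:
    if values.isna().to_numpy().any():
        raise ValueError("quantile normalization requires a complete matrix (no missing values)")
    arr = values.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = values.copy()
    for col in values.columns:
        first_ranks = values[col].rank(method="first").astype(int).to_numpy()
        assigned = ref[first_ranks - 1]
        # ties receive the mean of the reference values at their rank positions
        s = pd.Series(assigned, index=values.index)
        out[col] = s.groupby(values[col]).transform("mean")
    return out


def quantile_normalize(pset: PairedExpressionSet) -> PairedExpressionSet:
    """Quantile-normalize all samples (both conditions jointly).

    After normalization every column's sorted value vector is identical and
    within-column ranks are preserved.  The reference distribution is the
    across-sample mean of the sorted columns; ties within a column receive
    the mean reference value over their rank positions.  Idempotent.
    """
    if 2 * pset.n_patients < 2 or pset.n_patients < 1:
        raise ValueError("quantile normalization needs at least 2 samples")
    tumor = pset.tumor.copy()
    tumor.columns = [f"{c}|T" for c in tumor.columns]
    control = pset.control.copy()
    control.columns = [f"{c}|C" for c in control.columns]
    joint = pd.concat([tumor, control], axis=1)
    if joint.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    normed = _quantile_normalize_frame(joint)
    new_tumor = normed[tumor.columns].copy()
    new_tumor.columns = pset.patients
    new_control = normed[control.columns].copy()
    new_control.columns = pset.patients
    return PairedExpressionSet(control=new_control, tumor=new_tumor)
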