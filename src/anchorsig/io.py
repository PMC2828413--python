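"""Containers and tab-separated I/O for expression matrices and clinical tables.

The expression format is a plain TSV: one header row ``feature_id<TAB>sample1
<TAB>sample2...`` followed by one numeric row per feature.  The clinical
format is one row per sample with a fixed schema (survival endpoint plus the
standard urothelial prognostic covariates).  Both readers validate
aggressively and report offending line numbers, because silently coerced
cells are the classic way a cohort analysis goes wrong.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ExpressionMatrix",
    "ClinicalTable",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "CLINICAL_COLUMNS",
    "STAGE_LEVELS",
    "GRADE_LEVELS",
    "N_TUMOR_LEVELS",
]


class ParseError(ValueError):
    """Raised when an input table violates the expected format."""


STAGE_LEVELS = ("Ta", "T1")
GRADE_LEVELS = ("low", "high")
N_TUMOR_LEVELS = ("single", "2to7", "ge8")

#: exact column order of the clinical TSV (after the index column sample_id)
CLINICAL_COLUMNS = (
    "time_months",
    "event",
    "stage",
    "grade",
    "n_tumors",
    "size_gt3cm",
    "intravesical_therapy",
)


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()]))
        raise ParseError(f"duplicate {what} identifier(s): {', '.join(map(str, dups))}")


@dataclass
class ExpressionMatrix:
    """Features x samples matrix of continuous (log2-scale) expression values.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by feature identifier, columns by sample identifier.
        All values must be finite floats.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("ExpressionMatrix requires a pandas DataFrame")
        _check_unique(self.data.index, "feature")
        _check_unique(self.data.columns, "sample")
        self.data = self.data.astype(float)
        if not np.isfinite(self.data.to_numpy()).all():
            bad = int((~np.isfinite(self.data.to_numpy())).sum())
            raise ParseError(f"expression matrix contains {bad} non-finite value(s)")
        self.data.index.name = "feature_id"

    # -- convenience -------------------------------------------------------
    @property
    def feature_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_features(self, features) -> "ExpressionMatrix":
        missing = [f for f in features if f not in self.data.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.data.loc[list(features)].copy())

    def subset_samples(self, samples) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.data[list(samples)].copy())

    def feature(self, feature_id) -> pd.Series:
        if feature_id not in self.data.index:
            raise KeyError(f"feature {feature_id!r} not in matrix")
        return self.data.loc[feature_id]

    def __eq__(self, other) -> bool:  # identity up to float equality
        return (
            isinstance(other, ExpressionMatrix)
            and self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.array_equal(self.values, other.values)
        )


@dataclass
class ClinicalTable:
    """Per-sample survival endpoint and categorical prognostic covariates.

    Columns: time_months (>0), event (0/1, 1 = progression), stage (Ta/T1),
    grade (low/high), n_tumors (single/2to7/ge8), size_gt3cm (0/1),
    intravesical_therapy (0/1).  Indexed by sample_id.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise TypeError("ClinicalTable requires a pandas DataFrame")
        _check_unique(df.index, "sample")
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"clinical table missing column(s): {missing}")
        extra = [c for c in df.columns if c not in CLINICAL_COLUMNS]
        if extra:
            raise ParseError(f"clinical table has unexpected column(s): {extra}")
        df = df[list(CLINICAL_COLUMNS)].copy()
        df["time_months"] = df["time_months"].astype(float)
        if not (df["time_months"] > 0).all():
            bad = df.index[df["time_months"] <= 0].tolist()
            raise ParseError(f"time_months must be > 0; offending sample(s): {bad[:10]}")
        for col in ("event", "size_gt3cm", "intravesical_therapy"):
            vals = df[col].astype(int)
            if not vals.isin((0, 1)).all():
                raise ParseError(f"column {col} must be binary 0/1")
            df[col] = vals
        for col, levels in (("stage", STAGE_LEVELS), ("grade", GRADE_LEVELS), ("n_tumors", N_TUMOR_LEVELS)):
            vals = df[col].astype(str)
            bad = sorted(set(vals) - set(levels))
            if bad:
                raise ParseError(f"column {col} has invalid level(s) {bad}; allowed: {levels}")
            df[col] = vals
        df.index.name = "sample_id"
        self.data = df

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time_months"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    # catch duplicates before pandas silently mangles them to name.1, name.2, ...
    _check_unique(header[1:], f"{path.name} header")
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path.name}: malformed TSV ({exc})") from exc
    if df.index.isna().any():
        raise ParseError(f"{path.name}: missing row identifier")
    return df


def _to_numeric(df: pd.DataFrame, path_name: str) -> pd.DataFrame:
    """Convert a string frame to floats, reporting the first bad cells with line numbers."""
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna()
    if bad.to_numpy().any():
        msgs = []
        rows, cols = np.nonzero(bad.to_numpy())
        for r, c in list(zip(rows, cols))[:5]:
            cell = df.iat[r, c]
            what = "empty cell" if pd.isna(cell) else f"non-numeric cell {cell!r}"
            # +2: one for the header row, one for 1-based numbering
            msgs.append(f"line {r + 2}, column {df.columns[c]!r}: {what}")
        raise ParseError(f"{path_name}: " + "; ".join(msgs))
    return out


def read_expression(path) -> ExpressionMatrix:
    """Read a features-x-samples expression TSV."""
    df = _read_tsv(path)
    name = Path(path).name
    _check_unique(df.index, "feature")
    _check_unique(df.columns, "sample")
    return ExpressionMatrix(_to_numeric(df, name))


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write an expression TSV; values are formatted to 6 significant digits."""
    matrix.data.to_csv(path, sep="\t", index_label="feature_id", float_format="%.6g")


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV with the exact schema in :data:`CLINICAL_COLUMNS`."""
    df = _read_tsv(path)
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id", float_format="%.6g")
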