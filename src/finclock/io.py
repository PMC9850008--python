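"""On-disk formats: beta matrices, sample sheets, coefficient tables, reports.

All artifacts are delimited text (CSV by default, TSV via ``sep="\\t"``) or
JSON.  Floats are serialized with 17 significant digits so every
reader/writer pair round-trips exactly.  The canonical in-memory
orientation of a beta matrix is rows = CpGs, columns = samples (the
methylation-array convention); files written the other way round are
declared with ``orientation="samples"`` on read.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "SampleSheet",
    "CoefficientTable",
    "BetaFormatError",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_coefficients",
    "write_coefficients",
    "write_json_report",
]

_FLOAT_FMT = "%.17g"
SEX_LEVELS = ("F", "M")


class BetaFormatError(ValueError):
    """Malformed or invalid on-disk artifact."""


@dataclass
class BetaMatrix:
    """CpG-by-sample grid of methylation fractions.

    ``values`` is a float array with rows matching ``cpg_ids`` and columns
    matching ``sample_ids``; entries are beta values in [0, 1] or NaN for
    missing.
    """

    cpg_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cpg_ids), len(self.sample_ids)):
            raise BetaFormatError(
                f"value grid shape {self.values.shape} does not match "
                f"{len(self.cpg_ids)} CpGs x {len(self.sample_ids)} samples"
            )
        for name, ids in (("cpg", self.cpg_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dup = pd.Index(ids)[pd.Index(ids).duplicated()][0]
                raise BetaFormatError(f"duplicate {name} id: {dup!r}")
        bad = np.argwhere(
            ~np.isnan(self.values)
            & ((self.values < 0.0) | (self.values > 1.0))
        )
        if bad.size:
            i, j = bad[0]
            raise BetaFormatError(
                f"beta value out of [0, 1] at CpG {self.cpg_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}: {self.values[i, j]}"
            )

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.cpg_ids, name="cpg_id"),
            columns=self.sample_ids,
        )

    def select_samples(self, sample_ids) -> "BetaMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return BetaMatrix(
            self.cpg_ids, list(sample_ids), self.values[:, idx]
        )

    def drop_samples(self, sample_ids) -> "BetaMatrix":
        drop = set(sample_ids)
        keep = [s for s in self.sample_ids if s not in drop]
        return self.select_samples(keep)

    def imputed(self) -> np.ndarray:
        """Values with missing cells replaced by the per-CpG mean."""
        v = self.values.copy()
        if np.isnan(v).any():
            with np.errstate(invalid="ignore"):
                row_mean = np.nanmean(v, axis=1)
            row_mean = np.where(np.isnan(row_mean), 0.5, row_mean)
            nr, nc = np.nonzero(np.isnan(v))
            v[nr, nc] = row_mean[nr]
        return v

    def samples_by_cpgs(self, impute: bool = True) -> np.ndarray:
        """Model-facing design matrix: samples as rows, CpGs as columns."""
        v = self.imputed() if impute else self.values
        return np.ascontiguousarray(v.T)


def read_beta_matrix(
    path, orientation: str = "cpgs", sep: str = ","
) -> BetaMatrix:
    """Read a delimited beta-value matrix into canonical orientation.

    ``orientation`` declares the file layout: ``"cpgs"`` for rows = CpGs
    (canonical) or ``"samples"`` for rows = samples (transposed on read).
    Empty cells become missing values; out-of-range or duplicate entries
    raise :class:`BetaFormatError` naming the offender.
    """
    if orientation not in ("cpgs", "samples"):
        raise ValueError(f"orientation must be 'cpgs' or 'samples', got {orientation!r}")
    try:
        # round_trip parsing: values re-read exactly as written
        df = pd.read_csv(
            path, sep=sep, index_col=0, float_precision="round_trip"
        )
    except pd.errors.EmptyDataError as exc:
        raise BetaFormatError(f"empty beta-matrix file: {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise BetaFormatError(
            f"empty beta-matrix file (no data rows/columns): {path}"
        )
    df.index = df.index.astype(str)
    if df.index.duplicated().any() or pd.Index(df.columns).duplicated().any():
        dup = (
            df.index[df.index.duplicated()].tolist()
            + pd.Index(df.columns)[pd.Index(df.columns).duplicated()].tolist()
        )
        raise BetaFormatError(f"duplicate id(s) in beta matrix: {dup[:3]}")
    bad_cols = [c for c, t in df.dtypes.items() if t == object]
    if bad_cols:
        raise BetaFormatError(
            f"non-numeric beta value(s) in {path}, column(s) {bad_cols[:3]}"
        )
    values = df.to_numpy(dtype=float)
    if orientation == "samples":
        values = values.T
        return BetaMatrix(list(df.columns), list(df.index), values)
    return BetaMatrix(list(df.index), list(df.columns), values)


def write_beta_matrix(matrix: BetaMatrix, path, sep: str = ",") -> None:
    """Write in canonical orientation; missing values become empty fields."""
    matrix.to_frame().to_csv(path, sep=sep, float_format=_FLOAT_FMT)


@dataclass
class SampleSheet:
    """Per-sample metadata: age (years), age accuracy class (years), sex.

    Backed by a DataFrame indexed by unique ``sample_id`` with float
    columns ``age`` and ``age_accuracy`` (NaN = unknown) and string column
    ``sex`` in {"F", "M"} or NaN for unknown.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"age", "age_accuracy", "sex"}
        missing = required - set(df.columns)
        if missing:
            raise BetaFormatError(f"sample sheet missing column(s): {sorted(missing)}")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise BetaFormatError(f"duplicate sample_id: {dup!r}")
        if (df["age"].dropna() < 0).any():
            bad = df.index[df["age"] < 0][0]
            raise BetaFormatError(f"negative age for sample {bad!r}")
        if (df["age_accuracy"].dropna() <= 0).any():
            bad = df.index[df["age_accuracy"] <= 0][0]
            raise BetaFormatError(f"non-positive age_accuracy for sample {bad!r}")
        sex = df["sex"].dropna()
        bad_sex = sex[~sex.isin(SEX_LEVELS)]
        if len(bad_sex):
            raise BetaFormatError(
                f"sex must be one of {SEX_LEVELS} or unknown, got "
                f"{bad_sex.iloc[0]!r} for sample {bad_sex.index[0]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_records(cls, sample_ids, ages, accuracies, sexes) -> "SampleSheet":
        df = pd.DataFrame(
            {
                "age": np.asarray(ages, dtype=float),
                "age_accuracy": np.asarray(accuracies, dtype=float),
                "sex": pd.array(sexes, dtype="string"),
            },
            index=pd.Index([str(s) for s in sample_ids], name="sample_id"),
        )
        df["sex"] = df["sex"].astype(object).where(df["sex"].notna(), np.nan)
        return cls(df)


def read_sample_sheet(path, sep: str = ",") -> SampleSheet:
    df = pd.read_csv(
        path, sep=sep, dtype={"sample_id": str, "sex": str},
        float_precision="round_trip",
    )
    if "sample_id" not in df.columns:
        raise BetaFormatError(f"sample sheet {path} lacks a sample_id column")
    df = df.set_index("sample_id")
    df.index.name = "sample_id"
    for col in ("age", "age_accuracy"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "sex" in df.columns:
        sex = df["sex"].astype("string").str.strip().str.upper()
        sex = sex.where(~sex.isin(["", "UNKNOWN", "NA", "U"]), pd.NA)
        df["sex"] = sex.astype(object).where(sex.notna(), np.nan)
    return SampleSheet(df[["age", "age_accuracy", "sex"]])


def write_sample_sheet(sheet: SampleSheet, path, sep: str = ",") -> None:
    sheet.data.to_csv(path, sep=sep, float_format=_FLOAT_FMT)


@dataclass
class CoefficientTable:
    """Sparse fitted model: intercept, per-CpG coefficients, metadata.

    ``model_kind`` is ``"age"`` (metadata: ``adult_age``, ``offset`` of the
    age transform, so a saved clock is self-contained) or ``"sex"``
    (metadata: decision ``threshold``).
    """

    intercept: float
    entries: dict[str, float]
    model_kind: str = "age"
    metadata: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_kind not in ("age", "sex"):
            raise BetaFormatError(
                f"model_kind must be 'age' or 'sex', got {self.model_kind!r}"
            )
        self.intercept = float(self.intercept)
        self.entries = {str(k): float(v) for k, v in self.entries.items()}

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


_INTERCEPT_ROW = "(Intercept)"


def write_coefficients(table: CoefficientTable, path, sep: str = ",") -> None:
    """Commented-header coefficient file; lossless float round trip."""
    lines = [f"# model_kind={table.model_kind}"]
    for key, val in sorted(table.metadata.items()):
        lines.append(f"# {key}={_FLOAT_FMT % val}")
    lines.append(sep.join(["cpg_id", "coefficient"]))
    lines.append(sep.join([_INTERCEPT_ROW, _FLOAT_FMT % table.intercept]))
    for cpg, coef in table.entries.items():
        lines.append(sep.join([cpg, _FLOAT_FMT % coef]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_coefficients(path, sep: str = ",") -> CoefficientTable:
    text = Path(path).read_text()
    metadata: dict[str, float] = {}
    model_kind = "age"
    body: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            key, val = key.strip(), val.strip()
            if key == "model_kind":
                model_kind = val
            elif key:
                metadata[key] = float(val)
        elif line.strip():
            body.append(line)
    if not body:
        raise BetaFormatError(f"coefficient file {path} has no data rows")
    df = pd.read_csv(
        _io.StringIO("\n".join(body)), sep=sep, dtype={"cpg_id": str},
        float_precision="round_trip",
    )
    if not {"cpg_id", "coefficient"} <= set(df.columns):
        raise BetaFormatError(
            f"coefficient file {path} needs columns cpg_id, coefficient"
        )
    if df["cpg_id"].duplicated().any():
        dup = df["cpg_id"][df["cpg_id"].duplicated()].iloc[0]
        raise BetaFormatError(f"duplicate cpg_id in coefficient file: {dup!r}")
    mask = df["cpg_id"] == _INTERCEPT_ROW
    if not mask.any():
        raise BetaFormatError(
            f"coefficient file {path} lacks an {_INTERCEPT_ROW!r} row"
        )
    intercept = float(df.loc[mask, "coefficient"].iloc[0])
    rest = df.loc[~mask]
    entries = dict(zip(rest["cpg_id"], rest["coefficient"].astype(float)))
    return CoefficientTable(
        intercept=intercept, entries=entries,
        model_kind=model_kind, metadata=metadata,
    )


def write_json_report(obj, path) -> None:
    """Serialize a report-like object (dataclass dict or plain dict) to JSON."""

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
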