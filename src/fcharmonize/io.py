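"""Delimited-text readers and writers for phenotypes, time series and feature tables.

The dialect is chosen by extension: ``.csv`` is comma-delimited, ``.tsv``
(and ``.txt``) tab-delimited. Feature tables round-trip losslessly at 12+
significant digits with the feature index serialized as ``a_b`` headers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    DIAGNOSIS_CODES,
    SEX_CODES,
    FCFeatureTable,
    PhenotypeTable,
    ROITimeSeries,
)

FLOAT_FORMAT = "%.15g"


def _sep(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix in (".tsv", ".txt"):
        return "\t"
    raise ValueError(f"unsupported extension {suffix!r}: use .csv or .tsv")


def read_phenotypes(
    path: str | Path,
    columns: dict[str, str] | None = None,
    diagnosis_codes: dict[str, int] | None = None,
    sex_codes: dict[str, int] | None = None,
) -> PhenotypeTable:
    """Read a phenotype table, coercing diagnosis/sex labels to canonical codes.

    Parameters
    ----------
    columns
        Optional mapping from canonical names (``subject_id``, ``site``,
        ``diagnosis``, ``age``, ``sex``) to the file's column names.
    diagnosis_codes, sex_codes
        Label-to-code maps; defaults are control=0/patient=1, male=0/female=1.
        Numeric 0/1 entries are accepted as already coded.
    """
    df = pd.read_csv(path, sep=_sep(path), dtype={0: str})
    columns = columns or {}
    rename = {columns.get(k, k): k for k in ("subject_id", "site", "diagnosis", "age", "sex")}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {missing}")
    df = df.rename(columns=rename)[list(rename.values())]
    df["subject_id"] = df["subject_id"].astype(str)
    df["site"] = df["site"].astype(str)
    if df[["age", "diagnosis", "sex"]].isna().any().any():
        bad = df.index[df[["age", "diagnosis", "sex"]].isna().any(axis=1)].tolist()
        raise ValueError(f"{path}: missing age/sex/diagnosis in rows {bad}")
    df["diagnosis"] = _coerce_codes(df["diagnosis"], diagnosis_codes or DIAGNOSIS_CODES, "diagnosis")
    df["sex"] = _coerce_codes(df["sex"], sex_codes or SEX_CODES, "sex")
    df["age"] = df["age"].astype(float)
    return PhenotypeTable(df)


def _coerce_codes(series: pd.Series, codes: dict[str, int], what: str) -> pd.Series:
    def one(value):
        if isinstance(value, str):
            key = value.strip().lower()
            if key in codes:
                return codes[key]
            try:
                value = float(value)
            except ValueError:
                raise ValueError(f"unknown {what} label {value!r}") from None
        if float(value) in (0.0, 1.0):
            return int(value)
        raise ValueError(f"unknown {what} label {value!r}")

    return series.map(one).astype(int)


def write_phenotypes(phenotypes: PhenotypeTable, path: str | Path) -> None:
    phenotypes.data.to_csv(path, sep=_sep(path), index=False)


def read_timeseries(path: str | Path, subject_id: str | None = None) -> ROITimeSeries:
    """Read a T x R numeric matrix; an optional first header row names regions."""
    path = Path(path)
    sep = _sep(path)
    with open(path) as fh:
        first = fh.readline()
    labels = None
    skip = 0
    fields = first.strip().split(sep)
    try:
        [float(x) for x in fields]
    except ValueError:
        labels = fields
        skip = 1
    df = pd.read_csv(path, sep=sep, header=None, skiprows=skip, dtype=str)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError):
            mask = pd.to_numeric(df[col], errors="coerce").isna()
            i = int(np.argmax(mask.to_numpy()))
            raise ValueError(
                f"{path}: non-numeric cell at row {i + skip}, column {j}: {df[col].iloc[i]!r}"
            ) from None
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"{path}: non-finite cell at row {int(i) + skip}, column {int(j)}")
    if values.shape[0] < 3:
        raise ValueError(
            f"{path}: {values.shape[0]} timepoints; Pearson correlation needs at least 3"
        )
    return ROITimeSeries(subject_id or path.stem, values, labels)


def write_timeseries(ts: ROITimeSeries, path: str | Path) -> None:
    sep = _sep(path)
    header = sep.join(ts.region_labels) + "\n" if ts.region_labels else ""
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, ts.values, delimiter=sep, fmt=FLOAT_FORMAT)


def write_feature_table(table: FCFeatureTable, path: str | Path) -> None:
    """Write a feature table with ``subject_id`` first and ``a_b`` feature headers.

    Provenance is stored in a ``#provenance:`` comment line so that pipeline
    stage ordering survives a round trip.
    """
    sep = _sep(path)
    with open(path, "w") as fh:
        if table.provenance:
            fh.write("#provenance: " + ",".join(table.provenance) + "\n")
        fh.write(sep.join(["subject_id"] + table.feature_names()) + "\n")
        for sid, row in zip(table.subject_ids, table.values):
            fh.write(sid + sep + sep.join(FLOAT_FORMAT % x for x in row) + "\n")


def read_feature_table(
    path: str | Path, phenotypes: PhenotypeTable | None = None
) -> FCFeatureTable:
    """Read a feature table; if ``phenotypes`` is given, enforce row alignment."""
    sep = _sep(path)
    provenance: list[str] = []
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#provenance:"):
            provenance = [s for s in first.split(":", 1)[1].strip().split(",") if s]
            skiprows = 1
        else:
            skiprows = 0
    df = pd.read_csv(path, sep=sep, skiprows=skiprows, dtype={"subject_id": str})
    if df.columns[0] != "subject_id":
        raise ValueError(f"{path}: first column must be subject_id")
    pairs = []
    for name in df.columns[1:]:
        a, _, b = name.partition("_")
        try:
            pairs.append((int(a), int(b)))
        except ValueError:
            raise ValueError(f"{path}: feature header {name!r} is not of the form a_b") from None
    table = FCFeatureTable(
        df["subject_id"].tolist(), pairs, df.iloc[:, 1:].to_numpy(dtype=float), provenance
    )
    if phenotypes is not None:
        table.check_aligned(phenotypes)
    return table
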