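"""Readers and writers for the plain-text formats the pipeline touches.

Beta matrices travel as dense TSV (first column = site id, header row =
sample ids), EpiTYPER exports as long-format CSV, cohort metadata as CSV.
Missing values are written as ``NA``; on input ``""``, ``NA``, ``NaN`` and
``null`` are accepted case-insensitively. Readers validate aggressively and
report 1-based line numbers on malformed input.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError
from .matrix import CohortMetadata, MethylationMatrix

__all__ = [
    "read_beta_tsv",
    "write_beta_tsv",
    "read_epityper_long",
    "write_epityper_long",
    "read_metadata_csv",
    "write_metadata_csv",
]

_MISSING_TOKENS = {"", "na", "nan", "null"}
_PathLike = Union[str, Path]


def _parse_cell(token: str, line_no: int, site: str, sample: str, *, check_range: bool) -> float:
    if token.strip().lower() in _MISSING_TOKENS:
        return np.nan
    try:
        value = float(token)
    except ValueError:
        raise ParseError(
            f"line {line_no}: cannot parse {token!r} (site {site!r}, sample {sample!r})"
        ) from None
    if check_range and not (0.0 <= value <= 1.0):
        raise ValidationError(
            f"line {line_no}: value {value} out of [0,1] at site {site!r}, sample {sample!r}"
        )
    return value


def _read_dense_tsv(path: _PathLike, *, check_range: bool) -> pd.DataFrame:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if len(header) < 2:
            raise ParseError(f"{path}: line 1: header needs a site-id column plus samples")
        samples = header[1:]
        if len(set(samples)) != len(samples):
            raise ParseError(f"{path}: line 1: duplicate sample ids in header")
        sites: list[str] = []
        rows: list[list[float]] = []
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: line {line_no}: ragged row "
                    f"({len(row)} fields, expected {len(header)})"
                )
            site = row[0]
            sites.append(site)
            rows.append(
                [
                    _parse_cell(tok, line_no, site, samples[j], check_range=check_range)
                    for j, tok in enumerate(row[1:])
                ]
            )
        if len(set(sites)) != len(sites):
            seen: set[str] = set()
            dupes = sorted({s for s in sites if s in seen or seen.add(s)})
            raise ParseError(f"{path}: duplicate site ids: {dupes[:5]}")
    return pd.DataFrame(np.asarray(rows, dtype=float), index=sites, columns=samples)


def read_beta_tsv(path: _PathLike, aux_path: _PathLike | None = None) -> MethylationMatrix:
    """Read a dense beta TSV; optionally attach an aux layer from a second TSV.

    The aux file must have identical site and sample labels; aux values
    (detection p or confidence) are not range-restricted to [0,1].
    """
    values = _read_dense_tsv(path, check_range=True)
    aux = None
    if aux_path is not None:
        aux = _read_dense_tsv(aux_path, check_range=False)
        if not aux.index.equals(values.index) or not aux.columns.equals(values.columns):
            raise ValidationError(f"{aux_path}: aux labels do not match {path}")
    return MethylationMatrix(values, aux)


def _format_cell(x: float) -> str:
    return "NA" if np.isnan(x) else repr(float(x))


def _write_dense_tsv(frame: pd.DataFrame, path: _PathLike, id_column: str) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([id_column, *frame.columns])
        arr = frame.to_numpy(dtype=float)
        for site, row in zip(frame.index, arr):
            writer.writerow([site, *(_format_cell(x) for x in row)])


def write_beta_tsv(
    matrix: MethylationMatrix, path: _PathLike, aux_path: _PathLike | None = None
) -> None:
    """Write beta values (and optionally the aux layer) as dense TSV.

    Floats are written with ``repr`` so a read-back is bitwise identical.
    """
    _write_dense_tsv(matrix.values, path, "site_id")
    if aux_path is not None:
        if matrix.aux is None:
            raise ValidationError("matrix has no aux layer to write")
        _write_dense_tsv(matrix.aux, aux_path, "site_id")


_EPITYPER_COLUMNS = ["sample_id", "site_id", "methylation_fraction", "confidence"]


def read_epityper_long(path: _PathLike) -> MethylationMatrix:
    """Read an EpiTYPER-style long CSV and pivot it to a sites x samples matrix.

    Expected columns: sample_id, site_id, methylation_fraction, confidence.
    The confidence scores become the matrix's aux layer. Duplicate
    (sample, site) rows are an error.
    """
    path = Path(path)
    table = pd.read_csv(
        path, dtype={"sample_id": str, "site_id": str}, float_precision="round_trip"
    )
    missing = [c for c in _EPITYPER_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    dup = table.duplicated(subset=["sample_id", "site_id"])
    if dup.any():
        pairs = table.loc[dup, ["sample_id", "site_id"]].itertuples(index=False)
        raise ValidationError(
            f"{path}: duplicate (sample, site) rows: {[tuple(p) for p in pairs][:5]}"
        )
    values = table.pivot(index="site_id", columns="sample_id", values="methylation_fraction")
    conf = table.pivot(index="site_id", columns="sample_id", values="confidence")
    values.index.name = None
    values.columns.name = None
    conf.index.name = None
    conf.columns.name = None
    return MethylationMatrix(values, conf.loc[values.index, values.columns])


def write_epityper_long(matrix: MethylationMatrix, path: _PathLike) -> None:
    """Write a matrix with confidence aux as long-format EpiTYPER CSV.

    Rows where the value is missing are emitted with an NA fraction so the
    confidence score survives a round trip.
    """
    if matrix.aux is None:
        raise ValidationError("EpiTYPER export requires a confidence aux layer")
    long = (
        matrix.values.rename_axis(index="site_id", columns="sample_id")
        .stack(future_stack=True)
        .rename("methylation_fraction")
        .reset_index()
    )
    conf = (
        matrix.aux.rename_axis(index="site_id", columns="sample_id")
        .stack(future_stack=True)
        .rename("confidence")
        .reset_index()
    )
    long["confidence"] = conf["confidence"]
    long[["sample_id", "site_id", "methylation_fraction", "confidence"]].to_csv(
        path, index=False, float_format="%.17g"
    )


def read_metadata_csv(path: _PathLike) -> CohortMetadata:
    """Read cohort metadata (sample_id, age, sex, cohort, pair_id) from CSV."""
    path = Path(path)
    table = pd.read_csv(path, dtype={"sample_id": str, "pair_id": str})
    missing = [c for c in CohortMetadata.REQUIRED if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    ages = pd.to_numeric(table["age"], errors="coerce")
    if ages.isna().any():
        bad = table.loc[ages.isna(), "sample_id"].tolist()
        raise ParseError(f"{path}: unparseable age for samples {bad[:5]}")
    table["age"] = ages
    return CohortMetadata(table)


def write_metadata_csv(meta: CohortMetadata, path: _PathLike) -> None:
    meta.table.to_csv(path, index=False)
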