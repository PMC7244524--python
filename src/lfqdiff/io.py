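"""Readers and writers for the pipeline's tabular and sequence inputs.

All tables travel as tidy (long-format) pandas DataFrames. Readers
validate rather than coerce: malformed rows raise with the offending
1-based file line number, and sample identifiers are checked against the
design. TSV dialects (column names, linear-vs-log intensities, RT units,
protein-accession delimiter) can be declared in a YAML config.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO


class SchemaError(ValueError):
    """A table violates its declared schema (bad column, unknown sample...)."""


class ParseError(ValueError):
    """A cell could not be parsed; the message carries the file line number."""


@dataclass
class TableDialect:
    """How an input TSV maps onto the canonical long layout."""

    columns: dict[str, str] | None = None  # canonical name -> file column
    intensity_scale: str = "log10"  # or "linear"
    rt_unit: str = "seconds"  # or "minutes"
    protein_delimiter: str = ";"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TableDialect":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _rename(df: pd.DataFrame, dialect: TableDialect, required: Iterable[str]) -> pd.DataFrame:
    if dialect.columns:
        df = df.rename(columns={v: k for k, v in dialect.columns.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return df


def _check_numeric(df: pd.DataFrame, col: str, path: str | Path) -> pd.Series:
    converted = pd.to_numeric(df[col], errors="coerce")
    bad = converted.isna() & df[col].notna()
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
        raise ParseError(
            f"{path}: non-numeric value {df.loc[df.index[bad][0], col]!r} "
            f"in column '{col}' at line {line}"
        )
    if converted.isna().any():
        line = int(df.index[converted.isna()][0]) + 2
        raise ParseError(f"{path}: empty value in column '{col}' at line {line}")
    return converted.astype(float)


def _check_samples(df: pd.DataFrame, design: pd.DataFrame | None) -> None:
    if design is None:
        return
    known = set(design["sample_id"])
    unknown = set(df["sample_id"]) - known
    if unknown:
        raise SchemaError(
            f"sample_id(s) not present in the design: {sorted(unknown)[:5]}"
        )


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["strain", "medium", "time", "replicate", "sample_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"design lacks column(s): {', '.join(missing)}")
    if df["sample_id"].duplicated().any():
        raise SchemaError("duplicate sample_id in design")
    return df


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_peptide_table(
    path: str | Path,
    design: pd.DataFrame | None = None,
    dialect: TableDialect | None = None,
) -> pd.DataFrame:
    """Read a long-format peptide-charge intensity table.

    Canonical columns: ``peptide, charge, protein, rt_seconds, sample_id,
    log10_intensity``. Linear-scale intensities are log10-transformed and
    minute-scale retention times converted to seconds when the dialect
    says so.
    """
    dialect = dialect or TableDialect()
    value_col = "log10_intensity" if dialect.intensity_scale == "log10" else "intensity"
    rt_col = "rt_seconds" if dialect.rt_unit == "seconds" else "rt_minutes"
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = _rename(
        df, dialect, ["peptide", "charge", "protein", rt_col, "sample_id", value_col]
    )
    values = _check_numeric(df, value_col, path)
    if dialect.intensity_scale == "linear":
        if (values <= 0).any():
            line = int(df.index[values <= 0][0]) + 2
            raise ParseError(f"{path}: non-positive linear intensity at line {line}")
        values = np.log10(values)
    if not np.isfinite(values).all():
        line = int(df.index[~np.isfinite(values)][0]) + 2
        raise ParseError(f"{path}: non-finite intensity at line {line}")
    rt = _check_numeric(df, rt_col, path)
    if dialect.rt_unit == "minutes":
        rt = rt * 60.0
    if (rt < 0).any():
        line = int(df.index[rt < 0][0]) + 2
        raise ParseError(f"{path}: negative retention time at line {line}")
    out = pd.DataFrame(
        {
            "peptide": df["peptide"],
            "charge": _check_numeric(df, "charge", path).astype(int),
            "protein": df["protein"],
            "rt_seconds": rt,
            "sample_id": df["sample_id"],
            "log10_intensity": values,
        }
    )
    _check_samples(out, design)
    dup = out.duplicated(["peptide", "charge", "sample_id"])
    if dup.any():
        line = int(out.index[dup][0]) + 2
        raise SchemaError(
            f"{path}: duplicate (peptide, charge, sample_id) at line {line}"
        )
    return out


def read_wide_peptide_table(
    path: str | Path,
    design: pd.DataFrame,
    dialect: TableDialect | None = None,
    id_columns: tuple[str, ...] = ("peptide", "charge", "protein", "rt_seconds"),
) -> pd.DataFrame:
    """Convenience reader for wide exports with one intensity column per
    sample (MassChroQ-style); melts to the canonical long layout. Empty
    cells are treated as missing observations and dropped."""
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep="\t", dtype=str)
    if dialect.columns:
        df = df.rename(columns={v: k for k, v in dialect.columns.items()})
    missing = [c for c in id_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    sample_cols = [c for c in df.columns if c not in id_columns]
    unknown = set(sample_cols) - set(design["sample_id"])
    if unknown:
        raise SchemaError(f"intensity column(s) not in the design: {sorted(unknown)[:5]}")
    long = df.melt(
        id_vars=list(id_columns), var_name="sample_id", value_name="value"
    ).dropna(subset=["value"])
    long = long.reset_index(drop=True)
    tmp = long.rename(columns={"value": "log10_intensity"})
    value = _check_numeric(tmp, "log10_intensity", path)
    if dialect.intensity_scale == "linear":
        value = np.log10(value)
    return pd.DataFrame(
        {
            "peptide": long["peptide"],
            "charge": _check_numeric(long, "charge", path).astype(int),
            "protein": long["protein"],
            "rt_seconds": _check_numeric(long, "rt_seconds", path),
            "sample_id": long["sample_id"],
            "log10_intensity": value,
        }
    )


def split_protein_accessions(
    table: pd.DataFrame, delimiter: str = ";"
) -> pd.Series:
    """Protein field as a list of accessions per row (shared-peptide aware)."""
    return table["protein"].str.split(delimiter).map(
        lambda xs: [x.strip() for x in xs if x.strip()]
    )


def read_spectral_counts(
    path: str | Path, design: pd.DataFrame | None = None
) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for c in ("protein", "sample_id", "count"):
        if c not in df.columns:
            raise SchemaError(f"spectral-count table lacks column '{c}'")
    counts = _check_numeric(df, "count", path)
    if ((counts < 0) | (counts != counts.round())).any():
        bad = (counts < 0) | (counts != counts.round())
        line = int(df.index[bad][0]) + 2
        raise ParseError(f"{path}: count must be a non-negative integer at line {line}")
    out = pd.DataFrame(
        {"protein": df["protein"], "sample_id": df["sample_id"], "count": counts.astype(int)}
    )
    _check_samples(out, design)
    if out.duplicated(["protein", "sample_id"]).any():
        raise SchemaError(f"{path}: duplicate (protein, sample_id) rows")
    return out


def read_ct_table(
    path: str | Path,
    ct_range: tuple[float, float] = (5.0, 40.0),
) -> pd.DataFrame:
    """qRT-PCR cycle-threshold table: gene, sample_id, condition, ct,
    efficiency. Ct values outside the plausible range and efficiencies
    outside (1, 2.2] are rejected."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for c in ("gene", "sample_id", "condition", "ct", "efficiency"):
        if c not in df.columns:
            raise SchemaError(f"Ct table lacks column '{c}'")
    ct = _check_numeric(df, "ct", path)
    lo, hi = ct_range
    bad = (ct < lo) | (ct > hi)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ParseError(f"{path}: Ct outside [{lo}, {hi}] at line {line}")
    eff = _check_numeric(df, "efficiency", path)
    bad = (eff <= 1.0) | (eff > 2.2)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ParseError(f"{path}: efficiency outside (1, 2.2] at line {line}")
    return pd.DataFrame(
        {
            "gene": df["gene"],
            "sample_id": df["sample_id"],
            "condition": df["condition"],
            "ct": ct,
            "efficiency": eff,
        }
    )


RESULT_COLUMNS = ["protein", "term", "method", "estimate", "p_raw", "p_adj"]


def write_results(
    fits: pd.DataFrame, path: str | Path, float_format: str = "%.17g"
) -> None:
    """Write per-(protein, term) fit results as TSV; at the default
    precision the table round-trips losslessly through
    :func:`read_results`. Refuses to write an empty collection."""
    if fits is None or len(fits) == 0:
        raise ValueError("refusing to write an empty result collection")
    missing = [c for c in RESULT_COLUMNS if c not in fits.columns]
    if missing:
        raise SchemaError(f"result table lacks column(s): {', '.join(missing)}")
    fits.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"result table lacks column(s): {', '.join(missing)}")
    return df


def read_fasta(path: str | Path) -> list:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records, path: str | Path) -> None:
    SeqIO.write(records, str(path), "fasta")
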