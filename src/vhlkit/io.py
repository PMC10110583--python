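"""Table readers/writers for the purity, copy-number, variant and cell formats.

Canonical dialect: UTF-8 TSV with a header row; comma-separated files are
accepted on read by sniffing the header line.  ``""`` and ``"."`` both read
as missing.  Marker booleans accept ``0/1/true/false/+/-`` (and the Unicode
minus) and are written back as 0/1.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NA_VALUES = ["", "."]

CDS_CHANGE_RE = re.compile(r"^c\.?(\d+)\s*([ACGTacgt])\s*>\s*([ACGTacgt])$")

_TRUE_TOKENS = {"1", "true", "t", "+", "yes"}
_FALSE_TOKENS = {"0", "false", "f", "-", "−", "no"}


class FormatError(ValueError):
    """A table violates its required format (missing column, bad value)."""


def _sniff_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "," if header.count(",") > header.count("\t") else "\t"


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=_sniff_sep(path), na_values=NA_VALUES,
                       keep_default_na=True, dtype=None, encoding="utf-8")


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="")
    return path


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_purity_table(path) -> pd.DataFrame:
    """Per-sample purity/ploidy table (purity_consensus and ploidy required)."""
    df = read_table(path)
    _require_columns(df, ["sample_id", "purity_consensus", "ploidy"], path)
    for col in ("purity_absolute", "purity_estimate_method",
                "purity_consensus", "ploidy"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def read_copy_number_table(path) -> pd.DataFrame:
    """Gene-level copy-number table (sample_id, gene, cnr).

    Non-numeric ratio values are a format error naming the offending line
    (1-based, counting the header as line 1).
    """
    df = read_table(path)
    if "cnr" in df.columns and "cnr_observed" not in df.columns:
        df = df.rename(columns={"cnr": "cnr_observed"})
    _require_columns(df, ["sample_id", "gene", "cnr_observed"], path)
    raw = df["cnr_observed"]
    num = pd.to_numeric(raw, errors="coerce")
    bad = num.isna() & raw.notna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        raise FormatError(f"{path}: non-numeric cnr value(s) at line(s) {lines}")
    df["cnr_observed"] = num
    if len(df) == 0:
        logger.warning("%s: empty table (header only)", path)
    return df


def parse_cds_change(value) -> tuple[float, str | None, str | None]:
    """Parse an HGVS-like coding change such as ``c.506T>C``.

    Returns ``(position, ref, alt)``; unparsable strings give
    ``(nan, None, None)``.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return (np.nan, None, None)
    m = CDS_CHANGE_RE.match(str(value).strip())
    if not m:
        return (np.nan, None, None)
    return (float(m.group(1)), m.group(2).upper(), m.group(3).upper())


def parse_marker_bool(series: pd.Series, column: str = "") -> pd.Series:
    tokens = series.astype("string").str.strip().str.lower()
    out = pd.Series(pd.NA, index=series.index, dtype="boolean")
    out[tokens.isin(_TRUE_TOKENS)] = True
    out[tokens.isin(_FALSE_TOKENS)] = False
    unknown = out.isna() & tokens.notna()
    if unknown.any():
        raise FormatError(
            f"unrecognized boolean token(s) in column {column!r}: "
            f"{sorted(tokens[unknown].unique())[:5]}"
        )
    return out


def read_variant_table(path) -> pd.DataFrame:
    """MAF-like variant table.

    Required: sample_id, gene, vaf (or vaf_observed).  Optional ``cds_change``
    strings like ``c.506T>C`` are parsed into cds_position/ref_base/alt_base
    (unparsable -> missing, warned).  Rows with VAF outside [0, 1] are
    rejected with their line numbers.
    """
    df = read_table(path)
    if "vaf" in df.columns and "vaf_observed" not in df.columns:
        df = df.rename(columns={"vaf": "vaf_observed"})
    _require_columns(df, ["sample_id", "gene", "vaf_observed"], path)
    df["vaf_observed"] = pd.to_numeric(df["vaf_observed"], errors="coerce")
    bad = df["vaf_observed"].isna() | (df["vaf_observed"] < 0) | (df["vaf_observed"] > 1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        logger.warning("%s: rejected %d row(s) with VAF outside [0,1] at line(s) %s",
                       path, int(bad.sum()), lines)
        df = df[~bad].reset_index(drop=True)
    if "cds_change" in df.columns:
        parsed = df["cds_change"].map(parse_cds_change)
        df["cds_position"] = [p[0] for p in parsed]
        df["ref_base"] = [p[1] for p in parsed]
        df["alt_base"] = [p[2] for p in parsed]
        unparsed = df["cds_change"].notna() & df["cds_position"].isna()
        if unparsed.any():
            logger.warning("%s: %d cds_change value(s) not parsable; coding fields "
                           "left missing", path, int(unparsed.sum()))
    if "in_cosmic" in df.columns:
        df["in_cosmic"] = parse_marker_bool(df["in_cosmic"].astype(str)
                                            .where(df["in_cosmic"].notna()),
                                            "in_cosmic")
    if "vep_impact" in df.columns:
        df["vep_impact"] = df["vep_impact"].astype("string").str.upper()
    return df


def read_cells_table(path) -> pd.DataFrame:
    """Cell-coordinate table: x_um, y_um plus one boolean column per marker."""
    df = read_table(path)
    _require_columns(df, ["x_um", "y_um"], path)
    for col in ("x_um", "y_um"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df[["x_um", "y_um"]].isna().any().any():
        raise FormatError(f"{path}: non-numeric coordinates")
    for col in df.columns:
        if col in ("x_um", "y_um"):
            continue
        df[col] = parse_marker_bool(df[col].astype(str).where(df[col].notna()),
                                    col).fillna(False).astype(bool)
    return df


def write_cells_table(df: pd.DataFrame, path) -> Path:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    return write_table(out, path)
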