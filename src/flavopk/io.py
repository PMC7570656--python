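"""Delimited-table ingestion with schema checking, and report rendering."""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .validation import MatrixEffectSummary, PrecisionAccuracyResult, round_half_away

__all__ = ["TableSchema", "read_table", "render_report", "SCHEMAS"]


@dataclass(frozen=True)
class TableSchema:
    """Required columns of an input table and which must be numeric."""

    name: str
    required: tuple
    numeric: tuple
    unique_key: tuple = ()


SCHEMAS = {
    "factors": TableSchema(
        "factors", ("name", "units", "low", "center", "high"),
        ("low", "center", "high"), ("name",),
    ),
    "design": TableSchema("design", ("run_id",), (), ("run_id",)),
    "calibration": TableSchema(
        "calibration", ("analyte", "level_ng_per_ml", "area"),
        ("level_ng_per_ml", "area"),
    ),
    "qc": TableSchema(
        "qc",
        ("analyte", "nominal_ng_per_ml", "day", "replicate", "measured_ng_per_ml"),
        ("nominal_ng_per_ml", "day", "replicate", "measured_ng_per_ml"),
    ),
    "recovery": TableSchema(
        "recovery", ("analyte", "level_ng_per_ml", "set", "replicate", "area"),
        ("level_ng_per_ml", "replicate", "area"),
    ),
    "concentration": TableSchema(
        "concentration",
        ("analyte", "arm", "replicate", "time_h", "conc_ng_per_ml"),
        ("replicate", "time_h", "conc_ng_per_ml"),
    ),
    "dose": TableSchema(
        "dose", ("analyte", "arm", "dose_mg_per_kg", "body_weight_kg"),
        ("dose_mg_per_kg", "body_weight_kg"),
    ),
}


class SchemaError(ValueError):
    """Input table violates its schema; message carries the location."""


def _sniff_delimiter(path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_table(path, schema: str | TableSchema) -> pd.DataFrame:
    """Read a comma- or tab-delimited table and validate it against a schema.

    Raises SchemaError naming the missing column, the offending cell
    (1-based data row), or the duplicated key.
    """
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    df.columns = [c.strip() for c in df.columns]
    for col in schema.required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    for col in schema.numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise SchemaError(
                f"{path}: non-numeric value {df[col].iloc[row - 1]!r} "
                f"in column {col!r}, data row {row}"
            )
        df[col] = coerced
    if schema.unique_key:
        dup = df.duplicated(subset=list(schema.unique_key))
        if dup.any():
            key = df.loc[dup, list(schema.unique_key)].iloc[0].tolist()
            raise SchemaError(f"{path}: duplicate key {key} for {schema.unique_key}")
    return df


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def _round_col(series, ndigits):
    return [round_half_away(v, ndigits) for v in series]


def render_report(results, style: str, rounded: bool = True) -> pd.DataFrame:
    """Shape results into one of the standard report-table layouts.

    style 'calibration' -> per-analyte rows of slope/intercept/r/limits;
    'qc' -> precision & accuracy rows; 'recovery' -> per-level R1/R2/R3
    recovery and matrix-effect rows; 'pk' -> per-arm parameter mean +/- sd.
    ``rounded=False`` emits full precision for machine consumption.
    """
    if style == "qc":
        if not all(isinstance(r, PrecisionAccuracyResult) for r in results):
            raise TypeError("qc style needs PrecisionAccuracyResult items")
        df = pd.DataFrame([{
            "analyte": r.analyte, "nominal_ng_per_ml": r.nominal,
            "intra_measured": r.intra_mean, "intra_rsd_pct": r.intra_rsd,
            "intra_accuracy_pct": r.intra_accuracy,
            "inter_measured": r.inter_mean, "inter_rsd_pct": r.inter_rsd,
            "inter_accuracy_pct": r.inter_accuracy,
        } for r in results])
        if rounded:
            for c in df.columns[2:]:
                df[c] = _round_col(df[c], 2)
        return df
    if style == "recovery":
        if not all(isinstance(r, MatrixEffectSummary) for r in results):
            raise TypeError("recovery style needs MatrixEffectSummary items")
        rows = []
        for summ in results:
            for lv in summ.levels:
                rows.append({
                    "analyte": summ.analyte, "level_ng_per_ml": lv.level,
                    "r1_mean": lv.r1_mean, "r1_rsd_pct": lv.r1_rsd,
                    "r2_mean": lv.r2_mean, "r2_rsd_pct": lv.r2_rsd,
                    "r3_mean": lv.r3_mean, "r3_rsd_pct": lv.r3_rsd,
                    "recovery_pct": lv.recovery_pct,
                    "matrix_effect_pct": lv.matrix_effect_pct,
                    "classification": lv.classification,
                })
        df = pd.DataFrame(rows)
        if rounded:
            for c in ("r1_rsd_pct", "r2_rsd_pct", "r3_rsd_pct",
                      "recovery_pct", "matrix_effect_pct"):
                df[c] = _round_col(df[c], 0)
        return df
    if style == "calibration":
        df = pd.DataFrame([{
            "analyte": r.analyte, "slope": r.slope, "intercept": r.intercept,
            "slope_ci_halfwidth": r.slope_ci_halfwidth,
            "intercept_ci_halfwidth": r.intercept_ci_halfwidth,
            "r": r.r, "s_yx": r.s_yx, "lack_of_fit_p": r.lack_of_fit_p,
        } for r in results])
        if rounded:
            df["r"] = _round_col(df["r"], 4)
            for c in ("slope", "intercept", "slope_ci_halfwidth",
                      "intercept_ci_halfwidth", "s_yx"):
                df[c] = _round_col(df[c], 2)
        return df
    if style == "pk":
        df = results.copy() if isinstance(results, pd.DataFrame) else pd.DataFrame(results)
        if rounded:
            df["mean"] = _round_col(df["mean"], 2)
            df["sd"] = [round_half_away(v, 2) if np.isfinite(v) else v
                        for v in df["sd"]]
        return df
    raise ValueError(f"unknown report style {style!r}")
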