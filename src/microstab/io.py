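"""Delimited-text readers and writers for sample tables.

The canonical dialect is comma-separated UTF-8 with a period decimal
separator and a mandatory header row. Numeric fields are written with
``repr`` precision so a write/read round-trip is bit-for-bit.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
import pydantic

from .datatypes import AnalyteMeasurement
from .errors import MeasurementValidationError, SchemaError

__all__ = [
    "MEASUREMENT_COLUMNS",
    "read_measurement_table",
    "write_measurement_table",
    "measurements_to_frame",
    "read_timecourse_table",
    "write_timecourse_table",
]

MEASUREMENT_COLUMNS = (
    "sample_id",
    "role",
    "nominal_conc",
    "analyte_area",
    "is_area",
    "replicate_id",
    "batch_id",
    "time_min",
)
_REQUIRED = ("sample_id", "role", "analyte_area")

TIMECOURSE_COLUMNS = ("time_min", "replicate_id", "conc_ng_ml")


def _opt(value):
    return None if pd.isna(value) else value


def read_measurement_table(
    path: Union[str, Path], delimiter: str = ","
) -> list[AnalyteMeasurement]:
    """Read a sample table into validated measurement records.

    Row order is preserved. A missing required column raises
    :class:`SchemaError` naming the column; an invalid row raises
    :class:`MeasurementValidationError` naming the 0-based row index.
    """
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    for col in _REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    records = []
    for idx, row in df.iterrows():
        fields = {
            "sample_id": str(row["sample_id"]),
            "role": row["role"],
            "analyte_area": row["analyte_area"],
        }
        for col in ("nominal_conc", "is_area", "time_min"):
            if col in df.columns:
                fields[col] = _opt(row[col])
        for col in ("replicate_id", "batch_id"):
            if col in df.columns and not pd.isna(row[col]):
                fields[col] = int(row[col])
        try:
            records.append(AnalyteMeasurement(**fields))
        except pydantic.ValidationError as exc:
            raise MeasurementValidationError(f"{path}: row {idx}: {exc}") from exc
    return records


def measurements_to_frame(measurements: Iterable[AnalyteMeasurement]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": m.sample_id,
            "role": m.role.value,
            "nominal_conc": m.nominal_conc,
            "analyte_area": m.analyte_area,
            "is_area": m.is_area,
            "replicate_id": m.replicate_id,
            "batch_id": m.batch_id,
            "time_min": m.time_min,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def write_measurement_table(
    measurements: Sequence[AnalyteMeasurement],
    path: Union[str, Path],
    delimiter: str = ",",
) -> None:
    """Write measurements as CSV; numeric values keep full repr precision."""
    measurements_to_frame(measurements).to_csv(
        path, sep=delimiter, index=False, float_format=lambda v: repr(float(v))
    )


def read_timecourse_table(path: Union[str, Path], delimiter: str = ",") -> pd.DataFrame:
    """Read a depletion time course (time_min, replicate_id, conc_ng_ml).

    ``replicate_id`` is optional (defaults to 1, e.g. for tables of
    pre-averaged concentrations).
    """
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    for col in ("time_min", "conc_ng_ml"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if "replicate_id" not in df.columns:
        df["replicate_id"] = 1
    if (df["conc_ng_ml"] < 0).any():
        bad = int(df.index[df["conc_ng_ml"] < 0][0])
        raise MeasurementValidationError(f"{path}: row {bad}: negative concentration")
    return df[list(TIMECOURSE_COLUMNS)]


def write_timecourse_table(
    df: pd.DataFrame, path: Union[str, Path], delimiter: str = ","
) -> None:
    df.to_csv(
        path, sep=delimiter, index=False, columns=list(TIMECOURSE_COLUMNS),
        float_format=lambda v: repr(float(v)),
    )
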