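"""CSV schemas and validated readers/writers for the analysis inputs.

Three flat files tie the pipeline together, all UTF-8 with a header row
and '.' decimal:

* ``cycles.csv`` — animal_id, treatment, period_type, start_day, end_day,
  censored (per-animal ovarian-cycle periods tiling the window)
* ``durations.csv`` — animal_id, treatment, duration_days (completed,
  pooled pre-ovulatory durations)
* ``gestation.csv`` — species, mean_days, sd_days, group (cross-species
  gestation table for the allometry)

Validation failures raise :class:`SchemaError` naming the file, row
(1-based, counting the header as row 1) and column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimation import PreOvulatoryDataset
from .simulate import CYCLE_COLUMNS

__all__ = [
    "SchemaError",
    "read_cycles",
    "write_cycles",
    "read_durations",
    "write_durations",
    "read_gestation",
    "write_gestation",
    "durations_frame",
    "durations_to_datasets",
    "durations_to_animal_lists",
]

DURATION_COLUMNS = ("animal_id", "treatment", "duration_days")
GESTATION_COLUMNS = ("species", "mean_days", "sd_days", "group")


class SchemaError(ValueError):
    """Input file violates the expected schema."""

    def __init__(self, path, row: int | None, column: str | None, message: str):
        self.path, self.row, self.column = str(path), row, column
        loc = str(path)
        if row is not None:
            loc += f", row {row}"
        if column is not None:
            loc += f", column '{column}'"
        super().__init__(f"{loc}: {message}")


def _require_columns(df: pd.DataFrame, path, columns) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(path, None, missing[0], "missing required column")


def _first_bad_row(mask: np.ndarray) -> int:
    # +2: header is row 1, data starts at row 2
    return int(np.flatnonzero(mask)[0]) + 2


def read_cycles(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, path, CYCLE_COLUMNS)
    for col in ("start_day", "end_day"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna().to_numpy()
        if bad.any():
            raise SchemaError(path, _first_bad_row(bad), col, "not a number")
        df[col] = vals
    bad = (df["end_day"] <= df["start_day"]).to_numpy()
    if bad.any():
        raise SchemaError(path, _first_bad_row(bad), "end_day", "end_day must exceed start_day")
    bad = ~df["period_type"].isin(["pre_ovulatory", "post_ovulatory"]).to_numpy()
    if bad.any():
        raise SchemaError(path, _first_bad_row(bad), "period_type", "unknown period type")
    df["censored"] = df["censored"].astype(bool)
    return df


def write_cycles(records: pd.DataFrame, path) -> None:
    records.loc[:, list(CYCLE_COLUMNS)].to_csv(path, index=False)


def durations_frame(records: pd.DataFrame) -> pd.DataFrame:
    """Completed pre-ovulatory durations of a cycles frame, long format."""
    pre = records[(records["period_type"] == "pre_ovulatory") & (~records["censored"])]
    return pd.DataFrame(
        {
            "animal_id": pre["animal_id"].to_numpy(),
            "treatment": pre["treatment"].to_numpy(),
            "duration_days": (pre["end_day"] - pre["start_day"]).to_numpy(dtype=float),
        }
    )


def read_durations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, path, DURATION_COLUMNS)
    vals = pd.to_numeric(df["duration_days"], errors="coerce")
    bad = vals.isna().to_numpy()
    if bad.any():
        raise SchemaError(path, _first_bad_row(bad), "duration_days", "not a number")
    bad = (vals <= 0).to_numpy()
    if bad.any():
        raise SchemaError(
            path, _first_bad_row(bad), "duration_days", "duration must be positive"
        )
    df["duration_days"] = vals
    return df


def write_durations(durations: pd.DataFrame, path) -> None:
    durations.loc[:, list(DURATION_COLUMNS)].to_csv(path, index=False)


def durations_to_datasets(durations: pd.DataFrame) -> dict[str, PreOvulatoryDataset]:
    """Pool a durations frame into one dataset per treatment."""
    return {
        str(t): PreOvulatoryDataset(str(t), g["duration_days"].to_numpy(dtype=float))
        for t, g in durations.groupby("treatment", sort=False)
    }


def durations_to_animal_lists(durations: pd.DataFrame) -> dict[str, list[np.ndarray]]:
    """Per-animal duration arrays within each treatment (permutation input)."""
    out: dict[str, list[np.ndarray]] = {}
    for t, g in durations.groupby("treatment", sort=False):
        out[str(t)] = [
            a["duration_days"].to_numpy(dtype=float)
            for _, a in g.groupby("animal_id", sort=False)
        ]
    return out


def read_gestation(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, path, GESTATION_COLUMNS)
    for col in ("mean_days", "sd_days"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna().to_numpy()
        if bad.any():
            raise SchemaError(path, _first_bad_row(bad), col, "not a number")
        bad = (vals <= 0).to_numpy()
        if bad.any():
            raise SchemaError(path, _first_bad_row(bad), col, "must be positive")
        df[col] = vals
    return df


def write_gestation(table: pd.DataFrame, path) -> None:
    table.loc[:, list(GESTATION_COLUMNS)].to_csv(path, index=False)
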