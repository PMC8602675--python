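"""Panel CSV readers/writers with record-level validation.

The on-disk format is the tidy layout of :func:`airburden.synthetic.generate_panel`:
comma-separated, UTF-8, "." decimal, header required, one row per
(country, year, cause, pollutant). Numbers are written at full precision;
display rounding is confined to human-readable summaries.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RowError, SchemaError

__all__ = ["REQUIRED_COLUMNS", "read_panel", "write_panel", "validate_panel"]

REQUIRED_COLUMNS = (
    "country", "year", "cause", "pollutant",
    "apm25", "ozone", "hap", "population", "sdi", "gni",
    "deaths_total", "yll_total", "daly_total",
    "death_rate", "yll_rate", "daly_rate",
)

_EXPOSURE_COLS = ("apm25", "ozone", "hap")
_RATE_COLS = ("death_rate", "yll_rate", "daly_rate")
_TOTAL_COLS = ("deaths_total", "yll_total", "daly_total")
# slack for totals that were rounded on write: cause/pollutant cells may
# exceed their parent by at most this relative amount
_REL_TOL = 1e-9


def validate_panel(panel: pd.DataFrame) -> list[str]:
    """Record-invariant violations, one message per offending row.

    Checks positivity of exposures and population, non-negativity of rates,
    SDI in [0, 1], and the aggregation constraints (cause-specific totals
    never exceed the all-cause total within a pollutant tag; pollutant-
    specific totals never exceed the "all" tag within a cause). Row numbers
    are 1-based file lines (header = line 1).
    """
    errs: list[str] = []

    def flag(mask: pd.Series, message: str):
        for idx in panel.index[mask.to_numpy(dtype=bool)]:
            errs.append(f"line {idx + 2}: {message}")

    for col in _EXPOSURE_COLS + ("population",):
        flag(~(panel[col] > 0), f"{col} must be positive")
    for col in _RATE_COLS + _TOTAL_COLS:
        flag(panel[col] < 0, f"{col} must be non-negative")
    flag((panel["sdi"] < 0) | (panel["sdi"] > 1), "sdi must lie in [0, 1]")
    flag(panel["gni"].notna() & (panel["gni"] <= 0), "gni must be positive when present")

    # aggregation constraints
    key = ["country", "year"]
    for col in _TOTAL_COLS + _RATE_COLS:
        parent = panel[panel["cause"] == "all_cause"].set_index(key + ["pollutant"])[col]
        idx = pd.MultiIndex.from_frame(panel[key + ["pollutant"]])
        cap = parent.reindex(idx).to_numpy()
        bad = panel[col].to_numpy() > cap * (1 + _REL_TOL)
        flag(pd.Series(bad, index=panel.index) & (panel["cause"] != "all_cause"),
             f"cause-specific {col} exceeds all-cause total")
        parent = panel[panel["pollutant"] == "all"].set_index(key + ["cause"])[col]
        idx = pd.MultiIndex.from_frame(panel[key + ["cause"]])
        cap = parent.reindex(idx).to_numpy()
        bad = panel[col].to_numpy() > cap * (1 + _REL_TOL)
        flag(pd.Series(bad, index=panel.index) & (panel["pollutant"] != "all"),
             f"pollutant-specific {col} exceeds 'all' pollutant total")
    return sorted(set(errs))


def read_panel(path: str | Path, skip_invalid: bool = False) -> pd.DataFrame:
    """Read and validate a tidy panel CSV.

    Raises SchemaError when required columns are missing and RowError when
    any row violates the record invariants, unless ``skip_invalid`` is set,
    in which case offending rows are dropped.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df[list(REQUIRED_COLUMNS)].copy()
    df["year"] = df["year"].astype(int)
    errs = validate_panel(df)
    if errs:
        if not skip_invalid:
            raise RowError(errs)
        bad_lines = {int(e.split(":")[0].split()[1]) for e in errs}
        df = df.drop(index=[ln - 2 for ln in bad_lines]).reset_index(drop=True)
    return df


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy panel CSV (UTF-8, '.' decimal, full precision)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in panel.columns]
    if missing:
        raise SchemaError(f"panel is missing required columns: {missing}")
    panel[list(REQUIRED_COLUMNS)].to_csv(path, index=False, encoding="utf-8")
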