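"""Delimited-table I/O for the longitudinal patient tables.

Column dictionary (all dates ISO-8601, one row per record):

``fills.csv``
    patient_id, drug_code, drug_class, fill_date, days_supply
``stays.csv``
    patient_id, admit_date, discharge_date
``labs.csv``
    patient_id, analyte, lab_date, value
``viral_loads.csv``
    patient_id, vl_date, copies_per_ml
``conditions.csv``
    patient_id, code, kind (diagnosis|procedure|imaging), record_date
``deaths.csv``
    patient_id, death_date

Readers return the same frames with integer day-offset columns (suffix
``_day``) added, on the package's fixed epoch.
"""

from __future__ import annotations

import os

import pandas as pd

from .config import to_day, to_date

TABLES = {
    "fills": ["patient_id", "drug_code", "drug_class", "fill_date", "days_supply"],
    "stays": ["patient_id", "admit_date", "discharge_date"],
    "labs": ["patient_id", "analyte", "lab_date", "value"],
    "viral_loads": ["patient_id", "vl_date", "copies_per_ml"],
    "conditions": ["patient_id", "code", "kind", "record_date"],
    "deaths": ["patient_id", "death_date"],
}

_DATE_COLS = {
    "fills": ["fill_date"],
    "stays": ["admit_date", "discharge_date"],
    "labs": ["lab_date"],
    "viral_loads": ["vl_date"],
    "conditions": ["record_date"],
    "deaths": ["death_date"],
}


def write_tables(tables: dict, directory: str) -> dict:
    """Write the cohort tables as CSV; returns {name: path}."""
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for name, cols in TABLES.items():
        df = tables.get(name)
        if df is None:
            df = pd.DataFrame(columns=cols)
        out = df.copy()
        for col in _DATE_COLS[name]:
            if col not in out.columns and col.replace("_date", "_day") in out.columns:
                out[col] = to_date(out[col.replace("_date", "_day")])
        path = os.path.join(directory, f"{name}.csv")
        out.to_csv(path, index=False, columns=cols)
        paths[name] = path
    return paths


def _add_day_cols(name: str, df: pd.DataFrame) -> pd.DataFrame:
    for col in _DATE_COLS[name]:
        day_col = col.replace("_date", "_day")
        if len(df):
            df[day_col] = to_day(pd.to_datetime(df[col]).to_numpy())
        else:
            df[day_col] = pd.Series([], dtype="int64")
    return df


def read_tables(directory: str) -> dict:
    """Read the cohort tables back; adds integer ``*_day`` columns."""
    tables = {}
    for name, cols in TABLES.items():
        path = os.path.join(directory, f"{name}.csv")
        df = pd.read_csv(path)
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"{name}.csv is missing columns {sorted(missing)}")
        tables[name] = _add_day_cols(name, df)
    return tables


def day_tables(tables: dict) -> dict:
    """Ensure in-memory tables carry the ``*_day`` integer columns."""
    out = {}
    for name in TABLES:
        df = tables.get(name, pd.DataFrame(columns=TABLES[name])).copy()
        need = [c.replace("_date", "_day") for c in _DATE_COLS[name]]
        if all(c in df.columns for c in need):
            out[name] = df
        else:
            out[name] = _add_day_cols(name, df)
    return out
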