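"""CSV round-tripping for populations, samples, benchmarks and weights.

One dialect throughout: UTF-8, comma-separated, header row, '.'
decimal, empty field for missing.  Boolean flags are stored as 0/1.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .config import AGE_BANDS, AREAS, SEXES, TELEPHONE_STATUSES

_BOOL_COLS = ("listed_landline", "listed_mobile")
_CATEGORIES = {
    "age_group": list(AGE_BANDS),
    "sex": list(SEXES),
    "area": list(AREAS),
    "telephone_status": list(TELEPHONE_STATUSES),
}


def write_records_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in _BOOL_COLS:
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def read_records_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in _BOOL_COLS:
        if col in df.columns:
            df[col] = df[col].astype(bool)
    for col, cats in _CATEGORIES.items():
        if col in df.columns:
            df[col] = pd.Categorical(df[col], categories=cats)
    return df


def write_benchmark_csv(benchmark: pd.DataFrame, path: str | Path) -> None:
    benchmark.to_csv(path, index=False)


def read_benchmark_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "count" not in df.columns:
        raise ValueError(f"{path} is not a benchmark table (no 'count')")
    return df
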