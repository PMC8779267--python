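"""CSV dialect for the three event tables (UTF-8, '.' decimal, day indices)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import CLUTCH_COLUMNS, CONTAINER_COLUMNS, SUBJECT_COLUMNS

__all__ = ["write_tables", "read_subjects", "read_containers", "read_clutches"]

_DTYPES = {
    "time_days": float,
    "event": int,
    "total_eggs": int,
    "n_clutches": int,
    "female_days": float,
    "n_eggs": int,
    "n_success": int,
}


def write_tables(tables: dict[str, pd.DataFrame], outdir: str | Path) -> dict[str, Path]:
    """Write subjects/containers/clutches CSVs; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def _read(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    for col, dtype in _DTYPES.items():
        if col in df.columns:
            df[col] = df[col].astype(dtype)
    return df[columns]


def read_subjects(path: str | Path) -> pd.DataFrame:
    return _read(path, SUBJECT_COLUMNS)


def read_containers(path: str | Path) -> pd.DataFrame:
    return _read(path, CONTAINER_COLUMNS)


def read_clutches(path: str | Path) -> pd.DataFrame:
    return _read(path, CLUTCH_COLUMNS)
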