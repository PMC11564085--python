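"""CSV dialects and deterministic table writing.

All pipeline artifacts are plain CSV with a fixed float format so that a
rerun with identical config and inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

__all__ = [
    "write_table",
    "read_table",
    "file_sha256",
    "MORTALITY_COLS",
    "POPULATION_COLS",
    "INCOME_COLS",
]

FLOAT_FORMAT = "%.10g"

MORTALITY_COLS = ["country", "iso3", "sex", "age_group", "cause", "year", "rate"]
POPULATION_COLS = ["country", "iso3", "sex", "age_group", "year", "pop"]
INCOME_COLS = ["iso3", "year", "gni_pc"]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    return path


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if required is not None:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
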