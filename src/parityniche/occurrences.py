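"""Georeferenced occurrence records of the six lizard clades.

Clades A and B are oviparous (egg-laying); clades C-F are viviparous.
Occurrences are exchanged as a CSV with header ``lon,lat,clade,parity``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "OccurrenceRecord",
    "CLADES",
    "PARITY_OF_CLADE",
    "read_occurrences",
    "write_occurrences",
    "validate_occurrences",
]

CLADES = ("A", "B", "C", "D", "E", "F")

PARITY_OF_CLADE = {
    "A": "oviparous",
    "B": "oviparous",
    "C": "viviparous",
    "D": "viviparous",
    "E": "viviparous",
    "F": "viviparous",
}


@dataclass(frozen=True)
class OccurrenceRecord:
    lon: float
    lat: float
    clade: str
    parity: str

    def __post_init__(self) -> None:
        if self.clade not in PARITY_OF_CLADE:
            raise ValueError(f"unknown clade {self.clade!r}")
        if self.parity != PARITY_OF_CLADE[self.clade]:
            raise ValueError(
                f"clade {self.clade} is {PARITY_OF_CLADE[self.clade]}, "
                f"got parity {self.parity!r}"
            )


def validate_occurrences(df: pd.DataFrame) -> pd.DataFrame:
    """Check columns, clade labels and the clade->parity mapping."""
    required = {"lon", "lat", "clade", "parity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"occurrence table lacks columns {sorted(missing)}")
    bad_clade = ~df["clade"].isin(CLADES)
    if bad_clade.any():
        raise ValueError(f"unknown clade labels: {sorted(df.loc[bad_clade, 'clade'].unique())}")
    expected = df["clade"].map(PARITY_OF_CLADE)
    mismatch = df["parity"] != expected
    if mismatch.any():
        i = int(mismatch.idxmax())
        raise ValueError(
            f"row {i}: clade {df.loc[i, 'clade']} must be {expected.loc[i]}, "
            f"got {df.loc[i, 'parity']!r}"
        )
    return df


def read_occurrences(path: str | Path) -> pd.DataFrame:
    return validate_occurrences(pd.read_csv(path))


def write_occurrences(df: pd.DataFrame, path: str | Path) -> None:
    validate_occurrences(df)
    df.to_csv(path, index=False, columns=["lon", "lat", "clade", "parity"])
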