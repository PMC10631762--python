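"""Position-sensitive biophysical property profiles.

A property table assigns one scalar (charge, hydropathy, ...) to each of the
20 canonical amino acids; profiles report, per alignment column, the mean and
standard deviation of that property over sequences. Tables are z-normalized
to mean 0 / std 1 over the 20 values so that different scales are comparable
position by position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, PAD_CODE, UNKNOWN_CODE
from .encoding import AimsMatrix

__all__ = [
    "PropertyTable",
    "PropertyProfile",
    "normalize_table",
    "position_property_profile",
    "charge_table",
    "hydropathy_table",
]

# Sidechain formal charge at physiological pH. Histidine carries +0.1 for
# partial protonation (pKa ~ 6); this is a convention knob, not a measurement.
_CHARGE = {
    "K": 1.0, "R": 1.0, "H": 0.1,
    "D": -1.0, "E": -1.0,
}

# Kyte-Doolittle hydropathy index.
_KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}


@dataclass
class PropertyTable:
    """A scalar property per canonical amino acid, in alphabet order."""

    name: str
    values: np.ndarray  # length 20, order AMINO_ACIDS
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20,):
            raise ValueError("property table must have exactly 20 values")

    @classmethod
    def from_dict(cls, name: str, mapping: dict[str, float], default: float = 0.0
                  ) -> "PropertyTable":
        vals = np.array([mapping.get(aa, default) for aa in AMINO_ACIDS])
        return cls(name=name, values=vals)

    def value_of(self, aa: str) -> float:
        return float(self.values[AMINO_ACIDS.index(aa)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"aa": list(AMINO_ACIDS), "value": self.values})

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "PropertyTable":
        df = pd.read_csv(path)
        mapping = dict(zip(df["aa"], df["value"]))
        missing = set(AMINO_ACIDS) - set(mapping)
        if missing:
            raise ValueError(f"property CSV missing amino acids: {sorted(missing)}")
        return cls.from_dict(name or str(path), mapping)


def normalize_table(raw: PropertyTable) -> PropertyTable:
    """Z-score a table over its 20 values (mean 0, std 1; population std).

    Idempotent on already-normalized tables; raises on a constant table,
    whose z-score is undefined.
    """
    sd = raw.values.std()
    if sd == 0:
        raise ValueError(f"property table {raw.name!r} is constant; cannot z-score")
    return PropertyTable(
        name=raw.name,
        values=(raw.values - raw.values.mean()) / sd,
        normalization="zscore",
    )


def charge_table(normalized: bool = True) -> PropertyTable:
    t = PropertyTable.from_dict("charge", _CHARGE)
    return normalize_table(t) if normalized else t


def hydropathy_table(normalized: bool = True) -> PropertyTable:
    t = PropertyTable.from_dict("hydropathy", _KYTE_DOOLITTLE)
    return normalize_table(t) if normalized else t


@dataclass
class PropertyProfile:
    """Per-column mean/std of a property over sequences (pads excluded)."""

    columns: list[str]
    mean: np.ndarray  # NaN where a column holds no scoreable residue
    std: np.ndarray
    property_name: str
    n_sequences: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": self.columns,
                "region": [c.split(":")[0] for c in self.columns],
                "mean": self.mean,
                "std": self.std,
            }
        )


def position_property_profile(
    matrix: AimsMatrix, table: PropertyTable
) -> PropertyProfile:
    """Mean/std of a property at every alignment column.

    Pad cells (code 0) and unknown residues (code 21) never enter the
    statistics; a column containing nothing else is reported as missing
    (NaN), not zero.
    """
    n_cols = matrix.n_columns
    mean = np.full(n_cols, np.nan)
    std = np.full(n_cols, np.nan)
    for j in range(n_cols):
        col = matrix.codes[:, j]
        valid = col[(col != PAD_CODE) & (col != UNKNOWN_CODE)]
        if valid.size == 0:
            continue
        vals = table.values[valid - 1]
        mean[j] = vals.mean()
        std[j] = vals.std()
    return PropertyProfile(
        columns=matrix.column_labels(),
        mean=mean,
        std=std,
        property_name=table.name,
        n_sequences=matrix.n_rows,
    )
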