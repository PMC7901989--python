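"""Culture time-series data model and I/O.

A :class:`CultureSeries` holds one replicate bottle's timestamped
measurements: planktonic cell density, ethanol, acetate, and ferrozine-assayed
Fe(II) (total, and optionally the soluble fraction of a centrifuged sample),
together with the experiment metadata (species, growth condition, Fe(III)
mineral amendment, initial Fe(III) loading and culture volume).

Units are fixed by convention: time in days, concentrations in mM,
cell densities in cells/mL, volumes in mL.  ``concentration_to_amount``
converts mM in a known volume to µmol (mM x mL = µmol).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CultureSeries",
    "SchemaError",
    "ParseError",
    "read_culture_table",
    "write_culture_table",
    "concentration_to_amount",
    "TOLERANCE_MM",
]

CONDITIONS = ("organotrophic", "lithotrophic", "dialysis", "mineral-variant")
MINERALS = ("HFO", "goethite", "hematite", "Fe-NTA", "none")

#: Absolute tolerance (mM) for concentration consistency checks; set below the
#: replicate standard deviations typical of the ferrozine assay.
TOLERANCE_MM = 0.05

#: Canonical column order of the tabular interchange format.
COLUMNS = [
    "species",
    "condition",
    "mineral",
    "replicate",
    "time_days",
    "cells_per_ml",
    "ethanol_mM",
    "acetate_mM",
    "fe2_total_mM",
    "fe2_soluble_mM",
    "fe3_initial_mM",
    "volume_mL",
]

_REQUIRED = ("time_days", "acetate_mM", "fe2_total_mM")
_NUMERIC = (
    "time_days",
    "cells_per_ml",
    "ethanol_mM",
    "acetate_mM",
    "fe2_total_mM",
    "fe2_soluble_mM",
    "fe3_initial_mM",
    "volume_mL",
)


class SchemaError(ValueError):
    """A required column is missing or metadata is inconsistent."""


class ParseError(ValueError):
    """A cell could not be interpreted as a number."""


def _optional_array(values) -> np.ndarray | None:
    if values is None:
        return None
    arr = np.asarray(values, dtype=float)
    if arr.size and np.all(np.isnan(arr)):
        return None
    return arr


@dataclasses.dataclass
class CultureSeries:
    """One replicate's time course with its experiment metadata.

    Optional measurements that were not taken are ``None`` (whole vector) or
    NaN (single timepoints) — never zero.
    """

    species: str
    condition: str
    mineral: str
    replicate_id: str
    time_days: np.ndarray
    acetate_mM: np.ndarray
    fe2_total_mM: np.ndarray
    cell_density: np.ndarray | None = None
    ethanol_mM: np.ndarray | None = None
    fe2_soluble_mM: np.ndarray | None = None
    fe3_initial_mM: float = 9.0
    culture_volume_mL: float = 20.0

    def __post_init__(self) -> None:
        self.time_days = np.asarray(self.time_days, dtype=float)
        self.acetate_mM = np.asarray(self.acetate_mM, dtype=float)
        self.fe2_total_mM = np.asarray(self.fe2_total_mM, dtype=float)
        self.cell_density = _optional_array(self.cell_density)
        self.ethanol_mM = _optional_array(self.ethanol_mM)
        self.fe2_soluble_mM = _optional_array(self.fe2_soluble_mM)
        self._validate()

    def _validate(self) -> None:
        if self.condition not in CONDITIONS:
            raise SchemaError(f"unknown condition {self.condition!r}")
        if self.mineral not in MINERALS:
            raise SchemaError(f"unknown mineral {self.mineral!r}")
        n = self.time_days.size
        if n == 0:
            raise SchemaError("series has no timepoints")
        if np.any(self.time_days < 0):
            raise SchemaError("time_days must be non-negative")
        if np.any(np.diff(self.time_days) <= 0):
            raise SchemaError("time_days must be strictly increasing")
        for name in ("acetate_mM", "fe2_total_mM", "cell_density", "ethanol_mM", "fe2_soluble_mM"):
            vec = getattr(self, name)
            if vec is not None and vec.size != n:
                raise SchemaError(f"{name} has length {vec.size}, expected {n}")
        if not (self.fe3_initial_mM >= 0):
            raise SchemaError("fe3_initial_mM must be >= 0")
        if not (self.culture_volume_mL > 0):
            raise SchemaError("culture_volume_mL must be > 0")
        if self.fe2_soluble_mM is not None:
            excess = self.fe2_soluble_mM - self.fe2_total_mM
            if np.nanmax(excess, initial=-math.inf) > TOLERANCE_MM:
                raise SchemaError("soluble Fe(II) exceeds total Fe(II) beyond tolerance")
        if np.nanmax(self.fe2_total_mM, initial=-math.inf) > self.fe3_initial_mM + TOLERANCE_MM:
            raise SchemaError("Fe(II) exceeds the initial Fe(III) loading beyond tolerance")

    @property
    def group_key(self) -> tuple[str, str, str, str]:
        return (self.species, self.condition, self.mineral, self.replicate_id)

    @property
    def n_timepoints(self) -> int:
        return int(self.time_days.size)

    def to_frame(self) -> pd.DataFrame:
        n = self.n_timepoints
        nan = np.full(n, np.nan)
        return pd.DataFrame(
            {
                "species": self.species,
                "condition": self.condition,
                "mineral": self.mineral,
                "replicate": self.replicate_id,
                "time_days": self.time_days,
                "cells_per_ml": self.cell_density if self.cell_density is not None else nan,
                "ethanol_mM": self.ethanol_mM if self.ethanol_mM is not None else nan,
                "acetate_mM": self.acetate_mM,
                "fe2_total_mM": self.fe2_total_mM,
                "fe2_soluble_mM": self.fe2_soluble_mM if self.fe2_soluble_mM is not None else nan,
                "fe3_initial_mM": self.fe3_initial_mM,
                "volume_mL": self.culture_volume_mL,
            }
        )


def read_culture_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[CultureSeries]:
    """Read a culture CSV/TSV into one :class:`CultureSeries` per replicate.

    Parameters
    ----------
    path:
        CSV or TSV file (UTF-8, '#' comment lines, decimal point).
    schema:
        Optional mapping from file column names to the canonical names in
        :data:`COLUMNS`, for tables exported with different headers.

    Rows are grouped by (species, condition, mineral, replicate) and sorted by
    time within each group.  Missing metadata columns receive the cultivation
    defaults (9 mM Fe(III), 20 mL volume — 120 mL for the dialysis setup).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, comment="#", dtype=str, sep=sep, skip_blank_lines=True)
    # numeric conversion below uses pd.to_numeric, which round-trips repr output
    if schema:
        df = df.rename(columns=dict(schema))
    df.columns = [c.strip() for c in df.columns]

    for col in _REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path.name}")

    # metadata defaults for minimal tables
    for col, default in (
        ("species", "unknown"),
        ("condition", "organotrophic"),
        ("mineral", "HFO"),
        ("replicate", "1"),
    ):
        if col not in df.columns:
            df[col] = default
        else:
            df[col] = df[col].fillna(default).str.strip()

    for col in _NUMERIC:
        if col not in df.columns:
            df[col] = np.nan
            continue
        raw = df[col]
        values = np.empty(len(raw), dtype=float)
        for row, cell in enumerate(raw):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                values[row] = np.nan
                continue
            try:
                # exact float() parse: repr output round-trips bit-for-bit
                values[row] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric value {cell!r} in column {col!r}, row {row}"
                ) from None
        df[col] = values

    series: list[CultureSeries] = []
    for (species, condition, mineral, replicate), grp in df.groupby(
        ["species", "condition", "mineral", "replicate"], sort=True
    ):
        if grp["time_days"].duplicated().any():
            t = grp.loc[grp["time_days"].duplicated(), "time_days"].iloc[0]
            raise SchemaError(
                f"duplicate timepoint t={t} for replicate {replicate!r} of {species!r}"
            )
        grp = grp.sort_values("time_days")
        fe3 = grp["fe3_initial_mM"].dropna()
        vol = grp["volume_mL"].dropna()
        default_vol = 120.0 if condition == "dialysis" else 20.0
        series.append(
            CultureSeries(
                species=species,
                condition=condition,
                mineral=mineral,
                replicate_id=str(replicate),
                time_days=grp["time_days"].to_numpy(),
                acetate_mM=grp["acetate_mM"].to_numpy(),
                fe2_total_mM=grp["fe2_total_mM"].to_numpy(),
                cell_density=grp["cells_per_ml"].to_numpy(),
                ethanol_mM=grp["ethanol_mM"].to_numpy(),
                fe2_soluble_mM=grp["fe2_soluble_mM"].to_numpy(),
                fe3_initial_mM=float(fe3.iloc[0]) if len(fe3) else 9.0,
                culture_volume_mL=float(vol.iloc[0]) if len(vol) else default_vol,
            )
        )
    return series


def write_culture_table(series: Sequence[CultureSeries], path: str | Path) -> None:
    """Write series to CSV in the canonical column order.

    Floats are written with shortest round-tripping repr, so a
    read/write cycle reproduces every numeric field bit-for-bit.
    """
    frames = [s.to_frame() for s in series]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=COLUMNS)
    # shortest round-tripping repr, not pandas' default display formatting
    out.to_csv(path, index=False, columns=COLUMNS, float_format=lambda v: repr(float(v)))


def concentration_to_amount(conc_mM: float, volume_mL: float) -> float:
    """Convert a concentration (mM) in a known volume (mL) to µmol.

    mM x mL = µmol, e.g. 2.9 mM Fe(II) in a 20 mL bottle is 58 µmol.
    Accepts scalars or arrays in the concentration argument.
    """
    conc = np.asarray(conc_mM, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    if not volume_mL > 0:
        raise ValueError("volume must be > 0")
    out = conc * volume_mL
    return float(out) if out.ndim == 0 else out
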