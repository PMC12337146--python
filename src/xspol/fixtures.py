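"""Packaged reference tables and the default van-der-Waals radii.

The polarizability/mass tables ship as CSV exactly as printed in the
reference dataset, including one evidently misprinted experimental entry
(the 12-mer excess value 2450.6 Å³, flagged in the ``misprint`` column);
analyses must exclude or recompute that row explicitly, never silently
patch the fixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["FixtureTables", "load_tables", "load_radii", "DEFAULT_RADIUS_SCALE"]

#: Default scaling of base vdW radii for cavity construction (the common
#: continuum-solvation default for UFF radii).
DEFAULT_RADIUS_SCALE = 1.1


@dataclass(frozen=True)
class FixtureTables:
    """The four reference tables as DataFrames.

    ``table1``: water effective/energy-effective polarizabilities (Å³),
    computed and experimental (4 values).
    ``table3``: basis-set benchmark for the CT dimer and TAT trimer (Å³).
    ``table4``: 14 oligonucleotide energy-effective polarizabilities (Å³)
    versus molar mass (g/mol).
    ``table5``: 14 computed and experimental excess polarizabilities (Å³),
    with the misprint flag.
    """

    table1: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    table5: pd.DataFrame

    def water_values(self) -> dict:
        """Table 1 as a {quantity: value} mapping."""
        return dict(zip(self.table1["quantity"], self.table1["value"]))


def _read(name: str) -> pd.DataFrame:
    with resources.files("xspol.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_tables() -> FixtureTables:
    """Load the packaged reference tables."""
    t5 = _read("table5.csv")
    t5["misprint"] = t5["misprint"].astype(bool)
    tables = FixtureTables(
        table1=_read("table1.csv"),
        table3=_read("table3.csv"),
        table4=_read("table4.csv"),
        table5=t5,
    )
    if len(tables.table4) != 14 or len(tables.table5) != 14:
        raise ValueError("corrupt fixture: tables 4/5 must have 14 rows")
    return tables


def load_radii(scale: float = 1.0) -> dict:
    """Element → vdW radius (Å), UFF base values times ``scale``.

    Cavity construction conventionally applies ``DEFAULT_RADIUS_SCALE``
    on top of these base radii; ``load_radii`` itself returns unscaled
    values unless asked.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    df = _read("uff_radii.csv")
    return {el: float(r) * scale for el, r in zip(df["element"], df["radius"])}
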