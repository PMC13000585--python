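"""Shared physical constants and element tables.

Atomic masses follow the IUPAC standard atomic weights rounded to four
significant figures; van der Waals radii are the Bondi set. Both are
shipped as CSV data files so the provenance of every number used in
mass and steric calculations is inspectable.
"""

from __future__ import annotations

import csv
from importlib import resources

__all__ = ["ATOMIC_MASSES", "VDW_RADII"]


def _load_table(filename: str, value_col: str) -> dict[str, float]:
    ref = resources.files("phenoxscreen.data").joinpath(filename)
    with ref.open("r", encoding="utf-8") as fh:
        return {row["element"]: float(row[value_col]) for row in csv.DictReader(fh)}


#: Standard atomic weights, g/mol.
ATOMIC_MASSES: dict[str, float] = _load_table("atomic_masses.csv", "mass_g_mol")

#: Bondi van der Waals radii, Angstrom.
VDW_RADII: dict[str, float] = _load_table("vdw_radii.csv", "radius_angstrom")
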