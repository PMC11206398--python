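"""Curated reference data for the halogenated 4-anilinoquinazoline series.

The packaged CSV carries the literature-reported quantities for the
TKI-X series (X = H, F, Cl, Br, I; Cl is AG1478, Br is PD153035): measured
IC50 in nM, global-minimum and crystal-pose dipole moments, crystal strain
energies and populations, crystal-vs-minimum RMSDs, and the principal
absorption band (λmax, f) of the global minimum and the crystal pose. These
stand in for the upstream electronic-structure outputs, so the derived
columns (Δλmax, ln IC50, correlations) can be recomputed without any quantum
chemistry software.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import potency as _potency
from . import spectra as _spectra

__all__ = [
    "SUBSTITUENTS",
    "load_reference_table",
    "reference_descriptor_table",
    "reference_correlations",
]

SUBSTITUENTS = ("H", "F", "Cl", "Br", "I")


def load_reference_table() -> pd.DataFrame:
    """The raw packaged reference table, one row per substituent."""
    with resources.files(__package__).joinpath("data/tki_reference.csv").open() as fh:
        return pd.read_csv(fh)


def reference_descriptor_table() -> pd.DataFrame:
    """Descriptor table with Δλmax, shift class and ln IC50 recomputed.

    Only the raw inputs (λ pairs, IC50s, dipoles) are taken from the packaged
    file; every derived column is computed here through the package's own
    operations.
    """
    table = load_reference_table().copy()
    shifts = [
        _spectra.peak_shift(row.lambda_cal_nm, row.lambda_crystal_nm, row.substituent)
        for row in table.itertuples()
    ]
    table["delta_lambda_nm"] = [s.delta_lambda_nm for s in shifts]
    table["shift_class"] = [s.shift_class for s in shifts]
    table["ln_ic50"] = [_potency.ln_ic50(v) for v in table["ic50_nM"]]
    return table


def reference_correlations() -> dict:
    """Correlation block for the reference series.

    Returns dipole-vs-ln IC50 and Δλmax-vs-ln IC50 reports plus the
    blue-shift/potency separation summary.
    """
    table = reference_descriptor_table()
    return {
        "dipole_vs_ln_ic50": _potency.correlate(
            table["dipole_gm_D"], table["ln_ic50"]
        ),
        "delta_lambda_vs_ln_ic50": _potency.correlate(
            table["delta_lambda_nm"], table["ln_ic50"]
        ),
        "shift_potency": _potency.shift_potency_report(table),
    }
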