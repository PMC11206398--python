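"""Strain energies and Boltzmann conformer populations.

The strain energy (SE) of a conformer is its electronic energy above the
ensemble's global-minimum conformer, converted from hartree to kcal/mol.
Populations follow the degeneracy-weighted Boltzmann distribution

    p_i = g_i exp(-SE_i / RT) / sum_j g_j exp(-SE_j / RT)

with R = 0.0019872041 kcal mol^-1 K^-1 and T defaulting to room temperature
(298.15 K). Electronic energies are used directly — no zero-point or thermal
corrections are applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import softmax

from .ensembles import CompoundEnsemble
from .errors import ValidationError

__all__ = [
    "HARTREE_TO_KCAL_PER_MOL",
    "GAS_CONSTANT_KCAL",
    "ROOM_TEMPERATURE_K",
    "StrainTable",
    "strain_energies",
    "boltzmann_populations",
]

#: CODATA conversion factor, 1 hartree in kcal/mol.
HARTREE_TO_KCAL_PER_MOL = 627.509474

#: Molar gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 0.0019872041

ROOM_TEMPERATURE_K = 298.15


@dataclass(frozen=True)
class StrainTable:
    """Per-conformer strain energies, degeneracies and (optionally) populations.

    ``population_fractions`` is ``None`` until
    :func:`boltzmann_populations` has been applied.
    """

    labels: tuple[str, ...]
    strain_kcal: np.ndarray  # kcal/mol, >= 0, global minimum exactly 0
    degeneracies: np.ndarray  # positive integers
    temperature_K: Optional[float] = None
    population_fractions: Optional[np.ndarray] = None
    global_minimum_label: str = ""

    def __post_init__(self):
        se = np.asarray(self.strain_kcal, dtype=float)
        object.__setattr__(self, "strain_kcal", se)
        object.__setattr__(
            self, "degeneracies", np.asarray(self.degeneracies, dtype=int)
        )
        if np.any(se < 0):
            raise ValidationError("strain energies must be >= 0")
        if np.any(self.degeneracies < 1):
            raise ValidationError("degeneracies must be positive integers")
        if self.population_fractions is not None:
            p = np.asarray(self.population_fractions, dtype=float)
            object.__setattr__(self, "population_fractions", p)
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValidationError("population fractions must sum to 1 within 1e-9")

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: label, SE_kcal_mol and population_pct (3 decimals)."""
        frame = pd.DataFrame(
            {"label": self.labels, "SE_kcal_mol": self.strain_kcal}
        )
        if self.population_fractions is not None:
            frame["population_pct"] = np.round(
                100.0 * self.population_fractions, 3
            )
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    def population_of(self, label: str) -> float:
        if self.population_fractions is None:
            raise ValidationError("populations not computed yet")
        return float(self.population_fractions[self.labels.index(label)])


def strain_energies(ensemble: CompoundEnsemble) -> StrainTable:
    """Strain energy of every conformer relative to the ensemble global minimum.

    SE_i = (E_i - E_gm) * 627.509474 kcal/mol; the global minimum's entry is
    exactly 0. Raises if any conformer's energy is missing/non-finite, naming
    the offender.
    """
    gm = ensemble.global_minimum
    energies = []
    for c in ensemble.conformers:
        if c.total_energy is None or not np.isfinite(c.total_energy):
            raise ValidationError(
                f"conformer {c.label!r} has no usable total energy"
            )
        energies.append(c.total_energy)
    energies = np.asarray(energies, dtype=float)
    se = (energies - gm.total_energy) * HARTREE_TO_KCAL_PER_MOL
    if np.any(se < -1e-9):
        worst = ensemble.labels[int(np.argmin(se))]
        raise ValidationError(
            f"conformer {worst!r} lies below the tagged global minimum; "
            f"retag the ensemble"
        )
    se = np.maximum(se, 0.0)
    se[ensemble.labels.index(gm.label)] = 0.0
    return StrainTable(
        labels=tuple(ensemble.labels),
        strain_kcal=se,
        degeneracies=np.ones(len(se), dtype=int),
        global_minimum_label=gm.label,
    )


def boltzmann_populations(
    strain: StrainTable,
    temperature_K: float = ROOM_TEMPERATURE_K,
    degeneracies: Optional[Mapping[str, int]] = None,
) -> StrainTable:
    """Populate a strain table with Boltzmann fractions at ``temperature_K``.

    Fractions are computed with a numerically stable softmax so deep strain
    wells cannot underflow the normalization; they sum to 1 within 1e-9 for
    any input.
    """
    if temperature_K <= 0:
        raise ValidationError(f"temperature must be > 0 K, got {temperature_K}")
    if np.any(strain.strain_kcal < 0):
        raise ValidationError("strain energies must be >= 0")
    g = np.array(
        [
            (degeneracies or {}).get(label, int(d))
            for label, d in zip(strain.labels, strain.degeneracies)
        ],
        dtype=float,
    )
    if np.any(g < 1):
        raise ValidationError("degeneracies must be positive")
    log_weights = np.log(g) - strain.strain_kcal / (GAS_CONSTANT_KCAL * temperature_K)
    p = softmax(log_weights)
    p = p / p.sum()  # pin normalization to the 1e-9 invariant
    return StrainTable(
        labels=strain.labels,
        strain_kcal=strain.strain_kcal,
        degeneracies=g.astype(int),
        temperature_K=temperature_K,
        population_fractions=p,
        global_minimum_label=strain.global_minimum_label,
    )
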