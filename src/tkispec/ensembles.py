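"""Domain types for conformer ensembles of the halogenated TKI series.

A *compound ensemble* collects, for one X-substituted 4-anilinoquinazoline
inhibitor, its optimized conformers (one tagged as the global minimum, and
optionally a crystal-pose reference whose torsions were held fixed during
optimization), the excited-state stick spectrum of each structure, and the
measured IC50 potency in nM.

Energies are stored in hartree throughout; conversion to kcal/mol happens
only at API boundaries (see :mod:`tkispec.thermo`), which avoids precision
loss when energies are bookkept as offsets from a large integer base.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
from rdkit import Chem

from .errors import ValidationError

__all__ = [
    "Role",
    "Geometry",
    "ConformerRecord",
    "ExcitedState",
    "StickSpectrum",
    "CompoundEnsemble",
]

_PERIODIC_TABLE = Chem.GetPeriodicTable()


def is_valid_element(symbol: str) -> bool:
    """True if ``symbol`` names a periodic-table element (case-sensitive)."""
    try:
        return _PERIODIC_TABLE.GetAtomicNumber(symbol) > 0
    except Exception:
        return False


class Role(str, Enum):
    """Structural role of a conformer within its ensemble."""

    LOCAL_MINIMUM = "local_minimum"
    GLOBAL_MINIMUM = "global_minimum"
    CRYSTAL_REFERENCE = "crystal_reference"


@dataclass(frozen=True)
class Geometry:
    """An ordered molecular geometry: element symbols plus Cartesian Å coordinates."""

    symbols: tuple[str, ...]
    coords: np.ndarray  # shape (n_atoms, 3), Å

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if len(self.symbols) == 0:
            raise ValidationError("geometry must contain at least one atom")
        if coords.shape != (len(self.symbols), 3):
            raise ValidationError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.symbols)} atom symbols"
            )
        for i, sym in enumerate(self.symbols):
            if not is_valid_element(sym):
                raise ValidationError(f"unknown element symbol {sym!r} at atom {i}")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def heavy_indices(self) -> np.ndarray:
        """Indices of non-hydrogen atoms, in order."""
        return np.array([i for i, s in enumerate(self.symbols) if s != "H"], dtype=int)

    def atoms(self) -> list[tuple[str, float, float, float]]:
        """The geometry as an ordered list of (symbol, x, y, z) tuples."""
        return [
            (s, float(x), float(y), float(z))
            for s, (x, y, z) in zip(self.symbols, self.coords)
        ]

    def with_coords(self, coords: np.ndarray) -> "Geometry":
        return Geometry(self.symbols, np.asarray(coords, dtype=float))


@dataclass(frozen=True)
class ConformerRecord:
    """One optimized structure: label, electronic energy, dipole and geometry.

    Parameters
    ----------
    label : str
        Unique identifier within the ensemble.
    total_energy : float
        Total electronic energy in hartree.
    dipole_moment : float
        Dipole-moment magnitude in Debye (``>= 0``).
    geometry : Geometry
        Cartesian coordinates in Å.
    role_tag : Role
        ``local_minimum`` (default), ``global_minimum`` or
        ``crystal_reference``.
    """

    label: str
    total_energy: float
    dipole_moment: float
    geometry: Geometry
    role_tag: Role = Role.LOCAL_MINIMUM

    def __post_init__(self):
        if not self.label:
            raise ValidationError("conformer label must be non-empty")
        if self.dipole_moment < 0:
            raise ValidationError(
                f"conformer {self.label!r}: dipole_moment must be >= 0, "
                f"got {self.dipole_moment}"
            )
        object.__setattr__(self, "role_tag", Role(self.role_tag))


@dataclass(frozen=True)
class ExcitedState:
    """A single electronic excitation of a stick spectrum.

    ``transition_label`` and ``contribution_percent`` carry the dominant
    orbital transition (e.g. ``"HOMO->LUMO"``) and its percent weight when the
    upstream excited-state calculation reports them.
    """

    index: int
    wavelength_nm: float
    oscillator_strength: float
    transition_label: Optional[str] = None
    contribution_percent: Optional[float] = None

    def __post_init__(self):
        if self.index <= 0:
            raise ValidationError(f"state index must be positive, got {self.index}")
        if not np.isfinite(self.wavelength_nm) or self.wavelength_nm <= 0:
            raise ValidationError(
                f"state {self.index}: wavelength must be finite and positive, "
                f"got {self.wavelength_nm}"
            )
        if self.oscillator_strength < 0:
            raise ValidationError(
                f"state {self.index}: oscillator strength must be >= 0, "
                f"got {self.oscillator_strength}"
            )
        if self.contribution_percent is not None and not (
            0 <= self.contribution_percent <= 100
        ):
            raise ValidationError(
                f"state {self.index}: contribution_percent must lie in [0, 100]"
            )


@dataclass(frozen=True)
class StickSpectrum:
    """Ordered list of excitations belonging to one structure."""

    owner_label: str
    states: tuple[ExcitedState, ...]

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) == 0:
            raise ValidationError(
                f"stick spectrum for {self.owner_label!r} must contain >= 1 state"
            )

    def __len__(self) -> int:
        return len(self.states)

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array([s.wavelength_nm for s in self.states])

    @property
    def oscillator_strengths(self) -> np.ndarray:
        return np.array([s.oscillator_strength for s in self.states])


@dataclass(frozen=True)
class CompoundEnsemble:
    """All data for one compound: conformers, stick spectra and potency.

    Exactly one conformer must carry ``role_tag=global_minimum``; at most one
    may be the ``crystal_reference``. Stick spectra are keyed by conformer
    label, and every key must match an existing conformer.
    """

    substituent: str
    conformers: tuple[ConformerRecord, ...]
    stick_spectra: Mapping[str, StickSpectrum] = field(default_factory=dict)
    ic50_nM: Optional[float] = None
    atom_map: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "conformers", tuple(self.conformers))
        object.__setattr__(self, "stick_spectra", dict(self.stick_spectra))
        object.__setattr__(self, "atom_map", dict(self.atom_map))
        if len(self.conformers) == 0:
            raise ValidationError(
                f"ensemble {self.substituent!r} has no conformers"
            )
        labels = [c.label for c in self.conformers]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(
                f"ensemble {self.substituent!r}: duplicate conformer labels {dupes}"
            )
        n_global = sum(c.role_tag is Role.GLOBAL_MINIMUM for c in self.conformers)
        if n_global != 1:
            raise ValidationError(
                f"ensemble {self.substituent!r}: exactly one conformer must be "
                f"tagged global_minimum, found {n_global}"
            )
        n_crystal = sum(c.role_tag is Role.CRYSTAL_REFERENCE for c in self.conformers)
        if n_crystal > 1:
            raise ValidationError(
                f"ensemble {self.substituent!r}: at most one crystal_reference "
                f"allowed, found {n_crystal}"
            )
        for key in self.stick_spectra:
            if key not in labels:
                raise ValidationError(
                    f"ensemble {self.substituent!r}: stick spectrum key {key!r} "
                    f"matches no conformer label"
                )
        if self.ic50_nM is not None and self.ic50_nM <= 0:
            raise ValidationError(
                f"ensemble {self.substituent!r}: ic50_nM must be positive, "
                f"got {self.ic50_nM}"
            )

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.conformers]

    @property
    def global_minimum(self) -> ConformerRecord:
        return next(
            c for c in self.conformers if c.role_tag is Role.GLOBAL_MINIMUM
        )

    @property
    def crystal_reference(self) -> Optional[ConformerRecord]:
        for c in self.conformers:
            if c.role_tag is Role.CRYSTAL_REFERENCE:
                return c
        return None

    def conformer(self, label: str) -> ConformerRecord:
        for c in self.conformers:
            if c.label == label:
                return c
        raise KeyError(f"no conformer labelled {label!r}")

    def sticks_for(self, conformer: ConformerRecord | str) -> StickSpectrum:
        label = conformer if isinstance(conformer, str) else conformer.label
        try:
            return self.stick_spectra[label]
        except KeyError:
            raise KeyError(
                f"ensemble {self.substituent!r}: no stick spectrum for {label!r}"
            ) from None


def tag_global_minimum(
    conformers: Sequence[ConformerRecord],
) -> list[ConformerRecord]:
    """Tag the lowest-energy non-crystal conformer as the global minimum.

    Used when a manifest supplies no explicit role tags. Conformers already
    tagged are left untouched; if any conformer is already a global minimum
    the input is returned unchanged.
    """
    if any(c.role_tag is Role.GLOBAL_MINIMUM for c in conformers):
        return list(conformers)
    candidates = [
        (i, c)
        for i, c in enumerate(conformers)
        if c.role_tag is not Role.CRYSTAL_REFERENCE
    ]
    if not candidates:
        raise ValidationError("cannot tag a global minimum: all conformers are crystal references")
    i_min = min(candidates, key=lambda ic: ic[1].total_energy)[0]
    out = list(conformers)
    out[i_min] = replace(out[i_min], role_tag=Role.GLOBAL_MINIMUM)
    return out
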