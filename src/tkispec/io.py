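"""Readers and writers for XYZ geometries, stick tables and ensemble manifests.

Interchange formats are deliberately plain: standard XYZ for coordinates,
TSV or JSON for excited-state stick tables, YAML or JSON for the per-compound
manifest. All paths inside a manifest are resolved relative to the manifest
file's own directory.

Manifest schema (YAML)::

    substituent: Br
    ic50_nM: 0.025
    atom_map:            # optional named-atom table (anchors etc.)
      C1: 0
      C4: 3
      C10: 9
    conformers:
      - label: conf-1
        xyz: conf-1.xyz
        energy_hartree: -3507.379134
        dipole_D: 8.232
        role: global_minimum          # optional; lowest energy wins otherwise
        sticks: conf-1_sticks.tsv     # optional
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .ensembles import (
    CompoundEnsemble,
    ConformerRecord,
    ExcitedState,
    Geometry,
    Role,
    StickSpectrum,
    tag_global_minimum,
)
from .errors import ParseError, ValidationError

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_stick_table",
    "write_stick_table",
    "load_ensemble",
]

PathLike = Union[str, Path]


def read_xyz(path: PathLike) -> Geometry:
    """Read a standard XYZ file (count line, comment line, element x y z rows).

    Raises
    ------
    ParseError
        If the count line is malformed or disagrees with the number of
        coordinate rows.
    ValidationError
        If an element symbol is not on the periodic table.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        declared = int(lines[0].strip())
    except ValueError:
        raise ParseError(
            f"{path}, line 1: expected an atom count, got {lines[0]!r}"
        ) from None
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != declared:
        raise ParseError(
            f"{path}: declared atom count {declared} but found {len(body)} "
            f"coordinate rows"
        )
    symbols: list[str] = []
    coords = np.empty((declared, 3))
    for i, ln in enumerate(body):
        parts = ln.split()
        if len(parts) < 4:
            raise ParseError(f"{path}, atom row {i + 1}: expected 'El x y z', got {ln!r}")
        symbols.append(parts[0])
        try:
            coords[i] = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ParseError(
                f"{path}, atom row {i + 1}: non-numeric coordinate in {ln!r}"
            ) from None
    return Geometry(tuple(symbols), coords)


def write_xyz(geometry: Geometry, path: PathLike, comment: str = "") -> None:
    """Write a geometry as standard XYZ with 6-decimal coordinates."""
    path = Path(path)
    lines = [str(len(geometry)), comment.replace("\n", " ")]
    for sym, (x, y, z) in zip(geometry.symbols, geometry.coords):
        lines.append(f"{sym:<3s} {x:14.6f} {y:14.6f} {z:14.6f}")
    path.write_text("\n".join(lines) + "\n")


_STICK_COLUMNS = {"state", "wavelength_nm", "f"}


def read_stick_table(path: PathLike, owner_label: Optional[str] = None) -> StickSpectrum:
    """Read an excited-state stick table from TSV or JSON.

    TSV requires header columns ``state``, ``wavelength_nm``, ``f`` and
    accepts optional ``label`` and ``percent`` columns; JSON is a list of
    objects with the same keys.
    """
    path = Path(path)
    owner = owner_label if owner_label is not None else path.stem
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise ParseError(f"{path}: JSON stick table must be a list of objects")
        frame = pd.DataFrame.from_records(records)
    else:
        frame = pd.read_csv(path, sep="\t")
    if frame.empty:
        raise ValidationError(f"{path}: empty stick table")
    missing = _STICK_COLUMNS - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing stick-table columns {sorted(missing)}")
    states = []
    for _, row in frame.iterrows():
        label = row.get("label")
        percent = row.get("percent")
        states.append(
            ExcitedState(
                index=int(row["state"]),
                wavelength_nm=float(row["wavelength_nm"]),
                oscillator_strength=float(row["f"]),
                transition_label=None if pd.isna(label) else str(label),
                contribution_percent=None if pd.isna(percent) else float(percent),
            )
        )
    return StickSpectrum(owner_label=owner, states=tuple(states))


def write_stick_table(spectrum: StickSpectrum, path: PathLike) -> None:
    """Write a stick spectrum as a TSV table (round-trips read_stick_table)."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "state": [s.index for s in spectrum.states],
            "wavelength_nm": [s.wavelength_nm for s in spectrum.states],
            "f": [s.oscillator_strength for s in spectrum.states],
            "label": [s.transition_label for s in spectrum.states],
            "percent": [s.contribution_percent for s in spectrum.states],
        }
    )
    if frame["label"].isna().all() and frame["percent"].isna().all():
        frame = frame.drop(columns=["label", "percent"])
    frame.to_csv(path, sep="\t", index=False)


def load_ensemble(manifest: PathLike) -> CompoundEnsemble:
    """Load a fully validated :class:`CompoundEnsemble` from a manifest file.

    If no conformer carries an explicit ``role: global_minimum``, the
    lowest-energy non-crystal conformer is tagged. Duplicate labels or two
    global-minimum tags raise :class:`ValidationError`; the output always
    contains exactly as many conformers as the manifest lists.
    """
    manifest = Path(manifest)
    base = manifest.parent
    text = manifest.read_text()
    if manifest.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "conformers" not in doc:
        raise ParseError(f"{manifest}: manifest must be a mapping with a 'conformers' list")

    conformers: list[ConformerRecord] = []
    sticks: dict[str, StickSpectrum] = {}
    for entry in doc["conformers"]:
        try:
            label = str(entry["label"])
            geometry = read_xyz(base / entry["xyz"])
            record = ConformerRecord(
                label=label,
                total_energy=float(entry["energy_hartree"]),
                dipole_moment=float(entry["dipole_D"]),
                geometry=geometry,
                role_tag=Role(entry.get("role", Role.LOCAL_MINIMUM)),
            )
        except KeyError as exc:
            raise ParseError(f"{manifest}: conformer entry missing key {exc}") from None
        conformers.append(record)
        if "sticks" in entry:
            sticks[label] = read_stick_table(base / entry["sticks"], owner_label=label)

    n_global = sum(c.role_tag is Role.GLOBAL_MINIMUM for c in conformers)
    if n_global > 1:
        raise ValidationError(f"{manifest}: more than one conformer tagged global_minimum")
    if n_global == 0:
        conformers = tag_global_minimum(conformers)

    ic50 = doc.get("ic50_nM")
    return CompoundEnsemble(
        substituent=str(doc.get("substituent", manifest.stem)),
        conformers=tuple(conformers),
        stick_spectra=sticks,
        ic50_nM=None if ic50 is None else float(ic50),
        atom_map={str(k): int(v) for k, v in (doc.get("atom_map") or {}).items()},
    )
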