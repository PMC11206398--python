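import numpy as np
import pytest

from tkispec import (
    CompoundEnsemble,
    ConformerRecord,
    ExcitedState,
    Geometry,
    Role,
    StickSpectrum,
)

WATER_XYZ = """3
water
O   0.000000   0.000000   0.117300
H   0.000000   0.757200  -0.469200
H   0.000000  -0.757200  -0.469200
"""


@pytest.fixture
def water_xyz_file(tmp_path):
    path = tmp_path / "water.xyz"
    path.write_text(WATER_XYZ)
    return path


@pytest.fixture
def toy_geometry():
    """Asymmetric 4-point heavy-atom set (non-planar, non-collinear)."""
    return Geometry(
        ("C", "N", "O", "C"),
        np.array(
            [
                [0.0, 0.0, 0.0],
                [1.5, 0.0, 0.0],
                [0.3, 1.2, 0.0],
                [0.2, 0.4, 1.1],
            ]
        ),
    )


def make_stick(pairs, owner="test"):
    """Build a StickSpectrum from (wavelength, f) pairs."""
    states = tuple(
        ExcitedState(index=i + 1, wavelength_nm=w, oscillator_strength=f)
        for i, (w, f) in enumerate(pairs)
    )
    return StickSpectrum(owner_label=owner, states=states)


def make_ensemble(energies, substituent="X", with_crystal=None, dipoles=None, geometry=None):
    """Ensemble of point-geometry conformers with the given hartree energies.

    ``with_crystal`` optionally names one label to tag as crystal_reference;
    the lowest-energy remaining conformer becomes the global minimum.
    """
    if geometry is None:
        geometry = Geometry(
            ("C", "C", "C"),
            np.array([[0.0, 0.0, 0.0], [1.4, 0.0, 0.0], [0.7, 1.2, 0.0]]),
        )
    labels = [f"c{i}" for i in range(len(energies))]
    eligible = [i for i, lbl in enumerate(labels) if lbl != with_crystal]
    gm_idx = min(eligible, key=lambda i: energies[i])
    records = []
    for i, (lbl, e) in enumerate(zip(labels, energies)):
        if with_crystal == lbl:
            role = Role.CRYSTAL_REFERENCE
        elif i == gm_idx:
            role = Role.GLOBAL_MINIMUM
        else:
            role = Role.LOCAL_MINIMUM
        records.append(
            ConformerRecord(
                label=lbl,
                total_energy=e,
                dipole_moment=1.0 if dipoles is None else dipoles[i],
                geometry=geometry,
                role_tag=role,
            )
        )
    return CompoundEnsemble(substituent=substituent, conformers=tuple(records))
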